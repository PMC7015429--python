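"""Shared machinery for steady-state allocation of a conserved resource.

Both the translation model (ribosomes over mRNA pools) and the
transcription model (RNA polymerases over gene classes) reduce to the same
scalar conservation law for the free resource R:

    R + sum_i load_i * R / (K_i + R) * amount_i  =  total

with per-class occupancy following a hyperbolic (Michaelis/Langmuir) form.
The left side is strictly increasing in R, so the root on (0, total] is
unique; a vectorized bisection handles whole populations at once.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ValidationError

#: relative tolerance of the free-resource root
DEFAULT_RTOL = 1e-12


def _validate_finite_nonneg(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    if np.any(arr < 0):
        raise ValidationError(f"{name} must be non-negative, got {value!r}")


def solve_free_resource(loads, affinities, amounts, total, rtol=DEFAULT_RTOL):
    """Unique root R of ``R + sum_i loads_i*R/(K_i+R)*amounts_i = total``.

    Parameters are broadcast: ``loads``/``affinities`` have shape (k,) and
    ``amounts`` may be (k,) for a single cell or (k, n) for a population;
    ``total`` is scalar or (n,).  Returns a scalar or an (n,) array.

    The conservation function is strictly increasing in R with f(0) < 0 and
    f(total) >= 0, so plain bisection on [0, total] converges
    unconditionally; iterations are chosen so the final bracket is below
    ``rtol`` relative to the root.
    """
    loads = np.atleast_1d(np.asarray(loads, dtype=float))
    affinities = np.atleast_1d(np.asarray(affinities, dtype=float))
    amounts = np.asarray(amounts, dtype=float)
    total_arr = np.asarray(total, dtype=float)

    _validate_finite_nonneg("loads", loads)
    _validate_finite_nonneg("amounts", amounts)
    if not np.all(np.isfinite(affinities)) or np.any(affinities <= 0):
        raise ValidationError(f"affinities must be finite and > 0, got {affinities!r}")
    if not np.all(np.isfinite(total_arr)) or np.any(total_arr <= 0):
        raise ValidationError(f"total resource must be finite and > 0, got {total!r}")

    scalar_cell = amounts.ndim == 1 and total_arr.ndim == 0
    if amounts.ndim == 1:
        amounts = amounts[:, None]
    k = loads.shape[0]
    if amounts.shape[0] != k:
        raise ValidationError(
            f"amounts first axis ({amounts.shape[0]}) must match number of classes ({k})"
        )

    loads_c = loads[:, None]
    aff_c = affinities[:, None]
    total_b = np.broadcast_to(total_arr, np.broadcast_shapes(total_arr.shape, amounts.shape[1:])).astype(float)

    def f(R):
        # R has shape (n,); occupancy term summed over classes
        return R + np.sum(loads_c * R / (aff_c + R) * amounts, axis=0) - total_b

    lo = np.zeros_like(total_b)
    hi = total_b.copy()
    # no sequestration at all -> root is exactly `total`
    demand = np.sum(loads_c * amounts, axis=0)
    trivial = demand == 0.0

    # iterations: bracket width total * 2^-m must fall below rtol * root;
    # the root is >= total / (1 + sum load*amount / K) which bounds m.
    with np.errstate(divide="ignore"):
        root_lower = total_b / (1.0 + np.sum(loads_c * amounts / aff_c, axis=0))
    worst_ratio = float(np.max(total_b / np.maximum(root_lower, np.finfo(float).tiny)))
    n_iter = int(np.ceil(np.log2(max(worst_ratio, 1.0) / rtol))) + 2
    n_iter = min(max(n_iter, 48), 200)

    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        high_side = f(mid) > 0.0
        hi = np.where(high_side, mid, hi)
        lo = np.where(high_side, lo, mid)
    root = 0.5 * (lo + hi)

    # one Newton polish (f' >= 1 everywhere, safe) to kill the last bits
    fp = 1.0 + np.sum(loads_c * aff_c * amounts / (aff_c + root) ** 2, axis=0)
    root = np.clip(root - f(root) / fp, 0.0, total_b)
    root = np.where(trivial, total_b, root)

    if scalar_cell:
        return float(root[0]) if root.ndim else float(root)
    return root


def occupancy_jacobian(loads, affinities, amounts, total, R):
    """Partials of the free resource and of the per-class bound amounts.

    Implicit differentiation of the conservation law at the solved root R.
    With g_i(R) = load_i * R / (K_i + R) and g_i'(R) = load_i*K_i/(K_i+R)^2:

        dR/d(amount_j) = -g_j / D,    dR/d(total) = 1 / D,
        D = 1 + sum_i amount_i * g_i'(R)

    and bound_i = g_i(R) * amount_i chains through.

    Returns ``(dR, J)`` where ``dR`` is length k+1 (partials of R w.r.t. the
    k amounts then total) and ``J`` is (k, k+1): row i holds the partials of
    bound_i w.r.t. the k amounts then total.
    """
    loads = np.atleast_1d(np.asarray(loads, dtype=float))
    affinities = np.atleast_1d(np.asarray(affinities, dtype=float))
    amounts = np.atleast_1d(np.asarray(amounts, dtype=float))
    k = loads.shape[0]

    g = loads * R / (affinities + R)
    gp = loads * affinities / (affinities + R) ** 2
    D = 1.0 + np.sum(amounts * gp)

    dR = np.empty(k + 1)
    dR[:k] = -g / D
    dR[k] = 1.0 / D

    J = np.outer(amounts * gp, dR)
    J[np.arange(k), np.arange(k)] += g
    return dR, J
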