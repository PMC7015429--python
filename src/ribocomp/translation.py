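"""Coarse-grained steady state of ribosome allocation between two mRNA pools.

A heterologous module (subscript 1, e.g. an inducible burden gene on a
plasmid) and an endogenous module (subscript 2, e.g. a constitutive
chromosomal reporter) compete for a conserved pool of ribosomes. In a cell
with total mRNA pools M1T, M2T and total ribosomes RibT, the free-ribosome
count RibF satisfies the conservation law

    RibT = RibF + n1*RibF/(beta1+RibF)*M1T + n2*RibF/(beta2+RibF)*M2T,

where n_i is the mean number of ribosomes loaded per mRNA at saturation and
beta_i the ribosome-mRNA dissociation constant (free ribosomes at
half-maximal loading; small beta = strong capture). Steady-state protein
output P_i is proportional to the ribosomes sequestered by module i,
P_i = c_i * bound_i, with arbitrary-unit gains c_i that cancel in every
downstream correlation.

The left side is strictly monotone in RibF, so the steady state is unique;
sensitivities come from implicit differentiation rather than numerical
perturbation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._allocation import DEFAULT_RTOL, occupancy_jacobian, solve_free_resource
from .exceptions import ValidationError

# Default kinetics and operating point. The within-cell loading/affinity
# constants are calibrated so the model reproduces the qualitative behavior
# of the two-reporter E. coli system this package emulates: positive
# P1-P2 correlation at moderate input variability that reverses when
# heterologous-input variability dominates, and correlation increasing with
# mean burden beyond ~100 mRNAs (see docs/methods.md).
DEFAULT_N = 10.0
DEFAULT_BETA = 1000.0
DEFAULT_MEAN_M1T = 300.0
DEFAULT_MEAN_M2T = 900.0
DEFAULT_MEAN_RIBT = 10_000.0


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class KineticParams:
    """Per-module translation kinetics.

    n1, n2 : mean ribosomes loaded per mRNA at saturation (> 0, or 0 to
        silence a module); beta1, beta2 : dissociation constants in
        molecules/cell (> 0); c1, c2 : output gains in arbitrary units per
        bound ribosome (>= 0, default 1 — they rescale P linearly and cancel
        in correlations).
    """

    n1: float = DEFAULT_N
    n2: float = DEFAULT_N
    beta1: float = DEFAULT_BETA
    beta2: float = DEFAULT_BETA
    c1: float = 1.0
    c2: float = 1.0

    def __post_init__(self):
        for name in ("n1", "n2", "beta1", "beta2", "c1", "c2"):
            v = getattr(self, name)
            _require(math.isfinite(v), f"{name} must be finite, got {v}")
        _require(self.n1 >= 0 and self.n2 >= 0, "loading numbers n_i must be >= 0")
        _require(self.beta1 > 0 and self.beta2 > 0, "dissociation constants beta_i must be > 0")
        _require(self.c1 >= 0 and self.c2 >= 0, "gains c_i must be >= 0")

    @classmethod
    def from_rates(cls, beta1_plus, beta1_minus, beta2_plus, beta2_minus, **kw):
        """Build from binding/unbinding rate constants, beta_i = k-_i / k+_i."""
        return cls(beta1=beta1_minus / beta1_plus, beta2=beta2_minus / beta2_plus, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        d = dict(d)
        if "beta1_plus" in d:
            return cls.from_rates(
                d.pop("beta1_plus"), d.pop("beta1_minus"),
                d.pop("beta2_plus"), d.pop("beta2_minus"), **d,
            )
        return cls(**d)


@dataclass(frozen=True)
class CellInputs:
    """Heterogeneous per-cell inputs: total mRNA pools and total ribosomes."""

    M1T: float = DEFAULT_MEAN_M1T
    M2T: float = DEFAULT_MEAN_M2T
    RibT: float = DEFAULT_MEAN_RIBT

    def __post_init__(self):
        for name in ("M1T", "M2T", "RibT"):
            v = getattr(self, name)
            _require(math.isfinite(v), f"{name} must be finite, got {v}")
        _require(self.M1T >= 0 and self.M2T >= 0, "mRNA totals must be >= 0")
        _require(self.RibT > 0, "total ribosomes must be > 0")


@dataclass(frozen=True)
class SteadyState:
    RibF: float
    bound1: float
    bound2: float
    P1: float
    P2: float
    free_fraction: float


@dataclass(frozen=True)
class SensitivityMatrix:
    """Analytic Jacobian of the steady state at a given cell.

    ``J`` is 2x3: rows (P1, P2), columns (M1T, M2T, RibT). The free-ribosome
    partials most relevant to competition are exposed directly.
    """

    J: np.ndarray
    dRibF_dM1T: float
    dRibF_dM2T: float
    dRibF_dRibT: float

    @property
    def dP1_dM1T(self): return float(self.J[0, 0])
    @property
    def dP1_dM2T(self): return float(self.J[0, 1])
    @property
    def dP1_dRibT(self): return float(self.J[0, 2])
    @property
    def dP2_dM1T(self): return float(self.J[1, 0])
    @property
    def dP2_dM2T(self): return float(self.J[1, 1])
    @property
    def dP2_dRibT(self): return float(self.J[1, 2])


def solve_free_ribosome(kinetics: KineticParams, cell: CellInputs,
                        rtol: float = DEFAULT_RTOL) -> float:
    """Free-ribosome count RibF solving the conservation law for one cell."""
    if cell.M1T * kinetics.n1 == 0.0 and cell.M2T * kinetics.n2 == 0.0:
        return cell.RibT  # nothing sequesters ribosomes
    return solve_free_resource(
        [kinetics.n1, kinetics.n2],
        [kinetics.beta1, kinetics.beta2],
        [cell.M1T, cell.M2T],
        cell.RibT,
        rtol=rtol,
    )


def steady_state(kinetics: KineticParams, cell: CellInputs,
                 rtol: float = DEFAULT_RTOL) -> SteadyState:
    """Full steady state: free ribosomes, per-module bound ribosomes, proteins."""
    R = solve_free_ribosome(kinetics, cell, rtol=rtol)
    bound1 = kinetics.n1 * R / (kinetics.beta1 + R) * cell.M1T
    bound2 = kinetics.n2 * R / (kinetics.beta2 + R) * cell.M2T
    return SteadyState(
        RibF=R,
        bound1=bound1,
        bound2=bound2,
        P1=kinetics.c1 * bound1,
        P2=kinetics.c2 * bound2,
        free_fraction=R / cell.RibT,
    )


def steady_state_population(kinetics: KineticParams, M1T, M2T, RibT,
                            rtol: float = DEFAULT_RTOL):
    """Vectorized steady state for arrays of per-cell inputs.

    Returns ``(RibF, P1, P2)`` arrays; used by the Monte Carlo machinery.
    """
    M1T = np.asarray(M1T, dtype=float)
    M2T = np.asarray(M2T, dtype=float)
    RibT = np.asarray(RibT, dtype=float)
    R = solve_free_resource(
        [kinetics.n1, kinetics.n2],
        [kinetics.beta1, kinetics.beta2],
        np.vstack([M1T, M2T]),
        RibT,
        rtol=rtol,
    )
    P1 = kinetics.c1 * kinetics.n1 * R / (kinetics.beta1 + R) * M1T
    P2 = kinetics.c2 * kinetics.n2 * R / (kinetics.beta2 + R) * M2T
    return R, P1, P2


def sensitivity_matrix(kinetics: KineticParams, cell: CellInputs,
                       rtol: float = DEFAULT_RTOL) -> SensitivityMatrix:
    """Analytic partials of (P1, P2) and RibF w.r.t. (M1T, M2T, RibT).

    Implicit differentiation of the conservation law gives

        dRibF/dM1T = -[n1 RibF/(beta1+RibF)] / D,   dRibF/dRibT = 1 / D,
        D = 1 + sum_i n_i beta_i M_iT / (beta_i + RibF)^2,

    and the chain rule yields the protein partials. Sign structure:
    dP2/dM1T <= 0 and dP1/dM2T <= 0 (competition), dP_i/dRibT >= 0 (shared
    resource), dP1/dM1T >= 0 (own input).
    """
    R = solve_free_ribosome(kinetics, cell, rtol=rtol)
    dR, Jb = occupancy_jacobian(
        [kinetics.n1, kinetics.n2],
        [kinetics.beta1, kinetics.beta2],
        [cell.M1T, cell.M2T],
        cell.RibT,
        R,
    )
    J = np.diag([kinetics.c1, kinetics.c2]) @ Jb
    return SensitivityMatrix(
        J=J, dRibF_dM1T=float(dR[0]), dRibF_dM2T=float(dR[1]), dRibF_dRibT=float(dR[2])
    )


def competition_strength(kinetics: KineticParams, cell: CellInputs) -> float:
    """dP2/dM1T at the cell's steady state (<= 0; more negative = stronger
    repression of the endogenous module by heterologous burden)."""
    return sensitivity_matrix(kinetics, cell).dP2_dM1T


def sweep_m1t(kinetics: KineticParams, m1t_grid, M2T=DEFAULT_MEAN_M2T,
              RibT=DEFAULT_MEAN_RIBT):
    """Steady-state table over a grid of heterologous mRNA totals.

    Columns: M1T, M2T, RibT, RibF, free_fraction, P1, P2.
    """
    import pandas as pd

    rows = []
    for m1 in np.asarray(m1t_grid, dtype=float):
        ss = steady_state(kinetics, CellInputs(M1T=m1, M2T=M2T, RibT=RibT))
        rows.append((m1, M2T, RibT, ss.RibF, ss.free_fraction, ss.P1, ss.P2))
    return pd.DataFrame(
        rows, columns=["M1T", "M2T", "RibT", "RibF", "free_fraction", "P1", "P2"]
    )
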