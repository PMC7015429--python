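"""RNA-polymerase allocation over three gene classes.

The transcription-level analogue of the ribosome model: heterologous genes
(class 1), endogenous protein-coding genes (class 2) and the rRNA/tRNA
machinery genes (class 3, a fixed deterministic sink) compete for a
conserved RNAP pool,

    RNAPT = RNAPF + sum_i m_i * RNAPF/(K_i+RNAPF) * D_iT,

with m_i the RNAPs engaged per gene copy, K_i the RNAP-promoter
dissociation constant and D_iT gene (or promoter-strength-equivalent)
copies. Steady-state mRNA output is M_i = a_i * m_i*RNAPF/(K_i+RNAPF)*D_iT.

Because realistic K_i (0.1-10) sit far below the free-RNAP pool, promoter
occupancy is near-saturated: mRNA output tracks promoter copies almost
proportionally, heterologous genes barely repress endogenous transcription,
and r(M1, M2) is inherited from the promoter-copy correlation rather than
shaped by competition — which is why the pooled-condition sign reversal
seen at the protein level does not arise at the mRNA level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from ._allocation import DEFAULT_RTOL, occupancy_jacobian, solve_free_resource
from .exceptions import UndefinedCorrelationError, ValidationError

RNAPT_RANGE = (4000.0, 12000.0)
K_RANGE = (0.1, 10.0)
#: heterologous copy numbers above this are outside the realistic regime
UNREALISTIC_D1T = 200.0


@dataclass(frozen=True)
class TranscriptionParams:
    """Kinetics of RNAP allocation.

    Defaults put the system in the biologically expected regime: class 3
    engages about half the polymerase pool at RNAPT = 8000 (rRNA/tRNA
    dominance; tunable, not a measured value) and promoter occupancy is
    nearly saturated.
    """

    m1: float = 5.0
    m2: float = 5.0
    m3: float = 80.0
    K1: float = 1.0
    K2: float = 1.0
    K3: float = 1.0
    a1: float = 1.0
    a2: float = 1.0
    a3: float = 1.0
    RNAPT: float = 8000.0

    def __post_init__(self):
        for name in ("m1", "m2", "m3", "K1", "K2", "K3", "a1", "a2", "a3", "RNAPT"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"{name} must be finite")
        if min(self.m1, self.m2, self.m3) < 0:
            raise ValidationError("engaged-RNAP numbers m_i must be >= 0")
        if min(self.K1, self.K2, self.K3) <= 0:
            raise ValidationError("dissociation constants K_i must be > 0")
        if min(self.a1, self.a2, self.a3) < 0:
            raise ValidationError("gains a_i must be >= 0")
        if self.RNAPT <= 0:
            raise ValidationError("RNAPT must be > 0")
        for name in ("K1", "K2", "K3"):
            v = getattr(self, name)
            if not K_RANGE[0] <= v <= K_RANGE[1]:
                warnings.warn(
                    f"{name}={v} outside the modeled range {K_RANGE}", stacklevel=2
                )
        if not RNAPT_RANGE[0] <= self.RNAPT <= RNAPT_RANGE[1]:
            warnings.warn(
                f"RNAPT={self.RNAPT} outside the modeled range {RNAPT_RANGE}",
                stacklevel=2,
            )

    @property
    def loads(self):
        return np.array([self.m1, self.m2, self.m3])

    @property
    def affinities(self):
        return np.array([self.K1, self.K2, self.K3])

    @property
    def gains(self):
        return np.array([self.a1, self.a2, self.a3])


@dataclass(frozen=True)
class GeneCopies:
    """Per-cell gene/promoter copies of the three classes."""

    D1T: float = 10.0
    D2T: float = 100.0
    D3T: float = 50.0

    def __post_init__(self):
        for name in ("D1T", "D2T", "D3T"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0")

    @property
    def values(self):
        return np.array([self.D1T, self.D2T, self.D3T])


@dataclass(frozen=True)
class PromoterMoments:
    """Population moments of the variable inputs (D1T, D2T, RNAPT).

    Class-3 copies are a fixed deterministic sink. ``rho_D1D2`` is the
    promoter-strength correlation inherited by the competing mRNAs.
    """

    mean_D1T: float = 10.0
    mean_D2T: float = 100.0
    cv2_D1T: float = 0.1
    cv2_D2T: float = 0.1
    mean_RNAPT: float = 8000.0
    cv2_RNAPT: float = 0.0
    rho_D1D2: float = 0.0
    D3T: float = 50.0

    def __post_init__(self):
        if min(self.mean_D1T, self.mean_D2T, self.mean_RNAPT) <= 0:
            raise ValidationError("means must be > 0")
        if min(self.cv2_D1T, self.cv2_D2T, self.cv2_RNAPT) < 0:
            raise ValidationError("CV^2 must be >= 0")
        if abs(self.rho_D1D2) > 1:
            raise ValidationError("rho_D1D2 must lie in [-1, 1]")
        if self.D3T < 0:
            raise ValidationError("D3T must be >= 0")


def solve_free_rnap(tx: TranscriptionParams, copies: GeneCopies,
                    rtol: float = DEFAULT_RTOL) -> float:
    if float(np.sum(tx.loads * copies.values)) == 0.0:
        return tx.RNAPT
    return solve_free_resource(tx.loads, tx.affinities, copies.values, tx.RNAPT, rtol=rtol)


def steady_state_mrna(tx: TranscriptionParams, copies: GeneCopies,
                      rtol: float = DEFAULT_RTOL) -> tuple[float, float, float]:
    """mRNA outputs (M1, M2, M3) at the allocation steady state."""
    R = solve_free_rnap(tx, copies, rtol=rtol)
    M = tx.gains * tx.loads * R / (tx.affinities + R) * copies.values
    return float(M[0]), float(M[1]), float(M[2])


def mrna_sensitivity(tx: TranscriptionParams, copies: GeneCopies) -> np.ndarray:
    """2x3 Jacobian of (M1, M2) w.r.t. (D1T, D2T, RNAPT); D3T held fixed."""
    R = solve_free_rnap(tx, copies)
    _, Jb = occupancy_jacobian(tx.loads, tx.affinities, copies.values, tx.RNAPT, R)
    # Jb rows: bound_i over (D1T, D2T, D3T, RNAPT); keep rows 1,2 and drop the
    # D3T column, then apply output gains
    J = Jb[:2][:, [0, 1, 3]]
    return np.diag([tx.a1, tx.a2]) @ J


@dataclass(frozen=True)
class RepressionScan:
    table: pd.DataFrame  # columns D1T, RNAPF, M1, M2
    max_relative_repression: float


def repression_scan(tx: TranscriptionParams, d1_grid=None,
                    copies: GeneCopies | None = None) -> RepressionScan:
    """Endogenous mRNA output M2 as heterologous copies D1T increase.

    Reports max over the grid of 1 - M2(D1T)/M2(0). Grids extending past
    ``UNREALISTIC_D1T`` copies trigger a warning.
    """
    base = copies or GeneCopies()
    grid = np.asarray(
        d1_grid if d1_grid is not None else np.arange(1.0, 101.0), dtype=float
    )
    if np.any(grid > UNREALISTIC_D1T):
        warnings.warn(
            f"D1T > {UNREALISTIC_D1T:g} is outside the realistic regime", stacklevel=2
        )
    _, m2_ref, _ = steady_state_mrna(
        tx, GeneCopies(D1T=0.0, D2T=base.D2T, D3T=base.D3T)
    )
    rows = []
    for d1 in grid:
        c = GeneCopies(D1T=float(d1), D2T=base.D2T, D3T=base.D3T)
        R = solve_free_rnap(tx, c)
        m1, m2, _ = steady_state_mrna(tx, c)
        rows.append((d1, R, m1, m2))
    table = pd.DataFrame(rows, columns=["D1T", "RNAPF", "M1", "M2"])
    max_rep = float(np.max(1.0 - table["M2"].to_numpy() / m2_ref))
    return RepressionScan(table=table, max_relative_repression=max_rep)


def mrna_correlation(tx: TranscriptionParams, pm: PromoterMoments,
                     mode: Literal["full", "reduced"] = "full") -> float:
    """Linearized Pearson r(M1, M2) over sources (D1T, D2T, RNAPT).

    ``reduced`` drops RNAPT variability (sources {D1T, D2T} only); ``full``
    keeps all three. The only input cross-correlation is rho_D1D2.
    """
    copies = GeneCopies(D1T=pm.mean_D1T, D2T=pm.mean_D2T, D3T=pm.D3T)
    J = mrna_sensitivity(tx, copies)
    means = np.array([pm.mean_D1T, pm.mean_D2T, pm.mean_RNAPT])
    cv2s = np.array([pm.cv2_D1T, pm.cv2_D2T, pm.cv2_RNAPT])
    if mode == "reduced":
        cv2s = cv2s.copy()
        cv2s[2] = 0.0
    elif mode != "full":
        raise ValidationError(f"mode must be 'full' or 'reduced', got {mode!r}")
    sd = np.sqrt(cv2s) * means
    corr = np.array([[1.0, pm.rho_D1D2, 0.0], [pm.rho_D1D2, 1.0, 0.0], [0.0, 0.0, 1.0]])
    S = corr * np.outer(sd, sd)
    C = J @ S @ J.T
    if C[0, 0] <= 0.0 or C[1, 1] <= 0.0:
        raise UndefinedCorrelationError("an mRNA output has zero propagated variance")
    return float(np.clip(C[0, 1] / np.sqrt(C[0, 0] * C[1, 1]), -1.0, 1.0))


# ---------------------------------------------------------------------------
# Cross-model comparison: repression at matched resource burden
# ---------------------------------------------------------------------------

def _bisect_scalar(f, lo, hi, tol=1e-10, iters=200):
    flo = f(lo)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if (f(mid) > 0) == (flo > 0):
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, abs(hi)):
            break
    return 0.5 * (lo + hi)


def matched_burden_repression(kinetics, tx: TranscriptionParams,
                              resource_fraction: float,
                              M2T: float | None = None,
                              RibT: float | None = None,
                              copies: GeneCopies | None = None) -> tuple[float, float]:
    """Relative repression of the endogenous output in both models when the
    heterologous module consumes the same fraction of the shared resource.

    Finds M1T (translation) and D1T (transcription) such that the
    heterologous module sequesters ``resource_fraction`` of the total pool,
    then returns ``(1 - P2/P2(0), 1 - M2/M2(0))``. At realistic parameters
    the translational repression exceeds the transcriptional one by orders
    of magnitude.
    """
    from . import translation as trn

    if not 0 < resource_fraction < 1:
        raise ValidationError("resource_fraction must lie in (0, 1)")
    M2T = trn.DEFAULT_MEAN_M2T if M2T is None else M2T
    RibT = trn.DEFAULT_MEAN_RIBT if RibT is None else RibT
    base = copies or GeneCopies()

    def trans_frac(m1):
        ss = trn.steady_state(kinetics, trn.CellInputs(M1T=m1, M2T=M2T, RibT=RibT))
        return ss.bound1 / RibT - resource_fraction

    def tx_frac(d1):
        c = GeneCopies(D1T=d1, D2T=base.D2T, D3T=base.D3T)
        R = solve_free_rnap(tx, c)
        engaged1 = tx.m1 * R / (tx.K1 + R) * d1
        return engaged1 / tx.RNAPT - resource_fraction

    # upper brackets: grow until the fraction is exceeded (or give up)
    hi_m1 = 10.0
    while trans_frac(hi_m1) < 0 and hi_m1 < 1e9:
        hi_m1 *= 2
    hi_d1 = 10.0
    while tx_frac(hi_d1) < 0 and hi_d1 < 1e9:
        hi_d1 *= 2
    if trans_frac(hi_m1) < 0 or tx_frac(hi_d1) < 0:
        raise ValidationError(
            f"resource fraction {resource_fraction} unattainable for these parameters"
        )
    m1_star = _bisect_scalar(trans_frac, 0.0, hi_m1)
    d1_star = _bisect_scalar(tx_frac, 0.0, hi_d1)

    p2_ref = trn.steady_state(kinetics, trn.CellInputs(M1T=0.0, M2T=M2T, RibT=RibT)).P2
    p2 = trn.steady_state(kinetics, trn.CellInputs(M1T=m1_star, M2T=M2T, RibT=RibT)).P2
    _, m2_ref, _ = steady_state_mrna(tx, GeneCopies(D1T=0.0, D2T=base.D2T, D3T=base.D3T))
    _, m2, _ = steady_state_mrna(tx, GeneCopies(D1T=d1_star, D2T=base.D2T, D3T=base.D3T))
    return float(1.0 - p2 / p2_ref), float(1.0 - m2 / m2_ref)
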