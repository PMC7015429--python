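"""Propagation of cell-to-cell input variation through the allocation model.

Treating (M1T, M2T, RibT) as random variables across cells (constant in
time within a cell), the protein outputs linearize around the population
mean as P ~= Pbar + J (X - Xbar), where J is the analytic sensitivity
matrix. The protein covariance follows by propagating the input covariance:

    Cov(P1,P2) = sum over input pairs of  J1a * J2b * Cov(Xa, Xb),

six distinct terms for three inputs (full mode). When only RibT and M1T
vary appreciably and inputs are uncorrelated this reduces to two terms,

    Cov(P1,P2) = dP1/dRibT*dP2/dRibT*Var(RibT) + dP1/dM1T*dP2/dM1T*Var(M1T),

with the resource term >= 0 (both outputs rise with more ribosomes) and the
competition term <= 0 (burden pulls P2 down while raising P1). Their tug of
war sets the sign of the single-cell protein correlation, and therefore
whether pooling induction conditions produces a Simpson-style sign reversal:
within a condition, input variability is modest and the resource term wins
(r > 0); merging conditions inflates Var(M1T) until the competition term
dominates (r < 0).

Module-level correlations are exact for the linearized model; Monte Carlo of
the full nonlinear steady state validates the linearization in the
small-noise limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import translation as tr
from ._sampling import correlated_lognormal
from .exceptions import UndefinedCorrelationError, ValidationError

Mode = Literal["reduced", "full"]


@dataclass(frozen=True)
class PopulationMoments:
    """Means, squared CVs and pairwise Pearson correlations of the inputs.

    Variability is CV^2 = Var/mean^2 throughout. The implied 3x3 input
    covariance matrix must be positive semidefinite.
    """

    mean_M1T: float = tr.DEFAULT_MEAN_M1T
    mean_M2T: float = tr.DEFAULT_MEAN_M2T
    mean_RibT: float = tr.DEFAULT_MEAN_RIBT
    cv2_M1T: float = 0.1
    cv2_M2T: float = 0.0
    cv2_RibT: float = 0.1
    rho_M1M2: float = 0.0
    rho_M1Rib: float = 0.0
    rho_M2Rib: float = 0.0

    def __post_init__(self):
        if min(self.mean_M1T, self.mean_M2T, self.mean_RibT) <= 0:
            raise ValidationError("population means must be > 0")
        if min(self.cv2_M1T, self.cv2_M2T, self.cv2_RibT) < 0:
            raise ValidationError("CV^2 must be >= 0")
        for name in ("rho_M1M2", "rho_M1Rib", "rho_M2Rib"):
            if abs(getattr(self, name)) > 1:
                raise ValidationError(f"{name} must lie in [-1, 1]")
        if np.min(np.linalg.eigvalsh(self.correlation_matrix())) < -1e-10:
            raise ValidationError("input correlation matrix is not positive semidefinite")

    @property
    def means(self) -> np.ndarray:
        return np.array([self.mean_M1T, self.mean_M2T, self.mean_RibT])

    @property
    def cv2s(self) -> np.ndarray:
        return np.array([self.cv2_M1T, self.cv2_M2T, self.cv2_RibT])

    def correlation_matrix(self) -> np.ndarray:
        r12, r1R, r2R = self.rho_M1M2, self.rho_M1Rib, self.rho_M2Rib
        return np.array([[1.0, r12, r1R], [r12, 1.0, r2R], [r1R, r2R, 1.0]])

    def covariance_matrix(self) -> np.ndarray:
        """3x3 input covariance in (M1T, M2T, RibT) order."""
        sd = np.sqrt(self.cv2s) * self.means
        return self.correlation_matrix() * np.outer(sd, sd)

    def mean_cell(self) -> tr.CellInputs:
        return tr.CellInputs(M1T=self.mean_M1T, M2T=self.mean_M2T, RibT=self.mean_RibT)


@dataclass(frozen=True)
class ConditionSeries:
    """Ordered induction conditions, each with its own population moments."""

    conditions: tuple[tuple[str, PopulationMoments], ...]

    def __post_init__(self):
        if len(self.conditions) < 1:
            raise ValidationError("at least one condition is required")
        labels = [lab for lab, _ in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValidationError("condition labels must be unique")

    def __len__(self):
        return len(self.conditions)

    def __iter__(self):
        return iter(self.conditions)


def default_condition_series(n_conditions: int = 7,
                             m1t_range: tuple[float, float] = (30.0, 1000.0),
                             base: PopulationMoments | None = None) -> ConditionSeries:
    """Induction series used throughout: mean heterologous mRNA log-spaced
    over ``m1t_range`` with shared within-condition moments (CV^2 = 0.1 for
    M1T and RibT, endogenous pool fixed)."""
    base = base or PopulationMoments()
    levels = np.geomspace(m1t_range[0], m1t_range[1], n_conditions)
    conds = tuple(
        (f"cond{k+1}", replace(base, mean_M1T=float(m))) for k, m in enumerate(levels)
    )
    return ConditionSeries(conds)


# ---------------------------------------------------------------------------
# Linearized covariance / correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReducedCovariance:
    total: float
    term_rib: float  # resource term, >= 0
    term_m1: float   # competition term, <= 0


def covariance_full(sens: tr.SensitivityMatrix, pop: PopulationMoments) -> float:
    """Six-term linearized Cov(P1, P2): three variance terms and three
    symmetrized cross-covariance terms over (M1T, M2T, RibT)."""
    J = sens.J
    S = pop.covariance_matrix()
    cov = 0.0
    for a in range(3):
        cov += J[0, a] * J[1, a] * S[a, a]
    for a in range(3):
        for b in range(a + 1, 3):
            cov += (J[0, a] * J[1, b] + J[1, a] * J[0, b]) * S[a, b]
    return float(cov)


def covariance_reduced(sens: tr.SensitivityMatrix, pop: PopulationMoments) -> ReducedCovariance:
    """Two-source approximation keeping only Var(RibT) and Var(M1T)."""
    var_m1 = pop.cv2_M1T * pop.mean_M1T ** 2
    var_rib = pop.cv2_RibT * pop.mean_RibT ** 2
    term_rib = sens.dP1_dRibT * sens.dP2_dRibT * var_rib
    term_m1 = sens.dP1_dM1T * sens.dP2_dM1T * var_m1
    return ReducedCovariance(total=term_rib + term_m1, term_rib=term_rib, term_m1=term_m1)


def _propagated_variances(sens: tr.SensitivityMatrix, pop: PopulationMoments,
                          mode: Mode) -> tuple[float, float]:
    J = sens.J
    if mode == "full":
        S = pop.covariance_matrix()
        v = J @ S @ J.T
        return float(v[0, 0]), float(v[1, 1])
    if mode == "reduced":
        var_m1 = pop.cv2_M1T * pop.mean_M1T ** 2
        var_rib = pop.cv2_RibT * pop.mean_RibT ** 2
        v1 = J[0, 0] ** 2 * var_m1 + J[0, 2] ** 2 * var_rib
        v2 = J[1, 0] ** 2 * var_m1 + J[1, 2] ** 2 * var_rib
        return float(v1), float(v2)
    raise ValidationError(f"mode must be 'reduced' or 'full', got {mode!r}")


def protein_correlation(kinetics: tr.KineticParams, pop: PopulationMoments,
                        mode: Mode = "reduced") -> float:
    """Linearized single-cell Pearson r(P1, P2) at the population mean.

    The variance of each protein in the denominator is propagated from the
    same source set as the covariance (reduced: {M1T, RibT}, uncorrelated;
    full: all three inputs with their cross-covariances), keeping numerator
    and denominator internally consistent.
    """
    sens = tr.sensitivity_matrix(kinetics, pop.mean_cell())
    if mode == "full":
        cov = covariance_full(sens, pop)
    else:
        cov = covariance_reduced(sens, pop).total
    v1, v2 = _propagated_variances(sens, pop, mode)
    if v1 <= 0.0 or v2 <= 0.0:
        raise UndefinedCorrelationError(
            "a protein output has zero propagated variance; r(P1,P2) is undefined"
        )
    r = cov / np.sqrt(v1 * v2)
    return float(np.clip(r, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Correlation surfaces (axes over means / variabilities / input correlation)
# ---------------------------------------------------------------------------

_SURFACE_AXES = ("mean_M1T", "mean_RibT", "cv2_M1T", "cv2_RibT", "cv2_M2T", "rho_M1M2")


@dataclass(frozen=True)
class CorrelationSurfaceSpec:
    """Grid specification for an r(P1, P2) surface.

    ``x_axis``/``y_axis`` name population-moment fields; all other moments
    are held at ``base``. The sensitivity matrix is recomputed wherever an
    axis moves a mean.
    """

    x_axis: str
    x_grid: Sequence[float]
    y_axis: str
    y_grid: Sequence[float]
    base: PopulationMoments = field(default_factory=PopulationMoments)
    mode: Mode = "reduced"

    def __post_init__(self):
        for ax in (self.x_axis, self.y_axis):
            if ax not in _SURFACE_AXES:
                raise ValidationError(f"axis {ax!r} not one of {_SURFACE_AXES}")
        if self.x_axis == self.y_axis:
            raise ValidationError("x and y axes must differ")
        for g in (self.x_grid, self.y_grid):
            arr = np.asarray(g, dtype=float)
            if arr.size < 1 or not np.all(np.isfinite(arr)):
                raise ValidationError("grids must be finite and non-empty")


def correlation_surface(kinetics: tr.KineticParams,
                        spec: CorrelationSurfaceSpec) -> pd.DataFrame:
    """Evaluate r(P1, P2) on the grid; tidy frame with columns
    (x_axis, y_axis, r)."""
    rows = []
    for yv in np.asarray(spec.y_grid, dtype=float):
        for xv in np.asarray(spec.x_grid, dtype=float):
            pop = replace(spec.base, **{spec.x_axis: float(xv), spec.y_axis: float(yv)})
            rows.append((xv, yv, protein_correlation(kinetics, pop, spec.mode)))
    return pd.DataFrame(rows, columns=[spec.x_axis, spec.y_axis, "r"])


# ---------------------------------------------------------------------------
# Monte Carlo of the full nonlinear model
# ---------------------------------------------------------------------------

def monte_carlo_population(kinetics: tr.KineticParams, pop: PopulationMoments,
                           n: int, seed) -> pd.DataFrame:
    """Sample ``n`` cells from the nonlinear model.

    Inputs are drawn from lognormal marginals (means/CV^2 from ``pop``)
    coupled by a calibrated Gaussian copula; each cell's steady state is
    solved exactly. ``seed`` may be an int or a numpy Generator. Columns:
    M1T, M2T, RibT, RibF, P1, P2.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = correlated_lognormal(pop.means, pop.cv2s, pop.correlation_matrix(), n, rng)
    RibF, P1, P2 = tr.steady_state_population(kinetics, X[:, 0], X[:, 1], X[:, 2])
    return pd.DataFrame(
        {"M1T": X[:, 0], "M2T": X[:, 1], "RibT": X[:, 2], "RibF": RibF, "P1": P1, "P2": P2}
    )


@dataclass(frozen=True)
class SimpsonScenarioResult:
    labels: tuple[str, ...]
    within_r: tuple[float, ...]
    merged_r: float
    table: pd.DataFrame  # per-cell rows with a 'condition' column


def simpson_scenario(kinetics: tr.KineticParams, series: ConditionSeries,
                     n_per_condition: int = 3000, seed=0) -> SimpsonScenarioResult:
    """Simulate every condition and contrast within-condition r with the r of
    the pooled population.

    Per-condition random streams are spawned deterministically from the
    master seed (seed sequence keyed by condition index), so adding
    conditions never perturbs earlier ones.
    """
    frames, labels, within = [], [], []
    for k, (label, pop) in enumerate(series):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), k]))
        df = monte_carlo_population(kinetics, pop, n_per_condition, rng)
        df.insert(0, "condition", label)
        frames.append(df)
        labels.append(label)
        within.append(float(np.corrcoef(df["P1"], df["P2"])[0, 1]))
    table = pd.concat(frames, ignore_index=True)
    merged = float(np.corrcoef(table["P1"], table["P2"])[0, 1])
    return SimpsonScenarioResult(
        labels=tuple(labels), within_r=tuple(within), merged_r=merged, table=table
    )
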