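"""Survival of a heterogeneous population under two antibiotics.

Each cell carries two resistance proteins (R1, R2) that independently
deactivate antibiotics A1 and A2. Protein levels are lognormal across cells
with a tunable Pearson correlation rho_R imposed through a Gaussian copula
— the correlation that, at the expression level, resource competition and
shared-resource variability jointly set. A cell survives dose (A1, A2) iff

    R1 >= gamma1 * A1  and  R2 >= gamma2 * A2,

a sharp independent-deactivation threshold (a smooth Hill-type kill
probability is available as a variant). Under the copula model the survival
probability has a closed form: the orthant probability of the latent
bivariate normal, used here as an analytic cross-check of the Monte Carlo.
Positive correlation concentrates jointly-high cells in the upper-right
tail, so at high symmetric doses survival rises with rho_R.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._sampling import (
    attainable_pearson_range,
    correlated_lognormal,
    latent_from_pearson,
    lognormal_mu,
    lognormal_sigma,
)
from .exceptions import ValidationError

#: default per-protein CV^2 — the variability floor of abundant proteins
DEFAULT_CV2 = 0.1


@dataclass(frozen=True)
class ResistanceScenario:
    """Lognormal resistance-protein population with target correlation.

    ``rho_R`` is the Pearson correlation of (R1, R2) in protein space; it is
    checked against the attainable range for the marginals at construction.
    ``gamma_i`` convert antibiotic dose to the protein threshold needed to
    survive it.
    """

    mean1: float = 100.0
    mean2: float = 100.0
    cv2_1: float = DEFAULT_CV2
    cv2_2: float = DEFAULT_CV2
    rho_R: float = 0.0
    gamma1: float = 1.0
    gamma2: float = 1.0

    def __post_init__(self):
        for name in ("mean1", "mean2", "cv2_1", "cv2_2", "rho_R", "gamma1", "gamma2"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        if self.mean1 <= 0 or self.mean2 <= 0:
            raise ValidationError("means must be > 0")
        if self.cv2_1 < 0 or self.cv2_2 < 0:
            raise ValidationError("CV^2 must be >= 0")
        if self.gamma1 <= 0 or self.gamma2 <= 0:
            raise ValidationError("kill coefficients gamma_i must be > 0")
        # raises CalibrationError (with the attainable range) if out of reach
        latent_from_pearson(self.rho_R, *self._sigmas())

    def _sigmas(self):
        return lognormal_sigma(self.cv2_1), lognormal_sigma(self.cv2_2)

    def latent_correlation(self) -> float:
        return latent_from_pearson(self.rho_R, *self._sigmas())

    def attainable_rho(self) -> tuple[float, float]:
        return attainable_pearson_range(*self._sigmas())

    def marginal_quantile(self, q: float, which: int = 1) -> float:
        """q-quantile of the R1 (which=1) or R2 (which=2) marginal."""
        mean, cv2 = (self.mean1, self.cv2_1) if which == 1 else (self.mean2, self.cv2_2)
        s = lognormal_sigma(cv2)
        return float(np.exp(lognormal_mu(mean, cv2) + s * stats.norm.ppf(q)))

    def dose_at_quantile(self, q: float, which: int = 1) -> float:
        """Dose whose survival threshold sits at the marginal's q-quantile."""
        gamma = self.gamma1 if which == 1 else self.gamma2
        return self.marginal_quantile(q, which) / gamma


@dataclass(frozen=True)
class SurvivalResult:
    rate: float
    n: int
    replicate_mean: float | None = None
    replicate_sd: float | None = None


def sample_resistance(scenario: ResistanceScenario, n: int, seed) -> pd.DataFrame:
    """Draw ``n`` cells of (R1, R2) from the calibrated copula model."""
    if n < 2:
        raise ValidationError("n must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    corr = np.array([[1.0, scenario.rho_R], [scenario.rho_R, 1.0]])
    X = correlated_lognormal(
        [scenario.mean1, scenario.mean2],
        [scenario.cv2_1, scenario.cv2_2],
        corr, n, rng,
    )
    return pd.DataFrame({"R1": X[:, 0], "R2": X[:, 1]})


def survival_rate(population: pd.DataFrame, A1: float, A2: float,
                  scenario: ResistanceScenario) -> SurvivalResult:
    """Fraction of cells surviving the dose pair under the threshold rule."""
    if A1 < 0 or A2 < 0:
        raise ValidationError("doses must be >= 0")
    if len(population) == 0:
        raise ValidationError("population is empty")
    alive = (population["R1"].to_numpy() >= scenario.gamma1 * A1) & (
        population["R2"].to_numpy() >= scenario.gamma2 * A2
    )
    return SurvivalResult(rate=float(np.mean(alive)), n=len(population))


def hill_survival_rate(population: pd.DataFrame, A1: float, A2: float,
                       scenario: ResistanceScenario, hill: float = 4.0,
                       seed=None) -> SurvivalResult:
    """Smooth variant: each antibiotic independently kills with probability
    1/(1 + (R/(gamma*A))^h), approaching the sharp threshold as h grows."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.ones(len(population))
    for col, gamma, A in (("R1", scenario.gamma1, A1), ("R2", scenario.gamma2, A2)):
        if A > 0:
            x = population[col].to_numpy() / (gamma * A)
            p *= x**hill / (1.0 + x**hill)
    alive = rng.random(len(population)) < p
    return SurvivalResult(rate=float(np.mean(alive)), n=len(population))


def analytic_survival(scenario: ResistanceScenario, A1: float, A2: float) -> float:
    """Closed-form survival under the copula model.

    P(R1 >= g1 A1, R2 >= g2 A2) is the upper-orthant probability of the
    latent bivariate normal, evaluated via the bivariate normal CDF at the
    negated standardized thresholds.
    """
    if A1 < 0 or A2 < 0:
        raise ValidationError("doses must be >= 0")
    s1, s2 = scenario._sigmas()

    def z(thresh, mean, cv2, s):
        if thresh <= 0:
            return -np.inf
        if s == 0.0:
            return -np.inf if mean >= thresh else np.inf
        return (np.log(thresh) - lognormal_mu(mean, cv2)) / s

    z1 = z(scenario.gamma1 * A1, scenario.mean1, scenario.cv2_1, s1)
    z2 = z(scenario.gamma2 * A2, scenario.mean2, scenario.cv2_2, s2)
    if np.isinf(z1) or np.isinf(z2):
        # at least one marginal is decided with certainty
        if z1 == np.inf or z2 == np.inf:
            return 0.0
        if z1 == -np.inf and z2 == -np.inf:
            return 1.0
        return float(stats.norm.sf(z2 if z1 == -np.inf else z1))
    rho_z = scenario.latent_correlation()
    bvn = stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, rho_z], [rho_z, 1.0]], allow_singular=True
    )
    # P(Z1 >= z1, Z2 >= z2) = CDF at (-z1, -z2) by central symmetry
    return float(bvn.cdf(np.array([-z1, -z2])))


def correlation_sweep(scenario: ResistanceScenario, rho_grid, A1: float, A2: float,
                      n: int = 10_000, replicates: int = 100, seed=0) -> pd.DataFrame:
    """Replicated survival across resistance correlations.

    For each rho in ``rho_grid``: ``replicates`` independent populations of
    ``n`` cells, each scored at dose (A1, A2). Columns: rho, mean_survival,
    sd_survival, analytic.
    """
    rows = []
    for i, rho in enumerate(np.asarray(rho_grid, dtype=float)):
        scen = ResistanceScenario(
            mean1=scenario.mean1, mean2=scenario.mean2,
            cv2_1=scenario.cv2_1, cv2_2=scenario.cv2_2,
            rho_R=float(rho), gamma1=scenario.gamma1, gamma2=scenario.gamma2,
        )
        rates = np.empty(replicates)
        for rep in range(replicates):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), i, rep]))
            pop = sample_resistance(scen, n, rng)
            rates[rep] = survival_rate(pop, A1, A2, scen).rate
        rows.append(
            (rho, float(np.mean(rates)), float(np.std(rates, ddof=1)),
             analytic_survival(scen, A1, A2))
        )
    return pd.DataFrame(rows, columns=["rho", "mean_survival", "sd_survival", "analytic"])


def survival_grid(scenario: ResistanceScenario, a1_grid, a2_grid,
                  n: int = 100_000, seed=0) -> pd.DataFrame:
    """Dose-response matrix: survival at every (A1, A2) pair from a single
    simulated population. Index = A1 grid, columns = A2 grid."""
    rng = np.random.default_rng(seed)
    pop = sample_resistance(scenario, n, rng)
    a1 = np.asarray(a1_grid, dtype=float)
    a2 = np.asarray(a2_grid, dtype=float)
    r1 = pop["R1"].to_numpy()
    r2 = pop["R2"].to_numpy()
    mat = np.empty((a1.size, a2.size))
    for i, A1 in enumerate(a1):
        ok1 = r1 >= scenario.gamma1 * A1
        for j, A2 in enumerate(a2):
            mat[i, j] = np.mean(ok1 & (r2 >= scenario.gamma2 * A2))
    return pd.DataFrame(mat, index=a1, columns=a2)
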