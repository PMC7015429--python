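"""Synthetic single-cell measurement tables.

Two generators emulate the measurement layers of a two-reporter E. coli
experiment so the whole analysis pipeline is testable without any
experimental download:

* protein fluorescence — per-condition joint (channel1, channel2) levels
  produced by the mechanistic allocation model with lognormal cell-to-cell
  inputs, multiplicative lognormal measurement noise per channel and a small
  additive background;
* FISH mRNA intensities — integer transcript counts (Poisson for the
  constitutive gene; negative binomial for the induced, bursty one) times a
  noisy single-transcript unit intensity, scaled by a lognormal cell area,
  plus background, together with a pure-background negative-control sample
  for thresholding.

Latent truth columns (input draws, true copy numbers) are kept so recovery
can be scored exactly. The generators do not emulate pixel-level optics,
segmentation error, or temporal dynamics; see docs/methods.md for what that
implies about the scope of pipeline validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import translation as tr
from .exceptions import ValidationError
from .heterogeneity import ConditionSeries, default_condition_series, monte_carlo_population

#: pooled constitutive transcript rate, copies per cell
DEFAULT_CONSTITUTIVE_MEAN = 2.02


@dataclass(frozen=True)
class ProteinDatasetConfig:
    """Configuration of the protein-fluorescence generator.

    Channel 1 observes the heterologous protein P1, channel 2 the endogenous
    P2, each with multiplicative lognormal noise of CV ``noise_cv`` and an
    additive Gaussian background (truncated at 0) of ``background_frac``
    times the largest deterministic channel mean across conditions.
    """

    series: ConditionSeries = field(default_factory=default_condition_series)
    kinetics: tr.KineticParams = field(default_factory=tr.KineticParams)
    cells_per_condition: int = 3000
    noise_cv: float = 0.05
    background_frac: float = 0.02
    background_sd_frac: float = 0.25  # SD of the background, relative to its level
    area_cv2: float = 0.04
    keep_truth: bool = True

    def __post_init__(self):
        if self.cells_per_condition < 2:
            raise ValidationError("cells_per_condition must be >= 2")
        if self.noise_cv < 0 or self.background_frac < 0 or self.background_sd_frac < 0:
            raise ValidationError("noise and background parameters must be >= 0")
        if self.area_cv2 < 0:
            raise ValidationError("area_cv2 must be >= 0")


def _mult_noise(rng, cv, size):
    if cv == 0.0:
        return np.ones(size)
    s2 = np.log1p(cv * cv)
    return np.exp(rng.normal(-0.5 * s2, np.sqrt(s2), size))


def _area_draw(rng, cv2, size):
    if cv2 == 0.0:
        return np.ones(size)
    s2 = np.log1p(cv2)
    return np.exp(rng.normal(-0.5 * s2, np.sqrt(s2), size))


def generate_protein_dataset(cfg: ProteinDatasetConfig, seed=0) -> pd.DataFrame:
    """Simulate the full protein experiment across the induction series.

    Returns one row per cell with columns ``condition, area, channel1,
    channel2`` plus latent truth (``M1T, M2T, RibT, P1, P2``) when
    ``cfg.keep_truth``.
    """
    # deterministic channel means at each condition set the background scale
    det_p1, det_p2 = [], []
    for _, pop in cfg.series:
        ss = tr.steady_state(cfg.kinetics, pop.mean_cell())
        det_p1.append(ss.P1)
        det_p2.append(ss.P2)
    bg_level = (
        cfg.background_frac * max(max(det_p1), 1e-300),
        cfg.background_frac * max(max(det_p2), 1e-300),
    )

    frames = []
    for k, (label, pop) in enumerate(cfg.series):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), k]))
        cells = monte_carlo_population(cfg.kinetics, pop, cfg.cells_per_condition, rng)
        n = len(cells)
        area = _area_draw(rng, cfg.area_cv2, n)
        obs = {}
        for ch, (col, bg) in enumerate(zip(("P1", "P2"), bg_level), start=1):
            noisy = cells[col].to_numpy() * _mult_noise(rng, cfg.noise_cv, n)
            background = np.maximum(
                rng.normal(bg, cfg.background_sd_frac * bg if bg > 0 else 0.0, n), 0.0
            )
            obs[f"channel{ch}"] = noisy + background
        df = pd.DataFrame(
            {"condition": label, "area": area, **obs}
        )
        if cfg.keep_truth:
            for col in ("M1T", "M2T", "RibT", "P1", "P2"):
                df[col] = cells[col].to_numpy()
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class FishDatasetConfig:
    """Configuration of the FISH-like generator.

    Channel 1 carries the induced gene (negative-binomial counts whose mean
    rises along the induction series), channel 2 the constitutive gene
    (Poisson at ``constitutive_mean`` in every condition). Per-cell observed
    total intensity is ``(copies * unit * noise + background) * area`` so
    that area normalization downstream recovers the per-area density. The
    negative control draws pure background with the same area model.
    """

    n_conditions: int = 7
    cells_per_condition: int = 1000
    constitutive_mean: float = DEFAULT_CONSTITUTIVE_MEAN
    induced_means: tuple[float, ...] | None = None  # default geomspace 0.3..30
    induced_dispersion: float = 2.0
    unit_intensity: float = 100.0
    unit_cv: float = 0.05
    background_level: float = 10.0
    background_sd: float = 5.0
    area_cv2: float = 0.04
    rho_counts: float = 0.0  # optional weak cross-correlation of true counts
    n_negative_control: int = 1000
    keep_truth: bool = True

    def __post_init__(self):
        if self.cells_per_condition < 2 or self.n_negative_control < 2:
            raise ValidationError("need at least 2 cells per sample")
        if self.constitutive_mean < 0:
            raise ValidationError("constitutive mean must be >= 0")
        if self.induced_dispersion <= 0:
            raise ValidationError("NB dispersion must be > 0")
        if self.unit_intensity <= 0:
            raise ValidationError("unit intensity must be > 0")
        if min(self.unit_cv, self.background_level, self.background_sd, self.area_cv2) < 0:
            raise ValidationError("noise parameters must be >= 0")
        if abs(self.rho_counts) > 1:
            raise ValidationError("rho_counts must lie in [-1, 1]")
        if self.induced_means is not None and len(self.induced_means) != self.n_conditions:
            raise ValidationError("induced_means length must equal n_conditions")

    def induced_series(self) -> np.ndarray:
        if self.induced_means is not None:
            return np.asarray(self.induced_means, dtype=float)
        return np.geomspace(0.3, 30.0, self.n_conditions)


def _correlated_counts(rng, mean_nb, disp, mean_pois, rho, n):
    """Joint (NB, Poisson) counts, optionally coupled by a Gaussian copula."""
    if rho == 0.0:
        nb = rng.negative_binomial(disp, disp / (disp + mean_nb), n) if mean_nb > 0 else np.zeros(n, dtype=int)
        po = rng.poisson(mean_pois, n)
        return nb, po
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    u = stats.norm.cdf(z)
    nb = stats.nbinom.ppf(u[:, 0], disp, disp / (disp + mean_nb)).astype(int) if mean_nb > 0 else np.zeros(n, dtype=int)
    po = stats.poisson.ppf(u[:, 1], mean_pois).astype(int)
    return nb, po


def generate_fish_dataset(cfg: FishDatasetConfig, seed=0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the FISH experiment.

    Returns ``(cells, negative_control)``. ``cells`` has one row per cell:
    ``condition, area, channel1, channel2`` (+ ``copies1, copies2`` truth);
    the negative control has ``area, channel1, channel2`` of pure
    background.
    """
    induced = cfg.induced_series()
    frames = []
    for k in range(cfg.n_conditions):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101, k]))
        n = cfg.cells_per_condition
        c1, c2 = _correlated_counts(
            rng, float(induced[k]), cfg.induced_dispersion,
            cfg.constitutive_mean, cfg.rho_counts, n,
        )
        area = _area_draw(rng, cfg.area_cv2, n)
        df = {"condition": f"cond{k+1}", "area": area}
        for ch, copies in ((1, c1), (2, c2)):
            density = copies * cfg.unit_intensity * _mult_noise(rng, cfg.unit_cv, n)
            bg = np.maximum(rng.normal(cfg.background_level, cfg.background_sd, n), 0.0)
            df[f"channel{ch}"] = (density + bg) * area
        df = pd.DataFrame(df)
        if cfg.keep_truth:
            df["copies1"] = c1
            df["copies2"] = c2
        frames.append(df)
    cells = pd.concat(frames, ignore_index=True)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 999]))
    n0 = cfg.n_negative_control
    area0 = _area_draw(rng, cfg.area_cv2, n0)
    neg = pd.DataFrame(
        {
            "area": area0,
            "channel1": np.maximum(rng.normal(cfg.background_level, cfg.background_sd, n0), 0.0) * area0,
            "channel2": np.maximum(rng.normal(cfg.background_level, cfg.background_sd, n0), 0.0) * area0,
        }
    )
    return cells, neg
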