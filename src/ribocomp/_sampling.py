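"""Correlated lognormal sampling via a Gaussian copula.

Cell-to-cell inputs (mRNA pools, ribosome/RNAP totals, resistance protein
levels) are modelled as lognormal: strictly positive with the heavy right
tail typical of expression data. Marginals are parameterized by mean and
CV^2 (variance over squared mean); cross-correlations are imposed through a
latent multivariate normal. For lognormal marginals the Pearson correlation
in observation space has a closed form in the latent correlation,

    r = (exp(rho_z * s1 * s2) - 1) / sqrt((exp(s1^2)-1) * (exp(s2^2)-1)),

with s_i^2 = ln(1 + CV_i^2), so the copula is calibrated by exact inversion
rather than iteration. Setting rho_z = +/-1 gives the attainable (Frechet)
bounds for the requested marginals.
"""

from __future__ import annotations

import numpy as np

from .exceptions import CalibrationError, ValidationError


def lognormal_sigma(cv2: float) -> float:
    """Latent-normal sigma for a lognormal with squared CV ``cv2``."""
    if cv2 < 0:
        raise ValidationError(f"CV^2 must be >= 0, got {cv2}")
    return float(np.sqrt(np.log1p(cv2)))


def lognormal_mu(mean: float, cv2: float) -> float:
    if mean <= 0:
        raise ValidationError(f"lognormal mean must be > 0, got {mean}")
    return float(np.log(mean) - 0.5 * np.log1p(cv2))


def pearson_from_latent(rho_z: float, s1: float, s2: float) -> float:
    """Observation-space Pearson r of two lognormals with latent corr rho_z."""
    if s1 == 0.0 or s2 == 0.0:
        return 0.0
    num = np.expm1(rho_z * s1 * s2)
    den = np.sqrt(np.expm1(s1 * s1) * np.expm1(s2 * s2))
    return float(num / den)

def attainable_pearson_range(s1: float, s2: float) -> tuple[float, float]:
    return pearson_from_latent(-1.0, s1, s2), pearson_from_latent(1.0, s1, s2)


def latent_from_pearson(r: float, s1: float, s2: float) -> float:
    """Invert the lognormal correlation map; error if ``r`` is unattainable."""
    if abs(r) > 1:
        raise ValidationError(f"correlation must lie in [-1, 1], got {r}")
    if s1 == 0.0 or s2 == 0.0:
        if r != 0.0:
            raise CalibrationError(
                "cannot impose a nonzero correlation on a degenerate (CV^2=0) marginal"
            )
        return 0.0
    lo, hi = attainable_pearson_range(s1, s2)
    if not lo <= r <= hi:
        raise CalibrationError(
            f"Pearson r={r} is unattainable for these lognormal marginals; "
            f"attainable range is [{lo:.4f}, {hi:.4f}]"
        )
    rho_z = np.log1p(r * np.sqrt(np.expm1(s1 * s1) * np.expm1(s2 * s2))) / (s1 * s2)
    return float(np.clip(rho_z, -1.0, 1.0))


def correlated_lognormal(means, cv2s, pearson_corr, n, rng):
    """Draw ``n`` joint samples of correlated lognormal variables.

    Parameters
    ----------
    means, cv2s : sequences of length k
        Marginal means and squared CVs. A CV^2 of exactly 0 yields a
        degenerate (constant) column.
    pearson_corr : (k, k) array
        Target Pearson correlation matrix in observation space. Entries
        involving a degenerate marginal must be 0.
    n : int
        Number of samples (rows).
    rng : numpy.random.Generator

    Returns
    -------
    (n, k) ndarray
    """
    means = np.asarray(means, dtype=float)
    cv2s = np.asarray(cv2s, dtype=float)
    k = means.size
    corr = np.asarray(pearson_corr, dtype=float)
    if corr.shape != (k, k):
        raise ValidationError(f"correlation matrix must be ({k}, {k}), got {corr.shape}")
    if not np.allclose(corr, corr.T) or np.any(np.abs(corr) > 1 + 1e-12):
        raise ValidationError("correlation matrix must be symmetric with entries in [-1, 1]")

    sigmas = np.array([lognormal_sigma(c) for c in cv2s])
    mus = np.array([lognormal_mu(m, c) for m, c in zip(means, cv2s)])

    latent = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            latent[i, j] = latent[j, i] = latent_from_pearson(
                corr[i, j], sigmas[i], sigmas[j]
            )

    # PSD check of the calibrated latent matrix (tiny negative eigenvalues
    # from round-off are repaired; genuinely indefinite targets are rejected)
    w, V = np.linalg.eigh(latent)
    if np.min(w) < -1e-8:
        raise CalibrationError(
            "requested correlation structure has no Gaussian-copula representation "
            f"(latent matrix eigenvalue {np.min(w):.3e} < 0)"
        )
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    z = rng.standard_normal((n, k)) @ L.T
    return np.exp(mus + sigmas * z)
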