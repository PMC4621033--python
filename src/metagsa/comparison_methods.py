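"""Comparator methods: Wilcoxon GSA, simple p-pooling, pooled-GWAS GSA.

Three reference approaches against which META-GSA is benchmarked:

* ``wilcoxon_gsa`` -- the per-study competitive gene-set test: a one-sided
  Wilcoxon rank-sum test of whether the marker/gene p-values of the set
  are stochastically smaller than those of the complementary genes.
* ``spp`` -- simple p-pooling: the unweighted Fisher inverse chi-square
  combination of the per-study GSA p-values, referred to chi-square with
  2 * n_s degrees of freedom.
* ``pooled_gwas_gsa`` -- first a DerSimonian-Laird random-effects
  meta-analysis of each marker's log odds ratio across studies, then a
  single Wilcoxon GSA on the pooled two-sided p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, mannwhitneyu, norm

__all__ = [
    "GsaResult",
    "RandomEffectsResult",
    "wilcoxon_gsa",
    "spp",
    "random_effects_meta",
    "pooled_gwas_gsa",
]


@dataclass(frozen=True)
class GsaResult:
    """One-sided gene-set analysis result for one (possibly pooled) study."""

    es: float
    p: float
    flagged: bool = False


@dataclass(frozen=True)
class RandomEffectsResult:
    """DerSimonian-Laird random-effects pooled estimate."""

    theta: float
    se: float
    p: float
    tau2: float
    q: float
    k: int


def wilcoxon_gsa(gs_values, comp_values) -> GsaResult:
    """One-sided Wilcoxon rank-sum test for enrichment of low p-values in GS.

    Alternative hypothesis: the gene-set values are stochastically smaller
    than the complementary values. The exact null distribution is used for
    small groups (min(n1, n2) <= 8) without ties; otherwise the normal
    approximation with tie and continuity correction. If every value in
    both groups is identical there is no rank information and p = 0.5 is
    returned, flagged.
    """
    gs = np.asarray(gs_values, dtype=float)
    comp = np.asarray(comp_values, dtype=float)
    if gs.size == 0 or comp.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([gs, comp])
    if np.all(pooled == pooled[0]):
        return GsaResult(es=gs.size * comp.size / 2.0, p=0.5, flagged=True)
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(gs.size, comp.size) <= 8 and not ties) else "asymptotic"
    res = mannwhitneyu(gs, comp, alternative="less", method=method)
    return GsaResult(es=float(res.statistic), p=float(res.pvalue))


def spp(p_per_study, min_p: float = 1e-300) -> float:
    """Simple p-pooling: unweighted Fisher inverse chi-square combination.

    ``M = -2 sum_s ln(p_s)`` referred to chi-square with 2 n_s df. With a
    single study this is the identity ``p_SPP = p``.
    """
    p = np.asarray(p_per_study, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a nonempty vector of per-study p-values")
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.maximum(p, min_p)
    m = -2.0 * np.log(p).sum()
    return float(chi2.sf(m, 2 * p.size))


def _dl_batch(theta: np.ndarray, se: np.ndarray):
    """Vectorized DerSimonian-Laird over the leading axes (k studies last)."""
    w = 1.0 / se**2
    sw = w.sum(axis=-1)
    theta_fixed = (w * theta).sum(axis=-1) / sw
    q = (w * (theta - theta_fixed[..., None]) ** 2).sum(axis=-1)
    c = sw - (w**2).sum(axis=-1) / sw
    k = theta.shape[-1]
    tau2 = np.maximum(0.0, (q - (k - 1)) / c)
    w_star = 1.0 / (se**2 + tau2[..., None])
    sws = w_star.sum(axis=-1)
    pooled = (w_star * theta).sum(axis=-1) / sws
    pooled_se = 1.0 / np.sqrt(sws)
    z = pooled / pooled_se
    p = 2.0 * norm.sf(np.abs(z))
    return pooled, pooled_se, p, tau2, q


def random_effects_meta(theta_s, se_s) -> RandomEffectsResult:
    """DerSimonian-Laird random-effects meta-analysis of one marker.

    The heterogeneity variance is ``tau2 = max(0, (Q - (k-1)) / C)``; the
    pooled estimate uses inverse-variance weights ``1 / (se^2 + tau2)``
    and a two-sided Wald p-value. When Q <= k-1 (no excess heterogeneity)
    this reduces to the fixed-effect estimate. A single study is passed
    through with a warning.
    """
    theta = np.asarray(theta_s, dtype=float)
    se = np.asarray(se_s, dtype=float)
    if theta.shape != se.shape or theta.ndim != 1:
        raise ValueError("theta_s and se_s must be equal-length vectors")
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("standard errors must be finite and positive")
    if theta.size == 1:
        warnings.warn(
            "single study: fixed-effect passthrough, no heterogeneity estimate",
            stacklevel=2,
        )
        z = theta[0] / se[0]
        return RandomEffectsResult(
            theta=float(theta[0]),
            se=float(se[0]),
            p=float(2.0 * norm.sf(abs(z))),
            tau2=0.0,
            q=0.0,
            k=1,
        )
    pooled, pooled_se, p, tau2, q = _dl_batch(theta, se)
    return RandomEffectsResult(
        theta=float(pooled),
        se=float(pooled_se),
        p=float(p),
        tau2=float(tau2),
        q=float(q),
        k=theta.size,
    )


def pooled_gwas_gsa(p, theta, se, gs_mask) -> GsaResult:
    """Random-effects meta-analysis per marker, then one Wilcoxon GSA.

    Parameters
    ----------
    p, theta, se : ndarray (n_markers, n_studies)
        Marker-level two-sided p-values, log odds ratios and standard
        errors per study. The marker panel must be shared; a marker with a
        missing (NaN) entry in any study is dropped with a warning.
    gs_mask : boolean ndarray (n_markers,)
        True for markers belonging to the gene set of interest.

    With a single study the study's own marker p-values are used directly,
    so the result equals that study's :func:`wilcoxon_gsa`.
    """
    p = np.asarray(p, dtype=float)
    theta = np.asarray(theta, dtype=float)
    se = np.asarray(se, dtype=float)
    gs_mask = np.asarray(gs_mask, dtype=bool)
    if p.ndim != 2 or theta.shape != p.shape or se.shape != p.shape:
        raise ValueError("p, theta, se must share shape (n_markers, n_studies)")
    if gs_mask.shape != (p.shape[0],):
        raise ValueError("gs_mask must have one entry per marker")

    complete = ~(
        np.isnan(p).any(axis=1) | np.isnan(theta).any(axis=1) | np.isnan(se).any(axis=1)
    )
    if not complete.all():
        warnings.warn(
            f"{int((~complete).sum())} marker(s) missing in some study were dropped",
            stacklevel=2,
        )
        p, theta, se, gs_mask = p[complete], theta[complete], se[complete], gs_mask[complete]

    if p.shape[1] == 1:
        pooled_p = p[:, 0]
    else:
        _, _, pooled_p, _, _ = _dl_batch(theta, se)
    return wilcoxon_gsa(pooled_p[gs_mask], pooled_p[~gs_mask])
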