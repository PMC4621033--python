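"""The META-GSA test: weighted Fisher statistic, permutation null, pi0 correction.

The observed statistic for a gene set GS is

    M0 = -2 * sum_s w_s * ln(p_GS,s),

where p_GS,s are the per-study one-sided GSA p-values and w_s the
PCA-derived concordance weights. Because the weights are data-driven, may
be negative, and do not sum to 1, M0 does not follow the chi-square
distribution of the classical (Makambi-weighted) Fisher method; its null
distribution is obtained by permutation: each permutation draws a fresh
random gene set of the same size from the gene universe (to recompute the
weights) and fresh per-study p-values from U(0, 1). The permutation
p-value uses the add-one estimator (k + 1) / (n_perm + 1).

When many gene sets are tested, the proportion of true nulls pi0 is
estimated with the Storey-Tibshirani bootstrap and used in a
Bonferroni-like correction p_meta = min(1, p_permut * n_GS * pi0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.random import Generator, default_rng

from metagsa.concordance_weights import (
    _kendall_matrices_batch,
    _pca_weights_batch,
    kendall_matrix,
    pca_weights,
)
from metagsa.gene_level_pdr import (
    LdTable,
    MarkerStat,
    averaged_gene_stat,
    best_marker_stat,
    build_pdr_profiles,
    gene_stats_to_frames,
    pdr_profile_matrix,
)

__all__ = [
    "MetaGsaResult",
    "weighted_fisher",
    "permutation_null",
    "permutation_pvalue",
    "storey_pi0",
    "adjust",
    "run_meta_gsa",
]

_AGGREGATIONS = ("best", "all", "promising")


@dataclass(frozen=True)
class MetaGsaResult:
    """Per-gene-set META-GSA output."""

    gene_set: str
    n_genes: int
    m0: float
    p_permut: float
    pi0: float
    p_meta: float
    eff_studies: float
    weights: np.ndarray
    n_perm_used: int


def weighted_fisher(p_values, weights, min_p: float | None = None) -> float:
    """Weighted Fisher statistic ``M = -2 sum_s w_s ln(p_s)``.

    ``M`` may be negative when some weights are negative. Zero p-values are
    clamped to ``min_p`` when given (the META-GSA pipeline uses
    ``1 / (2 * n_perm)``, matching the permutation grid's resolution);
    without a clamp a zero p-value is an error.
    """
    p = np.asarray(p_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.shape != w.shape:
        raise ValueError(
            f"length mismatch: {p.shape[0] if p.ndim else 0} p-values vs "
            f"{w.shape[0] if w.ndim else 0} weights"
        )
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("p-values must lie in [0, 1]")
    if min_p is not None:
        p = np.maximum(p, min_p)
    if np.any(p == 0.0):
        raise ValueError("p = 0 encountered; pass min_p to clamp")
    return float(-2.0 * np.sum(w * np.log(p)))


def permutation_null(
    universe_pdr: np.ndarray,
    gs_size: int,
    n_perm: int,
    rng: Generator,
) -> np.ndarray:
    """Draw ``n_perm`` null statistics M_j.

    Each permutation re-allocates genes to the set (``gs_size`` drawn
    uniformly without replacement from the universe profile matrix),
    recomputes Kendall/PCA weights on that random set, draws per-study
    p-values from U(0, 1), and evaluates the weighted Fisher statistic.
    """
    X = np.asarray(universe_pdr, dtype=float)
    if X.ndim != 2:
        raise ValueError("universe_pdr must be a genes x studies matrix")
    n_genes, n_studies = X.shape
    if gs_size > n_genes:
        raise ValueError(f"gs_size {gs_size} exceeds universe size {n_genes}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    u = rng.random((n_perm, n_genes))
    idx = np.argpartition(u, gs_size - 1, axis=1)[:, :gs_size]
    profiles = X[idx]  # (n_perm, gs_size, n_studies)
    cms = _kendall_matrices_batch(profiles)
    weights, _ = _pca_weights_batch(cms)
    # guard against the (measure-zero) exact-0 draw; the resolution-matched
    # clamp 1/(2 n_perm) applies to the observed p_GS only
    draws = np.maximum(rng.random((n_perm, n_studies)), 1e-300)
    return -2.0 * np.einsum("bs,bs->b", weights, np.log(draws))


def permutation_pvalue(
    m0: float,
    universe_pdr: np.ndarray,
    gs_size: int,
    n_perm: int,
    rng: Generator,
    early_stop: bool = False,
    chunk: int = 200,
):
    """Permutation p-value of an observed statistic M0.

    Returns ``(p_permut, n_perm_used)`` with the add-one estimator
    ``(#{M_j >= M0} + 1) / (n + 1)`` (never exactly 0). Non-finite null
    draws (degenerate PCA) count as extreme, which is conservative.

    With ``early_stop=True`` permutations are generated in chunks and
    generation stops once the running estimate's 99% confidence interval
    lies entirely above 0.25 after at least 200 permutations -- a
    conservative screen for clearly non-significant sets whose p-values
    then remain coarse. Off by default.
    """
    if not early_stop:
        null = permutation_null(universe_pdr, gs_size, n_perm, rng)
        k = n_perm - int(np.count_nonzero(null < m0))
        return (k + 1) / (n_perm + 1), n_perm

    k = 0
    done = 0
    while done < n_perm:
        step = min(chunk, n_perm - done)
        null = permutation_null(universe_pdr, gs_size, step, rng)
        k += step - int(np.count_nonzero(null < m0))
        done += step
        if done >= 200:
            phat = (k + 1) / (done + 1)
            half = 2.576 * np.sqrt(phat * (1.0 - phat) / done)
            if phat - half > 0.25:
                break
    return (k + 1) / (done + 1), done


def storey_pi0(
    p_values,
    lambda_grid=None,
    n_boot: int = 100,
    rng: Generator | int | None = None,
) -> float:
    """Storey-Tibshirani bootstrap estimate of the true-null proportion pi0.

    ``pi0(lambda) = #{p > lambda} / (n (1 - lambda))`` is evaluated on the
    grid (default 0.05, 0.10, ..., 0.95); the tuning value minimizing the
    bootstrap mean-squared error against the minimum ``pi0(lambda)`` is
    selected. The estimate is clipped into (0, 1] (lower bound 1/n).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value to estimate pi0")
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("p-values must lie in [0, 1]")
    lam = (
        np.arange(0.05, 0.951, 0.05)
        if lambda_grid is None
        else np.asarray(lambda_grid, dtype=float)
    )
    if np.any((lam <= 0.0) | (lam >= 1.0)):
        raise ValueError("lambda grid must lie in (0, 1)")
    n = p.size
    pi0_lam = (p[None, :] > lam[:, None]).sum(axis=1) / (n * (1.0 - lam))
    min_pi0 = pi0_lam.min()
    gen = rng if isinstance(rng, Generator) else default_rng(rng)
    boot = p[gen.integers(0, n, size=(n_boot, n))]
    pi0_boot = (boot[:, None, :] > lam[None, :, None]).sum(axis=2) / (
        n * (1.0 - lam)
    )[None, :]
    mse = ((pi0_boot - min_pi0) ** 2).mean(axis=0)
    pi0 = pi0_lam[int(np.argmin(mse))]
    return float(np.clip(pi0, 1.0 / n, 1.0))


def adjust(p_permut: float, n_gs: int, pi0: float) -> float:
    """Bonferroni-like correction ``p_meta = min(1, p_permut * n_GS * pi0)``."""
    if not 0.0 < p_permut <= 1.0:
        raise ValueError("p_permut must lie in (0, 1]")
    if n_gs < 1:
        raise ValueError("n_gs must be >= 1")
    if not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must lie in (0, 1]")
    return min(1.0, p_permut * n_gs * pi0)


def _gene_level_stats(
    marker_stats: pd.DataFrame,
    ld: LdTable | None,
    aggregation: str,
    promising_threshold: float,
    df_mode: str,
):
    """Aggregate a marker-stats table to per-gene, per-study directed stats."""
    studies = sorted(marker_stats["study"].unique())
    gene_stats: dict[str, dict] = {}
    for gene, block in marker_stats.groupby("gene", sort=True):
        per_study = {
            study: [
                MarkerStat(str(row.marker), float(row.p), float(row.theta))
                for row in sub.itertuples()
            ]
            for study, sub in block.groupby("study")
        }
        if set(per_study) != set(studies):
            warnings.warn(
                f"gene {gene!r} absent from some studies; dropped from the "
                "universe",
                stacklevel=2,
            )
            continue
        if aggregation == "best":
            gene_stats[str(gene)] = best_marker_stat(per_study, ld)
        else:
            gene_stats[str(gene)] = {
                s: averaged_gene_stat(
                    stats,
                    ld,
                    promising_only=(aggregation == "promising"),
                    promising_threshold=promising_threshold,
                    df_mode=df_mode,
                )
                for s, stats in per_study.items()
            }
    if not gene_stats:
        raise ValueError("no gene is observed in every study")
    return gene_stats, studies


def run_meta_gsa(
    marker_stats: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
    gsa_pvalues: pd.DataFrame,
    ld: LdTable | None = None,
    aggregation: str = "best",
    promising_threshold: float = 0.05,
    df_mode: str = "2sumv",
    n_perm: int = 9999,
    seed: int | Generator | None = None,
    early_stop: bool = False,
) -> list[MetaGsaResult]:
    """Run META-GSA end to end for a collection of gene sets.

    Parameters
    ----------
    marker_stats : DataFrame
        Columns ``study, marker, gene, theta, p`` (long format, all studies).
    gene_sets : mapping name -> gene ids
    gsa_pvalues : DataFrame
        Columns ``study, gene_set, p``: the per-study one-sided GSA
        p-values to be pooled (produced by any GSA method).
    ld : LdTable, optional
        Needed when representative markers differ across studies
        (aggregation "best") or for LD-weighted averaging.
    aggregation : {"best", "all", "promising"}
        Marker-to-gene aggregation strategy.
    n_perm : int
        Permutations per gene set.
    seed : int or Generator
        Source of all randomness (permutations, pi0 bootstrap).

    Returns
    -------
    list of :class:`MetaGsaResult`, one per gene set, in sorted name order.
    Deterministic for a fixed seed.
    """
    if aggregation not in _AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {_AGGREGATIONS}")
    required = {"study", "marker", "gene", "theta", "p"}
    if not required.issubset(marker_stats.columns):
        raise ValueError(f"marker_stats needs columns {sorted(required)}")
    rng = seed if isinstance(seed, Generator) else default_rng(seed)

    gene_stats, studies = _gene_level_stats(
        marker_stats, ld, aggregation, promising_threshold, df_mode
    )
    P, D = gene_stats_to_frames(gene_stats, studies)
    pdr = pdr_profile_matrix(P, D, reorient=True)

    pv = gsa_pvalues.set_index(["gene_set", "study"])["p"]
    partial = []
    for name in sorted(map(str, gene_sets)):
        profile = build_pdr_profiles(pdr, gene_sets[name])
        cm = kendall_matrix(profile.to_numpy())
        ws = pca_weights(cm)
        try:
            p_vec = np.array([pv.loc[(name, s)] for s in studies], dtype=float)
        except KeyError as exc:
            raise ValueError(
                f"missing GSA p-value for gene set {name!r}, study {exc.args[0]}"
            ) from None
        m0 = weighted_fisher(p_vec, ws.weights, min_p=1.0 / (2.0 * n_perm))
        p_perm, n_used = permutation_pvalue(
            m0, pdr.to_numpy(), profile.shape[0], n_perm, rng, early_stop
        )
        partial.append((name, profile.shape[0], m0, p_perm, ws, n_used))

    n_sets = len(partial)
    pi0 = (
        storey_pi0([t[3] for t in partial], rng=rng) if n_sets > 1 else 1.0
    )
    return [
        MetaGsaResult(
            gene_set=name,
            n_genes=n_genes,
            m0=m0,
            p_permut=p_perm,
            pi0=pi0,
            p_meta=adjust(p_perm, n_sets, pi0),
            eff_studies=ws.eff_studies,
            weights=ws.weights,
            n_perm_used=n_used,
        )
        for name, n_genes, m0, p_perm, ws, n_used in partial
    ]
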