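"""From marker-level to gene-level: directed reversed p-values (PDRs).

A PDR combines the significance and the direction of a gene's observed
association in one number, ``p' = d * (1 - p)``, scaled like a correlation
coefficient: 0 means no evidence, +1/-1 strong positive/negative evidence.
Gene-level (p, d) pairs are built from marker-level results by one of three
aggregation strategies (most significant marker; weighted average over all
markers; weighted average over "promising" markers only), gene directions
are re-oriented along the across-study mean profile, and PDRs of the genes
in a set are assembled into a genes-by-studies profile matrix that feeds
the concordance weighting.

Linkage disequilibrium (LD) enters twice: when the representative marker of
a gene differs between studies, the direction is damped by the mean allele
correlation ``r`` between the selected markers; and when averaging over
markers, weights ``v_m = 1 / sum_{m' in block(m)} r^2(m', m)`` downweight
redundant markers so that ``sum v`` counts effectively independent markers.
LD blocks are formed by single-linkage clustering at ``r^2 >= 0.5`` within
a gene (configurable); the threshold-graph connected components define the
blocks, and an unknown pairwise ``r`` within a gene is treated as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "MissingLdError",
    "MarkerStat",
    "GeneDirectedStat",
    "LdTable",
    "pdr",
    "ld_blocks",
    "marker_weights",
    "best_marker_stat",
    "averaged_gene_stat",
    "reorient_directions",
    "build_pdr_profiles",
    "gene_stats_to_frames",
    "pdr_profile_matrix",
]


class MissingLdError(KeyError):
    """An LD entry needed for a cross-study marker pair is absent."""

    def __str__(self) -> str:  # KeyError quotes its message by default
        return self.args[0] if self.args else ""


class MarkerStat(NamedTuple):
    """One marker's association result in one study."""

    marker: str
    p: float
    theta: float


@dataclass(frozen=True)
class GeneDirectedStat:
    """Gene-level significance and direction in one study.

    ``d`` is real-valued in [-1, 1]: exactly +/-1 for a single marker or a
    shared representative marker, fractional after LD averaging. ``pdr``
    is the directed reversed p-value d * (1 - p).
    """

    p: float
    d: float
    marker: str | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("gene-level p must lie in [0, 1]")
        if abs(self.d) > 1.0 + 1e-12:
            raise ValueError("gene-level direction must lie in [-1, 1]")

    @property
    def pdr(self) -> float:
        return self.d * (1.0 - self.p)


class LdTable:
    """Symmetric map (marker, marker) -> signed allele correlation r.

    ``r(m, m)`` is 1 by definition and need not be stored. A lookup of an
    absent pair raises :class:`MissingLdError` naming the pair, because an
    assumed r = 0 would silently annihilate a gene's PDR.
    """

    def __init__(self, entries: Mapping[tuple, float] | None = None):
        self._r: dict[tuple, float] = {}
        if entries:
            for (a, b), r in entries.items():
                self.set(a, b, r)

    @staticmethod
    def _key(a: Hashable, b: Hashable) -> tuple:
        return (a, b) if str(a) <= str(b) else (b, a)

    def set(self, a: Hashable, b: Hashable, r: float) -> None:
        r = float(r)
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"|r| must be <= 1, got {r} for ({a}, {b})")
        if a == b and r != 1.0:
            raise ValueError("r(m, m) must be 1")
        if a != b:
            self._r[self._key(a, b)] = r

    def r(self, a: Hashable, b: Hashable) -> float:
        if a == b:
            return 1.0
        try:
            return self._r[self._key(a, b)]
        except KeyError:
            raise MissingLdError(
                f"no LD entry for marker pair ({a}, {b})"
            ) from None

    def r2(self, a: Hashable, b: Hashable) -> float:
        return self.r(a, b) ** 2

    def get_r(self, a: Hashable, b: Hashable, default: float | None = None):
        if a == b:
            return 1.0
        return self._r.get(self._key(a, b), default)

    def __contains__(self, pair: tuple) -> bool:
        a, b = pair
        return a == b or self._key(a, b) in self._r

    def __len__(self) -> int:
        return len(self._r)

    @classmethod
    def from_pairs(cls, triples: Iterable[tuple]) -> "LdTable":
        """Build from an iterable of (marker_a, marker_b, r)."""
        table = cls()
        for a, b, r in triples:
            table.set(a, b, r)
        return table


def pdr(p: float, d: float) -> float:
    """Directed reversed p-value ``p' = d * (1 - p)``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if abs(d) > 1.0 + 1e-12:
        raise ValueError("|d| must be <= 1")
    return d * (1.0 - p)


def ld_blocks(
    markers: Sequence[Hashable],
    ld: LdTable | None = None,
    r2_threshold: float = 0.5,
) -> dict[Hashable, int]:
    """Assign markers of one gene to LD blocks.

    Single-linkage: two markers join a block when their known ``r^2`` is at
    least ``r2_threshold``; blocks are the connected components of that
    graph. Without an LD table every marker is its own block.
    """
    markers = list(markers)
    parent = {m: m for m in markers}

    def find(m):
        while parent[m] != m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m

    if ld is not None:
        for i, a in enumerate(markers):
            for b in markers[i + 1 :]:
                r = ld.get_r(a, b)
                if r is not None and r * r >= r2_threshold:
                    parent[find(a)] = find(b)
    roots: dict[Hashable, int] = {}
    labels = {}
    for m in markers:
        root = find(m)
        labels[m] = roots.setdefault(root, len(roots))
    return labels


def marker_weights(
    markers: Sequence[Hashable],
    ld: LdTable | None = None,
    r2_threshold: float = 0.5,
) -> dict[Hashable, float]:
    """LD-redundancy weights ``v_m = 1 / sum_{m' in block(m)} r^2(m', m)``.

    The sum includes ``m`` itself (r^2 = 1), so independent markers get
    v = 1 and ``sum v`` equals the number of effectively independent
    markers. Unknown within-block r contributes 0.
    """
    blocks = ld_blocks(markers, ld, r2_threshold)
    weights = {}
    for m in markers:
        total = 0.0
        for m2 in markers:
            if blocks[m2] != blocks[m]:
                continue
            r = 1.0 if m2 == m else (ld.get_r(m, m2, 0.0) if ld else 0.0)
            total += r * r
        weights[m] = 1.0 / total
    return weights


def _sign(theta: float) -> int:
    return 1 if theta >= 0.0 else -1


def best_marker_stat(
    per_study: Mapping[Hashable, Sequence[MarkerStat]],
    ld: LdTable | None = None,
) -> dict[Hashable, GeneDirectedStat]:
    """Gene-level (p, d) per study from each study's most significant marker.

    ``p_g,s = min_m p_m|g,s``; ties on p are broken toward the
    lexicographically smallest marker id (deterministic). If every study
    selects the same representative marker, ``d = sign(theta)``; otherwise
    the sign is damped by the mean signed allele correlation ``r`` between
    this study's marker and the markers selected by the other studies,
    which requires an LD table covering those pairs.
    """
    selected: dict[Hashable, MarkerStat] = {}
    for study, stats in per_study.items():
        if not stats:
            raise ValueError(f"study {study!r} has no markers for this gene")
        selected[study] = min(stats, key=lambda t: (t.p, str(t.marker)))

    distinct = {stat.marker for stat in selected.values()}
    out: dict[Hashable, GeneDirectedStat] = {}
    if len(distinct) == 1:
        for study, stat in selected.items():
            out[study] = GeneDirectedStat(
                p=stat.p, d=float(_sign(stat.theta)), marker=stat.marker
            )
        return out

    if ld is None:
        raise MissingLdError(
            "representative markers differ across studies "
            f"({sorted(map(str, distinct))}); an LD table is required"
        )
    studies = list(selected)
    for study in studies:
        own = selected[study]
        rs = [
            ld.r(own.marker, selected[other].marker)
            for other in studies
            if other != study
        ]
        d = _sign(own.theta) * float(np.mean(rs))
        out[study] = GeneDirectedStat(p=own.p, d=d, marker=own.marker)
    return out


def averaged_gene_stat(
    markers: Sequence[MarkerStat],
    ld: LdTable | None = None,
    promising_only: bool = False,
    promising_threshold: float = 0.05,
    df_mode: str = "2sumv",
    r2_threshold: float = 0.5,
    min_p: float = 1e-300,
) -> GeneDirectedStat:
    """Gene-level (p, d) for one study by LD-weighted averaging over markers.

    Significance: the weighted Fisher sum ``C = -2 sum_i v_i ln p_i`` is
    referred to a chi-square distribution with ``df = 2 * sum(v)`` (default;
    ``df_mode="sumv"`` gives the strict sum-of-weights df). With a single
    marker the default reduces exactly to the marker itself
    (``p_g = p_m``, ``d_g = sign(theta)``).

    Direction: ``d = sum_i v_i sign(theta_i) / sum(v)``, normalized so that
    ``|d| <= 1`` and the PDR stays within [-1, 1].

    With ``promising_only=True`` only markers with ``p < 0.05`` (by default)
    enter; if none survive the gene is assigned p = 1, d = 0 and flagged.
    """
    if df_mode not in ("2sumv", "sumv"):
        raise ValueError("df_mode must be '2sumv' or 'sumv'")
    use = [m for m in markers if not promising_only or m.p < promising_threshold]
    if not use:
        return GeneDirectedStat(p=1.0, d=0.0, flagged=True)
    v = marker_weights([m.marker for m in use], ld, r2_threshold)
    sum_v = sum(v.values())
    stat = -2.0 * sum(v[m.marker] * np.log(max(m.p, min_p)) for m in use)
    df = 2.0 * sum_v if df_mode == "2sumv" else sum_v
    p_g = float(chi2.sf(stat, df))
    d_g = sum(v[m.marker] * _sign(m.theta) for m in use) / sum_v
    return GeneDirectedStat(p=p_g, d=float(d_g))


def reorient_directions(directions):
    """Re-orient gene directions along the across-study mean profile.

    ``directions`` is a genes-by-studies array (or DataFrame). For any gene
    whose mean direction over studies is negative, all its entries are
    negated so a positive value points toward the study-average (reference)
    direction. A mean of exactly zero leaves the gene unchanged
    (deterministic, unbiased tie-break). Idempotent.
    """
    values = directions.to_numpy() if isinstance(directions, pd.DataFrame) else np.asarray(directions, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a genes x studies matrix")
    flip = values.mean(axis=1) < 0.0
    out = np.where(flip[:, None], -values, values)
    if isinstance(directions, pd.DataFrame):
        return pd.DataFrame(out, index=directions.index, columns=directions.columns)
    return out


def build_pdr_profiles(pdrs: pd.DataFrame, gs_genes: Sequence[str]) -> pd.DataFrame:
    """Restrict a universe PDR matrix (genes x studies) to a gene set.

    Re-orientation must already have been applied. Genes absent from every
    study are dropped with a warning; a gene observed in only some studies
    (NaN entries) is an error, because profiles must be complete. Rows are
    ordered by gene id for determinism.
    """
    gs_genes = sorted(set(map(str, gs_genes)))
    index = pdrs.index.astype(str)
    present = [g for g in gs_genes if g in set(index)]
    missing = sorted(set(gs_genes) - set(present))
    if missing:
        warnings.warn(
            f"{len(missing)} gene-set gene(s) absent from all studies were "
            f"dropped: {missing[:5]}",
            stacklevel=2,
        )
    if not present:
        raise ValueError("no gene of the set is present in the data")
    sub = pdrs.loc[pdrs.index.astype(str).isin(present)].copy()
    sub.index = sub.index.astype(str)
    sub = sub.sort_index()
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        raise ValueError(
            f"incomplete PDR profile: gene(s) {bad[:5]} missing in some studies"
        )
    return sub


def gene_stats_to_frames(
    gene_stats: Mapping[str, Mapping[Hashable, GeneDirectedStat]],
    studies: Sequence[Hashable] | None = None,
):
    """Arrange per-gene, per-study stats into (P, D) DataFrames (genes x studies)."""
    genes = sorted(map(str, gene_stats))
    if studies is None:
        studies = sorted({s for per in gene_stats.values() for s in per})
    P = pd.DataFrame(np.nan, index=genes, columns=list(studies))
    D = pd.DataFrame(np.nan, index=genes, columns=list(studies))
    for gene, per_study in gene_stats.items():
        for study, stat in per_study.items():
            P.loc[str(gene), study] = stat.p
            D.loc[str(gene), study] = stat.d
    return P, D


def pdr_profile_matrix(P: pd.DataFrame, D: pd.DataFrame, reorient: bool = True) -> pd.DataFrame:
    """PDR matrix ``d * (1 - p)`` after (optional) re-orientation of D."""
    if not P.index.equals(D.index) or not P.columns.equals(D.columns):
        raise ValueError("P and D must share index and columns")
    D_use = reorient_directions(D) if reorient else D
    return D_use * (1.0 - P)
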