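"""File formats and input validation for real-data runs.

Formats
-------
* Marker stats: TSV with columns ``study, marker, gene, theta, se, p``
  (theta is the log odds ratio; ``se`` optional for META-GSA itself but
  required for the pooled-GWAS comparator).
* Gene sets: GMT (name, description, then gene ids, tab-separated).
* SNP-to-gene map: 2-column TSV ``marker, gene``.
* LD: PLINK ``.ld`` dialect (whitespace table with SNP_A/SNP_B and a
  signed R column; falls back to sqrt(R2) with a warning if only R2 is
  present) or a plain 3-column TSV ``marker_a, marker_b, r``.
* GSA p-values: long TSV ``study, gene_set, p``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from metagsa.gene_level_pdr import LdTable
from metagsa.meta_gsa_test import MetaGsaResult

__all__ = [
    "StudyInputBundle",
    "read_marker_stats",
    "write_marker_stats",
    "read_snp_gene_map",
    "read_gmt",
    "read_ld_table",
    "read_gsa_pvalues",
    "read_inputs",
    "write_results",
]

logger = logging.getLogger("metagsa")


@dataclass
class StudyInputBundle:
    """Validated inputs for a real-data META-GSA run."""

    marker_stats: pd.DataFrame
    gene_sets: dict[str, list[str]]
    gsa_pvalues: pd.DataFrame
    ld: LdTable | None = None
    snp_gene_map: pd.DataFrame | None = None

    @property
    def studies(self) -> list:
        return sorted(self.marker_stats["study"].unique())


def read_marker_stats(path) -> pd.DataFrame:
    """Read a per-study marker association table."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"study": str, "marker": str, "gene": str},
        float_precision="round_trip",
    )
    required = {"study", "marker", "gene", "theta", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    bad = df.index[(df["p"] < 0) | (df["p"] > 1) | df["p"].isna()]
    if len(bad):
        raise ValueError(f"{path}: invalid p-value at line {bad[0] + 2}")
    return df


def write_marker_stats(df: pd.DataFrame, path) -> None:
    """Write a marker-stats table, round-trip lossless to 17 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_snp_gene_map(path) -> pd.DataFrame:
    """Read a 2-column marker-to-gene map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (marker, gene)")
    df = df.iloc[:, :2]
    df.columns = ["marker", "gene"]
    return df


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name, description, then gene ids."""
    gene_sets: dict[str, list[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}, line {lineno}: expected name, description and "
                    "at least one gene"
                )
            gene_sets[fields[0]] = list(dict.fromkeys(fields[2:]))
    if not gene_sets:
        raise ValueError(f"{path}: empty gene-set file")
    return gene_sets


def read_ld_table(path) -> LdTable:
    """Read an LD table (PLINK .ld dialect or plain 3-column TSV)."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.upper(): c for c in df.columns}
    if "SNP_A" in cols and "SNP_B" in cols:
        a, b = df[cols["SNP_A"]], df[cols["SNP_B"]]
        if "R" in cols:
            r = df[cols["R"]].astype(float)
        elif "R2" in cols:
            warnings.warn(
                f"{path}: only R2 present; using sqrt(R2), sign information lost",
                stacklevel=2,
            )
            r = np.sqrt(df[cols["R2"]].astype(float))
        else:
            raise ValueError(f"{path}: PLINK LD table lacks an R or R2 column")
    elif df.shape[1] >= 3:
        a, b, r = df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2].astype(float)
    else:
        raise ValueError(f"{path}: expected 3 columns (marker_a, marker_b, r)")
    return LdTable.from_pairs(zip(a.astype(str), b.astype(str), r))


def read_gsa_pvalues(path) -> pd.DataFrame:
    """Read per-study, per-set GSA p-values (long TSV: study, gene_set, p)."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"study": str, "gene_set": str},
        float_precision="round_trip",
    )
    required = {"study", "gene_set", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    bad = df.index[(df["p"] < 0) | (df["p"] > 1) | df["p"].isna()]
    if len(bad):
        raise ValueError(f"{path}: invalid p-value at line {bad[0] + 2}")
    return df


def read_inputs(
    marker_stats,
    gene_sets,
    gsa_pvalues,
    ld=None,
    snp_gene_map=None,
    min_set_size: int = 15,
    max_set_size: int = 200,
) -> StudyInputBundle:
    """Read and cross-validate all inputs of a real-data run.

    Gene sets outside the [min_set_size, max_set_size] window are excluded
    (logged); the defaults avoid testing overly small or large sets.
    Study ids must agree between the marker stats and the GSA p-values,
    and every marker in the stats must be mapped to a gene.
    """
    stats = read_marker_stats(marker_stats)
    sets = read_gmt(gene_sets)
    pvals = read_gsa_pvalues(gsa_pvalues)
    ld_table = read_ld_table(ld) if ld is not None else None
    mapping = read_snp_gene_map(snp_gene_map) if snp_gene_map is not None else None

    if mapping is not None:
        unmapped = sorted(set(stats["marker"]) - set(mapping["marker"]))
        if unmapped:
            raise ValueError(
                f"{len(unmapped)} marker(s) in the stats are absent from the "
                f"SNP-to-gene map, e.g. {unmapped[:5]}"
            )

    stat_studies = set(stats["study"])
    pval_studies = set(pvals["study"])
    if stat_studies != pval_studies:
        raise ValueError(
            "inconsistent study ids: marker stats have "
            f"{sorted(stat_studies)}, GSA p-values have {sorted(pval_studies)}"
        )

    kept = {
        name: genes
        for name, genes in sets.items()
        if min_set_size <= len(genes) <= max_set_size
    }
    excluded = len(sets) - len(kept)
    if excluded:
        logger.info(
            "excluded %d gene set(s) outside the size window [%d, %d]",
            excluded,
            min_set_size,
            max_set_size,
        )
    if not kept:
        raise ValueError(
            f"no gene set within the size window [{min_set_size}, {max_set_size}]"
        )
    known_genes = set(stats["gene"])
    empty = [n for n, g in kept.items() if not known_genes.intersection(g)]
    if empty:
        raise ValueError(
            f"gene set(s) without any mapped gene in the data: {empty[:5]}"
        )
    return StudyInputBundle(
        marker_stats=stats,
        gene_sets=kept,
        gsa_pvalues=pvals,
        ld=ld_table,
        snp_gene_map=mapping,
    )


def write_results(results: Sequence[MetaGsaResult], path) -> None:
    """Write per-gene-set results, sorted by p_meta then gene-set id.

    Deterministic column order; per-study weights are JSON-encoded in one
    column. An empty result list yields a header-only file.
    """
    columns = [
        "gene_set",
        "n_genes",
        "m0",
        "p_permut",
        "pi0",
        "p_meta",
        "eff_studies",
        "weights",
        "n_perm_used",
    ]
    rows = [
        {
            "gene_set": r.gene_set,
            "n_genes": r.n_genes,
            "m0": r.m0,
            "p_permut": r.p_permut,
            "pi0": r.pi0,
            "p_meta": r.p_meta,
            "eff_studies": r.eff_studies,
            "weights": json.dumps([float(w) for w in r.weights]),
            "n_perm_used": r.n_perm_used,
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=columns)
    if len(df):
        df = df.sort_values(["p_meta", "gene_set"], kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
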