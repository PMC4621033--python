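"""Power simulation: the 20 registry scenarios and per-scenario Monte Carlo.

Each replicate simulates ``n_studies`` case-control GWASs over 100 genes
with one marker each (GS = first 10 genes), runs the per-study Wilcoxon
GSA, and evaluates three pooling approaches on the same data:

* META-GSA (concordance-weighted Fisher with permutation p-value),
* SPP (unweighted Fisher combination of the per-study GSA p-values),
* pooledGWAS-GSA (per-marker random-effects meta-analysis, one GSA).

Rejection fractions at the significance level give type-I error (null
scenarios) or power. Replicates use seed-sequence spawning, so results are
reproducible for a fixed seed regardless of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng

from metagsa.comparison_methods import pooled_gwas_gsa, spp, wilcoxon_gsa
from metagsa.concordance_weights import kendall_matrix, pca_weights
from metagsa.gene_level_pdr import reorient_directions
from metagsa.meta_gsa_test import permutation_pvalue, weighted_fisher
from metagsa.simulate_gwas import (
    ScenarioSpec,
    armitage_trend_test_batch,
    hwe_pvalues,
    simulate_studies,
)

__all__ = ["PowerResult", "scenario_registry", "run_scenario"]

METHODS = ("meta_gsa", "spp", "pooled_gwas_gsa")


@dataclass
class PowerResult:
    """Monte Carlo result of one scenario.

    ``crosstab`` is the 2x2 META-GSA x SPP agreement table
    [[both significant, META only], [SPP only, neither]].
    """

    scenario_id: int | None
    n_sim: int
    alpha: float
    p_meta: np.ndarray
    p_spp: np.ndarray
    p_pooled: np.ndarray

    @property
    def counts(self) -> dict[str, int]:
        return {
            "meta_gsa": int((self.p_meta <= self.alpha).sum()),
            "spp": int((self.p_spp <= self.alpha).sum()),
            "pooled_gwas_gsa": int((self.p_pooled <= self.alpha).sum()),
        }

    @property
    def power(self) -> dict[str, float]:
        if self.n_sim == 0:
            return {m: float("nan") for m in METHODS}
        return {m: c / self.n_sim for m, c in self.counts.items()}

    @property
    def crosstab(self) -> np.ndarray:
        meta_sig = self.p_meta <= self.alpha
        spp_sig = self.p_spp <= self.alpha
        return np.array(
            [
                [int((meta_sig & spp_sig).sum()), int((meta_sig & ~spp_sig).sum())],
                [int((~meta_sig & spp_sig).sum()), int((~meta_sig & ~spp_sig).sum())],
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        """One-row summary with rejection fractions and Monte Carlo SEs."""
        row: dict[str, object] = {
            "scenario": self.scenario_id,
            "n_sim": self.n_sim,
            "alpha": self.alpha,
        }
        for m, frac in self.power.items():
            row[f"power_{m}"] = frac
            row[f"se_{m}"] = (
                float(np.sqrt(frac * (1.0 - frac) / self.n_sim))
                if self.n_sim
                else float("nan")
            )
        ct = self.crosstab if self.n_sim else np.zeros((2, 2), dtype=int)
        row["n_both_sig"] = ct[0, 0]
        row["n_meta_only"] = ct[0, 1]
        row["n_spp_only"] = ct[1, 0]
        row["n_neither"] = ct[1, 1]
        return pd.DataFrame([row])


def _rr(*groups) -> tuple:
    """Expand (count, rr) pairs into a flat RR tuple, e.g. _rr((5,1),(5,1.5))."""
    out: list[float] = []
    for count, rr in groups:
        out.extend([float(rr)] * count)
    return tuple(out)


def scenario_registry() -> dict[int, ScenarioSpec]:
    """The 20 simulation scenarios (GS of 10 genes, 90 complementary genes).

    Scenarios 1-3 are null (same RR distribution in GS and GS'), 4-8 vary
    the effect size with 10 studies, 9-16 vary the number of studies at
    RR = 1.5, and 17-20 mix associated genes into both sets.
    """
    specs: dict[int, ScenarioSpec] = {}

    def add(sid: int, rr_gs, rr_comp, n_studies: int) -> None:
        specs[sid] = ScenarioSpec(
            n_studies=n_studies, rr_gs=rr_gs, rr_comp=rr_comp, scenario_id=sid
        )

    add(1, _rr((10, 1.0)), _rr((90, 1.0)), 10)
    add(2, _rr((10, 1.2)), _rr((90, 1.2)), 10)
    add(3, _rr((10, 1.5)), _rr((90, 1.5)), 10)
    for sid, rr in zip((4, 5, 6, 7, 8), (1.1, 1.2, 1.3, 1.4, 1.5)):
        add(sid, _rr((5, 1.0), (5, rr)), _rr((90, 1.0)), 10)
    for sid, n_studies in zip(range(9, 17), range(2, 10)):
        add(sid, _rr((5, 1.0), (5, 1.5)), _rr((90, 1.0)), n_studies)
    mixed_gs = _rr((5, 1.0), (4, 1.2), (1, 1.5))
    add(17, mixed_gs, _rr((90, 1.0)), 10)
    add(18, mixed_gs, _rr((63, 1.0), (18, 1.2), (9, 1.5)), 10)
    add(19, mixed_gs, _rr((41, 1.0), (32, 1.2), (17, 1.5)), 10)
    add(20, mixed_gs, _rr((45, 1.0), (36, 1.2), (9, 1.5)), 10)
    return specs


def _replicate(spec: ScenarioSpec, rng, n_perm: int, hwe_threshold: float):
    """One simulation replicate; returns (p_meta, p_spp, p_pooled)."""
    case, control = simulate_studies(spec, rng)
    p, theta, se, d, _ = armitage_trend_test_batch(case, control)  # (s, m)

    keep = (hwe_pvalues(control) >= hwe_threshold).all(axis=0)
    gs = np.zeros(spec.n_markers, dtype=bool)
    gs[: spec.gs_size] = True
    gs = gs[keep]
    p, theta, se, d = p[:, keep], theta[:, keep], se[:, keep], d[:, keep]

    p_gs = np.array(
        [wilcoxon_gsa(p[s][gs], p[s][~gs]).p for s in range(spec.n_studies)]
    )

    directions = reorient_directions(d.T.astype(float))  # (m, s)
    universe_pdr = directions * (1.0 - p.T)

    cm = kendall_matrix(universe_pdr[gs])
    ws = pca_weights(cm)
    m0 = weighted_fisher(p_gs, ws.weights, min_p=1.0 / (2.0 * n_perm))
    p_meta, _ = permutation_pvalue(m0, universe_pdr, int(gs.sum()), n_perm, rng)

    p_spp = spp(p_gs)
    p_pooled = pooled_gwas_gsa(p.T, theta.T, se.T, gs).p
    return p_meta, p_spp, p_pooled


def run_scenario(
    spec: ScenarioSpec,
    n_sim: int = 500,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int | SeedSequence = 0,
    hwe_threshold: float = 1e-7,
) -> PowerResult:
    """Monte Carlo rejection fractions of the three methods for one scenario.

    Each replicate gets an independent child seed spawned from ``seed``,
    so the result is reproducible and independent of batching.
    """
    if spec.n_studies < 2:
        raise ValueError("pooling methods need at least two studies")
    ss = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    children = ss.spawn(n_sim)
    out = np.empty((n_sim, 3))
    for i, child in enumerate(children):
        out[i] = _replicate(spec, default_rng(child), n_perm, hwe_threshold)
    return PowerResult(
        scenario_id=spec.scenario_id,
        n_sim=n_sim,
        alpha=alpha,
        p_meta=out[:, 0].copy(),
        p_spp=out[:, 1].copy(),
        p_pooled=out[:, 2].copy(),
    )
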