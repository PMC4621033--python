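"""Case-control GWAS simulation under per-gene relative risks.

Simulates multi-study case-control genotype data for a panel of diallelic
markers (one marker per gene) under a log-additive penetrance model, and
provides the marker-level association machinery: the Cochran-Armitage trend
test, a per-allele log-odds-ratio estimate with its direction, and a
Hardy-Weinberg-equilibrium (HWE) quality filter on controls.

Model
-----
Each marker has minor-allele frequency ``maf`` and genotypes in HWE. A
per-allele relative risk ``rr >= 1`` acts multiplicatively on penetrances,
``f_j = f0 * rr**j`` for ``j`` copies of the risk allele, with the baseline
``f0`` solved so that the population prevalence constraint
``sum_j f_j P_j = prevalence`` holds exactly. Which allele (minor or major)
carries the risk is randomized with probability 1/2 per associated marker,
so that observed association directions are not systematically tied to the
minor allele; the minor-allele frequency itself stays fixed. By default the
risk-allele orientation is drawn once per marker and shared by all studies
(the same variant is the risk variant in every study); setting
``ScenarioSpec.shared_direction=False`` re-randomizes it per study, which
destroys cross-study concordance of association patterns.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.random import Generator
from scipy.stats import chi2

__all__ = [
    "InvalidScenarioError",
    "ScenarioSpec",
    "GenotypeCounts",
    "MarkerAssociation",
    "genotype_distribution",
    "simulate_studies",
    "sample_study",
    "armitage_trend_test",
    "armitage_trend_test_batch",
    "hwe_pvalues",
    "hwe_filter",
]

_GENO = np.array([0.0, 1.0, 2.0])


class InvalidScenarioError(ValueError):
    """A scenario implies an impossible model (e.g. penetrance above 1)."""


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulated multi-study case-control setting.

    Parameters
    ----------
    n_studies : int
        Number of independent studies to combine.
    rr_gs : tuple of float
        Per-allele relative risks of the genes in the set of interest (GS),
        one value per gene, each >= 1. Direction is randomized separately.
    rr_comp : tuple of float
        Relative risks of the complementary genes (GS').
    maf : float
        Minor-allele frequency shared by all markers (0 < maf < 0.5).
    prevalence : float
        Population prevalence of the binary phenotype.
    n_cases, n_controls : int
        Per-study sample sizes.
    shared_direction : bool
        If True (default) the risk-allele orientation of each marker is the
        same in every study; if False it is re-drawn per study.
    scenario_id : int, optional
        Registry label, carried through to results.
    """

    n_studies: int
    rr_gs: tuple
    rr_comp: tuple
    maf: float = 0.30
    prevalence: float = 0.05
    n_cases: int = 500
    n_controls: int = 500
    shared_direction: bool = True
    scenario_id: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "rr_gs", tuple(float(r) for r in self.rr_gs))
        object.__setattr__(self, "rr_comp", tuple(float(r) for r in self.rr_comp))
        if self.n_studies < 1:
            raise InvalidScenarioError("n_studies must be >= 1")
        if not self.rr_gs:
            raise InvalidScenarioError("rr_gs must contain at least one gene")
        if any(r < 1.0 for r in self.rr_gs + self.rr_comp):
            raise InvalidScenarioError(
                "relative risks must be >= 1; direction is randomized separately"
            )
        if not 0.0 < self.maf < 0.5:
            raise InvalidScenarioError("maf must lie in (0, 0.5)")
        if not 0.0 < self.prevalence < 1.0:
            raise InvalidScenarioError("prevalence must lie in (0, 1)")
        if self.n_cases < 1 or self.n_controls < 1:
            raise InvalidScenarioError("n_cases and n_controls must be positive")

    @property
    def rr_all(self) -> np.ndarray:
        """Relative risks for the full marker panel, GS genes first."""
        return np.asarray(self.rr_gs + self.rr_comp, dtype=float)

    @property
    def n_markers(self) -> int:
        return len(self.rr_gs) + len(self.rr_comp)

    @property
    def gs_size(self) -> int:
        return len(self.rr_gs)


@dataclass
class GenotypeCounts:
    """Genotype counts (0/1/2 copies of the minor-coded allele) per arm."""

    cases: np.ndarray
    controls: np.ndarray

    def __post_init__(self) -> None:
        self.cases = np.asarray(self.cases, dtype=np.int64)
        self.controls = np.asarray(self.controls, dtype=np.int64)
        for arr in (self.cases, self.controls):
            if arr.shape != (3,) or np.any(arr < 0):
                raise ValueError("genotype counts must be three nonnegative integers")


@dataclass(frozen=True)
class MarkerAssociation:
    """Marker-level association result of one study.

    ``d`` follows the convention d = +1 if OR >= 1 and d = -1 otherwise.
    ``flagged`` marks monomorphic markers (p = 1, d = +1 by convention).
    """

    p: float
    d: int
    theta: float
    se: float
    flagged: bool = False


def _hwe_probs(freq):
    """HWE genotype probabilities for allele frequency ``freq`` (last axis)."""
    freq = np.asarray(freq, dtype=float)
    return np.stack(
        [(1.0 - freq) ** 2, 2.0 * freq * (1.0 - freq), freq**2], axis=-1
    )

def _case_control_probs(freq, rr, prevalence):
    """Genotype probabilities in cases/controls, risk-allele coded.

    ``freq`` is the frequency of the risk-coded allele (any value in (0,1):
    when the major allele carries the risk this is 1 - maf).
    """
    rr = np.asarray(rr, dtype=float)
    P = _hwe_probs(freq)
    rr_pow = rr[..., None] ** _GENO
    denom = (P * rr_pow).sum(axis=-1)
    f0 = prevalence / denom
    f = f0[..., None] * rr_pow
    if np.any(f > 1.0 + 1e-12):
        raise InvalidScenarioError(
            "penetrance f0*rr^2 exceeds 1 for this (maf, rr, prevalence)"
        )
    case = f * P / prevalence
    control = (1.0 - f) * P / (1.0 - prevalence)
    return case, control


def genotype_distribution(maf: float, rr: float, prevalence: float):
    """Genotype probabilities among cases and controls for one marker.

    Genotypes are coded as copies of the risk allele at frequency ``maf``.
    Returns ``(case_probs, control_probs)``, each a length-3 array summing
    to 1, under HWE and the log-additive penetrance model
    ``f_j = f0 * rr**j`` with ``sum_j f_j P_j = prevalence``.
    """
    if not 0.0 < maf < 0.5:
        raise InvalidScenarioError("maf must lie in (0, 0.5)")
    if rr < 1.0:
        raise InvalidScenarioError("rr must be >= 1")
    if not 0.0 < prevalence < 1.0:
        raise InvalidScenarioError("prevalence must lie in (0, 1)")
    case, control = _case_control_probs(np.asarray(maf), np.asarray(rr), prevalence)
    return case, control


def simulate_studies(spec: ScenarioSpec, rng: Generator):
    """Sample genotype counts for all studies of a scenario.

    Returns
    -------
    case_counts, control_counts : ndarray of shape (n_studies, n_markers, 3)
        Genotype counts coded as copies of the *minor* allele, so the sign
        of the fitted odds ratio reflects the randomized risk orientation.
    """
    m, s = spec.n_markers, spec.n_studies
    rr = np.broadcast_to(spec.rr_all, (s, m))
    if spec.shared_direction:
        risk_minor = np.broadcast_to(rng.random(m) < 0.5, (s, m)).copy()
    else:
        risk_minor = rng.random((s, m)) < 0.5
    freq = np.where(risk_minor, spec.maf, 1.0 - spec.maf)
    case_p, control_p = _case_control_probs(freq, rr, spec.prevalence)
    case = rng.multinomial(spec.n_cases, case_p)
    control = rng.multinomial(spec.n_controls, control_p)
    # flip to minor-allele coding where the major allele carries the risk
    flip = ~risk_minor
    case[flip] = case[flip][:, ::-1]
    control[flip] = control[flip][:, ::-1]
    return case, control


def sample_study(spec: ScenarioSpec, rng: Generator) -> list[GenotypeCounts]:
    """Sample one study's genotype counts, one :class:`GenotypeCounts` per marker."""
    single = dataclasses.replace(spec, n_studies=1)
    case, control = simulate_studies(single, rng)
    return [GenotypeCounts(case[0, j], control[0, j]) for j in range(spec.n_markers)]


def armitage_trend_test_batch(case_counts, control_counts):
    """Vectorized Cochran-Armitage trend test with log-OR direction.

    Parameters
    ----------
    case_counts, control_counts : ndarray (..., 3)
        Genotype counts with scores (0, 1, 2).

    Returns
    -------
    p, theta, se, d, monomorphic : ndarrays broadcast over the leading axes.
        ``p`` is the two-sided chi-square(1 df) p-value of the trend
        statistic; ``theta`` the per-allele log odds ratio from the allele
        dosage 2x2 table with Haldane-Anscombe 0.5 correction when any cell
        is zero (Woolf standard error); ``d = +1`` iff OR >= 1. Monomorphic
        markers get p = 1, theta = 0, d = +1.
    """
    r = np.asarray(case_counts, dtype=float)
    c = np.asarray(control_counts, dtype=float)
    R = r.sum(axis=-1)
    C = c.sum(axis=-1)
    N = R + C
    n = r + c
    T = r @ _GENO
    A = n @ _GENO
    B2 = n @ _GENO**2
    spread = N * B2 - A**2  # N^2 * genotype-score variance; 0 iff monomorphic
    mono = spread <= 0
    denom = R * C * spread
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, N * (N * T - R * A) ** 2 / denom, 0.0)
    p = chi2.sf(stat, 1)
    p = np.where(mono, 1.0, p)

    a = r[..., 1] + 2.0 * r[..., 2]  # minor alleles, cases
    b = 2.0 * R - a
    cc = c[..., 1] + 2.0 * c[..., 2]
    dd = 2.0 * C - cc
    zero = (a == 0) | (b == 0) | (cc == 0) | (dd == 0)
    a, b, cc, dd = (np.where(zero, x + 0.5, x) for x in (a, b, cc, dd))
    theta = np.log(a * dd) - np.log(b * cc)
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / cc + 1.0 / dd)
    theta = np.where(mono, 0.0, theta)
    d = np.where(theta >= 0.0, 1, -1)
    return p, theta, se, d, mono


def armitage_trend_test(counts: GenotypeCounts) -> MarkerAssociation:
    """Cochran-Armitage trend test for a single marker."""
    p, theta, se, d, mono = armitage_trend_test_batch(counts.cases, counts.controls)
    return MarkerAssociation(
        p=float(p), d=int(d), theta=float(theta), se=float(se), flagged=bool(mono)
    )


def hwe_pvalues(control_counts):
    """Chi-square (1 df) goodness-of-fit p-values for HWE, vectorized.

    Monomorphic markers satisfy HWE trivially (p = 1).
    """
    c = np.asarray(control_counts, dtype=float)
    n = c.sum(axis=-1)
    q = (c[..., 1] + 2.0 * c[..., 2]) / (2.0 * n)
    expected = n[..., None] * _hwe_probs(q)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (c - expected) ** 2 / expected, 0.0)
    stat = contrib.sum(axis=-1)
    mono = (q <= 0.0) | (q >= 1.0)
    return np.where(mono, 1.0, chi2.sf(stat, 1))


def hwe_filter(control_counts, threshold: float = 1e-7) -> bool:
    """True if the marker is kept (HWE p-value in controls >= threshold)."""
    if isinstance(control_counts, GenotypeCounts):
        control_counts = control_counts.controls
    return bool(hwe_pvalues(control_counts) >= threshold)
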