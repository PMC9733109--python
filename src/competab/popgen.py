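"""Microsatellite population assignment and parentage.

Offspring from a two-population enclosure experiment are classified as pure
or mixed (F1) via a supervised two-panel admixture maximum-likelihood
estimate: founders of the two source populations supply per-locus allele
frequency panels, and for each individual the admixture proportion ``q``
toward population A maximizes

    sum over observed alleles of  log( q * f_A(allele) + (1-q) * f_B(allele) )

with alleles treated independently across the 13 loci. Parentage uses a
single-parent likelihood-ratio (LOD) score against the room's allele
frequencies with an explicit genotyping-error rate, and the population
background of a mixed offspring's mother/father is accepted only when the
two highest-LOD candidates of that sex share a population (the top-2
consensus rule).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import stats
from .genepop import GenepopRecord
from .stats import TestResult

__all__ = [
    "Genotype",
    "AlleleFreqPanel",
    "AssignmentResult",
    "ParentageResult",
    "genotypes_from_records",
    "estimate_freqs",
    "pooled_freqs",
    "assign_origin",
    "parent_lod",
    "assign_parent_population",
    "sire_population_test",
]

N_LOCI_DEFAULT = 13
PURE_THRESHOLDS = (0.9, 0.1)
MIN_INFORMATIVE_LOCI = 6
UNSEEN_ALLELE_FREQ = 1e-4  # floor for alleles absent from every founder


@dataclass
class Genotype:
    """A diploid multilocus genotype plus individual metadata."""

    individual_id: str
    loci: tuple  # per locus: (a1, a2) or None
    sex: Optional[str] = None  # "M" | "F"
    cohort: Optional[str] = None  # "founder" | "healthcheck" | "final"
    room: Optional[str] = None
    population: Optional[str] = None  # known for founders

    def __post_init__(self) -> None:
        for g in self.loci:
            if g is not None and (g[0] <= 0 or g[1] <= 0):
                raise ValueError("alleles must be positive integers")

    @property
    def n_typed(self) -> int:
        return sum(g is not None for g in self.loci)


@dataclass
class AlleleFreqPanel:
    """Per-locus allele frequencies for one source population."""

    population: str
    freqs: tuple  # per locus: dict allele -> frequency (sums to 1)

    def freq(self, locus: int, allele: int) -> float:
        return self.freqs[locus].get(allele, UNSEEN_ALLELE_FREQ)


@dataclass
class AssignmentResult:
    individual_id: str
    q_hat: float  # admixture proportion toward population A (nan if unassigned)
    log_likelihood: float
    origin_class: str  # "pure_A" | "pure_B" | "mixed" | "unassigned"
    uninformative: bool = False


@dataclass
class ParentageResult:
    offspring_id: str
    candidates: dict = field(default_factory=dict)  # sex -> [(id, lod), (id, lod)]
    consensus: dict = field(default_factory=dict)  # sex -> population | "undetermined"


def genotypes_from_records(
    records: Sequence[GenepopRecord], manifest: pd.DataFrame
) -> list[Genotype]:
    """Join GenePop records with a manifest (individual_id, sex, cohort, room,
    population)."""
    meta = manifest.set_index("individual_id")
    out = []
    for rec in records:
        if rec.individual_id not in meta.index:
            raise ValueError(f"{rec.individual_id} missing from manifest")
        row = meta.loc[rec.individual_id]
        pop = row.get("population")
        out.append(
            Genotype(
                individual_id=rec.individual_id,
                loci=rec.genotypes,
                sex=row.get("sex"),
                cohort=row.get("cohort"),
                room=row.get("room"),
                population=None if pd.isna(pop) else pop,
            )
        )
    return out


def _allele_union(genotypes: Sequence[Genotype], n_loci: int) -> list[set]:
    union: list[set] = [set() for _ in range(n_loci)]
    for g in genotypes:
        for i, pair in enumerate(g.loci):
            if pair is not None:
                union[i].update(pair)
    return union


def estimate_freqs(
    founders_by_pop: Mapping[str, Sequence[Genotype]],
    pseudocount: float = 0.5,
    min_founders: int = 5,
) -> dict[str, AlleleFreqPanel]:
    """Counting allele-frequency estimator with additive smoothing.

    The allele support at each locus is the union over *all* founders, so
    every allele observed anywhere has positive frequency in both panels
    after smoothing.
    """
    pops = list(founders_by_pop)
    if len(pops) != 2:
        raise ValueError("exactly two founder populations are required")
    all_founders = [g for pop in pops for g in founders_by_pop[pop]]
    if not all_founders:
        raise ValueError("no founders supplied")
    n_loci = len(all_founders[0].loci)
    for pop in pops:
        if len(founders_by_pop[pop]) < min_founders:
            raise ValueError(
                f"population {pop!r} has fewer than {min_founders} founders"
            )
    union = _allele_union(all_founders, n_loci)
    panels = {}
    for pop in pops:
        per_locus = []
        for i in range(n_loci):
            alleles = sorted(union[i])
            counts = {a: float(pseudocount) for a in alleles}
            observed = 0
            for g in founders_by_pop[pop]:
                pair = g.loci[i]
                if pair is None:
                    continue
                counts[pair[0]] += 1.0
                counts[pair[1]] += 1.0
                observed += 1
            if observed == 0:
                warnings.warn(
                    f"locus {i} entirely missing in population {pop!r}; "
                    "using a uniform frequency panel"
                )
                counts = {a: 1.0 for a in alleles}
            total = sum(counts.values())
            if total == 0:
                counts = {a: 1.0 for a in alleles}
                total = float(len(alleles))
            per_locus.append({a: c / total for a, c in counts.items()})
        panels[pop] = AlleleFreqPanel(population=pop, freqs=tuple(per_locus))
    return panels


def pooled_freqs(
    genotypes: Sequence[Genotype], pseudocount: float = 0.5
) -> AlleleFreqPanel:
    """Room-pooled allele frequencies (the parentage background panel)."""
    if not genotypes:
        raise ValueError("no genotypes supplied")
    n_loci = len(genotypes[0].loci)
    union = _allele_union(genotypes, n_loci)
    per_locus = []
    for i in range(n_loci):
        counts = {a: float(pseudocount) for a in sorted(union[i])}
        for g in genotypes:
            pair = g.loci[i]
            if pair is None:
                continue
            counts[pair[0]] += 1.0
            counts[pair[1]] += 1.0
        total = sum(counts.values()) or 1.0
        per_locus.append({a: c / total for a, c in counts.items()})
    return AlleleFreqPanel(population="pooled", freqs=tuple(per_locus))


def _admixture_loglik(
    genotype: Genotype, panel_a: AlleleFreqPanel, panel_b: AlleleFreqPanel, q: float
) -> float:
    ll = 0.0
    for i, pair in enumerate(genotype.loci):
        if pair is None:
            continue
        for allele in pair:
            fa = panel_a.freq(i, allele)
            fb = panel_b.freq(i, allele)
            ll += math.log(q * fa + (1.0 - q) * fb)
    return ll


def assign_origin(
    genotype: Genotype,
    panel_a: AlleleFreqPanel,
    panel_b: AlleleFreqPanel,
    thresholds: tuple[float, float] = PURE_THRESHOLDS,
    min_loci: int = MIN_INFORMATIVE_LOCI,
    grid_step: float = 0.001,
) -> AssignmentResult:
    """Maximum-likelihood admixture proportion and pure/mixed class.

    ``q_hat`` maximizes the two-panel mixture likelihood over a grid of step
    ``grid_step`` followed by golden-section refinement. Individuals typed at
    fewer than ``min_loci`` loci are unassigned; identical panels leave the
    likelihood flat, in which case ``q_hat`` is tie-broken to 0.5 and the
    result flagged uninformative.
    """
    hi, lo = thresholds
    if not 0.0 < lo < hi < 1.0:
        raise ValueError("thresholds must satisfy 0 < lower < upper < 1")
    if genotype.n_typed < min_loci:
        return AssignmentResult(
            individual_id=genotype.individual_id,
            q_hat=float("nan"),
            log_likelihood=float("nan"),
            origin_class="unassigned",
        )
    qs = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    lls = np.array([_admixture_loglik(genotype, panel_a, panel_b, q) for q in qs])
    if lls.max() - lls.min() < 1e-9:
        return AssignmentResult(
            individual_id=genotype.individual_id,
            q_hat=0.5,
            log_likelihood=float(lls[0]),
            origin_class="mixed",
            uninformative=True,
        )
    best = float(qs[int(np.argmax(lls))])
    lo_b = max(0.0, best - grid_step)
    hi_b = min(1.0, best + grid_step)
    res = minimize_scalar(
        lambda q: -_admixture_loglik(genotype, panel_a, panel_b, q),
        bounds=(lo_b, hi_b),
        method="bounded",
        options={"xatol": 1e-6},
    )
    q_hat = float(np.clip(res.x, 0.0, 1.0))
    ll_hat = -float(res.fun)
    if ll_hat < lls.max():  # refinement must not lose to the grid
        q_hat, ll_hat = best, float(lls.max())
    if q_hat >= hi:
        cls = "pure_A"
    elif q_hat <= lo:
        cls = "pure_B"
    else:
        cls = "mixed"
    return AssignmentResult(
        individual_id=genotype.individual_id,
        q_hat=q_hat,
        log_likelihood=ll_hat,
        origin_class=cls,
    )


def _transmission_prob(
    off: tuple[int, int], cand: tuple[int, int], f: Mapping[int, float]
) -> float:
    """P(offspring genotype | candidate transmits one allele, the other is a
    random draw from the background frequencies)."""

    def t(allele: int) -> float:
        return 0.5 * (allele == cand[0]) + 0.5 * (allele == cand[1])

    def bg(allele: int) -> float:
        return f.get(allele, UNSEEN_ALLELE_FREQ)

    o1, o2 = off
    if o1 == o2:
        return t(o1) * bg(o1)
    return t(o1) * bg(o2) + t(o2) * bg(o1)


def _hwe_prob(off: tuple[int, int], f: Mapping[int, float]) -> float:
    o1, o2 = off

    def bg(allele: int) -> float:
        return f.get(allele, UNSEEN_ALLELE_FREQ)

    if o1 == o2:
        return bg(o1) ** 2
    return 2.0 * bg(o1) * bg(o2)


def parent_lod(
    offspring: Genotype,
    candidate: Genotype,
    background: AlleleFreqPanel,
    error_rate: float = 0.01,
) -> float:
    """Single-parent LOD score of ``candidate`` for ``offspring``.

    Per locus the parentage likelihood mixes Mendelian transmission with a
    genotyping-error escape: with probability ``1 - error_rate`` the
    offspring genotype follows transmission from the candidate (other allele
    from the background), with probability ``error_rate`` it is a random
    Hardy-Weinberg draw. The alternative is an unrelated Hardy-Weinberg
    genotype. Loci missing in either individual are skipped. With
    ``error_rate = 0`` a single Mendelian-impossible locus drives the LOD to
    ``-inf`` (hard exclusion).
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    lod = 0.0
    for i, off in enumerate(offspring.loci):
        cand = candidate.loci[i]
        if off is None or cand is None:
            continue
        f = background.freqs[i]
        p_hwe = _hwe_prob(off, f)
        num = (1.0 - error_rate) * _transmission_prob(off, cand, f) + error_rate * p_hwe
        if num == 0.0:
            return float("-inf")
        lod += math.log10(num / p_hwe)
    return lod


def assign_parent_population(
    offspring: Genotype,
    candidates: Sequence[Genotype],
    background: AlleleFreqPanel,
    error_rate: float = 0.01,
) -> ParentageResult:
    """Top-2 parent candidates per sex with the consensus population rule.

    Candidates are ranked by LOD (ties broken by id for determinism); the
    maternal/paternal population background is accepted only when the two
    highest-ranked candidates of that sex share a population. Sexes with
    fewer than two candidates are undetermined.
    """
    result = ParentageResult(offspring_id=offspring.individual_id)
    for sex in ("F", "M"):
        pool = [c for c in candidates if c.sex == sex]
        if len(pool) < 2:
            result.candidates[sex] = []
            result.consensus[sex] = "undetermined"
            continue
        scored = sorted(
            ((parent_lod(offspring, c, background, error_rate), c) for c in pool),
            key=lambda t: (-t[0], str(t[1].individual_id)),
        )
        top2 = [(c.individual_id, lod) for lod, c in scored[:2]]
        result.candidates[sex] = top2
        pops = {c.population for lod, c in scored[:2]}
        result.consensus[sex] = pops.pop() if len(pops) == 1 else "undetermined"
    return result


def sire_population_test(
    counts_per_room: Mapping[str, tuple[int, int]]
) -> dict[str, Optional[dict[str, TestResult]]]:
    """Equal-proportions tests on offspring sired per population.

    ``counts_per_room`` maps a room label to ``(n_sired_pop_a, n_sired_pop_b)``
    over offspring with a determined paternal background. Each room and the
    pooled counts are tested three ways: the one-sample continuity-corrected
    proportion test, the exact binomial, and the mirrored two-sample
    proportion test (k/n vs (n-k)/n, the form matching R's two-vector
    ``prop.test`` call on such count pairs).
    """
    out: dict[str, Optional[dict[str, TestResult]]] = {}
    pooled = [0, 0]
    for room, (ka, kb) in counts_per_room.items():
        pooled[0] += ka
        pooled[1] += kb
        out[room] = _sire_tests(ka, kb)
    out["pooled"] = _sire_tests(*pooled)
    return out


def _sire_tests(ka: int, kb: int) -> Optional[dict[str, TestResult]]:
    n = ka + kb
    if n == 0:
        return None
    return {
        "prop_cc": stats.prop_test_cc(ka, n, 0.5, "two_sided"),
        "binom_exact": stats.binom_exact(ka, n, 0.5, "two_sided"),
        "prop_mirrored": stats.prop_test_two_sample(ka, n, kb, n),
    }
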