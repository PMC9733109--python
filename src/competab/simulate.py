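"""Synthetic-data generators with attached ground truth.

Three generators emulate the statistical structure the analysis modules
assume, so every pipeline stage is testable without the original recordings:

* :func:`gen_dyad` — dyadic encounters: Poisson conflict bouts per 10-min
  session, a per-dyad dominant individual, role-specific behavior emission,
  and 15-s compartment scans from a per-role Markov chain.
* :func:`gen_enclosure` — two arenas joined by three double-antenna tubes;
  each mouse follows a continuous-time Markov chain over
  {home arena, tube, foreign arena} and every true antenna pass is detected
  with a configurable probability.
* :func:`gen_pedigree` — two divergent founder populations (Balding-Nichols
  allele frequencies at a target Fst), Hardy-Weinberg founders, Mendelian
  offspring from pure and mixed matings, then genotyping error and
  missingness.

Seeding: one root seed per generator call fans out to per-unit child streams
via ``numpy.random.SeedSequence.spawn`` in unit order, so enlarging a cohort
never perturbs the draws of earlier units. The same seed yields byte
identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genepop import GenepopRecord

__all__ = [
    "DyadSimConfig",
    "PopulationMovement",
    "EnclosureSimConfig",
    "PedigreeSimConfig",
    "CB_LIKE",
    "MC_LIKE",
    "gen_dyad",
    "gen_enclosure",
    "gen_pedigree",
]

DEFAULT_SEED = 1234


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# dyadic encounters
# ---------------------------------------------------------------------------

WINNER_EMISSION = {
    "attack": 0.3, "chase": 0.25, "tail_rattle": 0.2, "box": 0.1,
    "fight": 0.1, "bite": 0.05,
}
LOSER_EMISSION = {
    "flight": 0.6, "submissive_posture": 0.25, "escape_to_water": 0.15,
}
NEUTRAL_EMISSION = {"sniffing": 0.5, "cleaning": 0.3, "vocalization": 0.2}

# compartment preference vectors (home, neutral, foreign, escape, tube, water)
COMPARTMENTS = ("home", "neutral", "foreign", "escape", "tube", "water")
WINNER_PREF = (0.34, 0.24, 0.30, 0.02, 0.07, 0.03)
LOSER_PREF = (0.55, 0.26, 0.05, 0.06, 0.05, 0.03)
NEUTRAL_PREF = (0.44, 0.24, 0.20, 0.03, 0.06, 0.03)


@dataclass
class DyadSimConfig:
    """Encounter-generator settings; defaults mirror the study conditions
    (15 dyads, two 10-min sessions, ~21 conflicts/session of which ~42%
    are decided, near-total win asymmetry for the dominant)."""

    n_dyads: int = 15
    sessions_per_dyad: int = 2
    session_length_s: float = 600.0
    conflict_rate: float = 21.3  # Poisson mean bouts per session
    decided_prob: float = 0.42
    dominant_win_prob: float = 0.95
    prob_dominant_pop_a: float = 10 / 13
    pop_labels: tuple = ("CB", "MC")
    neutral_rate: float = 15.0  # Poisson mean neutral events per mouse-session
    scan_interval_s: float = 15.0
    gap_s: float = 15.0  # matched by the scorer's segmentation default
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        for p in (self.decided_prob, self.dominant_win_prob, self.prob_dominant_pop_a):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.conflict_rate < 0:
            raise ValueError("conflict_rate must be >= 0")


def _sample_behaviors(rng: np.random.Generator, table: dict, k: int) -> list[str]:
    names = list(table)
    probs = np.array([table[n] for n in names])
    return list(rng.choice(names, size=k, p=probs / probs.sum()))


def gen_dyad(config: DyadSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate encounter events, location scans, and per-dyad truth.

    Truth maps dyad id to members, populations, the true dominant, bout
    intervals per day, and conflict tallies. Bouts are spaced more than
    ``gap_s`` apart so gap-based segmentation can recover them exactly;
    bouts that no longer fit in the session are dropped (and absent from
    the truth as well).
    """
    rngs = _spawn_rngs(config.seed, config.n_dyads)
    events_rows, scan_rows = [], []
    truth: dict = {}
    pop_a, pop_b = config.pop_labels
    for d in range(1, config.n_dyads + 1):
        rng = rngs[d - 1]
        id_a = f"d{d:02d}_{pop_a}"
        id_b = f"d{d:02d}_{pop_b}"
        dominant = id_a if rng.random() < config.prob_dominant_pop_a else id_b
        subordinate = id_b if dominant == id_a else id_a
        bouts_truth = []
        n_conflicts = n_decided = 0
        wins = {id_a: 0, id_b: 0}
        for day in (1, 2):
            n_bouts = int(rng.poisson(config.conflict_rate))
            starts = np.sort(rng.uniform(0, config.session_length_s, size=n_bouts))
            t_prev_end = -math.inf
            for s in starts:
                start = max(s, t_prev_end + config.gap_s + 1.0)
                n_ev = int(rng.integers(2, 5))
                gaps = np.minimum(rng.exponential(1.0, size=n_ev - 1), 3.0)
                times = start + np.concatenate([[0.0], np.cumsum(gaps)])
                if times[-1] > config.session_length_s:
                    continue
                decided = rng.random() < config.decided_prob
                if decided:
                    winner = (
                        dominant
                        if rng.random() < config.dominant_win_prob
                        else subordinate
                    )
                    loser = id_b if winner == id_a else id_a
                    behaviors, actors = [], []
                    # at least one defensive event by the loser, offense by winner
                    n_def = max(1, int(rng.integers(1, max(2, n_ev // 2 + 1))))
                    n_off = n_ev - n_def
                    behaviors += _sample_behaviors(rng, LOSER_EMISSION, n_def)
                    actors += [loser] * n_def
                    behaviors += _sample_behaviors(
                        rng, WINNER_EMISSION, max(n_off, 0)
                    )
                    actors += [winner] * max(n_off, 0)
                    wins[winner] += 1
                    n_decided += 1
                else:
                    # both offensive, nobody defensive
                    behaviors = _sample_behaviors(rng, WINNER_EMISSION, n_ev)
                    actors = list(rng.choice([id_a, id_b], size=n_ev))
                order = rng.permutation(len(behaviors))
                for t, k in zip(times, order):
                    events_rows.append(
                        {
                            "dyad_id": d,
                            "day": day,
                            "time_s": float(t),
                            "actor_id": actors[k],
                            "behavior": behaviors[k],
                        }
                    )
                bouts_truth.append(
                    {"day": day, "start": float(times[0]), "end": float(times[-1]),
                     "decided": bool(decided)}
                )
                n_conflicts += 1
                t_prev_end = times[-1]
            # neutral chatter from both individuals
            for ind in (id_a, id_b):
                n_neu = int(rng.poisson(config.neutral_rate))
                for t in rng.uniform(0, config.session_length_s, size=n_neu):
                    events_rows.append(
                        {
                            "dyad_id": d,
                            "day": day,
                            "time_s": float(t),
                            "actor_id": ind,
                            "behavior": _sample_behaviors(rng, NEUTRAL_EMISSION, 1)[0],
                        }
                    )
            # 15-s compartment scans from a per-role Markov chain
            n_ticks = int(config.session_length_s // config.scan_interval_s)
            for ind in (id_a, id_b):
                if n_decided > 0:
                    pref = WINNER_PREF if ind == dominant else LOSER_PREF
                else:
                    pref = NEUTRAL_PREF
                pref = np.asarray(pref)
                state = 0  # home
                for tick in range(n_ticks):
                    probs = 0.5 * np.eye(len(COMPARTMENTS))[state] + 0.5 * pref
                    state = int(rng.choice(len(COMPARTMENTS), p=probs / probs.sum()))
                    scan_rows.append(
                        {
                            "dyad_id": d,
                            "day": day,
                            "time_s": (tick + 1) * config.scan_interval_s,
                            "individual_id": ind,
                            "compartment": COMPARTMENTS[state],
                        }
                    )
        truth[d] = {
            "members": (id_a, id_b),
            "populations": {id_a: pop_a, id_b: pop_b},
            "dominant": dominant if n_decided > 0 else None,
            "wins": wins,
            "n_conflicts": n_conflicts,
            "n_decided": n_decided,
            "bouts": bouts_truth,
        }
    events = pd.DataFrame(
        events_rows, columns=["dyad_id", "day", "time_s", "actor_id", "behavior"]
    ).sort_values(["dyad_id", "day", "time_s"], kind="stable").reset_index(drop=True)
    scans = pd.DataFrame(
        scan_rows,
        columns=["dyad_id", "day", "time_s", "individual_id", "compartment"],
    )
    return events, scans, truth


# ---------------------------------------------------------------------------
# enclosure movement
# ---------------------------------------------------------------------------


@dataclass
class PopulationMovement:
    """Continuous-time movement rates for one population (all means in s)."""

    mean_first_exploration_s: float
    mean_tube_entry_interval_s: float
    crossing_prob: float
    mean_tube_dwell_s: float
    mean_foreign_sojourn_s: float

    def __post_init__(self) -> None:
        for v in (
            self.mean_first_exploration_s,
            self.mean_tube_entry_interval_s,
            self.mean_tube_dwell_s,
            self.mean_foreign_sojourn_s,
        ):
            if v <= 0:
                raise ValueError("movement means must be positive")
        if not 0.0 <= self.crossing_prob <= 1.0:
            raise ValueError("crossing_prob must lie in [0, 1]")


# scenario presets: ordered contrasts only (shorter latencies, more
# crossings and longer foreign sojourns for the CB-like population)
CB_LIKE = PopulationMovement(90.0, 600.0, 0.5, 15.0, 2400.0)
MC_LIKE = PopulationMovement(300.0, 1800.0, 0.25, 15.0, 900.0)


@dataclass
class EnclosureSimConfig:
    """Enclosure-generator settings; the default cohort mirrors one room at
    the experiment start (23 CB-like in arena A, 27 MC-like in arena B) over
    a 12-week experiment."""

    n_pop_a: int = 23
    n_pop_b: int = 27
    movement_a: PopulationMovement = field(default_factory=lambda: CB_LIKE)
    movement_b: PopulationMovement = field(default_factory=lambda: MC_LIKE)
    pop_labels: tuple = ("CB", "MC")
    detection_prob: float = 0.9
    duration_s: float = 12 * 7 * 24 * 3600.0
    n_tubes: int = 3
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not 0.0 < self.detection_prob <= 1.0:
            raise ValueError("detection_prob must lie in (0, 1]")
        if self.duration_s <= 0 or self.n_tubes < 1:
            raise ValueError("invalid duration or tube count")


def gen_enclosure(config: EnclosureSimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate antenna reads plus the true continuous-time trajectory.

    Returns a read table (``timestamp, antenna_tube, antenna_side, tag_id``)
    and a truth dict per tag: home arena, population, sex, weight, true
    crossing times, true per-arena/tube occupancy seconds, and the true
    first tube-approach time.
    """
    n_total = config.n_pop_a + config.n_pop_b
    rngs = _spawn_rngs(config.seed, n_total)
    reads_rows = []
    truth: dict = {}
    pop_a, pop_b = config.pop_labels
    for m in range(n_total):
        rng = rngs[m]
        if m < config.n_pop_a:
            pop, move, home = pop_a, config.movement_a, "A"
            tag = f"{pop_a}{m + 1:03d}"
        else:
            pop, move, home = pop_b, config.movement_b, "B"
            tag = f"{pop_b}{m - config.n_pop_a + 1:03d}"
        sex = "M" if rng.random() < 0.5 else "F"
        weight = float(np.round(rng.normal(20.4, 4.3), 2))
        t = 0.0
        loc = home
        first_approach: Optional[float] = None
        crossings: list[float] = []
        occupancy = {"arena_A": 0.0, "arena_B": 0.0, "tube": 0.0}
        T = config.duration_s
        while t < T:
            if first_approach is None:
                wait = rng.exponential(move.mean_first_exploration_s)
            elif loc == home:
                wait = rng.exponential(move.mean_tube_entry_interval_s)
            else:
                wait = rng.exponential(move.mean_foreign_sojourn_s)
            if t + wait >= T:
                occupancy[f"arena_{loc}"] += T - t
                t = T
                break
            occupancy[f"arena_{loc}"] += wait
            t += wait
            if first_approach is None:
                first_approach = t
            tube = int(rng.integers(1, config.n_tubes + 1))
            # entrance antenna pass (on the current arena's side)
            if rng.random() < config.detection_prob:
                reads_rows.append((t, tube, loc, tag))
            dwell = rng.exponential(move.mean_tube_dwell_s)
            if t + dwell >= T:
                occupancy["tube"] += T - t
                t = T
                break
            occupancy["tube"] += dwell
            t += dwell
            cross = rng.random() < move.crossing_prob
            exit_side = ("B" if loc == "A" else "A") if cross else loc
            if rng.random() < config.detection_prob:
                reads_rows.append((t, tube, exit_side, tag))
            if cross:
                crossings.append(t)
                loc = exit_side
        truth[tag] = {
            "population": pop,
            "sex": sex,
            "weight": weight,
            "home_arena": home,
            "first_approach_s": first_approach,
            "crossing_times": crossings,
            "n_crossings": len(crossings),
            "occupancy_s": occupancy,
        }
    reads = pd.DataFrame(
        reads_rows, columns=["timestamp", "antenna_tube", "antenna_side", "tag_id"]
    ).sort_values("timestamp", kind="stable").reset_index(drop=True)
    return reads, truth


# ---------------------------------------------------------------------------
# pedigree / microsatellites
# ---------------------------------------------------------------------------


@dataclass
class PedigreeSimConfig:
    """Pedigree-generator settings; defaults target the study's marker panel
    (13 unlinked microsatellites) and a room-scale founder cohort."""

    n_loci: int = 13
    n_alleles: int = 14  # typical polymorphism of wild-mouse microsat panels
    fst: float = 0.15
    founders_per_population: int = 25
    n_pure_matings: int = 10
    n_mixed_matings: int = 10
    offspring_per_mating: int = 3
    genotyping_error: float = 0.01
    missing_rate: float = 0.01
    pop_labels: tuple = ("CB", "MC")
    room: str = "R1"
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.n_alleles < 2:
            raise ValueError("need >= 1 locus and >= 2 alleles")
        if self.fst < 0:
            raise ValueError("fst must be >= 0")
        for p in (self.genotyping_error, self.missing_rate):
            if not 0.0 <= p < 1.0:
                raise ValueError("rates must lie in [0, 1)")


def _population_freqs(
    rng: np.random.Generator, n_loci: int, n_alleles: int, fst: float
) -> tuple[np.ndarray, np.ndarray]:
    """Balding-Nichols: per-locus population frequencies around a common
    ancestral frequency, calibrated so the expected *pairwise* Fst (Nei's
    Gst) between the two populations approximates ``fst``.

    Each population diverges from the ancestral pool by F'; for two
    independently drawn populations the expected pairwise Gst is
    (F'/2) / (1 - F'/2), so F' = 2 fst / (1 + fst) targets ``fst``.
    """
    ancestral = rng.dirichlet(np.ones(n_alleles), size=n_loci)
    if fst <= 0:
        return ancestral.copy(), ancestral.copy()
    f_prime = 2.0 * fst / (1.0 + fst)
    scale = (1.0 - f_prime) / f_prime
    pa = np.vstack([rng.dirichlet(a * scale) for a in ancestral])
    pb = np.vstack([rng.dirichlet(a * scale) for a in ancestral])
    return pa, pb


def _draw_genotype(rng: np.random.Generator, freqs: np.ndarray) -> list[tuple[int, int]]:
    loci = []
    n_alleles = freqs.shape[1]
    for f in freqs:
        a, b = rng.choice(n_alleles, size=2, p=f) + 1  # alleles are 1-based labels
        loci.append((int(a), int(b)))
    return loci


def _mendel(
    rng: np.random.Generator,
    mother: list[tuple[int, int]],
    father: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    return [
        (m[int(rng.integers(2))], f[int(rng.integers(2))])
        for m, f in zip(mother, father)
    ]


def gen_pedigree(
    config: PedigreeSimConfig,
) -> tuple[list[GenepopRecord], pd.DataFrame, dict]:
    """Simulate founders and offspring genotypes with full truth.

    Returns GenePop-style records (block 0 = population A founders, block 1 =
    population B founders, block 2 = offspring), a manifest DataFrame
    (individual_id, sex, cohort, room, population), and truth mapping each
    offspring to its parents and class (``pure_A``/``pure_B``/``F1``).
    """
    streams = _spawn_rngs(config.seed, 4)
    rng_freq, rng_founder, rng_mate, rng_noise = streams
    pa, pb = _population_freqs(rng_freq, config.n_loci, config.n_alleles, config.fst)
    pop_a, pop_b = config.pop_labels

    founders: dict[str, list] = {pop_a: [], pop_b: []}
    true_geno: dict[str, list] = {}
    manifest_rows = []
    records: list[GenepopRecord] = []
    for pop, freqs, block in ((pop_a, pa, 0), (pop_b, pb, 1)):
        for i in range(config.founders_per_population):
            ind = f"{pop}_F{i + 1:03d}"
            sex = "M" if i % 2 == 0 else "F"
            loci = _draw_genotype(rng_founder, freqs)
            true_geno[ind] = loci
            founders[pop].append((ind, sex))
            manifest_rows.append(
                {
                    "individual_id": ind,
                    "sex": sex,
                    "cohort": "founder",
                    "room": config.room,
                    "population": pop,
                }
            )
            records.append(
                GenepopRecord(individual_id=ind, block=block, genotypes=tuple(loci))
            )

    def pick(pop: str, sex: str) -> str:
        pool = [ind for ind, s in founders[pop] if s == sex]
        return pool[int(rng_mate.integers(len(pool)))]

    truth: dict = {"offspring": {}, "populations": (pop_a, pop_b)}
    off_idx = 0
    matings = [("pure", pop_a)] * ((config.n_pure_matings + 1) // 2)
    matings += [("pure", pop_b)] * (config.n_pure_matings // 2)
    matings += [("mixed", None)] * config.n_mixed_matings
    for kind, pop in matings:
        if kind == "pure":
            father, mother = pick(pop, "M"), pick(pop, "F")
            cls = "pure_A" if pop == pop_a else "pure_B"
        else:
            if rng_mate.random() < 0.5:
                father, mother = pick(pop_a, "M"), pick(pop_b, "F")
            else:
                father, mother = pick(pop_b, "M"), pick(pop_a, "F")
            cls = "F1"
        for _ in range(config.offspring_per_mating):
            off_idx += 1
            ind = f"OFF{off_idx:03d}"
            loci = _mendel(rng_mate, true_geno[mother], true_geno[father])
            observed = []
            for a, b in loci:
                pair: Optional[tuple[int, int]] = (a, b)
                if config.genotyping_error > 0:
                    aa = (
                        int(rng_noise.integers(1, config.n_alleles + 1))
                        if rng_noise.random() < config.genotyping_error
                        else a
                    )
                    bb = (
                        int(rng_noise.integers(1, config.n_alleles + 1))
                        if rng_noise.random() < config.genotyping_error
                        else b
                    )
                    pair = (aa, bb)
                if config.missing_rate > 0 and rng_noise.random() < config.missing_rate:
                    pair = None
                observed.append(pair)
            sex = "M" if rng_noise.random() < 0.5 else "F"
            manifest_rows.append(
                {
                    "individual_id": ind,
                    "sex": sex,
                    "cohort": "final",
                    "room": config.room,
                    "population": None,
                }
            )
            records.append(
                GenepopRecord(individual_id=ind, block=2, genotypes=tuple(observed))
            )
            truth["offspring"][ind] = {
                "mother": mother,
                "father": father,
                "class": cls,
            }
    manifest = pd.DataFrame(manifest_rows)
    truth["allele_freqs"] = {pop_a: pa, pop_b: pb}
    return records, manifest, truth
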