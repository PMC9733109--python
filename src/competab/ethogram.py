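"""Dyadic-encounter ethogram analysis.

Reduces event streams from staged one-on-one encounters between males of two
populations to agonistic conflicts, winner calls per dyad, a population-level
dominance summary, a behavior-count matrix for ordination, and compartment
(cage) use summaries from interval location scans.

Input schemas
-------------
Events (one coded behavior observation per row)::

    dyad_id, day, time_s, actor_id, behavior

Scans (one location fix per individual per scan tick)::

    dyad_id, day, time_s, individual_id, compartment

Compartments are ``home, neutral, foreign, escape, tube, water``; behaviors
are classified offensive / defensive / neutral through a configurable JSON
map (see :func:`load_class_map`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import stats
from .stats import TestResult

__all__ = [
    "load_class_map",
    "ConflictRecord",
    "DyadSummary",
    "segment_conflicts",
    "classify_and_score",
    "summary_from_counts",
    "population_bias",
    "behavior_matrix",
    "cage_use",
    "day_effect",
]

EVENT_COLUMNS = ("dyad_id", "day", "time_s", "actor_id", "behavior")
SCAN_COLUMNS = ("dyad_id", "day", "time_s", "individual_id", "compartment")
MAIN_CAGES = ("home", "neutral", "foreign")

DEFAULT_GAP_S = 15.0
DEFAULT_ALPHA = 0.05


def load_class_map(path: Optional[str] = None) -> dict[str, str]:
    """Load a behavior -> class map from JSON.

    The JSON holds ``{"offensive": [...], "defensive": [...], "neutral":
    [...]}``. Without a path the packaged default vocabulary is used.
    """
    if path is None:
        text = (
            resources.files("competab.data")
            .joinpath("behavior_classes.json")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    by_class = json.loads(text)
    out: dict[str, str] = {}
    for cls in ("offensive", "defensive", "neutral"):
        for b in by_class.get(cls, []):
            out[b] = cls
    return out


@dataclass
class ConflictRecord:
    """One agonistic bout within a dyad session."""

    dyad_id: object
    day: int
    start: float
    end: float
    events: pd.DataFrame  # time_s, actor_id, behavior, behavior_class
    participants: tuple
    status: str  # "decided" | "undecided"
    winner_id: Optional[object] = None


@dataclass
class DyadSummary:
    """Decided-conflict tally and dominance call for one dyad (days pooled)."""

    dyad_id: object
    members: tuple
    wins: dict
    total_decided: int
    total_conflicts: int
    test: Optional[TestResult]
    dominant_id: Optional[object]
    status: str  # "hierarchy" | "no hierarchy"
    meta: dict = field(default_factory=dict)  # weight/age/population per member


def _check_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing columns {missing}")


def segment_conflicts(
    events: pd.DataFrame,
    gap_s: float = DEFAULT_GAP_S,
    class_map: Optional[Mapping[str, str]] = None,
    members: Optional[Mapping[object, tuple]] = None,
) -> list[ConflictRecord]:
    """Segment agonistic events into conflicts (bouts).

    Maximal runs of offensive/defensive events whose inter-event gaps do not
    exceed ``gap_s`` form one conflict; neutral-class events never open or
    extend a conflict. A conflict is *decided* iff exactly one of the dyad's
    two members shows defensive behavior in the bout; the other member is
    the winner.
    """
    if gap_s <= 0:
        raise ValueError("gap_s must be positive")
    if class_map is None:
        class_map = load_class_map()
    if events.empty:
        return []
    _check_columns(events, EVENT_COLUMNS, "events")
    ev = events.copy()
    ev["behavior_class"] = ev["behavior"].map(class_map)
    unknown = ev["behavior_class"].isna()
    if unknown.any():
        bad = sorted(ev.loc[unknown, "behavior"].unique())
        raise ValueError(f"behaviors missing from the class map: {bad}")
    conflicts: list[ConflictRecord] = []
    for (dyad, day), grp in ev.groupby(["dyad_id", "day"], sort=True):
        grp = grp.sort_values("time_s", kind="stable")
        if members is not None and dyad in members:
            pair = tuple(members[dyad])
        else:
            pair = tuple(pd.unique(ev.loc[ev["dyad_id"] == dyad, "actor_id"]))
        ago = grp[grp["behavior_class"] != "neutral"]
        if ago.empty:
            continue
        times = ago["time_s"].to_numpy(dtype=float)
        breaks = np.flatnonzero(np.diff(times) > gap_s) + 1
        for chunk in np.split(np.arange(len(ago)), breaks):
            bout = ago.iloc[chunk]
            conflicts.append(
                _make_conflict(dyad, int(day), bout, pair)
            )
    return conflicts


def _make_conflict(
    dyad: object, day: int, bout: pd.DataFrame, pair: tuple
) -> ConflictRecord:
    defensive_actors = set(
        bout.loc[bout["behavior_class"] == "defensive", "actor_id"]
    )
    participants = tuple(pd.unique(bout["actor_id"]))
    winner: Optional[object] = None
    if len(defensive_actors) == 1 and len(pair) == 2:
        loser = next(iter(defensive_actors))
        winner = pair[0] if loser == pair[1] else pair[1]
        status = "decided"
    else:
        status = "undecided"
    return ConflictRecord(
        dyad_id=dyad,
        day=day,
        start=float(bout["time_s"].iloc[0]),
        end=float(bout["time_s"].iloc[-1]),
        events=bout[["time_s", "actor_id", "behavior", "behavior_class"]].reset_index(
            drop=True
        ),
        participants=participants,
        status=status,
        winner_id=winner,
    )


def classify_and_score(
    conflicts: Sequence[ConflictRecord],
    members: Optional[tuple] = None,
    alpha: float = DEFAULT_ALPHA,
    meta: Optional[dict] = None,
) -> DyadSummary:
    """Tally decided conflicts for one dyad (days pooled) and call dominance.

    A member is dominant when it won more than half the decided conflicts
    and the exact binomial test against an even split is significant at
    ``alpha``. Dyads without decided conflicts get status ``"no hierarchy"``.
    """
    conflicts = [c for c in conflicts if c is not None]
    dyads = {c.dyad_id for c in conflicts}
    if len(dyads) > 1:
        raise ValueError(f"conflicts span multiple dyads: {sorted(map(str, dyads))}")
    usable = []
    for c in conflicts:
        if len(c.participants) == 0:
            warnings.warn("conflict with no participants skipped")
            continue
        usable.append(c)
    if members is None:
        pool: list = []
        for c in usable:
            pool.extend(c.participants)
            if c.winner_id is not None:
                pool.append(c.winner_id)
        members = tuple(pd.unique(pd.Series(pool))) if pool else ()
    dyad_id = next(iter(dyads)) if dyads else None
    wins = {m: 0 for m in members}
    total_decided = 0
    for c in usable:
        if c.status == "decided" and c.winner_id is not None:
            wins[c.winner_id] = wins.get(c.winner_id, 0) + 1
            total_decided += 1
    return summary_from_counts(
        dyad_id=dyad_id,
        members=tuple(wins.keys()),
        wins=wins,
        total_conflicts=len(usable),
        alpha=alpha,
        meta=meta,
    )


def summary_from_counts(
    dyad_id: object,
    members: tuple,
    wins: Mapping[object, int],
    total_conflicts: Optional[int] = None,
    alpha: float = DEFAULT_ALPHA,
    meta: Optional[dict] = None,
) -> DyadSummary:
    """Build a :class:`DyadSummary` directly from per-member win counts.

    This is the entry point for re-analyzing published per-dyad tallies
    without the underlying event stream.
    """
    wins = {m: int(wins.get(m, 0)) for m in members}
    total_decided = sum(wins.values())
    if total_conflicts is None:
        total_conflicts = total_decided
    if total_decided < sum(wins.values()) or total_conflicts < total_decided:
        raise ValueError("wins must sum to total decided <= total conflicts")
    if total_decided == 0:
        return DyadSummary(
            dyad_id=dyad_id,
            members=members,
            wins=wins,
            total_decided=0,
            total_conflicts=total_conflicts,
            test=None,
            dominant_id=None,
            status="no hierarchy",
            meta=meta or {},
        )
    top = max(wins, key=lambda m: (wins[m], str(m)))
    test = stats.binom_exact(wins[top], total_decided, 0.5, "two_sided")
    dominant = top if (test.p_value < alpha and wins[top] > total_decided / 2) else None
    return DyadSummary(
        dyad_id=dyad_id,
        members=members,
        wins=wins,
        total_decided=total_decided,
        total_conflicts=total_conflicts,
        test=test,
        dominant_id=dominant,
        status="hierarchy",
        meta=meta or {},
    )


def population_bias(
    summaries: Sequence[DyadSummary], pop_of: Mapping[object, str]
) -> dict:
    """Population-level dominance summary over dyads.

    Reports how many dyads formed a hierarchy and how the dominant
    individuals split between the two populations, each with a one-sided
    continuity-corrected proportion test toward the majority outcome.
    """
    n_dyads = len(summaries)
    decided = [s for s in summaries if s.total_decided > 0]
    n_hier = len(decided)
    wins_by_pop: dict[str, int] = {}
    for s in decided:
        if s.dominant_id is None:
            continue
        pop = pop_of[s.dominant_id]
        wins_by_pop[pop] = wins_by_pop.get(pop, 0) + 1
    out: dict = {
        "n_dyads": n_dyads,
        "n_with_hierarchy": n_hier,
        "dominant_by_population": wins_by_pop,
    }
    if n_hier == 0:
        out["notice"] = "no decided conflicts in any dyad; tests skipped"
        out["prevalence_test"] = None
        out["win_test"] = None
        return out
    out["prevalence_test"] = stats.prop_test_cc(n_hier, n_dyads, 0.5, "greater")
    n_dominated = sum(wins_by_pop.values())
    if n_dominated:
        majority = max(wins_by_pop, key=lambda p: (wins_by_pop[p], str(p)))
        out["majority_population"] = majority
        out["win_test"] = stats.prop_test_cc(
            wins_by_pop[majority], n_dominated, 0.5, "greater"
        )
    else:
        out["win_test"] = None
    return out


def behavior_matrix(
    events: pd.DataFrame, min_total_fraction: float = 0.05
) -> pd.DataFrame:
    """Per-individual behavior counts, keeping globally common behaviors.

    Behaviors are kept when they account for more than ``min_total_fraction``
    of all observed events (across all dyads).
    """
    _check_columns(events, EVENT_COLUMNS, "events")
    counts = pd.crosstab(events["actor_id"], events["behavior"])
    frac = counts.sum(axis=0) / counts.values.sum()
    return counts.loc[:, frac > min_total_fraction]


def day_effect(events: pd.DataFrame) -> Optional[TestResult]:
    """Paired signed-rank test of per-dyad conflict-event counts, day 1 vs 2."""
    _check_columns(events, EVENT_COLUMNS, "events")
    per_day = events.groupby(["dyad_id", "day"]).size().unstack(fill_value=0)
    if per_day.shape[1] != 2:
        return None
    d1, d2 = per_day.iloc[:, 0], per_day.iloc[:, 1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.wilcoxon_signed_rank(d1.to_numpy(), d2.to_numpy())


def cage_use(
    scans: pd.DataFrame,
    pop_of: Optional[Mapping[object, str]] = None,
    alpha: float = DEFAULT_ALPHA,
) -> dict:
    """Compartment-use proportions and the cage-preference test battery.

    Per individual, the share of 15-s location scans in each compartment
    (water and escape pooled). Friedman tests ask whether the three main
    cages are visited equally often (overall and per population); pairwise
    signed-rank tests between the main cages are Bonferroni-corrected
    (m = 3); foreign-cage use is compared between populations pairing the
    two members of each dyad.
    """
    _check_columns(scans, SCAN_COLUMNS, "scans")
    sc = scans.copy()
    sc["compartment"] = sc["compartment"].replace(
        {"water": "water_escape", "escape": "water_escape"}
    )
    categories = ["home", "neutral", "foreign", "tube", "water_escape"]
    bad = set(sc["compartment"]) - set(categories)
    if bad:
        raise ValueError(f"unknown compartments: {sorted(bad)}")
    counts = pd.crosstab(sc["individual_id"], sc["compartment"]).reindex(
        columns=categories, fill_value=0
    )
    zero = counts.sum(axis=1) == 0
    if zero.any():
        warnings.warn(
            f"individuals with zero scans excluded: {list(counts.index[zero])}"
        )
        counts = counts[~zero]
    props = counts.div(counts.sum(axis=1), axis=0)
    main = props[list(MAIN_CAGES)]

    report: dict = {"proportions": props}
    report["friedman_all"] = stats.friedman(main.to_numpy())
    if pop_of is not None:
        pops = pd.Series({i: pop_of[i] for i in main.index})
        for pop in sorted(pops.unique()):
            block = main.loc[pops[pops == pop].index]
            report[f"friedman_{pop}"] = (
                stats.friedman(block.to_numpy()) if len(block) >= 2 else None
            )
    pair_names, raw_p, pair_tests = [], [], {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for a, b in (("home", "neutral"), ("home", "foreign"), ("neutral", "foreign")):
            t = stats.wilcoxon_signed_rank(main[a].to_numpy(), main[b].to_numpy())
            pair_names.append(f"{a}_vs_{b}")
            raw_p.append(t.p_value)
            pair_tests[f"{a}_vs_{b}"] = t
    adjusted = stats.bonferroni(raw_p, m=3)
    report["pairwise_cages"] = pair_tests
    report["pairwise_cages_bonferroni"] = dict(zip(pair_names, adjusted))

    if pop_of is not None:
        dyad_of = sc.groupby("individual_id")["dyad_id"].first()
        foreign = props["foreign"]
        rows = []
        for dyad, inds in dyad_of.groupby(dyad_of):
            ids = list(inds.index)
            if len(ids) != 2:
                continue
            by_pop = {pop_of[i]: foreign[i] for i in ids}
            if len(by_pop) == 2:
                rows.append(by_pop)
        if len(rows) >= 2:
            paired = pd.DataFrame(rows)
            cols = sorted(paired.columns)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t = stats.wilcoxon_signed_rank(
                    paired[cols[0]].to_numpy(), paired[cols[1]].to_numpy()
                )
            report["foreign_between_populations"] = t
            report["foreign_between_populations_order"] = tuple(cols)
        else:
            report["foreign_between_populations"] = None
    return report
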