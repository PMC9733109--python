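"""End-to-end analysis stages and report tables.

Each ``run_*`` function is a pure function of (inputs, config): it consumes
parsed tables, runs the corresponding analysis modules, and returns a report
dict; with an output directory it also serializes the report tables as TSV
plus the effective configuration (including all seeds) as JSON, so a run
can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import ethogram, popgen, rfid, stats
from .ethogram import DyadSummary
from .genepop import GenepopRecord
from .popgen import Genotype

__all__ = ["RunConfig", "run_encounter", "encounter_report_from_counts",
           "run_enclosure", "run_popgen", "EmptyResultError"]


class EmptyResultError(RuntimeError):
    """Raised when a stage has nothing to analyze (CLI exit code 3)."""


@dataclass
class RunConfig:
    """All tunable stage parameters with their recorded defaults."""

    # ethogram
    gap_s: float = 15.0
    alpha: float = 0.05
    min_total_fraction: float = 0.05
    # rfid
    t_open: float = 0.0
    t_end: Optional[float] = None
    session_gap_s: float = 10.0
    tube_transit_max_s: Optional[float] = None  # accepted, unused by the
    # conservative occupancy rule (opposite-side reads always count one passage)
    # popgen
    pure_threshold: float = 0.9
    mixed_threshold: float = 0.1
    genotyping_error: float = 0.01
    pseudocount: float = 0.5
    min_informative_loci: int = 6
    # permutation tests
    n_perm_anosim: int = 999
    n_perm_mantel: int = 9999
    n_perm_permanova: int = 999
    seed: int = stats.DEFAULT_SEED

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _write_tsv(df: pd.DataFrame, path: Path, comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# encounter stage
# ---------------------------------------------------------------------------


def _dyad_table(summaries: list[DyadSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"dyad_id": s.dyad_id}
        for k, member in enumerate(s.members, start=1):
            meta = s.meta.get(member, {})
            row[f"id_{k}"] = member
            row[f"population_{k}"] = meta.get("population")
            row[f"weight_{k}"] = meta.get("weight")
            row[f"age_{k}"] = meta.get("age")
            row[f"wins_{k}"] = s.wins.get(member, 0)
        row["total_decided"] = s.total_decided
        row["total_conflicts"] = s.total_conflicts
        row["binomial_p"] = s.test.p_value if s.test else np.nan
        row["dominant_id"] = s.dominant_id
        row["status"] = s.status
        rows.append(row)
    return pd.DataFrame(rows)


def _aggregate_encounter(
    summaries: list[DyadSummary], pop_of: Mapping[object, str]
) -> dict:
    report: dict = {}
    report["dyad_table"] = _dyad_table(summaries)
    report["bias"] = ethogram.population_bias(summaries, pop_of)
    totals: dict[str, int] = {}
    for s in summaries:
        for m, w in s.wins.items():
            pop = pop_of[m]
            totals[pop] = totals.get(pop, 0) + w
    report["decided_by_population"] = totals
    report["total_decided"] = sum(s.total_decided for s in summaries)
    report["total_conflicts"] = sum(s.total_conflicts for s in summaries)

    # weight and age contrasts between the populations
    pops = sorted(set(pop_of.values()))
    if len(pops) == 2:
        by_pop: dict[str, dict[str, list[float]]] = {
            p: {"weight": [], "age": []} for p in pops
        }
        paired: dict[str, list[tuple[float, float]]] = {"weight": [], "age": []}
        for s in summaries:
            vals = {}
            for m in s.members:
                meta = s.meta.get(m, {})
                pop = pop_of[m]
                for v in ("weight", "age"):
                    if meta.get(v) is not None:
                        by_pop[pop][v].append(float(meta[v]))
                        vals.setdefault(v, {})[pop] = float(meta[v])
            for v in ("weight", "age"):
                if len(vals.get(v, {})) == 2:
                    paired[v].append((vals[v][pops[0]], vals[v][pops[1]]))
        report["mean_weight"] = {
            p: float(np.mean(by_pop[p]["weight"])) if by_pop[p]["weight"] else np.nan
            for p in pops
        }
        report["mean_age"] = {
            p: float(np.mean(by_pop[p]["age"])) if by_pop[p]["age"] else np.nan
            for p in pops
        }
        if all(by_pop[p]["weight"] for p in pops):
            report["weight_rank_sum"] = stats.mann_whitney(
                by_pop[pops[0]]["weight"], by_pop[pops[1]]["weight"]
            )
        if len(paired["weight"]) >= 2:
            w0 = [a for a, _ in paired["weight"]]
            w1 = [b for _, b in paired["weight"]]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report["weight_paired"] = {
                    f"{pops[0]}_minus_{pops[1]}": stats.wilcoxon_signed_rank(w0, w1),
                    f"{pops[1]}_minus_{pops[0]}": stats.wilcoxon_signed_rank(w1, w0),
                }
    return report


def encounter_report_from_counts(
    counts: pd.DataFrame, config: Optional[RunConfig] = None
) -> dict:
    """Encounter report from a per-dyad summary table.

    ``counts`` needs columns ``dyad_id`` and, for each member k in (1, 2):
    ``pop_k, weight_k, age_k, wins_k`` (the shape of the bundled
    ``encounter_dyads`` table).
    """
    config = config or RunConfig()
    summaries: list[DyadSummary] = []
    pop_of: dict[object, str] = {}
    for _, row in counts.iterrows():
        members, wins, meta = [], {}, {}
        for k in (1, 2):
            member = f"d{row['dyad_id']}_{row[f'pop_{k}']}"
            members.append(member)
            wins[member] = int(row[f"wins_{k}"])
            meta[member] = {
                "population": row[f"pop_{k}"],
                "weight": float(row[f"weight_{k}"]),
                "age": float(row[f"age_{k}"]),
            }
            pop_of[member] = row[f"pop_{k}"]
        summaries.append(
            ethogram.summary_from_counts(
                dyad_id=row["dyad_id"],
                members=tuple(members),
                wins=wins,
                alpha=config.alpha,
                meta=meta,
            )
        )
    return _aggregate_encounter(summaries, pop_of)


def run_encounter(
    events: Optional[pd.DataFrame] = None,
    scans: Optional[pd.DataFrame] = None,
    counts: Optional[pd.DataFrame] = None,
    pop_of: Optional[Mapping[object, str]] = None,
    config: Optional[RunConfig] = None,
    outdir: Optional[str] = None,
    class_map: Optional[Mapping[str, str]] = None,
) -> dict:
    """Score an encounter experiment end to end.

    Either raw ``events`` (plus optional ``scans``) or a per-dyad ``counts``
    table must be provided. With events, the report additionally carries the
    behavior matrix, its PCA, the Bray-Curtis/ANOSIM ordination test on the
    population grouping, and the day-1-vs-day-2 conflict check; with scans,
    the cage-use battery.
    """
    config = config or RunConfig()
    if counts is not None:
        report = encounter_report_from_counts(counts, config)
    elif events is not None and not events.empty:
        conflicts = ethogram.segment_conflicts(
            events, gap_s=config.gap_s, class_map=class_map
        )
        by_dyad: dict = {}
        for c in conflicts:
            by_dyad.setdefault(c.dyad_id, []).append(c)
        if pop_of is None:
            # infer population labels from the id suffix used by the simulator
            pop_of = {
                a: str(a).rsplit("_", 1)[-1] for a in events["actor_id"].unique()
            }
        summaries = [
            ethogram.classify_and_score(cs, alpha=config.alpha)
            for cs in by_dyad.values()
        ]
        for s in summaries:
            s.meta = {m: {"population": pop_of[m]} for m in s.members}
        report = _aggregate_encounter(summaries, pop_of)
        report["day_effect"] = ethogram.day_effect(events)
        bm = ethogram.behavior_matrix(events, config.min_total_fraction)
        report["behavior_matrix"] = bm
        if bm.shape[1] >= 2:
            report["pca"] = stats.pca_counts(bm, min_total_fraction=0.0)
            dm = stats.bray_curtis(bm)
            groups = [pop_of[i] for i in bm.index]
            if len(set(groups)) == 2 and min(
                pd.Series(groups).value_counts()
            ) >= 2:
                report["anosim_population"] = stats.anosim(
                    dm, groups, n_perm=config.n_perm_anosim, seed=config.seed
                )
    else:
        report = {"dyad_table": pd.DataFrame(), "notice": "no input events"}
    if scans is not None and not scans.empty:
        report["cage_use"] = ethogram.cage_use(scans, pop_of=pop_of)
    elif events is not None:
        report["cage_use"] = None
        report.setdefault("notices", []).append("no scans; cage use skipped")
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_json(out / "config.json")
        _write_tsv(
            report["dyad_table"], out / "dyad_summary.tsv",
            "per-dyad decided-conflict summary (weights, ages, wins, binomial p)",
        )
        named = _collect_named_tests(report)
        _write_tsv(stats.results_table(named), out / "encounter_stats.tsv",
                   "aggregate encounter statistics")
    return report


def _collect_named_tests(report: dict) -> dict:
    named: dict = {}
    bias = report.get("bias") or {}
    if bias.get("prevalence_test"):
        named["hierarchy_prevalence"] = bias["prevalence_test"]
    if bias.get("win_test"):
        named["population_dominance"] = bias["win_test"]
    if report.get("weight_rank_sum"):
        named["weight_rank_sum"] = report["weight_rank_sum"]
    for key, t in (report.get("weight_paired") or {}).items():
        named[f"weight_paired_{key}"] = t
    if report.get("day_effect"):
        named["day_effect"] = report["day_effect"]
    if report.get("anosim_population"):
        named["anosim_population"] = report["anosim_population"]
    cage = report.get("cage_use")
    if cage:
        for k, v in cage.items():
            if isinstance(v, stats.TestResult):
                named[f"cage_{k}"] = v
    return named


# ---------------------------------------------------------------------------
# enclosure stage
# ---------------------------------------------------------------------------


def run_enclosure(
    reads: pd.DataFrame,
    tag_manifest: pd.DataFrame,
    config: Optional[RunConfig] = None,
    outdir: Optional[str] = None,
    n_perm: Optional[int] = None,
) -> dict:
    """Track an enclosure room: occupancy, metrics, and comparisons.

    ``tag_manifest`` needs columns ``tag_id, home_arena`` and optionally
    ``population, sex, weight``. Tags never read are reported as excluded,
    mirroring how untracked transponders drop out of the analysis.
    """
    config = config or RunConfig()
    if config.t_end is None:
        if reads.empty:
            raise EmptyResultError("no reads and no explicit t_end")
        t_end = float(reads["time_s"].max())
    else:
        t_end = config.t_end
    metrics, occupancy_rows, excluded = [], [], []
    for _, row in tag_manifest.iterrows():
        tag = row["tag_id"]
        sub = reads[reads["tag_id"] == tag]
        m = rfid.compute_metrics(
            sub,
            home_arena=row["home_arena"],
            t_open=config.t_open,
            t_end=t_end,
            session_gap_s=config.session_gap_s,
            population=row.get("population"),
            sex=row.get("sex"),
            weight=row.get("weight"),
        )
        if m is None:
            excluded.append(tag)
            continue
        metrics.append(m)
        intervals, _ = rfid.infer_occupancy(
            sub, row["home_arena"], config.t_open, t_end
        )
        occupancy_rows.extend(
            {"tag_id": iv.tag_id, "start": iv.start, "end": iv.end,
             "location": iv.location}
            for iv in intervals
        )
    if not metrics:
        raise EmptyResultError("no tag was ever read")
    mdf = rfid.metrics_frame(metrics)
    report: dict = {
        "metrics": mdf,
        "excluded_tags": excluded,
        "occupancy": pd.DataFrame(occupancy_rows),
        "summary": rfid.summarize_metrics(mdf),
        "mean_fraction_assigned": float(mdf["fraction_assigned"].mean()),
    }
    pops = mdf["population"].dropna().unique()
    if len(pops) == 2 and min((mdf["population"] == p).sum() for p in pops) >= 2:
        report["compare"] = rfid.cohort_compare(
            mdf, n_perm=n_perm or config.n_perm_permanova, seed=config.seed
        )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_json(out / "config.json")
        _write_tsv(report["occupancy"], out / "occupancy.tsv",
                   "inferred per-tag occupancy intervals (BED-like)")
        _write_tsv(mdf, out / "metrics.tsv", "per-mouse behavioral metrics")
        _write_tsv(report["summary"], out / "metrics_summary.tsv",
                   "per-population metric summaries (mean, sd, median, min, max)")
    return report


# ---------------------------------------------------------------------------
# popgen stage
# ---------------------------------------------------------------------------


def run_popgen(
    records: list[GenepopRecord],
    manifest: pd.DataFrame,
    config: Optional[RunConfig] = None,
    outdir: Optional[str] = None,
    min_founders: int = 5,
) -> dict:
    """Assign population origin for all non-founders and resolve parentage.

    Founders (cohort == 'founder', labeled population) supply the two allele
    frequency panels. Mixed-class offspring get per-sex top-2 parentage with
    the consensus rule against all same-room adult candidates; sire counts
    per room feed the equal-proportions tests.
    """
    config = config or RunConfig()
    genotypes = popgen.genotypes_from_records(records, manifest)
    founders = [g for g in genotypes if g.cohort == "founder" and g.population]
    pops = sorted({g.population for g in founders})
    if len(pops) != 2:
        raise EmptyResultError("need founders labeled with exactly 2 populations")
    by_pop = {p: [g for g in founders if g.population == p] for p in pops}
    for p in pops:
        if len(by_pop[p]) < min_founders:
            raise EmptyResultError(f"founder panel for {p!r} is too small")
    panels = popgen.estimate_freqs(by_pop, pseudocount=config.pseudocount,
                                   min_founders=min_founders)
    panel_a, panel_b = panels[pops[0]], panels[pops[1]]

    non_founders = [g for g in genotypes if g.cohort != "founder"]
    assignments = {
        g.individual_id: popgen.assign_origin(
            g, panel_a, panel_b,
            thresholds=(config.pure_threshold, config.mixed_threshold),
            min_loci=config.min_informative_loci,
        )
        for g in non_founders
    }
    class_counts = (
        pd.Series([a.origin_class for a in assignments.values()])
        .value_counts()
        .to_dict()
    )
    origin_table = pd.DataFrame(
        [
            {
                "individual_id": a.individual_id,
                "q_hat": a.q_hat,
                "origin_class": a.origin_class,
                "uninformative": a.uninformative,
            }
            for a in assignments.values()
        ]
    )

    # parentage for mixed offspring, per room, against same-room adults
    geno_by_id = {g.individual_id: g for g in genotypes}
    mixed_ids = [i for i, a in assignments.items() if a.origin_class == "mixed"]
    parentage: dict = {}
    sire_counts: dict[str, list[int]] = {}
    for ind in mixed_ids:
        off = geno_by_id[ind]
        room = off.room
        candidates = [
            g for g in genotypes
            if g.room == room and g.individual_id != ind and g.cohort == "founder"
        ]
        background = popgen.pooled_freqs(
            [g for g in genotypes if g.room == room], config.pseudocount
        )
        res = popgen.assign_parent_population(
            off, candidates, background, error_rate=config.genotyping_error
        )
        parentage[ind] = res
        sire = res.consensus.get("M", "undetermined")
        key = str(room)
        sire_counts.setdefault(key, [0, 0])
        if sire == pops[0]:
            sire_counts[key][0] += 1
        elif sire == pops[1]:
            sire_counts[key][1] += 1
    report: dict = {
        "populations": tuple(pops),
        "panels": panels,
        "assignments": assignments,
        "origin_table": origin_table,
        "class_counts": class_counts,
        "parentage": parentage,
        "sire_counts": {k: tuple(v) for k, v in sire_counts.items()},
    }
    if sire_counts:
        report["sire_tests"] = popgen.sire_population_test(
            {k: tuple(v) for k, v in sire_counts.items()}
        )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_json(out / "config.json")
        _write_tsv(origin_table, out / "origin_assignments.tsv",
                   "admixture proportion and pure/mixed class per individual")
        sire_df = pd.DataFrame(
            [
                {"room": k, pops[0]: v[0], pops[1]: v[1]}
                for k, v in report["sire_counts"].items()
            ]
        )
        _write_tsv(sire_df, out / "sire_counts.tsv",
                   "offspring sired per population and room")
    return report
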