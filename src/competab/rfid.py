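"""RFID enclosure tracking: occupancy inference and behavioral metrics.

Two round arenas (A and B) are connected by three tubes, each carrying one
antenna at each arena entrance. Every antenna pass of a transpondered mouse
may produce a timestamped read. From the per-tag read stream this module
infers arena occupancy deterministically and conservatively:

* time before the first read belongs to the tag's home arena (animals are
  born and raised there before the connections open);
* the interval between two consecutive same-side reads (any tube) belongs
  to that side's arena;
* the interval between opposite-side reads is left unassigned and counts as
  exactly one passage — an odd number of crossings must have occurred and
  one is the minimum-evidence count, which is robust to missed reads;
* time after the last read belongs to the last read's arena.

The four behavioral metrics of interest are touch latency (first read after
the connections open), cross latency (first read on the foreign side after
the first read), the number of passages, and time in the home/foreign arena;
"sessions" (maximal same-antenna read runs with short internal gaps) index
overall antenna activity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import stats
from .stats import TestResult

__all__ = [
    "READ_COLUMNS",
    "OccupancyInterval",
    "BehavioralMetrics",
    "parse_reads",
    "infer_occupancy",
    "compute_metrics",
    "metrics_frame",
    "cohort_compare",
    "summarize_metrics",
]

logger = logging.getLogger(__name__)

READ_COLUMNS = ("timestamp", "antenna_tube", "antenna_side", "tag_id")
ARENAS = ("A", "B")
METRIC_VARS = ("touch_latency_s", "cross_latency_s", "n_sessions", "time_foreign_h")


@dataclass
class OccupancyInterval:
    tag_id: object
    start: float
    end: float
    location: str  # "arena_A" | "arena_B" | "unassigned"


@dataclass
class BehavioralMetrics:
    tag_id: object
    touch_latency_s: Optional[float]
    cross_latency_s: Optional[float]
    n_passages: int
    n_sessions: int
    time_home_h: float
    time_foreign_h: float
    fraction_assigned: float
    population: Optional[str] = None
    sex: Optional[str] = None
    weight: Optional[float] = None


def _other(arena: str) -> str:
    return "B" if arena == "A" else "A"


def parse_reads(path_or_buffer, valid_tubes: Sequence[int] = (1, 2, 3)) -> pd.DataFrame:
    """Read an antenna log CSV into a clean read table.

    Expects columns ``timestamp, antenna_tube, antenna_side, tag_id`` with
    ISO-8601 or epoch-seconds timestamps. Rows with unknown antenna ids are
    rejected (counted in ``df.attrs['n_rejected']`` and logged); duplicate
    (tag, antenna, timestamp) rows are collapsed; output is sorted per tag.
    """
    df = pd.read_csv(path_or_buffer)
    if df.empty:
        out = pd.DataFrame(columns=["time_s", "tube", "side", "tag_id"])
        out.attrs["n_rejected"] = 0
        return out
    missing = [c for c in READ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"read log is missing columns {missing}")
    ts = df["timestamp"]
    if pd.api.types.is_numeric_dtype(ts):
        time_s = ts.astype(float)
    else:
        parsed = pd.to_datetime(ts, format="ISO8601", utc=True)
        time_s = parsed.astype("int64") / 1e9
    out = pd.DataFrame(
        {
            "time_s": time_s,
            "tube": pd.to_numeric(df["antenna_tube"], errors="coerce"),
            "side": df["antenna_side"].astype(str).str.upper(),
            "tag_id": df["tag_id"],
        }
    )
    ok = out["tube"].isin(list(valid_tubes)) & out["side"].isin(ARENAS)
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("rejected %d reads with unknown antenna ids", n_rejected)
    out = out[ok]
    out["tube"] = out["tube"].astype(int)
    out = (
        out.drop_duplicates(subset=["tag_id", "tube", "side", "time_s"])
        .sort_values(["tag_id", "time_s"], kind="stable")
        .reset_index(drop=True)
    )
    out.attrs["n_rejected"] = n_rejected
    return out


def infer_occupancy(
    reads: pd.DataFrame,
    home_arena: str,
    t_open: float,
    t_end: float,
) -> Optional[tuple[list[OccupancyInterval], int]]:
    """Infer occupancy intervals and the passage count for one tag.

    Returns ``None`` for tags with zero reads (they are excluded from
    metrics downstream). Otherwise the returned intervals tile
    ``[t_open, t_end]`` exactly and the second element is the number of
    inferred arena crossings.
    """
    if home_arena not in ARENAS:
        raise ValueError("home_arena must be 'A' or 'B'")
    if not t_open < t_end:
        raise ValueError("t_open must precede t_end")
    if reads.empty:
        return None
    tags = reads["tag_id"].unique()
    if len(tags) != 1:
        raise ValueError("infer_occupancy expects reads from a single tag")
    tag = tags[0]
    r = reads.sort_values("time_s", kind="stable")
    outside = (r["time_s"] < t_open) | (r["time_s"] > t_end)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} reads outside [t_open, t_end] clipped for tag {tag}"
        )
        r = r[~outside]
        if r.empty:
            return None
    times = r["time_s"].to_numpy(dtype=float)
    sides = r["side"].to_numpy()

    intervals: list[OccupancyInterval] = []
    passages = 0

    def push(start: float, end: float, location: str) -> None:
        if end <= start:
            return
        if intervals and intervals[-1].location == location and intervals[-1].end == start:
            intervals[-1].end = end
        else:
            intervals.append(OccupancyInterval(tag, start, end, location))

    push(t_open, times[0], f"arena_{home_arena}")
    for idx in range(len(times) - 1):
        if sides[idx] == sides[idx + 1]:
            push(times[idx], times[idx + 1], f"arena_{sides[idx]}")
        else:
            push(times[idx], times[idx + 1], "unassigned")
            passages += 1
    push(times[-1], t_end, f"arena_{sides[-1]}")
    # instantaneous boundary bookkeeping: ensure exact tiling
    if not intervals:
        intervals.append(
            OccupancyInterval(tag, t_open, t_end, f"arena_{sides[-1]}")
        )
    return intervals, passages


def _count_sessions(r: pd.DataFrame, session_gap_s: float) -> int:
    """Maximal same-antenna read runs with intra-run gaps <= session_gap_s."""
    if r.empty:
        return 0
    times = r["time_s"].to_numpy(dtype=float)
    antenna = list(zip(r["tube"].to_numpy(), r["side"].to_numpy()))
    sessions = 1
    for idx in range(1, len(times)):
        if antenna[idx] != antenna[idx - 1] or times[idx] - times[idx - 1] > session_gap_s:
            sessions += 1
    return sessions


def compute_metrics(
    reads: pd.DataFrame,
    home_arena: str,
    t_open: float,
    t_end: float,
    session_gap_s: float = 10.0,
    population: Optional[str] = None,
    sex: Optional[str] = None,
    weight: Optional[float] = None,
) -> Optional[BehavioralMetrics]:
    """Compute the per-mouse behavioral metrics from its read stream.

    Returns ``None`` when the tag was never read. Touch latency is the time
    from ``t_open`` to the first read; cross latency the time from the first
    read to the first read at a foreign-side antenna (missing when the mouse
    never reached the foreign side).
    """
    occ = infer_occupancy(reads, home_arena, t_open, t_end)
    if occ is None:
        return None
    intervals, passages = occ
    r = reads.sort_values("time_s", kind="stable")
    r = r[(r["time_s"] >= t_open) & (r["time_s"] <= t_end)]
    times = r["time_s"].to_numpy(dtype=float)
    sides = r["side"].to_numpy()
    first = times[0]
    foreign = _other(home_arena)
    foreign_times = times[sides == foreign]
    cross = float(foreign_times[0] - first) if foreign_times.size else None
    dur = {"arena_A": 0.0, "arena_B": 0.0, "unassigned": 0.0}
    for iv in intervals:
        dur[iv.location] += iv.end - iv.start
    total = t_end - t_open
    return BehavioralMetrics(
        tag_id=r["tag_id"].iloc[0],
        touch_latency_s=float(first - t_open),
        cross_latency_s=cross,
        n_passages=passages,
        n_sessions=_count_sessions(r, session_gap_s),
        time_home_h=dur[f"arena_{home_arena}"] / 3600.0,
        time_foreign_h=dur[f"arena_{foreign}"] / 3600.0,
        fraction_assigned=(total - dur["unassigned"]) / total,
        population=population,
        sex=sex,
        weight=weight,
    )


def metrics_frame(metrics: Iterable[Optional[BehavioralMetrics]]) -> pd.DataFrame:
    """Stack per-mouse metrics into a DataFrame, dropping excluded (None) tags."""
    rows = [vars(m) for m in metrics if m is not None]
    return pd.DataFrame(rows)


def summarize_metrics(df: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd, median, min and max per population for each metric."""
    vars_ = ["weight", "n_sessions", "touch_latency_s", "cross_latency_s",
             "n_passages", "time_home_h", "time_foreign_h"]
    rows = []
    for pop, grp in df.groupby("population"):
        for v in vars_:
            if v not in grp:
                continue
            vals = grp[v].dropna().astype(float)
            if vals.empty:
                continue
            rows.append(
                {
                    "population": pop,
                    "metric": v,
                    "n": len(vals),
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                    "median": vals.median(),
                    "min": vals.min(),
                    "max": vals.max(),
                }
            )
    return pd.DataFrame(rows)


def cohort_compare(
    metrics: pd.DataFrame,
    n_perm: int = 999,
    seed: int = stats.DEFAULT_SEED,
) -> dict:
    """Between-population comparison battery on the behavioral metrics.

    Rank-sum tests per metric, the two headline Pearson correlations
    (touch vs cross latency; foreign time vs passages), and a sequential
    PERMANOVA of the four metrics on population + sex + weight. Mice missing
    a metric are excluded pairwise from that comparison and listwise from
    the PERMANOVA.
    """
    pops = sorted(metrics["population"].dropna().unique())
    if len(pops) != 2:
        raise ValueError("cohort_compare expects exactly 2 populations")
    a, b = pops
    if (metrics["population"] == a).sum() < 2 or (metrics["population"] == b).sum() < 2:
        raise ValueError("need at least 2 mice per population")
    out: dict = {"populations": (a, b), "summary": summarize_metrics(metrics)}
    tests: dict[str, Optional[TestResult]] = {}
    for v in ("weight", "touch_latency_s", "cross_latency_s", "n_passages",
              "n_sessions", "time_foreign_h"):
        if v not in metrics:
            continue
        xa = metrics.loc[metrics["population"] == a, v].dropna().to_numpy(dtype=float)
        xb = metrics.loc[metrics["population"] == b, v].dropna().to_numpy(dtype=float)
        if xa.size == 0 or xb.size == 0:
            tests[v] = None
            continue
        tests[v] = stats.mann_whitney(xa, xb)
    out["rank_sum"] = tests

    lat = metrics[["touch_latency_s", "cross_latency_s"]].dropna()
    out["corr_touch_cross"] = (
        stats.pearson(lat["touch_latency_s"], lat["cross_latency_s"])
        if len(lat) >= 3
        else None
    )
    fp = metrics[["time_foreign_h", "n_passages"]].dropna()
    out["corr_foreign_passages"] = (
        stats.pearson(fp["time_foreign_h"], fp["n_passages"]) if len(fp) >= 3 else None
    )

    needed = list(METRIC_VARS) + ["population", "sex", "weight"]
    complete = metrics.dropna(subset=[c for c in needed if c in metrics])
    if len(complete) >= 6:
        response = complete[list(METRIC_VARS)]
        predictors = pd.DataFrame(
            {
                "population": complete["population"].astype("category"),
                "sex": complete["sex"].astype("category"),
                "weight": complete["weight"].astype(float),
            },
            index=complete.index,
        )
        out["permanova"] = stats.permanova(
            response, predictors, n_perm=n_perm, seed=seed
        )
    else:
        out["permanova"] = None
    return out
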