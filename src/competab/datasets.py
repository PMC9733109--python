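"""Bundled example tables.

Two small published-style summary tables from a two-population house-mouse
competition experiment ship with the package so the encounter and paternity
reports can be exercised without raw recordings:

* ``encounter_dyads`` — per-dyad weights (g), ages (days) and decided-conflict
  win counts for 15 male-male dyads (one CB and one MC individual each).
* ``sire_counts`` — per-room counts of mixed-background offspring sired by
  CB vs MC males, plus offspring whose paternal background stayed
  undetermined under the top-2 consensus rule.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("competab.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_encounter_dyads() -> pd.DataFrame:
    """Per-dyad encounter summary (15 dyads; columns for both members)."""
    return _read("encounter_dyads.tsv")


def load_sire_counts() -> pd.DataFrame:
    """Per-room sired-offspring counts for mixed-background offspring."""
    return _read("sire_counts.tsv")
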