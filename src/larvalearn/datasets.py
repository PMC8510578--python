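"""Bundled reference data: pooled approach/avoid counts per experimental
condition from the individual-larva CO2 / reward-neuron Y-maze conditioning
study.  These aggregate tallies are the published summary of the per-decision
source data; they support worked-example arithmetic (pooled preferences,
Fisher exact tests on pre/post counts) without the per-animal spreadsheets.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_counts", "reference_condition", "pooled_preference"]


def load_reference_counts() -> pd.DataFrame:
    """Pooled choice counts per condition.

    Columns: figure, experiment, genotype, n_larvae, approach/avoid counts
    for the pre-training, post-training, and next-day test phases (NaN where
    a phase was not run).
    """
    with resources.files("larvalearn").joinpath("reference_counts.csv").open() as fh:
        return pd.read_csv(fh)


def reference_condition(experiment: str, figure: str | None = None) -> pd.Series:
    """One condition's row, selected by experiment label (and figure when the
    label is reused across figures)."""
    df = load_reference_counts()
    sel = df[df["experiment"] == experiment]
    if figure is not None:
        sel = sel[sel["figure"] == figure]
    if len(sel) == 0:
        raise KeyError(f"no reference condition {experiment!r}")
    return sel.iloc[0]


def pooled_preference(row: pd.Series, phase: str = "post") -> float:
    """Decision-weighted preference from a reference row: approach / total."""
    a = row[f"approach_{phase}"]
    v = row[f"avoid_{phase}"]
    return float(a) / (float(a) + float(v))
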