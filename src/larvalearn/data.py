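"""Domain types and table I/O for individual-larva two-alternative choice data.

A larva crawling in a Y-maze repeatedly chooses between a channel carrying
CO2-laden air and a channel carrying clean air.  Each junction crossing is one
binary decision (APPROACH = entered the CO2 channel, AVOID = entered the clean
channel; backing up before the junction is not a choice and is never recorded).
Decisions are scored in temporal sequence within experimental phases: an
hour-long naive test (PRE), an hour-long test after training (POST), and an
optional retest the following day (NEXT_DAY).

The on-disk format is a delimiter-separated table with one decision per row::

    larva_id,group,n_cycles,phase,decision_index,outcome[,time_s]

which is the minimal lossless schema for "each individual animal's decisions
in temporal sequence" style spreadsheets.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "Outcome",
    "Phase",
    "Decision",
    "LarvaRecord",
    "ExperimentGroup",
    "CountsSummary",
    "TableDialect",
    "SchemaError",
    "IntegrityError",
    "read_decision_table",
    "write_decision_table",
    "counts_summary",
]


class SchemaError(ValueError):
    """A required column is missing or an outcome token is unknown."""


class IntegrityError(ValueError):
    """Rows are present but internally inconsistent (duplicates, bad ordering)."""


class Outcome(enum.Enum):
    APPROACH = "approach"
    AVOID = "avoid"


class Phase(enum.Enum):
    PRE = "pre"
    POST = "post"
    NEXT_DAY = "next_day"


@dataclass(frozen=True)
class Decision:
    """One junction choice: ``outcome`` at ordinal position ``index`` (0-based)
    within its phase, optionally stamped with seconds from phase start."""

    outcome: Outcome
    index: int
    time_s: float | None = None


@dataclass
class LarvaRecord:
    """One animal's ordered decisions per phase plus its training dose.

    ``n_cycles`` is the number of CS+US training cycles the animal received
    (the training dose n_c).  Phases with no decisions are kept as empty
    lists: inactive animals stay in the analysis and simply contribute no
    decision weight.
    """

    larva_id: str
    group: str
    n_cycles: int
    decisions: dict[Phase, list[Decision]] = field(default_factory=dict)

    def phase_decisions(self, phase: Phase) -> list[Decision]:
        if not isinstance(phase, Phase):
            raise ValueError(f"unknown phase: {phase!r}")
        return self.decisions.get(phase, [])

    def phase_counts(self, phase: Phase) -> tuple[int, int]:
        """(approach, avoid) tallies for one phase."""
        dec = self.phase_decisions(phase)
        a = sum(1 for d in dec if d.outcome is Outcome.APPROACH)
        return a, len(dec) - a

    def validate(self) -> None:
        if self.n_cycles < 0:
            raise IntegrityError(f"{self.larva_id}: negative n_cycles")
        for phase, dec in self.decisions.items():
            idx = [d.index for d in dec]
            if any(j <= i for i, j in zip(idx, idx[1:])):
                raise IntegrityError(
                    f"{self.larva_id}/{phase.value}: decision_index not strictly increasing"
                )
            times = [d.time_s for d in dec if d.time_s is not None]
            if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
                raise IntegrityError(
                    f"{self.larva_id}/{phase.value}: time_s decreases along the sequence"
                )


@dataclass
class ExperimentGroup:
    """A set of larvae run under one protocol (one row of a summary table)."""

    name: str
    larvae: list[LarvaRecord] = field(default_factory=list)
    protocol: dict = field(default_factory=dict)

    def validate(self) -> None:
        ids = [rec.larva_id for rec in self.larvae]
        if len(ids) != len(set(ids)):
            raise IntegrityError(f"group {self.name}: duplicate larva_id")
        for rec in self.larvae:
            rec.validate()


@dataclass(frozen=True)
class CountsSummary:
    """Pooled approach/avoid tallies per phase over every larva in a group."""

    n_larvae: int
    approach: Mapping[Phase, int]
    avoid: Mapping[Phase, int]

    def totals(self, phase: Phase) -> tuple[int, int]:
        return self.approach.get(phase, 0), self.avoid.get(phase, 0)


@dataclass(frozen=True)
class TableDialect:
    """Column map + delimiter for decision tables.

    The deposited spreadsheets do not come with a fixed column layout, so the
    reader takes a configurable map from semantic role to column name.
    """

    delimiter: str = ","
    columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "larva_id": "larva_id",
            "group": "group",
            "n_cycles": "n_cycles",
            "phase": "phase",
            "decision_index": "decision_index",
            "outcome": "outcome",
            "time_s": "time_s",
        }
    )


_REQUIRED = ("larva_id", "group", "n_cycles", "phase", "decision_index", "outcome")


def _parse_outcome(token: str) -> Outcome:
    try:
        return Outcome(str(token).strip().lower())
    except ValueError:
        raise SchemaError(f"unknown outcome token: {token!r}") from None


def _parse_phase(token: str) -> Phase:
    try:
        return Phase(str(token).strip().lower())
    except ValueError:
        raise SchemaError(f"unknown phase label: {token!r}") from None


def read_decision_table(
    path: str | Path, dialect: TableDialect | None = None
) -> list[ExperimentGroup]:
    """Read a per-decision table into validated :class:`ExperimentGroup` lists.

    Groups are partitioned by the group label; decisions are ordered by
    decision_index within each (larva, phase).
    """
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    cols = dialect.columns
    missing = [role for role in _REQUIRED if cols[role] not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(cols[m] for m in missing)}")
    has_time = cols.get("time_s") in df.columns

    if df.empty:
        return []

    key_cols = [cols["larva_id"], cols["phase"], cols["decision_index"]]
    if df.duplicated(subset=key_cols).any():
        dup = df[df.duplicated(subset=key_cols)].iloc[0]
        raise IntegrityError(
            "duplicate (larva_id, phase, decision_index): "
            f"({dup[key_cols[0]]}, {dup[key_cols[1]]}, {dup[key_cols[2]]})"
        )

    groups: dict[str, ExperimentGroup] = {}
    for (gname, lid), sub in df.groupby([cols["group"], cols["larva_id"]], sort=True):
        n_cycles = int(sub[cols["n_cycles"]].iloc[0])
        rec = LarvaRecord(larva_id=str(lid), group=str(gname), n_cycles=n_cycles)
        for phase_token, psub in sub.groupby(cols["phase"], sort=True):
            phase = _parse_phase(phase_token)
            psub = psub.sort_values(cols["decision_index"], key=lambda s: s.astype(int))
            decisions = []
            for _, row in psub.iterrows():
                t = None
                if has_time and str(row[cols["time_s"]]).strip() != "":
                    t = float(row[cols["time_s"]])
                decisions.append(
                    Decision(
                        outcome=_parse_outcome(row[cols["outcome"]]),
                        index=int(row[cols["decision_index"]]),
                        time_s=t,
                    )
                )
            rec.decisions[phase] = decisions
        rec.validate()
        groups.setdefault(str(gname), ExperimentGroup(name=str(gname))).larvae.append(rec)

    out = list(groups.values())
    for g in out:
        g.validate()
    return out


def write_decision_table(
    groups: Sequence[ExperimentGroup], path: str | Path, dialect: TableDialect | None = None
) -> Path:
    """Write groups to a decision table; lossless round trip with the reader.

    Rows are sorted by (group, larva_id, phase, decision_index).
    """
    dialect = dialect or TableDialect()
    cols = dialect.columns
    rows = []
    any_time = False
    for g in groups:
        g.validate()
        for rec in sorted(g.larvae, key=lambda r: r.larva_id):
            for phase in Phase:
                for d in rec.decisions.get(phase, []):
                    if d.time_s is not None:
                        any_time = True
                    rows.append(
                        {
                            cols["larva_id"]: rec.larva_id,
                            cols["group"]: g.name,
                            cols["n_cycles"]: rec.n_cycles,
                            cols["phase"]: phase.value,
                            cols["decision_index"]: d.index,
                            cols["outcome"]: d.outcome.value,
                            cols["time_s"]: "" if d.time_s is None else d.time_s,
                        }
                    )
    header = [cols[r] for r in _REQUIRED] + ([cols["time_s"]] if any_time or not rows else [])
    df = pd.DataFrame(rows, columns=header)
    path = Path(path)
    df.to_csv(path, sep=dialect.delimiter, index=False)
    return path


def counts_summary(group: ExperimentGroup) -> CountsSummary:
    """Pooled per-phase approach/avoid counts — the decision-weighted tallies
    from which the population preference is computed."""
    approach = {p: 0 for p in Phase}
    avoid = {p: 0 for p in Phase}
    for rec in group.larvae:
        for phase in Phase:
            a, v = rec.phase_counts(phase)
            approach[phase] += a
            avoid[phase] += v
    return CountsSummary(n_larvae=len(group.larvae), approach=approach, avoid=avoid)
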