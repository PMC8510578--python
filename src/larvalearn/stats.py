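"""Preference indices, nested bootstraps, and pre/post significance tests.

The population preference of a group is decision-weighted: the total number
of approach choices made by any larva divided by the total number of choices
made by any larva, so animals that made more decisions contribute more
heavily.  Because successive choices of one animal are not independent,
error bars come from resampling at the animal level:

* hierarchical bootstrap — resample larvae with replacement, then within each
  selected larva resample its decisions with replacement (independently per
  condition);
* animal-only bootstrap — resample larvae with replacement but keep each
  larva's decision sequence intact, preserving within-animal correlations.

In a paired comparison (e.g. the same animals before and after training) the
same resampled animals enter every condition in each replicate.  The
comparison p-value is a ranking-consistency score: the fraction of replicates
whose condition ranking disagrees with (or ties) the reference ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .data import ExperimentGroup, LarvaRecord, Phase

__all__ = [
    "PreferenceEstimate",
    "BootstrapResult",
    "BootstrapComparison",
    "larva_preference",
    "population_preference",
    "hierarchical_bootstrap",
    "animal_bootstrap",
    "fisher_pre_post",
    "mannwhitney_groups",
    "early_late_split",
]


@dataclass(frozen=True)
class PreferenceEstimate:
    """Approach fraction with its decision and animal support.

    ``value`` is NaN (and ``defined`` False) when no decisions were scored.
    """

    value: float
    n_decisions: int
    n_larvae: int

    @property
    def defined(self) -> bool:
        return self.n_decisions > 0

    def as_percent(self) -> float:
        """Preference on the percentage scale, rounded half-up to an integer."""
        if not self.defined:
            return math.nan
        return math.floor(self.value * 100.0 + 0.5)


@dataclass
class BootstrapResult:
    point: float
    replicates: np.ndarray
    sd: float
    B: int
    seed: int


@dataclass
class BootstrapComparison:
    """Per-condition bootstrap summaries plus the ranking-consistency p."""

    results: list[BootstrapResult]
    p_value: float | None
    p_label: str | None

    @property
    def significant_label(self) -> str | None:
        return self.p_label


def larva_preference(record: LarvaRecord, phase: Phase) -> PreferenceEstimate:
    """Single-animal preference: #approach / (#approach + #avoid) in a phase."""
    a, v = record.phase_counts(phase)
    n = a + v
    return PreferenceEstimate(value=a / n if n else math.nan, n_decisions=n, n_larvae=1)


def population_preference(group: ExperimentGroup, phase: Phase) -> PreferenceEstimate:
    """Decision-weighted pooled preference of a group (equals the ratio of the
    pooled counts-summary tallies)."""
    a_tot = v_tot = 0
    for rec in group.larvae:
        a, v = rec.phase_counts(phase)
        a_tot += a
        v_tot += v
    n = a_tot + v_tot
    return PreferenceEstimate(
        value=a_tot / n if n else math.nan, n_decisions=n, n_larvae=len(group.larvae)
    )


def _condition_counts(group: ExperimentGroup, phase: Phase) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([rec.phase_counts(phase)[0] for rec in group.larvae], dtype=np.int64)
    n = np.array([sum(rec.phase_counts(phase)) for rec in group.larvae], dtype=np.int64)
    return a, n


def _paired(conditions: Sequence[tuple[ExperimentGroup, Phase]]) -> bool:
    id_sets = [tuple(sorted(r.larva_id for r in g.larvae)) for g, _ in conditions]
    return all(s == id_sets[0] for s in id_sets[1:])


def _bootstrap(
    conditions: Sequence[tuple[ExperimentGroup, Phase]],
    B: int,
    seed: int,
    resample_decisions: bool,
) -> BootstrapComparison:
    if B <= 0:
        raise ValueError("B must be >= 1")
    if any(len(g.larvae) == 0 for g, _ in conditions):
        raise ValueError("every condition needs at least one larva")
    rng = np.random.default_rng(seed)
    paired = _paired(conditions)

    counts = [_condition_counts(g, p) for g, p in conditions]
    points = []
    for a, n in counts:
        tot = int(n.sum())
        points.append(a.sum() / tot if tot else math.nan)

    shared_idx = None
    if paired:
        x = len(conditions[0][0].larvae)
        shared_idx = rng.integers(0, x, size=(B, x))

    results: list[BootstrapResult] = []
    reps_per_condition: list[np.ndarray] = []
    for (a, n), point in zip(counts, points):
        x = len(a)
        idx = shared_idx if shared_idx is not None else rng.integers(0, x, size=(B, x))
        n_sel = n[idx]
        if resample_decisions:
            p = np.divide(a, n, out=np.zeros(len(a), dtype=float), where=n > 0)
            a_sel = rng.binomial(n_sel, p[idx])
        else:
            a_sel = a[idx]
        denom = n_sel.sum(axis=1)
        reps = np.divide(
            a_sel.sum(axis=1), denom, out=np.full(B, math.nan), where=denom > 0
        )
        reps_per_condition.append(reps)
        results.append(
            BootstrapResult(
                point=point, replicates=reps, sd=float(np.nanstd(reps)), B=B, seed=seed
            )
        )

    p_value = p_label = None
    if len(conditions) == 2:
        diff = reps_per_condition[0] - reps_per_condition[1]
        sign = np.sign(diff)
        ref = math.copysign(1.0, points[0] - points[1]) if points[0] != points[1] else 0.0
        if ref == 0.0:
            # exact tie in point estimates: score consistency against the
            # majority ranking of the replicates themselves
            ref = 1.0 if (sign > 0).sum() >= (sign < 0).sum() else -1.0
        # a replicate supports the reference ranking, opposes it, or ties;
        # ties split half-half so fully degenerate comparisons score p = 0.5
        p_value = float(np.mean(sign == -ref) + 0.5 * np.mean(sign == 0.0))
        p_label = f"< {1.0 / B:g}" if p_value == 0.0 else f"{p_value:.4g}"
    return BootstrapComparison(results=results, p_value=p_value, p_label=p_label)


def hierarchical_bootstrap(
    conditions: Sequence[tuple[ExperimentGroup, Phase]], B: int = 10_000, seed: int = 0
) -> BootstrapComparison:
    """Animal-then-decision resampling.  With two conditions the returned
    comparison carries the ranking-consistency p-value."""
    return _bootstrap(conditions, B, seed, resample_decisions=True)


def animal_bootstrap(
    conditions: Sequence[tuple[ExperimentGroup, Phase]], B: int = 10_000, seed: int = 0
) -> BootstrapComparison:
    """Animal-only resampling: decision sequences kept intact, preserving any
    correlation between one animal's decisions."""
    return _bootstrap(conditions, B, seed, resample_decisions=False)


def fisher_pre_post(
    pre: tuple[int, int], post: tuple[int, int]
) -> float:
    """Two-sided Fisher exact p for the 2x2 table of pooled (approach, avoid)
    counts before and after training.

    Two-sided by the point-probability rule: sum of probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's.  Degenerate tables (any zero margin) return 1.
    """
    a, b = pre
    c, d = post
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)


def mannwhitney_groups(
    prefs_a: Sequence[float], prefs_b: Sequence[float], exact_max_n: int = 8
) -> float:
    """Two-sided Mann-Whitney U p-value treating each larva's preference as
    one measurement.  Exact enumeration for small untied samples
    (min(n, m) <= ``exact_max_n``), tie-corrected normal approximation with
    continuity correction otherwise."""
    a = np.asarray(prefs_a, dtype=float)
    b = np.asarray(prefs_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(a.size, b.size) <= exact_max_n and not has_ties) else "asymptotic"
    return float(
        sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def early_late_split(
    record: LarvaRecord,
    phase: Phase,
    k: int | None = None,
    time_cut_s: float | None = None,
) -> tuple[PreferenceEstimate, PreferenceEstimate]:
    """Split one phase into disjoint early/late preference estimates, either
    by the first ``k`` choices or by a time cut in seconds from phase start.
    Used to test whether the learned preference decays during the readout."""
    if (k is None) == (time_cut_s is None):
        raise ValueError("specify exactly one of k or time_cut_s")
    decisions = record.phase_decisions(phase)
    if k is not None:
        if k < 1:
            raise ValueError("k must be >= 1")
        early, late = decisions[:k], decisions[k:]
    else:
        if any(d.time_s is None for d in decisions):
            raise ValueError("time-based split requires time_s on every decision")
        early = [d for d in decisions if d.time_s <= time_cut_s]
        late = [d for d in decisions if d.time_s > time_cut_s]

    def _est(dec) -> PreferenceEstimate:
        n = len(dec)
        a = sum(1 for d in dec if d.outcome.value == "approach")
        return PreferenceEstimate(value=a / n if n else math.nan, n_decisions=n, n_larvae=1)

    return _est(early), _est(late)
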