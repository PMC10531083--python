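"""Per-animal seizure metrics over a 72-h follow-up and the group statistics.

Outcome measures per animal: latency to the first electrographic seizure,
seizure count, mean seizure duration, cumulative seizure duration, and mean
Racine score, each overall and within three consecutive 24-h epochs
([0, 24), [24, 48), [48, 72] hours post-impact; the final epoch is closed so
the partition is exhaustive).  Conventions, chosen to match how the source
summaries behave:

* event-free animals contribute 0 to count/duration metrics but are
  *excluded* from latency means (latency is undefined without a seizure);
* seizures whose behavioral severity could not be graded ("unknown" Racine)
  are excluded from Racine means — the denominator is graded seizures only.

Group-level battery: Fisher's exact test (own hypergeometric enumeration,
two-sided by the minimum-likelihood rule) for seizure occurrence;
Kruskal-Wallis omnibus plus pairwise Mann-Whitney U vs the vehicle group
with Bonferroni correction for continuous metrics; Friedman's test across
epochs within a group; and pooled-SD Cohen's delta (no small-sample
correction) as the effect size throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SeizureEvent",
    "AnimalRecord",
    "EpochSummary",
    "GroupComparison",
    "EPOCHS",
    "occurrence",
    "latency_to_first",
    "epoch_metrics",
    "animal_metrics",
    "metrics_table",
    "group_summary",
    "fisher_exact_2x2",
    "cohens_delta",
    "cohens_delta_from_samples",
    "group_battery",
    "within_group_evolution",
]

#: (start hour, end hour, closed right edge?) of the three 24-h epochs
EPOCHS = ((0.0, 24.0, False), (24.0, 48.0, False), (48.0, 72.0, True))

_METRICS = ("count", "mean_duration", "cumulative_duration", "racine")


@dataclass(frozen=True)
class SeizureEvent:
    onset_h: float
    duration_s: float
    racine: int | None = None  # None = behavior could not be graded

    def __post_init__(self) -> None:
        if self.onset_h < 0:
            raise ValueError("onset before impact")
        if self.duration_s < 0:
            raise ValueError("negative duration")
        if self.racine is not None and not 0 <= self.racine <= 5:
            raise ValueError("Racine score must be 0-5 or None")


@dataclass
class AnimalRecord:
    animal_id: str
    group: str
    events: list[SeizureEvent] = field(default_factory=list)
    follow_up_h: float = 72.0

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.onset_h > self.follow_up_h:
                raise ValueError(
                    f"{self.animal_id}: onset {ev.onset_h} h beyond follow-up"
                )
        self.events = sorted(self.events, key=lambda e: e.onset_h)


@dataclass(frozen=True)
class EpochSummary:
    epoch: str
    count: int
    cumulative_duration_s: float
    mean_duration_s: float
    mean_racine: float | None  # None when no graded seizure in the epoch


@dataclass(frozen=True)
class GroupComparison:
    test: str
    groups: tuple[str, ...]
    statistic: float
    p: float
    p_adjusted: float
    family_size: int
    cohens_delta: float | None = None


def occurrence(records: list[AnimalRecord]) -> tuple[int, int, float]:
    """(animals with >= 1 seizure, group size, proportion)."""
    if not records:
        raise ValueError("empty group")
    k = sum(1 for r in records if r.events)
    return k, len(records), k / len(records)


def latency_to_first(record: AnimalRecord) -> float | None:
    """Onset of the earliest seizure, or None for an event-free animal."""
    return record.events[0].onset_h if record.events else None


def _summarize(events: list[SeizureEvent], label: str) -> EpochSummary:
    n = len(events)
    cum = float(sum(e.duration_s for e in events))
    graded = [e.racine for e in events if e.racine is not None]
    return EpochSummary(
        epoch=label,
        count=n,
        cumulative_duration_s=cum,
        mean_duration_s=cum / n if n else 0.0,
        mean_racine=float(np.mean(graded)) if graded else None,
    )


def epoch_metrics(record: AnimalRecord) -> tuple[list[EpochSummary], EpochSummary]:
    """Per-epoch summaries plus the 0-72 h totals for one animal.

    Events are assigned to epochs by onset; an onset exactly at 24 or 48 h
    falls in the later epoch, and 72 h in the last.  The decomposition
    conserves counts and seconds exactly.
    """
    if record.follow_up_h < 72.0:
        raise ValueError("epoch metrics require >= 72 h follow-up")
    per_epoch = []
    for lo, hi, closed in EPOCHS:
        sel = [
            e
            for e in record.events
            if lo <= e.onset_h < hi or (closed and e.onset_h == hi)
        ]
        per_epoch.append(_summarize(sel, f"{lo:g}-{hi:g}h"))
    total = _summarize([e for e in record.events if e.onset_h <= 72.0], "0-72h")
    return per_epoch, total


def animal_metrics(record: AnimalRecord) -> dict:
    """Flat per-animal metric dict (one row of the output table)."""
    per_epoch, total = epoch_metrics(record)
    row = {
        "animal": record.animal_id,
        "group": record.group,
        "latency_h": latency_to_first(record),
        "count": total.count,
        "mean_duration": total.mean_duration_s,
        "cumulative_duration": total.cumulative_duration_s,
        "racine": total.mean_racine,
    }
    for ep in per_epoch:
        tag = ep.epoch.replace("-", "_").rstrip("h")
        row[f"count_{tag}"] = ep.count
        row[f"cumulative_duration_{tag}"] = ep.cumulative_duration_s
        row[f"mean_duration_{tag}"] = ep.mean_duration_s
        row[f"racine_{tag}"] = ep.mean_racine
    return row


def metrics_table(records: list[AnimalRecord]) -> pd.DataFrame:
    return pd.DataFrame([animal_metrics(r) for r in records])


def group_summary(records: list[AnimalRecord], metric: str) -> dict:
    """Mean, SD, median, range and n of a per-animal metric for one group."""
    vals = _metric_values(records, metric)
    return {
        "n": len(vals),
        "mean": float(np.mean(vals)) if len(vals) else math.nan,
        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else math.nan,
        "median": float(np.median(vals)) if len(vals) else math.nan,
        "min": float(np.min(vals)) if len(vals) else math.nan,
        "max": float(np.max(vals)) if len(vals) else math.nan,
    }


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Full hypergeometric enumeration with fixed margins; the two-sided p sums
    the probabilities of every table whose probability does not exceed the
    observed one (minimum-likelihood rule, with a 1e-7 relative slack for
    floating-point ties, as exact-test implementations conventionally use).
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValueError("negative counts")
    n = sum(counts)
    if n == 0:
        raise ValueError("empty table")
    r, k = a + b, a + c
    lo, hi = max(0, r + k - n), min(r, k)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r, k)
    p_obs = stats.hypergeom.pmf(a, n, r, k)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def cohens_delta(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Standardized mean difference (mean1 - mean2) / pooled SD.

    The pooled SD is the (n-1)-weighted root mean square of the two group
    SDs; no small-sample (Hedges) correction is applied, which is the
    convention that reproduces the source study's printed effect sizes.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("negative SD")
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ZeroDivisionError("zero pooled SD")
    return (mean1 - mean2) / math.sqrt(pooled_var)


def cohens_delta_from_samples(x1: np.ndarray, x2: np.ndarray) -> float:
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    return cohens_delta(
        float(np.mean(x1)), float(np.std(x1, ddof=1)), len(x1),
        float(np.mean(x2)), float(np.std(x2, ddof=1)), len(x2),
    )


def _metric_values(records: list[AnimalRecord], metric: str) -> np.ndarray:
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; one of {_METRICS}")
    rows = metrics_table(records)
    if rows.empty:
        return np.array([])
    vals = rows[metric if metric != "count" else "count"]
    if metric == "racine":
        vals = vals.dropna()  # animals with no graded seizure drop out
    return vals.to_numpy(dtype=float)


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact when small and tie-free."""
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def group_battery(
    records_by_group: dict[str, list[AnimalRecord]],
    metric: str,
    vehicle_group: str = "VEH",
) -> list[GroupComparison]:
    """Kruskal-Wallis omnibus plus pairwise tests vs the vehicle group.

    Pairwise Mann-Whitney p-values are Bonferroni-adjusted over the number
    of pairwise tests; each pair also carries a pooled-SD Cohen's delta with
    the vehicle-minus-treatment sign convention (positive = favorable for a
    damage/seizure-burden metric).  Degenerate all-tied data yield the
    statistic-undefined, p = 1 convention.
    """
    groups = list(records_by_group)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if vehicle_group not in records_by_group:
        raise ValueError(f"vehicle group {vehicle_group!r} absent")
    samples = {g: _metric_values(records_by_group[g], metric) for g in groups}
    for g, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 usable animals")

    all_vals = np.concatenate(list(samples.values()))
    out: list[GroupComparison] = []
    if np.all(all_vals == all_vals[0]):
        omni_stat, omni_p = math.nan, 1.0
    else:
        kw = stats.kruskal(*samples.values())
        omni_stat, omni_p = float(kw.statistic), float(kw.pvalue)
    out.append(
        GroupComparison(
            test="kruskal-wallis",
            groups=tuple(groups),
            statistic=omni_stat,
            p=omni_p,
            p_adjusted=omni_p,
            family_size=1,
        )
    )

    others = [g for g in groups if g != vehicle_group]
    family = len(others)
    veh = samples[vehicle_group]
    for g in others:
        trt = samples[g]
        combined = np.concatenate([veh, trt])
        if np.all(combined == combined[0]):
            stat, p = math.nan, 1.0
        else:
            stat, p = _mannwhitney(veh, trt)
        try:
            delta = cohens_delta_from_samples(veh, trt)
        except ZeroDivisionError:
            delta = None
        out.append(
            GroupComparison(
                test="mann-whitney",
                groups=(vehicle_group, g),
                statistic=stat,
                p=p,
                p_adjusted=min(1.0, p * family),
                family_size=family,
                cohens_delta=delta,
            )
        )
    return out


def within_group_evolution(
    records: list[AnimalRecord], metric: str = "cumulative_duration"
) -> list[GroupComparison]:
    """Friedman's rank test of a metric across the three epochs in one group.

    Post hoc: pairwise sign tests between epochs (exact binomial on the sign
    of within-animal differences, zeros dropped), Bonferroni-corrected over
    the three epoch pairs.
    """
    if len(records) < 3:
        raise ValueError("Friedman test needs >= 3 animals")
    if metric not in ("count", "cumulative_duration", "mean_duration"):
        raise ValueError(f"metric {metric!r} not defined per-epoch for all animals")
    tags = ["0_24", "24_48", "48_72"]
    rows = metrics_table(records)
    cols = [f"{metric}_{t}" for t in tags]
    data = rows[cols].to_numpy(dtype=float)

    if np.all(data == data[:, [0]]):
        stat, p = math.nan, 1.0
    else:
        fr = stats.friedmanchisquare(*data.T)
        stat, p = float(fr.statistic), float(fr.pvalue)
    out = [
        GroupComparison(
            test="friedman",
            groups=tuple(tags),
            statistic=stat,
            p=p,
            p_adjusted=p,
            family_size=1,
        )
    ]
    pairs = [(0, 1), (1, 2), (0, 2)]
    for i, j in pairs:
        diff = data[:, i] - data[:, j]
        nz = diff[diff != 0]
        if len(nz) == 0:
            stat_ij, p_ij = math.nan, 1.0
        else:
            k = int(np.sum(nz > 0))
            res = stats.binomtest(k, len(nz), 0.5)
            stat_ij, p_ij = float(k), float(res.pvalue)
        out.append(
            GroupComparison(
                test="sign",
                groups=(tags[i], tags[j]),
                statistic=stat_ij,
                p=p_ij,
                p_adjusted=min(1.0, p_ij * len(pairs)),
                family_size=len(pairs),
            )
        )
    return out
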