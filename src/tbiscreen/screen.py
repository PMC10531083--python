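"""In vitro plate-assay normalization, batch adjustment, scoring, lead choice.

Three percent-of-control scales, each anchored by two control conditions
measured on the same plates:

* neuronal viability (MAP-2, 650 nm): untreated inflamed co-culture
  (LPS/IFNg+) = 0 %, iNOS-inhibitor 1400W = 100 %;
* nitrite (Griess, 548 nm): 1400W = 0 %, LPS/IFNg+ = 100 %;
* TNFα (ELISA, 450 nm): IL10 = 0 %, LPS/IFNg+ = 100 %.

Percentages outside [0, 100] are legal and informative (a drug can beat its
positive control).  Replicate plates from independent experiments are
combined with an additive linear model (condition + batch), and the
normalizations are applied to batch-adjusted condition estimates, which
makes them invariant to per-batch absorbance offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ASSAYS",
    "CONTROL_CONDITIONS",
    "AnchorDegenerateError",
    "AssayResult",
    "CompoundScore",
    "ScoreCriteria",
    "BatchFit",
    "default_criteria",
    "normalize_viability",
    "normalize_nitrite",
    "normalize_tnfa",
    "fit_batch_model",
    "normalize_plate",
    "score_compound",
    "select_lead",
]

ASSAYS = ("viability", "nitrite", "tnfa")
CONTROL_CONDITIONS = ("LPS/IFNg+", "LPS/IFNg-", "BV2-", "1400W", "IL10")

#: anchor conditions per assay: (zero-percent anchor, hundred-percent anchor)
_ANCHORS = {
    "viability": ("LPS/IFNg+", "1400W"),
    "nitrite": ("1400W", "LPS/IFNg+"),
    "tnfa": ("IL10", "LPS/IFNg+"),
}


class AnchorDegenerateError(ZeroDivisionError):
    """The two anchor conditions have identical (batch-adjusted) absorbance."""


def _percent(drug_mean: float, zero_mean: float, hundred_mean: float) -> float:
    denom = hundred_mean - zero_mean
    if denom == 0:
        raise AnchorDegenerateError("anchor conditions coincide; percent undefined")
    # ratio first so the hundred-anchor identity is exact in floating point
    return 100.0 * ((drug_mean - zero_mean) / denom)


def normalize_viability(drug_mean: float, lps_mean: float, w1400_mean: float) -> float:
    """Percent neuronal viability: 100*(drug - LPS/IFNg+)/(1400W - LPS/IFNg+)."""
    return _percent(drug_mean, lps_mean, w1400_mean)


def normalize_nitrite(drug_mean: float, lps_mean: float, w1400_mean: float) -> float:
    """Percent nitrite: 100*(drug - 1400W)/(LPS/IFNg+ - 1400W).

    Anchors are swapped relative to viability: the iNOS inhibitor defines
    0 % and the untreated inflamed culture 100 %.
    """
    return _percent(drug_mean, w1400_mean, lps_mean)


def normalize_tnfa(drug_mean: float, lps_mean: float, il10_mean: float) -> float:
    """Percent TNFα: 100*(drug - IL10)/(LPS/IFNg+ - IL10)."""
    return _percent(drug_mean, il10_mean, lps_mean)


_NORMALIZERS = {
    "viability": normalize_viability,
    "nitrite": normalize_nitrite,
    "tnfa": normalize_tnfa,
}


def _condition_key(row: pd.Series) -> str:
    if row["condition"] == "drug":
        return f"drug:{row['drug']}@{row['conc_molar']:g}"
    return str(row["condition"])


@dataclass
class BatchFit:
    """Batch-adjusted condition estimates and contrasts vs LPS/IFNg+."""

    assay: str
    estimates: pd.Series          # condition key -> adjusted mean absorbance
    contrasts: pd.DataFrame       # condition key -> (estimate_diff, p)
    n_batches: int
    n_wells: int


def fit_batch_model(wells: pd.DataFrame, assay: str) -> BatchFit:
    """Fit absorbance = condition + batch by OLS and return adjusted means.

    With a single batch the batch term is dropped and the estimates are the
    raw condition means.  A condition observed in only one batch together
    with a batch observed for only that condition makes the design singular
    and raises ``ValueError``.  Contrast p-values are two-sided t-tests of
    each condition against the LPS/IFNg+ reference.
    """
    df = wells[wells["assay"] == assay].copy()
    if df.empty:
        raise ValueError(f"no wells for assay {assay!r}")
    df["cond_key"] = df.apply(_condition_key, axis=1)
    ref = "LPS/IFNg+"
    if ref not in set(df["cond_key"]):
        raise ValueError("LPS/IFNg+ reference wells missing")

    cond = pd.Categorical(
        df["cond_key"], categories=[ref] + sorted(set(df["cond_key"]) - {ref})
    )
    X = pd.get_dummies(
        pd.Series(cond, name="cond"), prefix="cond", drop_first=True, dtype=float
    )
    batches = sorted(df["batch"].astype(str).unique())
    if len(batches) > 1:
        B = pd.get_dummies(
            df["batch"].astype(str), prefix="batch", drop_first=True, dtype=float
        )
        B.index = X.index
        X = pd.concat([X, B], axis=1)
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("condition confounded with batch: singular design")
    fit = sm.OLS(df["absorbance"].to_numpy(dtype=float), X).fit()

    # adjusted mean for each condition = fit at the across-batch average
    # (the dropped reference batch contributes an offset of 0)
    batch_cols = [c for c in X.columns if c.startswith("batch_")]
    batch_avg = (
        sum(fit.params[c] for c in batch_cols) / (len(batch_cols) + 1)
        if batch_cols
        else 0.0
    )
    estimates, contrasts = {}, {}
    for key in cond.categories:
        col = f"cond_{key}"
        if key == ref:
            estimates[key] = fit.params["const"] + batch_avg
        else:
            estimates[key] = fit.params["const"] + fit.params[col] + batch_avg
            contrasts[key] = (float(fit.params[col]), float(fit.pvalues[col]))
    return BatchFit(
        assay=assay,
        estimates=pd.Series(estimates, name="absorbance"),
        contrasts=pd.DataFrame.from_dict(
            contrasts, orient="index", columns=["estimate", "p"]
        ),
        n_batches=len(batches),
        n_wells=len(df),
    )


@dataclass(frozen=True)
class AssayResult:
    drug: str
    conc_molar: float
    assay: str
    percent: float
    n_wells: int
    n_batches: int


def normalize_plate(wells: pd.DataFrame, assay: str) -> list[AssayResult]:
    """Batch-adjust one assay's wells and normalize every drug x conc cell."""
    fit = fit_batch_model(wells, assay)
    zero_anchor, hundred_anchor = _ANCHORS[assay]
    for anchor in (zero_anchor, hundred_anchor):
        if anchor not in fit.estimates.index:
            raise ValueError(f"anchor condition {anchor!r} missing for {assay}")
    lo = fit.estimates[zero_anchor]
    hi = fit.estimates[hundred_anchor]
    df = wells[(wells["assay"] == assay) & (wells["condition"] == "drug")]
    out = []
    for (drug, conc), grp in df.groupby(["drug", "conc_molar"], sort=True):
        key = f"drug:{drug}@{conc:g}"
        pct = _percent(fit.estimates[key], lo, hi)
        out.append(
            AssayResult(
                drug=str(drug),
                conc_molar=float(conc),
                assay=assay,
                percent=float(pct),
                n_wells=len(grp),
                n_batches=grp["batch"].nunique(),
            )
        )
    return out


@dataclass
class ScoreCriteria:
    """Monotone percent -> [0, 1] score mapping per assay.

    ``direction`` is ``"higher"`` (more percent is better; viability) or
    ``"lower"`` (less is better; nitrite, TNFα).  ``breakpoints`` is a list
    of (percent threshold, score); a percent earns the best score whose
    threshold it meets (>= for "higher", <= for "lower"), else 0.
    """

    direction: str
    breakpoints: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.direction not in ("higher", "lower"):
            raise ValueError("direction must be 'higher' or 'lower'")
        bp = sorted(self.breakpoints)
        scores = [s for _, s in bp]
        ok = scores == sorted(scores) if self.direction == "higher" else scores == sorted(scores, reverse=True)
        if not ok:
            raise ValueError("non-monotone score criteria")
        if any(not 0 <= s <= 1 for s in scores):
            raise ValueError("scores must lie in [0, 1]")
        self.breakpoints = bp

    def score(self, percent: float) -> float:
        best = 0.0
        for thr, s in self.breakpoints:
            if (self.direction == "higher" and percent >= thr) or (
                self.direction == "lower" and percent <= thr
            ):
                best = max(best, s)
        return best


def default_criteria() -> dict[str, ScoreCriteria]:
    """Reconstructed default scoring criteria.

    The published appendix criteria are unavailable; these monotone
    five-breakpoint tables reproduce the lead-selection-relevant published
    rows (trichostatin A 0.75/0.75/1 and calpain inhibitor 0.60/1/1) from
    the published screen percentages.  The full published score table is
    demonstrably not a function of the single summary percentages alone
    (equal percentages map to different published scores), so exact
    reproduction of every row from percentages is impossible; supply scores
    directly, or override these criteria, when full fidelity is needed.
    """
    return {
        "viability": ScoreCriteria(
            "higher", [(0, 0.15), (20, 0.45), (40, 0.60), (65, 0.75), (90, 1.0)]
        ),
        "nitrite": ScoreCriteria(
            "lower", [(0, 1.0), (35, 0.75), (60, 0.45), (85, 0.30), (100, 0.15)]
        ),
        "tnfa": ScoreCriteria(
            "lower", [(0, 1.0), (25, 0.75), (50, 0.60), (75, 0.45), (90, 0.30)]
        ),
    }


@dataclass(frozen=True)
class CompoundScore:
    drug: str
    viability: float | None
    nitrite: float | None
    tnfa: float | None

    @property
    def total(self) -> float:
        return sum(s for s in (self.viability, self.nitrite, self.tnfa) if s is not None)

    @property
    def missing(self) -> tuple[str, ...]:
        return tuple(
            a for a, s in zip(ASSAYS, (self.viability, self.nitrite, self.tnfa))
            if s is None
        )


def score_compound(
    drug: str,
    percents: dict[str, float | None],
    criteria: dict[str, ScoreCriteria] | None = None,
) -> CompoundScore:
    """Map one drug's percent-of-control outcomes to 0-1 scores.

    Missing assays (value ``None`` or absent key) contribute nothing to the
    total and are flagged via :attr:`CompoundScore.missing`.
    """
    criteria = criteria if criteria is not None else default_criteria()
    vals: dict[str, float | None] = {}
    for assay in ASSAYS:
        pct = percents.get(assay)
        vals[assay] = None if pct is None else criteria[assay].score(float(pct))
    return CompoundScore(drug=drug, **vals)


def select_lead(
    scores: list[CompoundScore],
    policy: str = "total",
    toxicity_flags: set[str] | frozenset[str] = frozenset(),
) -> CompoundScore:
    """Pick the lead compound.

    ``policy="total"``: highest total score.  ``policy="viability-priority"``:
    highest neuronal-viability score (the published selection rationale —
    the top-total compound was passed over for the best neuroprotector).
    Toxicity-flagged drugs are excluded first under either policy; ties
    break by total score then lexicographic drug name.
    """
    if policy not in ("total", "viability-priority"):
        raise ValueError(f"unknown policy {policy!r}")
    pool = [s for s in scores if s.drug not in toxicity_flags]
    if not pool:
        raise ValueError("no candidate compounds after toxicity exclusion")

    def sort_key(s: CompoundScore):
        primary = s.total if policy == "total" else (s.viability if s.viability is not None else -1.0)
        return (-primary, -s.total, s.drug)

    return sorted(pool, key=sort_key)[0]
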