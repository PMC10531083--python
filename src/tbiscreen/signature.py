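"""Injury-signature construction and concordance-based compound ranking.

A *signature* is the set of genes surviving differential-expression
thresholds (|fold-change| >= 1.5 on the ratio scale and FDR < 0.05 by
default), weighted by signed log2 fold-change.  Compound signatures are
scored against the injury signature with a bounded concordance statistic in
[-1, +1]; strong negative concordance (signature reversal) is the
therapeutic hypothesis.  The concordance statistic used here is the Spearman
rank correlation of the weight vectors over the gene intersection — an
openly declared stand-in, since the upstream service that produced the
published concordance values does not document its formula.  Published
concordance values are therefore treated as input data when ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Signature",
    "ConcordanceResult",
    "InsufficientOverlapError",
    "build_signature",
    "concordance",
    "rank_candidates",
    "merge_signatures",
    "signature_to_records",
]


class InsufficientOverlapError(ValueError):
    """Raised when two signatures share fewer genes than ``min_overlap``."""


@dataclass
class Signature:
    """A gene -> signed-weight map (weights are signed log2 fold-changes)."""

    label: str
    weights: pd.Series  # index: gene id, values: float
    empty_after_filter: bool = False

    def __post_init__(self) -> None:
        if self.weights.index.has_duplicates:
            raise ValueError("duplicate gene ids in signature")
        self.weights = self.weights.astype(float)

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def genes(self) -> set[str]:
        return set(self.weights.index)


@dataclass(frozen=True)
class ConcordanceResult:
    compound: str
    concordance: float
    n_shared: int
    cell_line: str = ""


def _to_log2_weight(fc: np.ndarray, fc_scale: str) -> np.ndarray:
    """Convert fold-changes to signed log2 weights.

    ``ratio`` dialect: |FC| >= 1 with sign giving direction (FC = -2 means
    2-fold down); values in (0, 1) are down-regulation expressed as plain
    ratios and map to negative log2.  ``log2`` dialect: already log2.
    """
    if fc_scale == "log2":
        return np.asarray(fc, dtype=float)
    if fc_scale != "ratio":
        raise ValueError(f"unknown fold-change dialect: {fc_scale!r}")
    fc = np.asarray(fc, dtype=float)
    out = np.empty_like(fc)
    frac = (fc > 0) & (fc < 1)  # plain down-ratio, e.g. 0.5 = 2-fold down
    out[frac] = np.log2(fc[frac])
    out[~frac] = np.sign(fc[~frac]) * np.log2(np.abs(fc[~frac]))
    return out


def build_signature(
    de_table: pd.DataFrame,
    fc_min: float = 1.5,
    fdr_max: float = 0.05,
    fc_scale: str = "ratio",
    label: str = "",
) -> Signature:
    """Filter a DE table to the injury signature.

    Parameters
    ----------
    de_table
        Columns ``gene``, ``fc``, ``fdr``.
    fc_min
        Minimum absolute fold-change on the ratio scale (equivalently
        |log2 FC| >= log2(fc_min)).
    fdr_max
        Strict upper bound on the false-discovery rate.
    fc_scale
        ``"ratio"`` or ``"log2"`` (see :func:`_to_log2_weight`).
    """
    if fc_min <= 0 or fdr_max <= 0:
        raise ValueError("thresholds must be positive")
    df = de_table
    required = {"gene", "fc", "fdr"}
    if not required.issubset(df.columns):
        raise ValueError(f"DE table must have columns {sorted(required)}")
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate gene ids in DE table: {dupes[:5]}")
    fc = df["fc"].to_numpy(dtype=float)
    fdr = df["fdr"].to_numpy(dtype=float)
    if not np.all(np.isfinite(fc)) or np.any(fc == 0):
        raise ValueError("fold-changes must be finite and nonzero")
    if np.any((fdr < 0) | (fdr > 1)):
        raise ValueError("FDR values must lie in [0, 1]")
    weight = _to_log2_weight(fc, fc_scale)
    keep = (np.abs(weight) >= math.log2(fc_min)) & (fdr < fdr_max)
    weights = pd.Series(weight[keep], index=df.loc[keep, "gene"], name="weight")
    return Signature(label=label, weights=weights, empty_after_filter=not keep.any())


def signature_to_records(sig: Signature) -> pd.DataFrame:
    """Re-express a signature as a DE table (log2 dialect, FDR 0).

    Feeding the result back through :func:`build_signature` with the same
    thresholds is the identity (filter idempotence).
    """
    return pd.DataFrame(
        {"gene": sig.weights.index, "fc": sig.weights.to_numpy(), "fdr": 0.0}
    )


def concordance(
    sig_a: Signature,
    sig_b: Signature,
    min_overlap: int = 10,
    compound: str = "",
    cell_line: str = "",
) -> ConcordanceResult:
    """Spearman rank correlation of weights over the gene intersection."""
    if len(sig_a) == 0 or len(sig_b) == 0:
        raise ValueError("signatures must be nonempty")
    shared = sig_a.weights.index.intersection(sig_b.weights.index)
    if len(shared) < min_overlap:
        raise InsufficientOverlapError(
            f"{len(shared)} shared genes < min_overlap={min_overlap}"
        )
    rho = stats.spearmanr(
        sig_a.weights.loc[shared].to_numpy(), sig_b.weights.loc[shared].to_numpy()
    ).statistic
    return ConcordanceResult(
        compound=compound or sig_b.label,
        concordance=float(rho),
        n_shared=len(shared),
        cell_line=cell_line,
    )


def rank_candidates(
    library: list[ConcordanceResult] | pd.DataFrame,
    n_pos: int = 20,
    n_neg: int = 20,
) -> pd.DataFrame:
    """Select the strongest signature mimics and reversers.

    Returns a frame with columns ``compound, concordance, n_shared, bucket``
    holding the ``n_pos`` highest positive and ``n_neg`` lowest negative
    concordances, each bucket sorted by |concordance| descending with
    lexicographic tie-break on compound id.  Zero concordance falls in
    neither bucket.
    """
    if isinstance(library, pd.DataFrame):
        df = library.copy()
        if "n_shared" not in df.columns:
            df["n_shared"] = 0
    else:
        df = pd.DataFrame(
            [(r.compound, r.concordance, r.n_shared) for r in library],
            columns=["compound", "concordance", "n_shared"],
        )
    if df.empty:
        raise ValueError("empty concordance library")
    df["_abs"] = df["concordance"].abs()
    df = df.sort_values(["_abs", "compound"], ascending=[False, True], kind="stable")
    pos = df[df["concordance"] > 0].head(n_pos).assign(bucket="positive")
    neg = df[df["concordance"] < 0].head(n_neg).assign(bucket="negative")
    out = pd.concat([pos, neg]).drop(columns="_abs").reset_index(drop=True)
    return out[["compound", "concordance", "n_shared", "bucket"]]


def merge_signatures(sig_compound: Signature, sig_tbi: Signature) -> pd.DataFrame:
    """Common-gene list with both weights (network analysis is downstream)."""
    if len(sig_compound) == 0 or len(sig_tbi) == 0:
        raise ValueError("signatures must be nonempty")
    shared = sig_compound.weights.index.intersection(sig_tbi.weights.index)
    return pd.DataFrame(
        {
            "gene": shared,
            "weight_compound": sig_compound.weights.loc[shared].to_numpy(),
            "weight_tbi": sig_tbi.weights.loc[shared].to_numpy(),
        }
    ).reset_index(drop=True)
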