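"""Synthetic generators for all five input kinds, with known ground truth.

The study this package re-implements deposited no raw data, so every
downstream stage is exercised on synthetic inputs whose generating truth is
returned alongside: differential-expression tables with planted DE genes,
compound-signature libraries with planted mimics/reversers, plate-assay well
tables with planted percent-of-control effects and batch offsets, and animal
cohorts with planted seizure rates, durations, Racine mixtures and biomarker
distributions.

Seizure onsets follow a time-inhomogeneous Poisson process with
exponentially decaying rate lambda(t) = rate0 * exp(-decay * t) over the
72-h follow-up, sampled by thinning — the simplest process reproducing the
spontaneous decay of seizure frequency seen in the untreated injured
animals.  Each animal is seizure-susceptible with its group's seizure
probability; a susceptible animal whose Poisson draw is empty receives one
onset from the normalized rate density, so the fraction of animals with
seizures matches the planted probability exactly.  Per-seizure durations are
log-normal (the source reports no distributional form; this is a modeling
choice).  A configurable fraction of seizures carries an ungradable
("unknown") Racine label so the exclusion rule is exercised.

Every generator takes one integer seed; per-animal / per-plate sub-streams
are spawned deterministically from it, so output is byte-identical seed for
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screen import ASSAYS, CONTROL_CONDITIONS
from .seizures import AnimalRecord, SeizureEvent
from .signature import Signature

__all__ = [
    "gen_de_table",
    "gen_compound_library",
    "PlateSpec",
    "gen_plate",
    "GroupSpec",
    "CohortSpec",
    "SyntheticCohort",
    "gen_cohort",
    "default_cohort_spec",
    "CONTROL_PERCENTS",
]


def _check_finite(**params: float) -> None:
    for name, v in params.items():
        if not math.isfinite(v):
            raise ValueError(f"non-finite parameter {name}={v!r}")


# ---------------------------------------------------------------- DE tables


def gen_de_table(
    n_genes: int,
    frac_de: float,
    effect_size: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a DE table (gene, fc, fdr) with planted truth labels.

    Exactly ``round(frac_de * n_genes)`` genes are drawn from the
    alternative: |log2 FC| centered on ``effect_size`` with FDR below 0.05.
    Null genes get small log2 FC and FDR uniform on [0.05, 1], so with the
    default downstream thresholds no null gene can pass.  Fold-changes are
    emitted in the signed-ratio dialect.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 <= frac_de <= 1:
        raise ValueError("frac_de must lie in [0, 1]")
    _check_finite(frac_de=frac_de, effect_size=effect_size)
    rng = np.random.default_rng(seed)
    n_de = round(frac_de * n_genes)
    genes = np.array([f"g{i:05d}" for i in range(n_genes)])
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[rng.choice(n_genes, size=n_de, replace=False)] = True

    log2fc = rng.normal(0.0, 0.15, size=n_genes)
    log2fc[is_de] = rng.choice([-1, 1], size=n_de) * np.maximum(
        rng.normal(effect_size, 0.2 * effect_size, size=n_de), 0.05
    )
    log2fc[log2fc == 0] = 0.01  # fold-change must be nonzero
    fdr = rng.uniform(0.05, 1.0, size=n_genes)
    fdr[is_de] = rng.uniform(0.0, 0.049, size=n_de)

    ratio = np.sign(log2fc) * 2.0 ** np.abs(log2fc)
    table = pd.DataFrame({"gene": genes, "fc": ratio, "fdr": fdr})
    truth = pd.Series(is_de, index=genes, name="is_de")
    return table, truth


# ------------------------------------------------------- compound libraries


def gen_compound_library(
    n_compounds: int,
    reference: Signature,
    planted: list[tuple[str, int]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[str, Signature]:
    """Simulate compound gene-weight signatures over the reference's genes.

    ``planted`` entries are (compound name, sign): +1 plants a mimic (the
    reference signature plus noise), -1 a reverser (its negation plus
    noise).  Remaining compounds get independent standard-normal weights, so
    their concordance with the reference is centered on zero.
    """
    planted = planted or []
    names = [p[0] for p in planted]
    if len(set(names)) != len(names):
        raise ValueError("planted compound names must be unique")
    if n_compounds < len(planted):
        raise ValueError("n_compounds < number of planted compounds")
    rng = np.random.default_rng(seed)
    genes = reference.weights.index
    lib: dict[str, Signature] = {}
    for name, sign in planted:
        if sign not in (-1, 1):
            raise ValueError("planted sign must be +1 (mimic) or -1 (reverser)")
        w = sign * reference.weights.to_numpy() + rng.normal(0, noise_sd, len(genes))
        lib[name] = Signature(label=name, weights=pd.Series(w, index=genes))
    for i in range(n_compounds - len(planted)):
        name = f"cmpd_{i:04d}"
        w = rng.normal(0.0, 1.0, size=len(genes))
        lib[name] = Signature(label=name, weights=pd.Series(w, index=genes))
    return lib


# ------------------------------------------------------------------- plates

#: Latent percent-of-control values of the control conditions on each
#: assay's scale (anchors are exact by construction; the remaining controls
#: sit near the values the source screen reports for them).
CONTROL_PERCENTS = {
    "viability": {"LPS/IFNg+": 0.0, "1400W": 100.0, "LPS/IFNg-": 48.0,
                  "BV2-": 126.0, "IL10": 6.0},
    "nitrite": {"1400W": 0.0, "LPS/IFNg+": 100.0, "LPS/IFNg-": -20.0,
                "BV2-": -21.0, "IL10": 63.0},
    "tnfa": {"IL10": 0.0, "LPS/IFNg+": 100.0, "LPS/IFNg-": -367.0,
             "BV2-": -385.0, "1400W": 61.0},
}

#: absorbance = base + span * percent/100 (+ batch offset + noise)
_ABS_MAP = {"viability": (0.20, 0.80), "nitrite": (0.05, 1.00), "tnfa": (0.10, 0.90)}


@dataclass
class PlateSpec:
    """Layout and planted truth of a simulated screen.

    ``drug_effects`` maps (drug, molar concentration) to the planted
    percent-of-control per assay, e.g. ``{("TSA", 5e-8): {"viability": 73,
    "nitrite": 28, "tnfa": -139}}``.  ``batch_offsets`` (absorbance units,
    one per batch) defaults to zero; replicate counts follow the source
    screen (two independent experiments, three replicates for viability and
    four for the medium assays — use ``replicates`` to override uniformly).
    """

    drug_effects: dict[tuple[str, float], dict[str, float]]
    batches: int = 2
    replicates: int = 3
    batch_offsets: list[float] | None = None
    noise_sd: float = 0.0
    assays: tuple[str, ...] = ASSAYS
    conditions: tuple[str, ...] = CONTROL_CONDITIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batches < 1 or self.replicates < 1:
            raise ValueError("batches and replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.batch_offsets is None:
            self.batch_offsets = [0.0] * self.batches
        if len(self.batch_offsets) != self.batches:
            raise ValueError("one batch offset per batch required")
        for assay in self.assays:
            needed = {c for c, p in CONTROL_PERCENTS[assay].items()
                      if p in (0.0, 100.0)}
            missing = needed - set(self.conditions)
            if missing:
                raise ValueError(
                    f"anchor controls {sorted(missing)} missing for {assay}"
                )


def gen_plate(spec: PlateSpec) -> pd.DataFrame:
    """One row per well: batch, assay, condition, drug, conc_molar, absorbance."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for b in range(spec.batches):
        batch = f"batch{b + 1}"
        offset = spec.batch_offsets[b]
        for assay in spec.assays:
            base, span = _ABS_MAP[assay]
            cells: list[tuple[str, str, float, float]] = [
                (cond, "", math.nan, CONTROL_PERCENTS[assay][cond])
                for cond in spec.conditions
            ]
            cells += [
                ("drug", drug, conc, effects[assay])
                for (drug, conc), effects in spec.drug_effects.items()
                if assay in effects
            ]
            for cond, drug, conc, pct in cells:
                mean_abs = base + span * pct / 100.0 + offset
                noise = rng.normal(0, spec.noise_sd, spec.replicates)
                for r in range(spec.replicates):
                    rows.append(
                        (batch, assay, cond, drug, conc, mean_abs + noise[r])
                    )
    return pd.DataFrame(
        rows,
        columns=["batch", "assay", "condition", "drug", "conc_molar", "absorbance"],
    )


# ------------------------------------------------------------------ cohorts


@dataclass
class GroupSpec:
    """One treatment group's planted parameters."""

    label: str
    n: int
    seizure_prob: float
    rate0: float = 0.45        # events/h at t = 0
    decay: float = 0.033       # 1/h; 0 = homogeneous
    dur_meanlog: float = 3.76  # log-seconds
    dur_sdlog: float = 0.61
    pnfh: tuple[float, float] = (7394.0, 592.0)   # pg/mL mean, SD
    lesion: tuple[float, float] = (25.9, 3.0)     # mm^2 mean, SD

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.seizure_prob <= 1:
            raise ValueError("seizure probability must lie in [0, 1]")
        if self.rate0 < 0 or self.decay < 0:
            raise ValueError("rate parameters must be >= 0")
        if self.dur_sdlog <= 0:
            raise ValueError("duration scale must be > 0")
        _check_finite(
            seizure_prob=self.seizure_prob, rate0=self.rate0, decay=self.decay,
            dur_meanlog=self.dur_meanlog, dur_sdlog=self.dur_sdlog,
        )


#: Racine-score mixture of graded seizures (mostly non-convulsive, mean ~0.2
#: in the untreated injured animals).
DEFAULT_RACINE_PROBS = {0: 0.86, 1: 0.06, 2: 0.04, 3: 0.02, 4: 0.01, 5: 0.01}


@dataclass
class CohortSpec:
    groups: list[GroupSpec]
    racine_probs: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_RACINE_PROBS)
    )
    unknown_racine_prob: float = 0.06  # fraction of ungradable seizures
    follow_up_h: float = 72.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        if not 0 <= self.unknown_racine_prob <= 1:
            raise ValueError("unknown_racine_prob must lie in [0, 1]")
        tot = sum(self.racine_probs.values())
        if not math.isclose(tot, 1.0, rel_tol=1e-9):
            raise ValueError("racine_probs must sum to 1")
        if self.follow_up_h <= 0:
            raise ValueError("follow-up must be positive")


@dataclass
class SyntheticCohort:
    records: list[AnimalRecord]
    biomarkers: pd.DataFrame  # animal, group, pnfh, lesion

    @property
    def by_group(self) -> dict[str, list[AnimalRecord]]:
        out: dict[str, list[AnimalRecord]] = {}
        for r in self.records:
            out.setdefault(r.group, []).append(r)
        return out


def _sample_onsets(rng: np.random.Generator, g: GroupSpec, T: float) -> np.ndarray:
    """Inhomogeneous-Poisson onsets by thinning lambda(t)=rate0*exp(-decay t)."""
    if g.rate0 == 0:
        return np.array([])
    n_cand = rng.poisson(g.rate0 * T)
    t = np.sort(rng.uniform(0, T, n_cand))
    if g.decay > 0:
        keep = rng.uniform(size=n_cand) < np.exp(-g.decay * t)
        t = t[keep]
    return t


def _forced_onset(rng: np.random.Generator, g: GroupSpec, T: float) -> float:
    """One onset from the normalized rate density (inverse CDF)."""
    u = rng.uniform()
    if g.decay == 0:
        return float(u * T)
    return float(-math.log(1 - u * (1 - math.exp(-g.decay * T))) / g.decay)


def gen_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Simulate per-animal seizure streams and biomarkers for every group."""
    root = np.random.SeedSequence(spec.seed)
    scores = np.array(sorted(spec.racine_probs))
    score_p = np.array([spec.racine_probs[s] for s in scores])
    records: list[AnimalRecord] = []
    bio_rows = []
    animal_seeds = root.spawn(sum(g.n for g in spec.groups))
    idx = 0
    for g in spec.groups:
        for i in range(g.n):
            rng = np.random.default_rng(animal_seeds[idx])
            idx += 1
            aid = f"{g.label}-{i + 1:03d}"
            events: list[SeizureEvent] = []
            if rng.uniform() < g.seizure_prob:
                onsets = _sample_onsets(rng, g, spec.follow_up_h)
                if onsets.size == 0:
                    onsets = np.array([_forced_onset(rng, g, spec.follow_up_h)])
                for t in onsets:
                    dur = float(rng.lognormal(g.dur_meanlog, g.dur_sdlog))
                    racine = (
                        None
                        if rng.uniform() < spec.unknown_racine_prob
                        else int(rng.choice(scores, p=score_p))
                    )
                    events.append(SeizureEvent(float(t), dur, racine))
            records.append(
                AnimalRecord(aid, g.label, events, follow_up_h=spec.follow_up_h)
            )
            bio_rows.append(
                (
                    aid,
                    g.label,
                    max(0.0, rng.normal(*g.pnfh)),
                    max(0.0, rng.normal(*g.lesion)),
                )
            )
    return SyntheticCohort(
        records=records,
        biomarkers=pd.DataFrame(
            bio_rows, columns=["animal", "group", "pnfh", "lesion"]
        ),
    )


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """A cohort mirroring the source study's group structure and magnitudes.

    Group sizes and seizure probabilities follow the published occurrence
    table; seizure-rate parameters are calibrated so the untreated group
    shows ~12 seizures/animal with ~87 % of seizures in the first 48 h and a
    median first onset near 9 h, and the treated groups show the published
    suppression ordering.  Biomarker distributions follow the published
    group means/SDs.
    """
    return CohortSpec(
        groups=[
            GroupSpec("VEH", 16, 0.81, rate0=0.45,
                      pnfh=(7394.0, 592.0), lesion=(25.9, 3.0)),
            GroupSpec("TSA", 7, 0.86, rate0=0.45,
                      pnfh=(6073.0, 1695.0), lesion=(22.8, 5.0)),
            GroupSpec("LEVlow", 10, 0.50, rate0=0.22, dur_meanlog=2.9,
                      pnfh=(5183.0, 3256.0), lesion=(27.1, 13.7)),
            GroupSpec("LEVhigh", 10, 0.40, rate0=0.06, dur_meanlog=2.6,
                      pnfh=(5183.0, 3256.0), lesion=(27.1, 13.7)),
            GroupSpec("LEVhigh+TSA", 10, 0.30, rate0=0.08, dur_meanlog=2.6,
                      pnfh=(5183.0, 3256.0), lesion=(22.8, 5.0)),
        ],
        seed=seed,
    )
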