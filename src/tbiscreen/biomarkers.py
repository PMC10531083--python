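"""ELISA reduction to concentrations and biomarker-lesion statistics.

The plasma axonal-injury marker pNF-H is quantified by sandwich ELISA:
the 630 nm reference absorbance is subtracted from the 450 nm reading, the
corrected signal is inverted through the standard curve, and the result is
multiplied by the sample dilution factor (1:6 in the source protocol).
The kit's curve form is undocumented, so the default standard-curve model is
monotone piecewise-linear interpolation in log10 concentration (switchable
to linear concentration); samples outside the standards' signal range are
flagged rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .seizures import cohens_delta_from_samples, _mannwhitney

__all__ = [
    "ElisaStandard",
    "ElisaSample",
    "ElisaRun",
    "ElisaResult",
    "reduce_elisa",
    "correlate",
    "group_effect",
]


@dataclass(frozen=True)
class ElisaStandard:
    concentration: float  # pg/mL
    a450: float
    a630: float

    @property
    def signal(self) -> float:
        return self.a450 - self.a630


@dataclass(frozen=True)
class ElisaSample:
    sample_id: str
    a450: float
    a630: float

    @property
    def signal(self) -> float:
        return self.a450 - self.a630


@dataclass
class ElisaRun:
    standards: list[ElisaStandard]
    samples: list[ElisaSample]
    dilution: float = 6.0
    log_concentration: bool = True

    def __post_init__(self) -> None:
        if len(self.standards) < 4:
            raise ValueError("need >= 4 standards")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")
        self.standards = sorted(self.standards, key=lambda s: s.concentration)


@dataclass(frozen=True)
class ElisaResult:
    sample_id: str
    signal: float
    concentration: float | None  # pg/mL in the undiluted sample; None if flagged
    flag: str = ""  # "", "below-range", "above-range"


def reduce_elisa(run: ElisaRun) -> list[ElisaResult]:
    """Invert corrected signals through the standard curve.

    Standards must be strictly monotone increasing in corrected signal
    (A450 - A630) with concentration.  In-range samples are interpolated
    (in log10 concentration by default) and scaled by the dilution factor;
    out-of-range samples are flagged, never extrapolated.
    """
    sig = np.array([s.signal for s in run.standards])
    conc = np.array([s.concentration for s in run.standards])
    if np.any(np.diff(sig) <= 0):
        raise ValueError("standards not strictly monotone in corrected signal")
    if run.log_concentration and np.any(conc <= 0):
        raise ValueError("log-concentration curve needs positive standards")
    y = np.log10(conc) if run.log_concentration else conc

    out = []
    for s in run.samples:
        if s.signal < sig[0]:
            out.append(ElisaResult(s.sample_id, s.signal, None, "below-range"))
        elif s.signal > sig[-1]:
            out.append(ElisaResult(s.sample_id, s.signal, None, "above-range"))
        else:
            v = float(np.interp(s.signal, sig, y))
            c = 10**v if run.log_concentration else v
            out.append(ElisaResult(s.sample_id, s.signal, c * run.dilution, ""))
    return out


def correlate(x, y) -> tuple[float, float, float]:
    """Pearson correlation between two biomarker vectors: (r, r^2, p).

    Two-sided p from the t distribution with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired finite observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def group_effect(vehicle, treatment) -> dict:
    """Vehicle-vs-treatment effect on a damage marker.

    Returns the pooled-SD Cohen's delta with the vehicle-minus-treatment
    sign (positive = treatment lowered the damage marker = favorable) and
    the two-sided Mann-Whitney p.
    """
    vehicle = np.asarray(vehicle, dtype=float)
    treatment = np.asarray(treatment, dtype=float)
    if len(vehicle) < 2 or len(treatment) < 2:
        raise ValueError("need >= 2 per group")
    delta = cohens_delta_from_samples(vehicle, treatment)
    _, p = _mannwhitney(vehicle, treatment)
    return {"cohens_delta": delta, "p": p, "n": (len(vehicle), len(treatment))}
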