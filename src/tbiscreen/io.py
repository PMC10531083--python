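"""Delimited-text readers and writers for every pipeline input and output.

Schemas (all plain text, reproducible byte for byte):

* DE table — TSV, header ``gene<TAB>fc<TAB>fdr``
* signature — TSV ``gene<TAB>weight`` preceded by a ``# label:`` line
* candidate list — TSV ``compound, concordance, n_shared, bucket``
* well table — CSV ``batch,assay,condition,drug,conc_molar,absorbance``
* event log — CSV ``animal,group,onset_h,duration_s,racine`` (racine blank
  for ungradable seizures)
* biomarker table — CSV ``animal,group,pnfh,lesion``
* ELISA run — CSV with a ``role`` column (``standard`` | ``sample``)
* score criteria — YAML mapping assay -> {direction, breakpoints}
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .biomarkers import ElisaRun, ElisaSample, ElisaStandard
from .screen import ScoreCriteria
from .seizures import AnimalRecord, SeizureEvent
from .signature import Signature

__all__ = [
    "read_de_table", "write_de_table",
    "read_signature", "write_signature",
    "write_candidates",
    "read_well_table", "write_well_table",
    "read_event_log", "write_event_log",
    "read_biomarker_table", "write_biomarker_table",
    "read_elisa_run",
    "read_criteria", "write_criteria",
    "write_truth_sidecar",
]


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "fc", "fdr"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table {path}: missing columns {sorted(missing)}")
    return df


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_signature(path: str | Path) -> Signature:
    path = Path(path)
    label = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# label:"):
            label = first.split(":", 1)[1].strip()
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    return Signature(label=label, weights=df.set_index("gene")["weight"])


def write_signature(sig: Signature, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# label: {sig.label}\n")
        sig.weights.rename_axis("gene").rename("weight").to_csv(fh, sep="\t")


def write_candidates(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_well_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"batch", "assay", "condition", "drug", "conc_molar", "absorbance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"well table {path}: missing columns {sorted(missing)}")
    df["drug"] = df["drug"].fillna("")
    return df


def write_well_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_event_log(path: str | Path) -> list[AnimalRecord]:
    df = pd.read_csv(path)
    records = []
    for (animal, group), grp in df.groupby(["animal", "group"], sort=True):
        events = [
            SeizureEvent(
                onset_h=float(r.onset_h),
                duration_s=float(r.duration_s),
                racine=None if pd.isna(r.racine) else int(r.racine),
            )
            for r in grp.itertuples()
            if pd.notna(r.onset_h)
        ]
        records.append(AnimalRecord(str(animal), str(group), events))
    return records


def write_event_log(records: list[AnimalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        if not r.events:  # keep event-free animals visible with a blank row
            rows.append((r.animal_id, r.group, "", "", ""))
        for e in r.events:
            rows.append(
                (r.animal_id, r.group, e.onset_h, e.duration_s,
                 "" if e.racine is None else e.racine)
            )
    pd.DataFrame(
        rows, columns=["animal", "group", "onset_h", "duration_s", "racine"]
    ).to_csv(path, index=False)


def read_biomarker_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"animal", "group", "pnfh", "lesion"} - set(df.columns)
    if missing:
        raise ValueError(f"biomarker table {path}: missing columns {sorted(missing)}")
    return df


def write_biomarker_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_elisa_run(path: str | Path, dilution: float = 6.0) -> ElisaRun:
    df = pd.read_csv(path)
    standards = [
        ElisaStandard(float(r.concentration), float(r.a450), float(r.a630))
        for r in df[df["role"] == "standard"].itertuples()
    ]
    samples = [
        ElisaSample(str(r.sample_id), float(r.a450), float(r.a630))
        for r in df[df["role"] == "sample"].itertuples()
    ]
    return ElisaRun(standards=standards, samples=samples, dilution=dilution)


def read_criteria(path: str | Path) -> dict[str, ScoreCriteria]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        assay: ScoreCriteria(
            direction=spec["direction"],
            breakpoints=[(float(p), float(s)) for p, s in spec["breakpoints"]],
        )
        for assay, spec in raw.items()
    }


def write_criteria(criteria: dict[str, ScoreCriteria], path: str | Path) -> None:
    raw = {
        assay: {
            "direction": c.direction,
            "breakpoints": [[p, s] for p, s in c.breakpoints],
        }
        for assay, c in criteria.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


def write_truth_sidecar(truth: dict, path: str | Path) -> None:
    """Ground-truth parameters of a synthetic dataset, as sorted JSON."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
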