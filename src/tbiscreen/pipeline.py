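"""Orchestration of the in-silico -> in-vitro -> in-vivo flow.

Each stage is runnable standalone from files, or the whole flow can run on
bundled synthetic inputs (``simulate`` first).  Stages are isolated: a
failing stage records its error in the report and never corrupts the
outputs of earlier stages.  The report carries no timestamps, so identical
config + seeds give identical report bytes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomarkers as bm
from . import io as tio
from . import screen as scr
from . import seizures as sz
from . import signature as sg
from . import synthetic as syn

log = logging.getLogger("tbiscreen")

__all__ = ["PipelineConfig", "run_pipeline", "simulate_inputs", "default_config"]


@dataclass
class PipelineConfig:
    out_dir: str = "tbiscreen_out"
    seed: int = 0
    # signature stage
    de_table: str | None = None
    fc_min: float = 1.5
    fdr_max: float = 0.05
    fc_scale: str = "ratio"
    # ranking stage
    concordance_table: str | None = None  # TSV compound/concordance/n_shared
    n_pos: int = 20
    n_neg: int = 20
    min_overlap: int = 10
    # screen stage
    well_table: str | None = None
    criteria: str | None = None  # YAML path; None = package defaults
    policy: str = "viability-priority"
    toxicity_flags: list[str] = field(default_factory=list)
    # in vivo stages
    event_log: str | None = None
    biomarker_table: str | None = None
    vehicle_group: str = "VEH"
    epoch_metric: str = "cumulative_duration"

    def __post_init__(self) -> None:
        if self.fc_min <= 0 or self.fdr_max <= 0 or self.min_overlap < 1:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def default_config() -> dict:
    """All defaults as a plain dict (what ``show-config`` prints)."""
    cfg = PipelineConfig()
    return {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}


def simulate_inputs(out_dir: str | Path, seed: int = 0) -> dict:
    """Write one synthetic dataset of every input kind, plus truth sidecar.

    The planted structure mirrors the study design: a DE table whose
    surviving genes form the injury signature, a compound library with one
    planted strong reverser, a plate with the screen percentages planted for
    the five shortlisted compounds, and the default cohort with the
    published group structure.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**31)

    de, de_truth = syn.gen_de_table(2000, 0.1, effect_size=2.0, seed=rng_seed)
    tio.write_de_table(de, out / "de_table.tsv")

    ref = sg.build_signature(de, label="synthetic-injury")
    planted = [("planted_reverser", -1), ("planted_mimic", +1)]
    lib = syn.gen_compound_library(
        50, ref, planted=planted, noise_sd=0.3, seed=rng_seed + 1
    )
    conc_rows = [
        (name, sg.concordance(ref, s, compound=name).concordance, len(s))
        for name, s in lib.items()
    ]
    pd.DataFrame(conc_rows, columns=["compound", "concordance", "n_shared"]).to_csv(
        out / "concordance_table.tsv", sep="\t", index=False
    )

    drug_effects = {
        ("Trichostatin A", 5e-8): {"viability": 73, "nitrite": 28, "tnfa": -139},
        ("Calpain inhibitor", 5e-5): {"viability": 47, "nitrite": -21, "tnfa": -226},
        ("7,8-dihydroxychlorpromazine", 5e-5): {
            "viability": 57, "nitrite": 81, "tnfa": -41
        },
        ("(+)-Tranylcypromine", 1e-6): {"viability": 2, "nitrite": 81},
        ("Geldanamycin", 1e-8): {"viability": 5, "nitrite": 55},
    }
    plate = syn.gen_plate(
        syn.PlateSpec(
            drug_effects=drug_effects,
            batches=2,
            replicates=3,
            batch_offsets=[0.0, 0.12],
            noise_sd=0.01,
            seed=rng_seed + 2,
        )
    )
    tio.write_well_table(plate, out / "well_table.csv")

    cohort = syn.gen_cohort(syn.default_cohort_spec(seed=rng_seed + 3))
    tio.write_event_log(cohort.records, out / "event_log.csv")
    tio.write_biomarker_table(cohort.biomarkers, out / "biomarkers.csv")

    truth = {
        "n_de_genes": int(de_truth.sum()),
        "planted_reverser": "planted_reverser",
        "planted_lead_viability": "Trichostatin A",
        "planted_lead_total": "Calpain inhibitor",
        "drug_effects": {f"{d}@{c:g}": e for (d, c), e in drug_effects.items()},
        "seizure_probs": {g.label: g.seizure_prob
                          for g in syn.default_cohort_spec().groups},
    }
    tio.write_truth_sidecar(truth, out / "truth.json")
    return truth


def _stage_signature(cfg: PipelineConfig) -> dict:
    de = tio.read_de_table(cfg.de_table)
    log.info("signature: %d rows, fc_min=%g fdr_max=%g scale=%s",
             len(de), cfg.fc_min, cfg.fdr_max, cfg.fc_scale)
    sig = sg.build_signature(
        de, fc_min=cfg.fc_min, fdr_max=cfg.fdr_max, fc_scale=cfg.fc_scale,
        label="injury",
    )
    out = Path(cfg.out_dir) / "signature.tsv"
    tio.write_signature(sig, out)
    return {"n_genes": len(sig), "empty": sig.empty_after_filter,
            "path": str(out)}


def _stage_rank(cfg: PipelineConfig) -> dict:
    lib = pd.read_csv(cfg.concordance_table, sep="\t")
    log.info("rank: %d compounds, n_pos=%d n_neg=%d",
             len(lib), cfg.n_pos, cfg.n_neg)
    ranked = sg.rank_candidates(lib, n_pos=cfg.n_pos, n_neg=cfg.n_neg)
    out = Path(cfg.out_dir) / "candidates.tsv"
    tio.write_candidates(ranked, out)
    top = {
        b: grp.iloc[0]["compound"]
        for b, grp in ranked.groupby("bucket") if len(grp)
    }
    return {"n_ranked": len(ranked), "top": top, "path": str(out)}


def _stage_screen(cfg: PipelineConfig) -> dict:
    wells = tio.read_well_table(cfg.well_table)
    results = []
    for assay in scr.ASSAYS:
        if (wells["assay"] == assay).any():
            results.extend(scr.normalize_plate(wells, assay))
    log.info("screen: %d wells -> %d drug x conc x assay results",
             len(wells), len(results))
    df = pd.DataFrame([r.__dict__ for r in results])
    out = Path(cfg.out_dir) / "assay_results.tsv"
    df.to_csv(out, sep="\t", index=False)
    return {"n_results": len(results), "path": str(out)}


def _stage_score(cfg: PipelineConfig, screen_out: dict) -> dict:
    df = pd.read_csv(screen_out["path"], sep="\t")
    criteria = tio.read_criteria(cfg.criteria) if cfg.criteria else scr.default_criteria()
    scores = []
    for drug, grp in df.groupby("drug", sort=True):
        # score each concentration, keep the drug's best-scoring one
        best = None
        for conc, cell in grp.groupby("conc_molar"):
            percents = dict(zip(cell["assay"], cell["percent"]))
            s = scr.score_compound(str(drug), percents, criteria)
            if best is None or s.total > best[1].total:
                best = (conc, s)
        scores.append(best[1])
    lead = scr.select_lead(
        scores, policy=cfg.policy, toxicity_flags=set(cfg.toxicity_flags)
    )
    log.info("score: policy=%s lead=%s (total %.2f)",
             cfg.policy, lead.drug, lead.total)
    table = pd.DataFrame(
        [
            (s.drug, s.viability, s.nitrite, s.tnfa, s.total)
            for s in sorted(scores, key=lambda s: (-s.total, s.drug))
        ],
        columns=["drug", "viability", "nitrite", "tnfa", "total"],
    )
    out = Path(cfg.out_dir) / "compound_scores.tsv"
    table.to_csv(out, sep="\t", index=False)
    return {"lead": lead.drug, "lead_total": lead.total, "policy": cfg.policy,
            "path": str(out)}


def _stage_seizures(cfg: PipelineConfig) -> dict:
    records = tio.read_event_log(cfg.event_log)
    table = sz.metrics_table(records)
    out = Path(cfg.out_dir) / "seizure_metrics.tsv"
    table.to_csv(out, sep="\t", index=False)
    by_group: dict[str, list] = {}
    for r in records:
        by_group.setdefault(r.group, []).append(r)
    log.info("seizures: %d animals in %d groups", len(records), len(by_group))
    result: dict = {"n_animals": len(records), "path": str(out), "groups": {}}
    for gname, recs in by_group.items():
        k, n, prop = sz.occurrence(recs)
        result["groups"][gname] = {"occurrence": f"{k}/{n}", "proportion": prop}
    veh = cfg.vehicle_group
    if veh in by_group and len(by_group) > 1 and all(
        len(v) >= 2 for v in by_group.values()
    ):
        kv, nv, _ = sz.occurrence(by_group[veh])
        fisher = {}
        for gname, recs in by_group.items():
            if gname == veh:
                continue
            kg, ng, _ = sz.occurrence(recs)
            fisher[gname] = sz.fisher_exact_2x2(kv, nv - kv, kg, ng - kg)
        comps = sz.group_battery(by_group, cfg.epoch_metric, vehicle_group=veh)
        result["fisher_vs_vehicle"] = fisher
        result["battery_metric"] = cfg.epoch_metric
        result["battery"] = [
            {"test": c.test, "groups": list(c.groups), "p": c.p,
             "p_adjusted": c.p_adjusted, "cohens_delta": c.cohens_delta}
            for c in comps
        ]
    return result


def _stage_biomarkers(cfg: PipelineConfig) -> dict:
    df = tio.read_biomarker_table(cfg.biomarker_table)
    veh = cfg.vehicle_group
    result: dict = {"n_animals": len(df)}
    try:
        r, r2, p = bm.correlate(df["pnfh"], df["lesion"])
        result["pnfh_lesion"] = {"r": r, "r2": r2, "p": p}
    except ValueError as exc:
        result["pnfh_lesion"] = {"error": str(exc)}
    if veh in set(df["group"]):
        vmask = df["group"] == veh
        for marker in ("pnfh", "lesion"):
            result[marker] = {}
            for gname in sorted(set(df["group"]) - {veh}):
                eff = bm.group_effect(
                    df.loc[vmask, marker], df.loc[df["group"] == gname, marker]
                )
                result[marker][gname] = {
                    "cohens_delta": eff["cohens_delta"], "p": eff["p"]
                }
    return result


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Run every configured stage; return (and write) the report bundle.

    Stages with no configured input are skipped.  A stage failure is
    recorded under ``errors`` and later stages still run; the report's
    ``ok`` flag is False if anything failed.
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig.from_dict(config)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
                    "stages": {}, "errors": {}}

    def run_stage(name: str, fn, *args) -> dict | None:
        try:
            result = fn(cfg, *args)
            report["stages"][name] = result
            return result
        except Exception as exc:  # noqa: BLE001 — stage isolation by design
            log.error("stage %s failed: %s", name, exc)
            report["errors"][name] = f"{type(exc).__name__}: {exc}"
            return None

    if cfg.de_table:
        run_stage("signature", _stage_signature)
    if cfg.concordance_table:
        run_stage("rank", _stage_rank)
    screen_out = run_stage("screen", _stage_screen) if cfg.well_table else None
    if screen_out:
        run_stage("score", _stage_score, screen_out)
    if cfg.event_log:
        run_stage("seizures", _stage_seizures)
    if cfg.biomarker_table:
        run_stage("biomarkers", _stage_biomarkers)

    report["ok"] = not report["errors"]
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    with open(out_dir / "report.txt", "w") as fh:
        fh.write(_render_report(report))
    return report


def _render_report(report: dict) -> str:
    lines = ["tbiscreen pipeline report", "=" * 25]
    for name, res in report["stages"].items():
        lines.append(f"\n[{name}]")
        for k, v in res.items():
            lines.append(f"  {k}: {v}")
    if report["errors"]:
        lines.append("\n[errors]")
        for name, msg in report["errors"].items():
            lines.append(f"  {name}: {msg}")
    lines.append(f"\nok: {report['ok']}")
    return "\n".join(lines) + "\n"
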