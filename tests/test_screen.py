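"""Plate normalization, batch adjustment, compound scoring, lead selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tbiscreen import study_inputs as si
from tbiscreen.screen import (
    ASSAYS,
    AnchorDegenerateError,
    CompoundScore,
    ScoreCriteria,
    default_criteria,
    fit_batch_model,
    normalize_nitrite,
    normalize_plate,
    normalize_tnfa,
    normalize_viability,
    score_compound,
    select_lead,
)
from tbiscreen.synthetic import PlateSpec, gen_plate


class TestNormalizationEquations:
    @pytest.mark.parametrize(
        "fn, zero_args, hundred_args",
        [
            # (drug at the 0% anchor), (drug at the 100% anchor)
            (normalize_viability, (0.2, 0.2, 1.0), (1.0, 0.2, 1.0)),
            (normalize_nitrite, (0.1, 0.9, 0.1), (0.9, 0.9, 0.1)),
            (normalize_tnfa, (0.15, 0.8, 0.15), (0.8, 0.8, 0.15)),
        ],
    )
    def test_anchor_identities(self, fn, zero_args, hundred_args):
        assert fn(*zero_args) == pytest.approx(0.0)
        assert fn(*hundred_args) == pytest.approx(100.0)

    def test_direct_arithmetic(self):
        assert normalize_viability(0.6, 0.2, 1.0) == pytest.approx(50.0)

    def test_below_anchor_percent_is_negative(self):
        # beating the positive control is legal and reported as < 0 %
        assert normalize_nitrite(0.05, 0.9, 0.1) < 0
        assert normalize_tnfa(0.05, 0.8, 0.15) < 0

    def test_degenerate_anchors_raise(self):
        with pytest.raises(AnchorDegenerateError):
            normalize_viability(0.5, 0.4, 0.4)


class TestBatchModel:
    def _plate(self, offsets, noise, seed=0):
        return gen_plate(
            PlateSpec(
                drug_effects={("D", 1e-6): {"viability": 73.0}},
                batches=len(offsets),
                replicates=3,
                batch_offsets=list(offsets),
                noise_sd=noise,
                assays=("viability",),
                seed=seed,
            )
        )

    def test_zero_offsets_estimates_equal_raw_means(self):
        wells = self._plate([0.0, 0.0], noise=0.02, seed=1)
        fit = fit_batch_model(wells, "viability")
        raw = (
            wells.assign(key=wells.apply(
                lambda r: f"drug:{r['drug']}@{r['conc_molar']:g}" if r["condition"] == "drug" else r["condition"],
                axis=1,
            ))
            .groupby("key")["absorbance"].mean()
        )
        # balanced design: adjusted estimates coincide with raw means
        for key, est in fit.estimates.items():
            assert est == pytest.approx(raw[key], abs=1e-10)

    def test_planted_offsets_noiseless_exact(self):
        wells = self._plate([0.0, 0.2, -0.15], noise=0.0)
        res = normalize_plate(wells, "viability")
        assert res[0].percent == pytest.approx(73.0, abs=1e-9)

    def test_affine_invariance_of_percentages(self):
        wells = self._plate([0.0, 0.2], noise=0.01, seed=3)
        before = normalize_plate(wells, "viability")[0].percent
        shifted = wells.copy()
        shifted.loc[shifted["batch"] == "batch2", "absorbance"] += 0.37
        after = normalize_plate(shifted, "viability")[0].percent
        assert after == pytest.approx(before, abs=1e-9)

    def test_confounded_design_raises(self):
        wells = self._plate([0.0, 0.1], noise=0.0)
        # put the drug wells in a third batch containing nothing else
        wells.loc[wells["condition"] == "drug", "batch"] = "batch3"
        with pytest.raises(ValueError, match="singular|confounded"):
            fit_batch_model(wells, "viability")

    def test_null_contrast_pvalues_uniform(self):
        """With no condition effects the contrast p-values are U(0,1)."""
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(500):
            wells = pd.DataFrame(
                {
                    "batch": ["b1"] * 6 + ["b2"] * 6,
                    "assay": "viability",
                    "condition": ["LPS/IFNg+", "1400W", "drug"] * 4,
                    "drug": ["", "", "D"] * 4,
                    "conc_molar": [np.nan, np.nan, 1e-6] * 4,
                    "absorbance": rng.normal(0.5, 0.05, 12),
                }
            )
            fit = fit_batch_model(wells, "viability")
            pvals.append(fit.contrasts.loc["drug:D@1e-06", "p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_batch_offset_recovery_study(self):
        """±0.2 batch offsets: planted effects recovered within 2 %."""
        errs = []
        for seed in range(50):
            wells = gen_plate(
                PlateSpec(
                    drug_effects={("D", 1e-6): {"viability": 73.0, "nitrite": 28.0}},
                    batches=2,
                    replicates=3,
                    batch_offsets=[0.2, -0.2],
                    noise_sd=0.01,
                    assays=("viability", "nitrite"),
                    seed=seed,
                )
            )
            for assay, planted in [("viability", 73.0), ("nitrite", 28.0)]:
                errs.append(abs(normalize_plate(wells, assay)[0].percent - planted))
        assert max(errs) < 2.0


class TestScoring:
    def test_published_score_rows_total(self):
        tsa = CompoundScore("Trichostatin A", 0.75, 0.75, 1.0)
        cal = CompoundScore("Calpain inhibitor", 0.60, 1.0, 1.0)
        assert tsa.total == pytest.approx(2.5)
        assert cal.total == pytest.approx(2.60)

    def test_default_criteria_reproduce_lead_rows_from_percents(self):
        crit = default_criteria()
        tsa = score_compound("Trichostatin A", {"viability": 73, "nitrite": 28, "tnfa": -139}, crit)
        assert (tsa.viability, tsa.nitrite, tsa.tnfa) == (0.75, 0.75, 1.0)
        cal = score_compound("Calpain inhibitor", {"viability": 47, "nitrite": -21, "tnfa": -226}, crit)
        assert (cal.viability, cal.nitrite, cal.tnfa) == (0.60, 1.0, 1.0)

    def test_missing_assay_flagged_and_excluded_from_total(self):
        s = score_compound("X", {"viability": 73, "nitrite": 28})
        assert s.missing == ("tnfa",)
        assert s.total == pytest.approx(0.75 + 0.75)

    def test_all_zero_scores_total_zero(self):
        s = CompoundScore("X", 0.0, 0.0, 0.0)
        assert s.total == 0.0

    def test_non_monotone_criteria_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            ScoreCriteria("higher", [(0, 0.5), (50, 0.25)])
        with pytest.raises(ValueError, match="monotone"):
            ScoreCriteria("lower", [(0, 0.25), (50, 0.5)])


class TestSelectLead:
    @staticmethod
    def _published_scores() -> list[CompoundScore]:
        return [
            CompoundScore(r.compound, r.viability, r.nitrite,
                          None if pd.isna(r.tnfa) else r.tnfa)
            for r in si.SCORE_TABLE.itertuples()
        ]

    def test_total_policy_picks_calpain_inhibitor(self):
        lead = select_lead(self._published_scores(), policy="total")
        assert lead.drug == "Calpain inhibitor"

    def test_viability_priority_picks_trichostatin(self):
        lead = select_lead(self._published_scores(), policy="viability-priority")
        assert lead.drug == "Trichostatin A"

    def test_single_candidate_returns_itself(self):
        only = CompoundScore("X", 0.1, 0.1, None)
        assert select_lead([only], policy="total").drug == "X"

    def test_toxicity_flags_exclude_first(self):
        scores = self._published_scores()
        # flag everything except one low scorer: it must win by default
        flags = {s.drug for s in scores} - {"Geldanamycin"}
        assert select_lead(scores, policy="total", toxicity_flags=flags).drug == "Geldanamycin"
        with pytest.raises(ValueError, match="no candidate"):
            select_lead(scores, toxicity_flags={s.drug for s in scores})
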