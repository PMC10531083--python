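# tbiscreen

Signature-based compound prioritization and preclinical seizure-outcome
statistics for traumatic brain injury (TBI).

After severe experimental TBI (lateral fluid-percussion injury in the rat),
gene-network dysregulation drives secondary damage in parallel with acute
electrographic seizures. A systems-biology repurposing strategy attacks
this in three tiers, and `tbiscreen` implements the quantitative core of
each:

1. **In silico.** Build the injury expression signature — the genes with
   |fold-change| ≥ 1.5 and FDR < 0.05 in perilesional cortex — and rank
   compound expression signatures against it by a concordance score in
   [−1, +1]. Strong *negative* concordance (signature reversal) is the
   therapeutic hypothesis; candidate lists take the top positive and top
   negative concordances.
2. **In vitro.** Normalize neuron–microglia co-culture plate assays to
   percent-of-control scales anchored by on-plate controls — neuronal
   viability (inflamed untreated = 0 %, iNOS-inhibitor 1400W = 100 %),
   nitrite (1400W = 0 %, inflamed = 100 %) and TNFα (IL10 = 0 %,
   inflamed = 100 %) — combine independent experiments with an additive
   condition + batch linear model, map outcomes to 0–1 scores per assay,
   and select the lead compound (by total score, or prioritizing neuronal
   viability).
3. **In vivo.** Reduce per-animal 72-h seizure event logs to outcome
   metrics (latency to first seizure, counts, durations, cumulative
   duration, Racine severity; overall and per 24-h epoch) and run the
   statistical battery: Fisher's exact test on seizure occurrence
   (full hypergeometric enumeration, two-sided by minimum likelihood),
   Kruskal–Wallis + Bonferroni-corrected Mann–Whitney vs vehicle, Friedman
   across epochs, Pearson correlation of biomarkers, and the pooled-SD
   Cohen's delta

   d = (m₁ − m₂) / s_p,  s_p² = [(n₁−1)s₁² + (n₂−1)s₂²] / (n₁+n₂−2)

   with no small-sample correction — the convention that reproduces the
   originating study's printed effect sizes.

Because the raw data behind the original analyses were never deposited, the
package ships generators (`tbiscreen.synthetic`) for all five input kinds —
DE tables, compound libraries, plate well tables, seizure event logs,
biomarker tables — with known planted truth, calibrated to the study
conditions (group sizes 16/7/10/10/10, vehicle seizure probability 0.81,
exponentially decaying seizure rate, log-normal durations). Published
summary tables enter only as *inputs* via `tbiscreen.study_inputs`.

Intended users: preclinical epilepsy/TBI researchers and computational
biologists who need a tested, scriptable reimplementation of this class of
screening-plus-outcome analysis.

## Worked example

Effect sizes recomputed from the published group summaries
(`examples/04_biomarkers.py`):

```
$ python examples/04_biomarkers.py
rat-01: corrected signal 0.543 ->    7047 pg/mL
rat-02: corrected signal -0.020 -> flagged below-range

published-summary effect sizes (vehicle minus treatment, pooled SD):
  pNF-H, TSA   Cohen's delta = +0.882
  pNF-H, LEV   Cohen's delta = -1.018
  lesion, TSA  Cohen's delta = +0.699
  lesion, LEV  Cohen's delta = -0.547
```

The first two lines invert a synthetic pNF-H ELISA: the 630 nm reference
reading is subtracted from the 450 nm reading, the corrected signal is
interpolated on the standard curve and multiplied by the 1:6 dilution;
signals outside the standards are flagged, never extrapolated. The deltas
are pooled-SD standardized mean differences computed from published group
means/SDs/ns with the vehicle-minus-treatment sign, so a positive value
means the treatment lowered the damage marker: the HDAC inhibitor
trichostatin A shows moderate favorable effects on both the axonal-injury
plasma marker and the cortical lesion area, whereas low-dose levetiracetam
trends unfavorable on both.

The other examples cover signature construction and ranking (`01`), the
plate screen and both lead-selection policies (`02`), the seizure battery
(`03`), and the full pipeline on synthetic inputs (`05`). The same flow is
available from the shell:

```sh
tbiscreen run-all --seed 7 --out-dir out/
tbiscreen show-config
```

## Layout

```
src/tbiscreen/
  signature.py     injury signature, concordance, candidate ranking
  screen.py        plate normalization, batch model, scoring, lead selection
  seizures.py      seizure metrics, Fisher exact, Cohen's delta, batteries
  biomarkers.py    ELISA reduction, Pearson correlation, group effects
  synthetic.py     ground-truth generators for all five input kinds
  study_inputs.py  published summary tables (inputs, never recomputed)
  io.py            delimited-text schemas
  pipeline.py/cli.py  orchestration and the `tbiscreen` command
docs/methods.md    model, conventions, numerical choices, limitations
examples/          one narrative script per capability
```
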