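"""ELISA reduction and biomarker effect sizes from published summaries.

First inverts a synthetic pNF-H ELISA (A450 - A630 correction, standard
curve, 1:6 dilution), then reproduces the published effect sizes from the
published group summary statistics.
"""

from tbiscreen import ElisaRun, ElisaSample, ElisaStandard, reduce_elisa
from tbiscreen.seizures import cohens_delta
from tbiscreen.study_inputs import LESION_SUMMARY, PNFH_SUMMARY

standards = [
    ElisaStandard(c, 0.05 + 0.0004 * c + 0.04, 0.04)
    for c in (62.5, 125, 250, 500, 1000, 2000)
]
samples = [
    ElisaSample("rat-01", 0.05 + 0.0004 * 1232 + 0.04, 0.04),
    ElisaSample("rat-02", 0.02, 0.04),  # below the lowest standard
]
for res in reduce_elisa(ElisaRun(standards, samples, dilution=6.0)):
    conc = "flagged " + res.flag if res.concentration is None else f"{res.concentration:7.0f} pg/mL"
    print(f"{res.sample_id}: corrected signal {res.signal:.3f} -> {conc}")

print("\npublished-summary effect sizes (vehicle minus treatment, pooled SD):")
for name, (veh_key, trt_key), table in [
    ("pNF-H, TSA", ("VEH-TSA", "TSA"), PNFH_SUMMARY),
    ("pNF-H, LEV", ("VEH-LEV", "LEVlow"), PNFH_SUMMARY),
    ("lesion, TSA", ("VEH-TSA", "TSA"), LESION_SUMMARY),
    ("lesion, LEV", ("VEH-LEV", "LEVlow"), LESION_SUMMARY),
]:
    d = cohens_delta(*table[veh_key], *table[trt_key])
    print(f"  {name:<12} Cohen's delta = {d:+.3f}")
print("\nPositive delta = the treatment lowered the damage marker (favorable);")
print("the HDAC inhibitor shows moderate favorable deltas on both markers.")
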