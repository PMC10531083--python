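"""Published summary tables from the originating study, exposed as inputs.

The raw per-animal, per-well and per-gene data behind these summaries were
never deposited, so they enter the package only as *inputs*: printed
concordance values for the five shortlisted compounds, the printed per-assay
0-1 scores, seizure occurrence counts per treatment group, and group summary
statistics (mean, SD, n) for the biomarkers and the cumulative seizure
duration.  Downstream code recomputes rankings, score totals, lead
selection, exact tests and effect sizes from these inputs; it never
recomputes the summaries themselves.

Group labels: VEH = vehicle, TSA = trichostatin A 1 mg/kg/d,
LEVlow/LEVhigh = levetiracetam 54/150 mg/kg/d, LEVhigh+TSA = combination.
"""

from __future__ import annotations

import pandas as pd

#: Concordance of each shortlisted compound's expression signature with the
#: injury signature, per post-injury timepoint, with the assay cell line.
CONCORDANCE_TABLE = pd.DataFrame(
    [
        ("Trichostatin A", 0.331, "Neu", 0.373, "Neu"),
        ("Geldanamycin", 0.281, "Neu-KCL", 0.375, "Neu-KCL"),
        ("Calpain inhibitor", 0.268, "Neu-KCL", 0.367, "Neu-KCL"),
        ("7,8-dihydroxychlorpromazine", 0.221, "Neu-KCL", 0.226, "Neu-KCL"),
        ("(+)-Tranylcypromine", -0.206, "Neu-KCL", -0.251, "Neu-KCL"),
    ],
    columns=["compound", "conc_32h", "cell_32h", "conc_3mo", "cell_3mo"],
)

#: Per-assay 0-1 scores of the in vitro screen at the most effective tested
#: concentration.  TNFα was not assayed for the two compounds without
#: viability/nitrite effects (None = not available).
SCORE_TABLE = pd.DataFrame(
    [
        ("Trichostatin A", "50 nM", 0.75, 0.75, 1.0),
        ("7,8-dihydroxychlorpromazine", "50 uM", 0.45, 0.30, 1.0),
        ("Calpain inhibitor", "50 uM", 0.60, 1.0, 1.0),
        ("(+)-Tranylcypromine", "1 uM", 0.15, 0.15, None),
        ("Geldanamycin", "10 nM", 0.15, 0.15, None),
    ],
    columns=["compound", "concentration", "viability", "nitrite", "tnfa"],
)

#: Percent-of-control outcomes of the screen at the scored concentration
#: (viability: LPS/IFNγ+ = 0, 1400W = 100; nitrite: 1400W = 0, LPS/IFNγ+ =
#: 100; TNFα: IL10 = 0, LPS/IFNγ+ = 100).  None = assay not run.
SCREEN_PERCENTS = pd.DataFrame(
    [
        ("Trichostatin A", 73.0, 28.0, -139.0),
        ("7,8-dihydroxychlorpromazine", 57.0, 81.0, -41.0),
        ("Calpain inhibitor", 47.0, -21.0, -226.0),
        ("(+)-Tranylcypromine", 2.0, 81.0, None),
        ("Geldanamycin", 5.0, 55.0, None),
    ],
    columns=["compound", "viability", "nitrite", "tnfa"],
)

#: Animals with >= 1 electrographic seizure during 0-72 h / group size.
SEIZURE_OCCURRENCE = {
    "VEH": (13, 16),
    "TSA": (6, 7),
    "LEVlow": (5, 10),
    "LEVhigh": (4, 10),
    "LEVhigh+TSA": (3, 10),
}

#: Cumulative seizure duration (s) over 0-72 h: group mean, SD, n.
CUMULATIVE_DURATION_SUMMARY = {
    "VEH": (727.0, 688.0, 16),
    "TSA": (898.0, 937.0, 7),
    "LEVlow": (358.0, 715.0, 10),
    "LEVhigh": (42.0, 64.0, 10),
    "LEVhigh+TSA": (109.0, 282.0, 10),
}

#: Plasma pNF-H at 72 h (pg/mL): mean, SD, n.  Each treatment group is
#: compared against its own vehicle subgroup.
PNFH_SUMMARY = {
    "VEH-TSA": (7394.0, 592.0, 3),
    "TSA": (6073.0, 1695.0, 7),
    "VEH-LEV": (2183.0, 166.0, 3),
    "LEVlow": (5183.0, 3256.0, 10),
}

#: Cortical lesion area on day 14 (mm^2): mean, SD, n.
LESION_SUMMARY = {
    "VEH-TSA": (25.9, 3.0, 3),
    "TSA": (22.8, 5.0, 5),
    "VEH-LEV": (20.4, 4.4, 3),
    "LEVlow": (27.1, 13.7, 8),
}

#: Reported Pearson correlation between plasma pNF-H and lesion area
#: (raw pairs unpublished; input constant only, never recomputed here).
PNFH_LESION_CORRELATION = {"r": 0.558, "r2": 0.31}

#: Compounds flagged toxic from post-exposure microscopy (input flag; the
#: package never infers toxicity from assay values).
TOXICITY_FLAGS = frozenset({"Geldanamycin"})
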