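"""Reference cohort profile and published summary numbers.

The pipeline is designed around a large published pan-cancer serum miRNA
screening cohort: 13 cancer types (3352 cancer samples) plus 2809
non-cancer controls, profiled on the same microarray platform and split
into training and validation sets with per-type training fractions.
The constants below encode that cohort's composition and headline
accounting; the synthetic generator uses them as its default simulation
profile, and the frequency table is the published 100-model
stability-selection outcome used as a worked example in docs and tests.
"""

from __future__ import annotations

#: per-cancer-type sample counts of the reference cohort
COHORT_COUNTS = {
    "prostate": 809,
    "ovarian": 320,
    "bladder": 392,
    "hepatocellular": 345,
    "breast": 155,
    "colorectal": 205,
    "sarcoma": 205,
    "pancreatic": 205,
    "gastric": 205,
    "lung": 153,
    "esophageal": 178,
    "glioma": 90,
    "biliary": 90,
}

#: per-type training fractions used for the stratified split (prostate is
#: down-weighted, the three next-largest types moderately so, to limit
#: over-representation of any one cancer in the training set)
TRAINING_FRACTIONS = {
    "prostate": 0.40,
    "ovarian": 0.70,
    "bladder": 0.70,
    "hepatocellular": 0.70,
    "breast": 0.80,
    "colorectal": 0.80,
    "sarcoma": 0.80,
    "pancreatic": 0.80,
    "gastric": 0.80,
    "lung": 0.80,
    "esophageal": 0.80,
    "glioma": 0.80,
    "biliary": 0.80,
}

#: non-cancer training fraction chosen so the overall training share of the
#: reference cohort is reproduced (2247 of 2809 controls in training)
NON_CANCER_TRAINING_FRACTION = 0.7997

#: headline sample accounting reported for the reference cohort
REPORTED = {
    "total_cancer": 3352,
    "total_non_cancer": 2809,
    "train_cancer": 2253,
    "train_non_cancer": 2247,
    "validation_cancer": 1102,
    "validation_non_cancer": 562,
    "training_share": 0.73,
    "n_balanced": 5,
}

#: published stability-selection frequencies: how often each miRNA ranked in
#: the per-model top 10 by mean decrease in Gini across 100 random forest
#: models; markers at frequency >= 90 were called "balanced"
STABILITY_FREQUENCIES = {
    "hsa-miR-3184-5p": 100,
    "hsa-miR-663a": 100,
    "hsa-miR-6784-5p": 100,
    "hsa-miR-6802-5p": 96,
    "hsa-miR-8073": 90,
    "hsa-miR-4783-3p": 87,
    "hsa-miR-1307-3p": 86,
    "hsa-miR-4730": 79,
    "hsa-miR-320a-3p": 63,
    "hsa-miR-5100": 45,
    "hsa-miR-1343-3p": 43,
    "hsa-miR-1469": 38,
    "hsa-miR-1233-5p": 30,
    "hsa-miR-1290": 14,
    "hsa-miR-4675": 11,
    "hsa-miR-1238-5p": 8,
    "hsa-miR-320b": 7,
    "hsa-miR-4532": 2,
    "hsa-miR-4687-5p": 1,
}
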