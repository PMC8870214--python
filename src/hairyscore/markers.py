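"""Panel, group and threshold constants shared across the pipeline.

The marker panel is the 15-antibody surface panel used to characterise
villous B-cell neoplasms; the first 13 are the "extended phenotype" set,
CD26 and CD27 are the add-on markers.
"""

from __future__ import annotations

# Diagnosis groups
CHCL = "cHCL"
VHCL_SDRPL = "vHCL_SDRPL"
HCL_LIKE_NOS = "HCL_like_NOS"
GROUPS = (CHCL, VHCL_SDRPL, HCL_LIKE_NOS)
#: groups pooled as the "HCL-like" negative class in diagnostic evaluation
HCL_LIKE_GROUPS = (VHCL_SDRPL, HCL_LIKE_NOS)

#: full surface panel, in acquisition order
PANEL = (
    "CD19", "CD20", "CD79b", "FMC7", "CD5", "CD10", "CD23", "CD43",
    "CD38", "CD11c", "CD103", "CD123", "CD25", "CD26", "CD27",
)

#: the 13 markers entering the all-marker ordination
MARKERS_13 = PANEL[:13]

#: constituents of the classical 4-marker immunologic HCL score
SCORE4_MARKERS = ("CD11c", "CD25", "CD103", "CD123")
#: CD26-extended 5-marker score
SCORE5_MARKERS = SCORE4_MARKERS + ("CD26",)

GENES = ("BRAF_V600E", "MAP2K1", "KLF2")

# Event populations in an event table
TUMOR_B = "tumor_B"
NORMAL_B = "normal_B"
T4 = "T4"
T8 = "T8"
OTHER = "other"
POPULATIONS = (TUMOR_B, NORMAL_B, T4, T8, OTHER)
#: populations counted as lymphocytes for the infiltration denominator
LYMPHOCYTE_POPULATIONS = (TUMOR_B, NORMAL_B, T4, T8)

# Interpretation thresholds
POSITIVITY_PCT = 20.0        # marker positive when >= 20% of abnormal cells express it
DIM_MFI = 500.0              # dim expression: MFI < 500
BRIGHT_MFI = 1000.0          # bright expression: MFI > 1000
CD4_CD8_CUTOFF = 2.0         # survival stratification cut-off (strictly > 2)

INTENSITY_CLASSES = ("negative", "dim", "moderate", "bright")
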