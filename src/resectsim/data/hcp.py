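"""Full-scale atlas building blocks: HCP-MMP1.0 cortical area names.

``GLASSER_AREAS`` lists the 180 multimodal-parcellation cortical areas per
hemisphere in the standard atlas index order; ``LOBE_ASSIGNMENT`` groups
them into the eight cortical regions analysed per hemisphere (frontal,
sensorimotor, medial frontal, operculum, temporal, lateral parietal, medial
parietal, occipital).  ``SUBCORTICAL`` lists the 19 non-resectable
subcortical/cerebellar/brainstem components (8 per hemisphere, one
cerebellar region per hemisphere, brainstem).

The *physical adjacency* of the shipped full-scale atlas is synthetic: a
connected within-lobe lattice plus links between anatomically neighbouring
lobes, built by :func:`resectsim.synthetic_cohort.generate_atlas`.  It is a
stand-in with realistic scale and structure, not a measured border graph.
"""

from __future__ import annotations

GLASSER_AREAS: tuple[str, ...] = (
    "V1", "MST", "V6", "V2", "V3", "V4", "V8", "4", "3b", "FEF",
    "PEF", "55b", "V3A", "RSC", "POS2", "V7", "IPS1", "FFC", "V3B", "LO1",
    "LO2", "PIT", "MT", "A1", "PSL", "SFL", "PCV", "STV", "7Pm", "7m",
    "POS1", "23d", "v23ab", "d23ab", "31pv", "5m", "5mv", "23c", "5L", "24dd",
    "24dv", "7AL", "SCEF", "6ma", "7Am", "7PL", "7PC", "LIPv", "VIP", "MIP",
    "1", "2", "3a", "6d", "6mp", "6v", "p24pr", "33pr", "a24pr", "p32pr",
    "a24", "d32", "8BM", "p32", "10r", "47m", "8Av", "8Ad", "9m", "8BL",
    "9p", "10d", "8C", "44", "45", "47l", "a47r", "6r", "IFJa", "IFJp",
    "IFSp", "IFSa", "p9-46v", "46", "a9-46v", "9-46d", "9a", "10v", "a10p", "10pp",
    "11l", "13l", "OFC", "47s", "LIPd", "6a", "i6-8", "s6-8", "43", "OP4",
    "OP1", "OP2-3", "52", "RI", "PFcm", "PoI2", "TA2", "FOP4", "MI", "Pir",
    "AVI", "AAIC", "FOP1", "FOP3", "FOP2", "PFt", "AIP", "EC", "PreS", "H",
    "ProS", "PeEc", "STGa", "PBelt", "A5", "PHA1", "PHA3", "STSda", "STSdp", "STSvp",
    "TGd", "TE1a", "TE1p", "TE2a", "TF", "TE2p", "PHT", "PH", "TPOJ1", "TPOJ2",
    "TPOJ3", "DVT", "PGp", "IP2", "IP1", "IP0", "PFop", "PF", "PFm", "PGi",
    "PGs", "V6A", "VMV1", "VMV3", "PHA2", "V4t", "FST", "V3CD", "LO3", "VMV2",
    "31pd", "31a", "VVC", "25", "s32", "pOFC", "PoI1", "Ig", "FOP5", "p10p",
    "p47r", "TGv", "MBelt", "LBelt", "A4", "STSva", "TE1m", "PI", "a32pr", "p24",
)

#: The eight cortical regions assessed per hemisphere.
LOBE_NAMES: tuple[str, ...] = (
    "frontal",
    "sensorimotor",
    "medial_frontal",
    "operculum",
    "temporal",
    "lateral_parietal",
    "medial_parietal",
    "occipital",
)

LOBE_ASSIGNMENT: dict[str, tuple[str, ...]] = {
    "frontal": (
        "8Av", "8Ad", "8BL", "8C", "9p", "9a", "9-46d", "46", "a9-46v",
        "p9-46v", "IFJa", "IFJp", "IFSp", "IFSa", "44", "45", "47l", "47m",
        "47s", "a47r", "p47r", "10d", "a10p", "p10p", "10pp", "11l", "13l",
        "OFC", "pOFC", "i6-8", "s6-8",
    ),
    "sensorimotor": (
        "4", "3a", "3b", "1", "2", "FEF", "PEF", "55b", "SFL", "6d", "6a",
        "6v", "6r", "6ma", "6mp",
    ),
    "medial_frontal": (
        "9m", "8BM", "SCEF", "24dd", "24dv", "a24", "p24", "a24pr", "p24pr",
        "33pr", "a32pr", "p32pr", "d32", "p32", "s32", "25", "10v", "10r",
    ),
    "operculum": (
        "43", "OP4", "OP1", "OP2-3", "52", "RI", "PFcm", "PoI1", "PoI2",
        "TA2", "FOP1", "FOP2", "FOP3", "FOP4", "FOP5", "MI", "Pir", "AVI",
        "AAIC", "Ig", "PI", "A1", "A4", "A5", "MBelt", "LBelt", "PBelt",
        "PSL",
    ),
    "temporal": (
        "STGa", "STSda", "STSdp", "STSva", "STSvp", "TGd", "TGv", "TE1a",
        "TE1m", "TE1p", "TE2a", "TE2p", "TF", "PHT", "PH", "EC", "PreS",
        "H", "PeEc", "PHA1", "PHA2", "PHA3", "TPOJ1", "TPOJ2", "TPOJ3",
        "STV",
    ),
    "lateral_parietal": (
        "7AL", "7Am", "7PL", "7PC", "LIPv", "LIPd", "VIP", "MIP", "AIP",
        "IP0", "IP1", "IP2", "IPS1", "PF", "PFm", "PFt", "PFop", "PGi",
        "PGs", "PGp",
    ),
    "medial_parietal": (
        "POS1", "POS2", "7m", "7Pm", "PCV", "RSC", "23d", "23c", "v23ab",
        "d23ab", "31pv", "31pd", "31a", "5m", "5mv", "5L",
    ),
    "occipital": (
        "V1", "V2", "V3", "V4", "V6", "V7", "V8", "V3A", "V3B", "V3CD",
        "V4t", "V6A", "LO1", "LO2", "LO3", "MT", "MST", "FST", "PIT",
        "FFC", "VMV1", "VMV2", "VMV3", "VVC", "ProS", "DVT",
    ),
}

#: Pairs of lobes that physically border each other (within one hemisphere);
#: used to place inter-lobe adjacency edges in the synthetic border graph.
LOBE_BORDERS: tuple[tuple[str, str], ...] = (
    ("frontal", "sensorimotor"),
    ("frontal", "medial_frontal"),
    ("frontal", "operculum"),
    ("sensorimotor", "medial_frontal"),
    ("sensorimotor", "operculum"),
    ("sensorimotor", "lateral_parietal"),
    ("operculum", "temporal"),
    ("temporal", "lateral_parietal"),
    ("temporal", "occipital"),
    ("lateral_parietal", "occipital"),
    ("lateral_parietal", "medial_parietal"),
    ("medial_parietal", "occipital"),
    ("medial_frontal", "medial_parietal"),
)

#: FreeSurfer-style subcortical components: (name, hemisphere).
SUBCORTICAL: tuple[tuple[str, str], ...] = tuple(
    [
        (f"{h}_{name}", hemi)
        for hemi, h in (("left", "L"), ("right", "R"))
        for name in (
            "Thalamus", "Caudate", "Putamen", "Pallidum",
            "Hippocampus", "Amygdala", "Accumbens", "VentralDC",
        )
    ]
    + [("L_Cerebellum", "left"), ("R_Cerebellum", "right"), ("Brainstem", "midline")]
)
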