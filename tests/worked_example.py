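"""Case-study inputs for the PS2Aa1-APN complex.

These are the published tabular results of the docking/MD study of the
parasporin PS2Aa1 against the aminopeptidase N receptor: the top-10
docking models with their interface hydrogen-bond counts, the residues
selected per MD replicate by the >80% contact-persistence criterion, and
the per-residue COM distance statistics (Å). The raw ensembles and
trajectories were never deposited, so these printed values are the
ground-truth inputs for the worked examples.
"""

# (model_id, interface hydrogen-bond count), in published order
DOCKING_RANKING_INPUT = [
    (560, 9),
    (3413, 9),
    (105, 9),
    (819, 8),
    (994, 8),
    (2079, 8),
    (3521, 8),
    (1015, 8),
    (1742, 8),
    (708, 8),
]

# residues passing the contact criteria, per MD replicate
REPLICATE_SELECTIONS = {
    "rep1": {"PRO255", "GLY256"},
    "rep2": {
        "ARG76", "PRO238", "ILE239", "THR240", "VAL241", "ARG266",
        "GLY256", "GLY257", "THR272", "SER273", "GLY274",
    },
    "rep3": {
        "ARG76", "PRO238", "ILE239", "THR240", "VAL241", "ASP242",
        "PRO255", "GLY256", "GLY257", "ARG266", "ASP267", "ASN270",
        "THR272", "SER273", "GLY274", "THR275",
    },
}

# per-residue COM distance to the closest APN residue: (mean, SD) in Å
DISTANCE_TABLE = {
    "GLY256": (4.44, 0.21),
    "THR272": (5.53, 0.61),
    "SER273": (5.58, 0.09),
    "PRO255": (5.77, 0.26),
    "THR240": (6.04, 0.27),
    "ARG266": (6.29, 0.70),
    "PRO238": (6.30, 0.58),
    "GLY274": (6.33, 0.23),
    "ASP267": (6.49, 0.44),
    "ARG76": (6.58, 0.55),
    "GLY257": (6.64, 0.69),
    "ASN270": (7.04, 0.79),
    "THR275": (7.59, 0.45),
    "VAL241": (7.64, 0.75),
    "ILE239": (7.74, 0.25),
}
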