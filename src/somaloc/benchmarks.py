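"""Published reference measurements used as arithmetic fixtures.

These tables come from a stereological and deep-learning survey of
NeuN-labelled neurons in four slabs (6, 18, 30, 42) of a cleared human
Broca's area imaged by light-sheet microscopy at 3.6 um isotropic
resolution.  They serve as ground truth for the *bookkeeping* code paths:
recomputing F1 from printed precision/recall, aggregating per-slab
densities into layer means and sample standard deviations, and summing
per-slab marker counts.  No model output is involved.
"""

# per-slab localization metrics of the soft-target detection method against
# stereological annotations: slab -> (precision %, recall %, F1 %)
DETECTION_VS_STEREOLOGY = {
    "6": (69.0, 84.4, 75.9),
    "18": (76.9, 68.7, 72.6),
    "30": (72.0, 81.6, 76.5),
    "42": (76.4, 82.6, 79.4),
    "total": (73.8, 78.0, 75.8),
}

# stereological marker counts per slab and their printed total
STEREOLOGY_MARKERS_PER_SLAB = {"6": 379, "18": 746, "30": 626, "42": 494}
STEREOLOGY_MARKERS_TOTAL = 2245

# stereological densities (cells/mm^3) per cortical layer across the four
# slabs, with the printed layer mean and sample standard deviation
STEREOLOGY_DENSITIES = {
    3: {
        "per_slab": [10_646.75, 13_412.64, 11_649.91, 12_251.03],
        "mean": 11_990.08,
        "sd": 1_156.44,
    },
    5: {
        "per_slab": [12_162.03, 17_037.78, 16_708.95, 20_484.54],
        "mean": 16_598.32,
        "sd": 3_415.10,
    },
    6: {
        "per_slab": [13_890.03, 17_602.81, 15_462.57, 23_231.62],
        "mean": 17_546.76,
        "sd": 4_083.97,
    },
}
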