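"""Published reference values for a Tdrd7-deficient P4 lens miRNA comparison.

These printed group means, fold changes and intensities are treated as inputs:
tests recompute the derived quantities from the means and compare against the
printed values.  ``CONSISTENT_DE_ROWS`` lists the features whose printed fold
change reproduces exactly from the printed (rounded) means at one-decimal
rounding; the remaining rows reflect unrounded means and are excluded from
exact assertions.
"""

# feature, knockout mean, control mean, printed signed FC, printed p
REPORTED_DE_MIRNAS = [
    ("mmu-mir-1198", 18.3, 30.6, -1.7, 0.024),
    ("mmu-mir-382", 16.6, 28.6, -1.7, 0.044),
    ("mmu-mir-1947", 30.6, 45.1, -1.5, 0.048),
    ("mmu-mir-409", 62.5, 80.6, -1.4, 0.019),
    ("mmu-mir-3092", 14.5, 20.1, -1.4, 0.021),
    ("mmu-let-7b", 483.7, 627.0, -1.3, 0.031),
    ("mmu-mir-298", 77.9, 99.5, -1.3, 0.022),
    ("mmu-mir-34c", 102.5, 120.5, -1.2, 0.044),
    ("mmu-mir-3107", 92.4, 75.7, 1.2, 0.049),
    ("mmu-mir-378b", 27.6, 21.3, 1.3, 0.046),
    ("mmu-mir-339", 27.3, 20.4, 1.4, 0.031),
    ("mmu-mir-384", 7.4, 5.2, 1.4, 0.018),
    ("mmu-mir-138", 9.8, 6.5, 1.5, 0.042),
    ("mmu-mir-1224", 18.5, 12.2, 1.5, 0.006),
    ("mmu-mir-1935", 11.0, 7.0, 1.6, 0.018),
    ("mmu-mir-328", 25.2, 16.4, 1.6, 0.024),
    ("mmu-mir-3102", 20.0, 12.5, 1.6, 0.008),
    ("mmu-mir-19a", 13.0, 8.2, 1.7, 0.049),
    ("mmu-mir-345", 8.2, 4.4, 1.8, 0.027),
    ("mmu-mir-1946a", 14.5, 7.4, 1.9, 0.035),
    ("mmu-mir-467a", 15.3, 7.5, 2.1, 0.010),
    ("mmu-mir-15a", 15.8, 7.2, 2.2, 0.012),
]

# features whose printed FC reproduces from the printed means (1 d.p. rounding)
CONSISTENT_DE_ROWS = {
    "mmu-mir-1198",
    "mmu-mir-382",
    "mmu-mir-1947",
    "mmu-mir-3092",
    "mmu-let-7b",
    "mmu-mir-298",
    "mmu-mir-34c",
    "mmu-mir-3107",
    "mmu-mir-378b",
    "mmu-mir-384",
    "mmu-mir-138",
    "mmu-mir-1224",
    "mmu-mir-1935",
    "mmu-mir-3102",
    "mmu-mir-15a",
}

# highly expressed control-lens miRNAs: (id, control P4 intensity); the
# catalog is defined by intensity >= 500
REPORTED_HIGH_EXPRESSION = [
    ("mir-184", 15592.3),
    ("mir-709", 8631.6),
    ("mir-31", 5871.0),
    ("let-7e", 3255.7),
    ("mir-26a", 3129.2),
    ("mir-17", 2697.1),
    ("mir-181a", 2298.5),
    ("mir-181b", 2227.2),
    ("mir-125a", 2226.9),
    ("mir-99b", 2181.6),
    ("mir-20a", 1956.3),
    ("let-7c-1", 1708.8),
    ("mir-24", 1397.8),
    ("mir-125b", 1339.0),
    ("mir-103", 1280.4),
    ("mir-23b", 1133.3),
    ("mir-23a", 1088.0),
    ("mir-191", 947.9),
    ("mir-93", 939.8),
    ("mir-107", 910.4),
    ("let-7a", 889.8),
    ("mir-5105", 752.1),
    ("mir-16", 727.8),
    ("mir-5109", 684.1),
    ("mir-92a", 634.0),
    ("let-7b", 627.0),
    ("mir-106a", 601.0),
    ("mir-130a", 594.7),
    ("mir-5126", 590.7),
    ("let-7d", 590.4),
    ("mir-204", 515.4),
]

# detection summary of the reference profiling: 697 mature miRNAs detected,
# 503 of them at intensity <= 5.0
N_DETECTED = 697
N_LOW_INTENSITY = 503
LOW_INTENSITY_PERCENT = 72.2
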