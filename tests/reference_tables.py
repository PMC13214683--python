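"""Frozen reference values from the published JADER anti-MRSA safety screen.

``SIGNAL_ROWS`` holds every SMQ-level signal row as printed: the 2×2
counts (cases with / without the target drug against the drug and
non-drug report totals) together with the rounded PRR, Yates-corrected
chi-squared and ROR point estimate. ``IC025_REFERENCE`` carries the
printed lower credibility bounds; only the vancomycin / acute-renal-
failure value is asserted tightly, the published IC formulation being
only approximately recoverable.

``WEIBULL_CLASS_ROWS`` holds every published Weibull shape estimate with
its 95% CI and the published failure-type label.
"""

# (drug, term, a, drug_total, c, nondrug_total, prr, chi2, ror)
SIGNAL_ROWS = [
    ("vancomycin", "acute renal failure", 510, 2318, 31495, 952859, 6.66, 2490.21, 8.25),
    ("vancomycin", "hypersensitivity", 684, 2318, 112677, 952859, 2.50, 689.60, 3.12),
    ("vancomycin", "severe cutaneous adverse reactions", 273, 2318, 27823, 952859, 4.03, 632.35, 4.44),
    ("vancomycin", "haematopoietic cytopenias", 513, 2318, 98672, 952859, 2.14, 343.32, 2.46),
    ("vancomycin", "oropharyngeal disorders", 165, 2318, 25951, 952859, 2.61, 166.28, 2.74),
    ("vancomycin", "tubulointerstitial diseases", 59, 2318, 5258, 952859, 4.61, 162.42, 4.71),
    ("vancomycin", "agranulocytosis", 176, 2318, 34207, 952859, 2.12, 105.62, 2.21),
    ("vancomycin", "chronic kidney disease", 46, 2318, 4950, 952859, 3.82, 92.59, 3.88),
    ("vancomycin", "DRESS syndrome", 44, 2318, 5152, 952859, 3.51, 76.27, 3.56),
    ("vancomycin", "hearing and vestibular disorders", 27, 2318, 2878, 952859, 3.86, 53.96, 3.89),
    ("vancomycin", "pseudomembranous colitis", 21, 2318, 2085, 952859, 4.14, 46.55, 4.17),
    ("vancomycin", "sepsis", 59, 2318, 10684, 952859, 2.27, 40.90, 2.30),
    ("teicoplanin", "haematopoietic cytopenias", 305, 838, 98880, 954339, 3.51, 607.07, 4.95),
    ("teicoplanin", "acute renal failure", 101, 838, 31904, 954339, 3.61, 193.44, 3.96),
    ("teicoplanin", "agranulocytosis", 98, 838, 34285, 954339, 3.26, 156.06, 3.55),
    ("teicoplanin", "hepatic disorders", 130, 838, 71835, 954339, 2.06, 75.50, 2.26),
    ("teicoplanin", "severe cutaneous adverse reactions", 60, 838, 28036, 954339, 2.44, 50.81, 2.55),
    ("teicoplanin", "chronic kidney disease", 18, 838, 4978, 954339, 4.12, 39.49, 4.19),
    ("teicoplanin", "acute pancreatitis", 11, 838, 4881, 954339, 2.57, 9.03, 2.59),
    ("teicoplanin", "pseudomembranous colitis", 6, 838, 2100, 954339, 3.25, 7.24, 3.27),
    ("arbekacin", "acute renal failure", 74, 227, 31931, 954950, 9.75, 590.79, 13.98),
    ("arbekacin", "chronic kidney disease", 14, 227, 4982, 954950, 11.82, 128.39, 12.53),
    ("arbekacin", "hepatic disorders", 39, 227, 71926, 954950, 2.28, 28.96, 2.55),
    ("arbekacin", "pseudomembranous colitis", 4, 227, 2102, 954950, 8.01, 18.02, 8.13),
    ("daptomycin", "eosinophilic pneumonia", 76, 552, 5641, 954625, 23.30, 1588.04, 26.86),
    ("daptomycin", "interstitial lung disease", 111, 552, 53977, 954625, 3.56, 213.07, 4.20),
    ("daptomycin", "rhabdomyolysis/myopathy", 33, 552, 8499, 954625, 6.71, 155.63, 7.08),
    ("daptomycin", "lack of efficacy/effect", 17, 552, 4441, 954625, 6.62, 75.65, 6.80),
    ("daptomycin", "acute renal failure", 54, 552, 31951, 954625, 2.92, 68.58, 3.13),
    ("daptomycin", "sepsis", 21, 552, 10722, 954625, 3.39, 33.29, 3.48),
    ("daptomycin", "severe cutaneous adverse reactions", 35, 552, 28061, 954625, 2.16, 21.18, 2.24),
    ("daptomycin", "acute central respiratory depression", 10, 552, 7048, 954625, 2.45, 7.26, 2.48),
    ("linezolid", "haematopoietic cytopenias", 1103, 1750, 98082, 953427, 6.13, 5215.83, 14.87),
    ("linezolid", "agranulocytosis", 361, 1750, 34022, 953427, 5.78, 1460.20, 7.02),
    ("linezolid", "hyponatremia/SIADH", 96, 1750, 6745, 953427, 7.75, 554.18, 8.15),
    ("linezolid", "optic nerve disorders", 33, 1750, 931, 953427, 19.31, 536.34, 19.66),
    ("linezolid", "lactic acidosis", 39, 1750, 2088, 953427, 10.18, 308.51, 10.39),
    ("linezolid", "peripheral neuropathy", 38, 1750, 7446, 953427, 2.78, 41.67, 2.82),
    ("linezolid", "pseudomembranous colitis", 13, 1750, 2093, 953427, 3.38, 19.43, 3.40),
    ("linezolid", "torsade de pointes/QT prolongation", 22, 1750, 5832, 953427, 2.06, 10.91, 2.07),
    ("linezolid", "taste and smell disorders", 7, 1750, 1159, 953427, 3.29, 8.94, 3.30),
    ("linezolid", "lack of efficacy/effect", 17, 1750, 4441, 953427, 2.09, 8.56, 2.10),
    ("linezolid", "hearing and vestibular disorders", 12, 1750, 2893, 953427, 2.26, 7.21, 2.27),
    ("tedizolid", "haematopoietic cytopenias", 20, 39, 99165, 955138, 4.94, 65.78, 9.09),
    ("tedizolid", "agranulocytosis", 7, 39, 34376, 955138, 4.99, 19.19, 5.86),
]

# (drug, term, ic025) for the rows above, in the same order
IC025_REFERENCE = {
    ("vancomycin", "acute renal failure"): 2.58,
}

# (drug, term, beta, ci_low, ci_high, published failure-type label)
WEIBULL_CLASS_ROWS = [
    ("vancomycin", "acute renal failure", 1.35, 1.22, 1.48, "wear-out"),
    ("teicoplanin", "acute renal failure", 1.25, 1.02, 1.47, "wear-out"),
    ("arbekacin", "acute renal failure", 1.75, 1.40, 2.10, "wear-out"),
    ("daptomycin", "acute renal failure", 1.23, 0.88, 1.57, "random"),
    ("linezolid", "acute renal failure", 0.86, 0.63, 1.08, "random"),
    ("vancomycin", "hypersensitivity", 1.09, 1.0049, 1.17, "wear-out"),
    ("teicoplanin", "hypersensitivity", 0.92, 0.81, 1.03, "random"),
    ("daptomycin", "hypersensitivity", 0.98, 0.81, 1.14, "random"),
    ("linezolid", "hypersensitivity", 1.17, 0.89, 1.45, "random"),
    ("vancomycin", "severe cutaneous adverse reactions", 1.20, 1.06, 1.34, "wear-out"),
    ("teicoplanin", "severe cutaneous adverse reactions", 1.68, 1.29, 2.08, "wear-out"),
    ("daptomycin", "severe cutaneous adverse reactions", 1.38, 0.98, 1.79, "random"),
    ("vancomycin", "hepatic disorders", 1.37, 1.17, 1.57, "wear-out"),
    ("teicoplanin", "hepatic disorders", 1.48, 1.25, 1.72, "wear-out"),
    ("arbekacin", "hepatic disorders", 1.63, 1.21, 2.05, "wear-out"),
    ("daptomycin", "hepatic disorders", 1.57, 1.22, 1.91, "wear-out"),
    ("linezolid", "hepatic disorders", 0.96, 0.76, 1.17, "random"),
    ("daptomycin", "eosinophilic pneumonia", 1.65, 1.34, 1.97, "wear-out"),
    ("daptomycin", "interstitial lung disease", 1.89, 1.58, 2.20, "wear-out"),
    ("vancomycin", "haematopoietic cytopenias", 1.63, 1.49, 1.77, "wear-out"),
    ("teicoplanin", "haematopoietic cytopenias", 1.79, 1.60, 1.98, "wear-out"),
    ("arbekacin", "haematopoietic cytopenias", 1.24, 0.84, 1.64, "random"),
    ("daptomycin", "haematopoietic cytopenias", 0.92, 0.70, 1.15, "random"),
    ("linezolid", "haematopoietic cytopenias", 1.22, 1.15, 1.29, "wear-out"),
    ("vancomycin", "agranulocytosis", 1.73, 1.45, 2.02, "wear-out"),
    ("teicoplanin", "agranulocytosis", 1.87, 1.44, 2.31, "wear-out"),
    ("linezolid", "agranulocytosis", 1.11, 0.99, 1.23, "random"),
]
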