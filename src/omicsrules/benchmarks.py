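"""Published reference values from a high-grade soft-tissue sarcoma
multi-omics rule-mining study (GEO accession GSE52392).

These tables are inputs for validating the ranking and summary
operations on real published numbers: the 24 mined directional rules
with their interestingness metrics and relative-closeness scores, and
the per-rule cross-validated classification metrics of the top-10 rules
of three mining strategies (the dynamic-threshold method and the Apriori
and Eclat baselines). Percentages are stored as printed.
"""

from __future__ import annotations

import pandas as pd

# rule label, confidence, support, lift, avg. network distance,
# relative closeness score, published post-optimization rank
SARCOMA_RULES = [
    ("STAT3+ -> MAPK3+",                0.009,       0.003461538, 0.0195,     0.00339,     0.3596, 2),
    ("TP53- -> MAPK3+",                 0.008888889, 0.003076923, 0.01925926, 0.00408,     0.3547, 6),
    ("MAPK3+, TP53- -> STAT3+",         0.00875,     0.002692308, 0.02275,    0.00543,     0.346, 15),
    ("STAT3+, TP53- -> MAPK3+",         0.01,        0.002692308, 0.02166667, 0.003735,    0.36,   1),
    ("ESR1+ -> MAPK3+",                 0.008333333, 0.001923077, 0.01805556, 0.00357,     0.3565, 4),
    ("JUN+, STAT3+ -> MAPK3+",          0.008571429, 0.002307692, 0.01857143, 0.00388,     0.355,  5),
    ("JUN+, FYN+ -> MAPK3+",            0.01,        0.002307692, 0.02166667, 0.008,       0.3354, 22),
    ("STAT3+, FYN+ -> MAPK3+",          0.01,        0.002692308, 0.02166667, 0.00751,     0.3384, 19),
    ("JUN+, TP53- -> MAPK3+",           0.008571429, 0.002307692, 0.01857143, 0.004225,    0.3525, 7),
    ("JUN+, STAT3+, TP53 -> MAPK3+",    0.01,        0.001923077, 0.02166667, 0.003946667, 0.3588, 3),
    ("FYN+, TP53 -> MAPK3+",            0.01,        0.002307692, 0.02166667, 0.007855,    0.3361, 21),
    ("JUN+, AR+ -> MAPK3+",             0.01,        0.001923077, 0.02166667, 0.00567,     0.3474, 14),
    ("JUN+, AR+ -> TP53-",              0.01,        0.001923077, 0.02888889, 0.0072,      0.3399, 18),
    ("TP53-, AR+ -> JUN+",              0.01,        0.001923077, 0.026,      0.00541,     0.3494, 13),
    ("JUN+, AR+ -> MAPK3+, TP53-",      0.01,        0.001923077, 0.0325,     0.006435,    0.3444, 17),
    ("MAPK3+, JUN+, AR+ -> TP53-",      0.01,        0.001923077, 0.02888889, 0.00616,     0.3454, 16),
    ("TP53-, AR+ -> MAPK3+, JUN+",      0.01,        0.001923077, 0.0325,     0.0054675,   0.3496, 12),
    ("MAPK3+, TP53-, AR+ -> JUN+",      0.01,        0.001923077, 0.026,      0.005063333, 0.3514, 9),
    ("JUN+, TP53-, AR+ -> MAPK3+",      0.01,        0.001923077, 0.02166667, 0.00514,     0.351, 11),
    ("GRB2 -> STAT3-",                  0.01,        0.002692308, 0.02888889, 0.01145,     0.324, 23),
    ("FYN -> TP53+",                    0.01,        0.003076923, 0.026,      0.01186,     0.3228, 24),
    ("ESR1-, FYN -> TP53+",             0.01,        0.002307692, 0.026,      0.00783,     0.337, 20),
    ("ESR1-, MAPK3 -> STAT3-",          0.01,        0.001923077, 0.02888889, 0.005065,    0.3516, 8),
    ("STAT3-, MAPK3 -> ESR1-",          0.01,        0.001923077, 0.02888889, 0.005155,    0.3511, 10),
]


def sarcoma_rule_table() -> pd.DataFrame:
    """The 24 published rules with metrics, scores and published ranks."""
    return pd.DataFrame(
        SARCOMA_RULES,
        columns=["rule", "confidence", "support", "lift", "avg_wesd",
                 "relative_score", "published_rank"],
    )


# Top-10 rule classification metrics, one row per rule:
# (accuracy %, specificity %, sensitivity %, AUC)
DYNAMIC_TOP10_METRICS = [
    (85.38, 85.38, 83.84, 0.926),
    (84.61, 76.92, 92.30, 0.918),
    (89.23, 89.23, 89.23, 0.967),
    (80.76, 76.92, 76.15, 0.830),
    (92.30, 90.00, 87.69, 0.956),
    (73.84, 85.38, 83.84, 0.771),
    (83.46, 95.38, 71.53, 0.877),
    (84.61, 83.84, 85.38, 0.942),
    (91.92, 82.30, 82.30, 0.956),
    (84.61, 83.84, 85.38, 0.942),
]

APRIORI_TOP10_METRICS = [
    (84.23, 83.84, 87.69, 0.878),
    (83.46, 76.92, 100.00, 0.888),
    (88.46, 76.92, 100.00, 0.888),
    (81.15, 85.38, 76.92, 0.900),
    (76.53, 76.92, 76.15, 0.815),
    (84.23, 79.23, 88.46, 0.915),
    (84.61, 82.30, 86.92, 0.902),
    (78.84, 74.61, 83.07, 0.817),
    (83.07, 77.69, 88.46, 0.826),
    (75.00, 65.38, 87.69, 0.777),
]

ECLAT_TOP10_METRICS = [
    (84.61, 85.38, 83.84, 0.902),
    (80.76, 84.61, 76.92, 0.897),
    (84.61, 85.38, 83.84, 0.903),
    (81.15, 85.38, 76.92, 0.900),
    (76.92, 79.23, 77.69, 0.816),
    (80.77, 84.62, 76.92, 0.897),
    (84.23, 77.69, 90.77, 0.915),
    (84.62, 76.92, 92.30, 0.817),
    (83.46, 76.15, 90.77, 0.826),
    (75.38, 68.46, 82.30, 0.714),
]

METRIC_COLUMNS = ["accuracy_pct", "specificity_pct", "sensitivity_pct", "auc"]


def top10_metric_table(method: str) -> pd.DataFrame:
    """Published per-rule classification metrics for one mining method
    ("dynamic", "apriori" or "eclat")."""
    tables = {
        "dynamic": DYNAMIC_TOP10_METRICS,
        "apriori": APRIORI_TOP10_METRICS,
        "eclat": ECLAT_TOP10_METRICS,
    }
    if method not in tables:
        raise KeyError(f"unknown method {method!r}; expected one of {sorted(tables)}")
    return pd.DataFrame(tables[method], columns=METRIC_COLUMNS)
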