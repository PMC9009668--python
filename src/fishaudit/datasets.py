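"""Published summary tables from a 2018 Mexican seafood market survey.

These are the printed aggregate tables of a three-city DNA-barcoding audit
of fish sold in Mexico (376 samples, 48 commercial names, 116 mislabeled):
the per-name audit table for the 18 commercial names with at least six
samples, and the city × vendor-type sample sizes with mislabeling
percentages.  They serve as desk-scale inputs for reproducing the study's
headline statistics; sample-level data is not included.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .audit import NameAudit

__all__ = [
    "mexico_name_audits",
    "mexico_audit_counts",
    "mexico_city_vendor_counts",
    "STUDY_MISLABELED",
    "STUDY_SAMPLES",
]

#: Study-wide mislabeled / total called samples.
STUDY_MISLABELED = 116
STUDY_SAMPLES = 376

# columns: name, verbal sample number, correctly labeled, mislabeling
# diversity, substitutability frequency, substitutability diversity
_AUDIT_COUNTS = [
    ("atun", 58, 52, 4, 15, 4),
    ("salmon", 39, 37, 2, 3, 2),
    ("cazon", 32, 29, 3, 5, 3),
    ("dorado", 31, 19, 9, 11, 10),
    ("marlin", 18, 1, 5, 0, 0),
    ("tilapia", 18, 16, 1, 6, 6),
    ("mero", 15, 2, 9, 2, 2),
    ("robalo", 15, 7, 8, 3, 3),
    ("mojarra", 15, 9, 3, 1, 1),
    ("huachinango", 13, 6, 7, 1, 1),
    ("basa", 12, 12, 0, 8, 3),
    ("pargo", 11, 7, 4, 2, 1),
    ("sierra", 9, 1, 7, 3, 3),
    ("curvina", 6, 3, 3, 3, 2),
    ("cochito", 6, 4, 2, 3, 2),
    ("lenguado", 6, 4, 2, 0, 0),
    ("peto", 6, 4, 2, 5, 3),
    ("trucha", 6, 4, 2, 0, 0),
]

# city → vendor type → (N, printed %M); percentages are truncated to 1 d.p.
_CITY_VENDOR = {
    "Mazatlan": {"fish_market": (33, 33.3), "grocery_store": (24, 8.3), "restaurant": (63, 38.0)},
    "Mexico City": {"fish_market": (47, 44.6), "grocery_store": (33, 24.2), "restaurant": (70, 31.4)},
    "Cancun": {"fish_market": (27, 25.9), "grocery_store": (21, 14.2), "restaurant": (58, 31.0)},
}


def mexico_audit_counts() -> pd.DataFrame:
    """Primitive per-name counts of the published 18-name audit table."""
    return pd.DataFrame(
        _AUDIT_COUNTS,
        columns=[
            "commercial_name", "verbal_sample_number", "correctly_labeled",
            "mislabeling_diversity", "substitutability_frequency",
            "substitutability_diversity",
        ],
    )


def mexico_name_audits() -> list[NameAudit]:
    """The 18 published audits as :class:`NameAudit` (derived cells recomputed)."""
    return [
        NameAudit.from_counts(name, verbal, correct, misdiv, subfreq, subdiv)
        for name, verbal, correct, misdiv, subfreq, subdiv in _AUDIT_COUNTS
    ]


def mexico_city_vendor_counts() -> pd.DataFrame:
    """City × vendor-type sample sizes with mislabeled counts.

    Mislabeled counts are recovered from the printed (1-d.p.-truncated)
    percentages as ``k = round(N * %M / 100)``; the recovery is exact in the
    sense that it reproduces every printed margin and the study-wide 116/376.
    """
    rows = []
    for city, vendors in _CITY_VENDOR.items():
        for vendor, (n, pct) in vendors.items():
            rows.append(
                {
                    "city": city, "vendor_type": vendor, "n": n,
                    "printed_pct": pct, "mislabeled": int(np.round(n * pct / 100.0)),
                }
            )
    return pd.DataFrame(rows)
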