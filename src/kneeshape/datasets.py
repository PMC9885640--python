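"""Bundled reference values from a published paired CT-MR knee study.

The package ships the published cross-modality agreement table (bias,
limits of agreement, R^2, CCC for ten measures), the published test-retest
smallest detectable differences for the two shape scores, and the study's
per-timepoint acquisition counts.  These are *inputs* for the internal
consistency checks — Bland-Altman limit symmetry, pair counting, the
medial-lateral joint-space bias gap — not values the pipeline estimates.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_reference_agreement",
    "REFERENCE_SDD",
    "REFERENCE_COUNTS",
    "reference_pair_manifest",
]

# published test-retest smallest detectable differences (score units)
REFERENCE_SDD = {"B-score": 0.227, "z-score": 0.373}

# complete CT-MR acquisition pairs available per timepoint in the study
REFERENCE_COUNTS = {"baseline": 231, "24m": 203}


def load_reference_agreement() -> pd.DataFrame:
    """The published agreement table, one row per measure."""
    with resources.files("kneeshape.data").joinpath(
            "reference_agreement.csv").open() as fh:
        return pd.read_csv(fh)


def reference_pair_manifest() -> pd.DataFrame:
    """A per-scan availability manifest matching the published counts.

    One row per (subject, timepoint, knee, modality) with both modalities
    present for every listed timepoint: 231 subjects at baseline and 203
    at 24 months.  Group labels are not part of the published manifest and
    are set to 'ungraded'.
    """
    rows = []
    for tp, n in REFERENCE_COUNTS.items():
        for i in range(n):
            for modality in ("CT", "MR"):
                rows.append({"subject": f"S{i:03d}", "timepoint": tp,
                             "knee": "index", "modality": modality,
                             "group": "ungraded"})
    return pd.DataFrame(rows)
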