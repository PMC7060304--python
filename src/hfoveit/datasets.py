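"""Bundled reference tables.

The package ships one small table: the selected optimal mPaw per subject
from a published ten-pig decremental HFOV trial, one column per titration
strategy. It is the canonical worked example for the cohort-statistics
layer and for checking the quantile convention against its printed
summaries.
"""

from __future__ import annotations

import pandas as pd

# (subject, oxygenation, cov, regions) -- optimal mPaw in cmH2O
_EXAMPLE_COHORT = [
    (1, 18, 15, 18),
    (2, 21, 18, 18),
    (3, 21, 18, 21),
    (4, 24, 21, 18),
    (5, 21, 21, 24),
    (6, 18, 12, 18),
    (7, 21, 21, 21),
    (8, 18, 15, 18),
    (9, 18, 21, 21),
    (10, 21, 21, 24),
]


def example_cohort() -> pd.DataFrame:
    """Ten-subject experimental cohort of selected optimal mPaw (cmH2O).

    Columns: ``subject``, ``oxygenation``, ``cov``, ``regions`` -- the
    pressure each titration strategy picked for each animal.
    """
    return pd.DataFrame(
        _EXAMPLE_COHORT, columns=["subject", "oxygenation", "cov", "regions"]
    )
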