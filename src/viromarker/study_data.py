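"""Reference survey dataset: twelve soil metagenomes from a hydrocarbon-
polluted former military site (four boreholes, three depths each).

These are the published per-sample values the pipeline's thresholds were
standardized on: the library-size normalized percentage of reads mapping to
the marker virus (replicate-averaged over three DNA isolations), the binary
virus-presence call at the 0.01% threshold, and the binary pollution status
at the 125 ppm TPH quantification floor. ENA sample accessions identify the
deposited read sets; raw reads are not shipped with the package.
"""

from __future__ import annotations

import pandas as pd

PRESENCE_THRESHOLD_PCT = 0.01
TPH_THRESHOLD_PPM = 125.0

_ROWS = [
    # sample, accession, percent mapped, presence flag, TPH pollution flag
    ("B1 1.0m", "SAMEA4368876", 0.0, 0, 0),
    ("B1 5.8m", "SAMEA4368878", 0.0, 0, 0),
    ("B1 7.5m", "SAMEA4368881", 8.4, 1, 1),
    ("B2 1.0m", "SAMEA4373315", 0.0, 0, 0),
    ("B2 5.5m", "SAMEA4373317", 0.0, 0, 0),
    ("B2 7.5m", "SAMEA4373321", 0.8, 1, 1),
    ("B3 1.0m", "SAMEA4373324", 0.0, 0, 0),
    ("B3 5.5m", "SAMEA4373325", 0.0, 0, 0),
    ("B3 7.8m", "SAMEA4373328", 0.0, 0, 0),
    ("B4 0.8m", "SAMEA4373332", 0.0, 0, 0),
    ("B4 5.5m", "SAMEA4373334", 0.0, 0, 0),
    ("B4 7.5m", "SAMEA4373336", 0.1, 1, 1),
]


def reference_survey() -> pd.DataFrame:
    """The published survey table as a DataFrame (one row per soil sample)."""
    return pd.DataFrame(
        _ROWS,
        columns=["sample_name", "accession", "percent_mapped", "presence_flag", "tph_flag"],
    )
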