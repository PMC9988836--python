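"""Published count data bundled as package inputs.

Two small tables from the histamine-sensitization (Bphs) literature, keyed
in from the printed tables so the exact-test stages can be exercised on the
real study counts without any download:

* the dose-response screen of *Hrh1*-resistant strains (deaths/tested per
  histamine dose, pooled C3H substrains as the resistant reference),
* the companion H1R-knockout F1 panel, and
* the (AKR x PWK) x AKR BC1 linkage-scan contingency counts per Chr6 marker.

Counts are data, not expected test outputs: every statistic is recomputed
from them at run time.
"""

from __future__ import annotations

import pandas as pd

from .datatypes import DoseResponseTable

__all__ = [
    "hrh1r_screen_dose_response",
    "knockout_f1_dose_response",
    "backcross_marker_counts",
]

# strain -> list of (dose mg/kg, affected, tested); '-' cells in the source
# table are simply absent rows.
_HRH1R_SCREEN = {
    "C3H/HeJ": [(100, 0, 3), (50, 0, 2), (25, 0, 2)],
    "C3H/HeN": [(100, 0, 2), (50, 0, 2), (25, 0, 2)],
    "C3H": [(100, 0, 5), (50, 0, 4), (25, 0, 4)],
    "AKR/J": [(100, 1, 3), (50, 0, 2), (25, 0, 2)],
    "CAST/EiJ": [(100, 1, 3), (50, 0, 3), (25, 0, 3)],
    "CBA/J": [(100, 0, 3), (50, 0, 2), (25, 0, 2)],
    "CBA/N": [(100, 0, 3), (50, 0, 2), (25, 0, 2)],
    "CBA": [(100, 0, 6), (50, 0, 4), (25, 0, 4)],
    "I/LnJ": [(100, 2, 7), (50, 0, 3)],
    "MSM/Ms": [(100, 0, 3), (50, 0, 3)],
    "MRL/MpJ": [(100, 0, 3), (50, 0, 2), (25, 0, 2)],
    "SF/CamEiJ": [(100, 0, 4), (50, 0, 2)],
    "SKIVE/EiJ": [(100, 2, 7), (50, 1, 6), (25, 0, 2)],
    "BPL/1 J": [(100, 1, 2), (50, 2, 2), (25, 2, 2)],
    "CZECHII/EiJ": [(100, 4, 4), (50, 2, 4), (25, 2, 2)],
    "JF1/MsJ": [(100, 2, 3), (50, 2, 3)],
    "MOLD/EiJ": [(100, 2, 2), (50, 1, 2), (25, 2, 2)],
    "MOLF/EiJ": [(100, 2, 2), (50, 5, 5), (25, 5, 5)],
    "PWD/PhJ": [(100, 5, 7)],
    "PWK/PhJ": [(100, 2, 2), (50, 2, 2), (25, 2, 2)],
    "RF/J": [(100, 2, 2), (50, 2, 2), (25, 2, 2)],
}

_KO_F1_PANEL = {
    "H1R KO": [(100, 0, 2), (50, 0, 2), (25, 0, 2), (12.5, 0, 2), (6.25, 0, 2)],
    "C57BL/6J": [(100, 3, 3), (50, 3, 3), (25, 3, 3), (12.5, 2, 2), (6.25, 1, 2)],
    "(B6 x H1R KO) F1": [(100, 4, 4), (50, 4, 4), (25, 4, 4), (12.5, 3, 4), (6.25, 3, 3)],
    "C3H.Bphs-SJL": [(100, 3, 3), (50, 2, 2), (25, 2, 2), (12.5, 2, 2), (6.25, 2, 2)],
    "(Bphs-SJL x H1R KO) F1": [(100, 2, 2), (50, 2, 2), (25, 2, 2), (12.5, 2, 2), (6.25, 2, 2)],
    "C3H/HeJ": [(100, 1, 3), (50, 0, 2), (25, 0, 2), (12.5, 0, 2), (6.25, 0, 2)],
    "(C3H x H1R KO) F1": [(100, 0, 2), (50, 0, 2), (25, 0, 2), (12.5, 0, 2), (6.25, 0, 2)],
    "CBA/J": [(100, 0, 3), (50, 0, 2), (25, 0, 2), (12.5, 0, 2), (6.25, 0, 2)],
    "(CBA x H1R KO) F1": [(100, 0, 2), (50, 0, 3), (25, 0, 2), (12.5, 0, 2), (6.25, 0, 2)],
    "AKR/J": [(100, 1, 3), (50, 0, 2), (25, 0, 2), (12.5, 0, 2), (6.25, 0, 2)],
    "(AKR x H1R KO) F1": [(100, 0, 2), (50, 0, 2), (25, 0, 2), (12.5, 0, 2), (6.25, 0, 2)],
    "MRL/MpJ": [(100, 0, 3), (50, 0, 2), (25, 0, 2), (12.5, 0, 2), (6.25, 0, 2)],
    "(MRL x H1R KO) F1": [(100, 2, 3), (50, 0, 2), (25, 0, 2), (12.5, 0, 2), (6.25, 0, 2)],
    "PWK/PhJ": [(100, 3, 3), (50, 3, 3), (25, 2, 2), (12.5, 1, 2), (6.25, 0, 2)],
    "(PWK x H1R KO) F1": [(100, 3, 3), (50, 2, 2), (25, 2, 2), (12.5, 1, 2), (6.25, 1, 2)],
    "MOLF/MpJ": [(100, 2, 2), (50, 2, 2), (25, 2, 2), (12.5, 2, 2), (6.25, 0, 2)],
    "(MOLF x H1R KO) F1": [(100, 2, 2), (50, 2, 2), (25, 2, 2), (12.5, 2, 2), (6.25, 0, 2)],
}

# Chr6 marker counts from the (AKR x PWK) x AKR BC1 linkage scan:
# affected Ho, affected He, unaffected Ho, unaffected He.
_BC_MARKER_COUNTS = [
    ("rs36385580", 59_353_905, 28, 52, 65, 20),
    ("rs38650989", 72_592_521, 28, 52, 66, 19),
    ("D6Mit186", 73_387_511, 30, 53, 66, 19),
    ("D6Mit102", 93_463_949, 25, 58, 66, 19),
    ("D6Mit65", 101_387_523, 25, 58, 68, 17),
    ("D6Mit149", 106_005_405, 27, 56, 68, 17),
    ("rs31698248", 120_207_163, 26, 56, 69, 16),
    ("D6Mit254", 125_356_646, 26, 56, 66, 19),
    ("rs30853093", 125_365_703, 26, 57, 65, 20),
    ("rs30662734", 125_370_997, 26, 57, 65, 20),
    ("rs36868180", 127_629_804, 27, 56, 65, 20),
    ("D6Mit135", 128_834_894, 27, 56, 63, 22),
]


def _to_table(data: dict) -> DoseResponseTable:
    rows = [
        (strain, dose, affected, tested)
        for strain, entries in data.items()
        for dose, affected, tested in entries
    ]
    return DoseResponseTable(pd.DataFrame(rows, columns=["strain", "dose", "affected", "tested"]))


def hrh1r_screen_dose_response() -> DoseResponseTable:
    """Dose-response counts for the *Hrh1*-resistant strain screen; the
    pooled ``C3H`` rows are the resistant reference."""
    return _to_table(_HRH1R_SCREEN)


def knockout_f1_dose_response() -> DoseResponseTable:
    """Dose-response counts for the H1R-knockout F1 panel; ``H1R KO`` is the
    reference."""
    return _to_table(_KO_F1_PANEL)


def backcross_marker_counts() -> pd.DataFrame:
    """Per-marker 2x2 segregation counts from the Chr6 BC1 linkage scan."""
    return pd.DataFrame(
        _BC_MARKER_COUNTS, columns=["marker_id", "pos", "a_ho", "a_he", "u_ho", "u_he"]
    )
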