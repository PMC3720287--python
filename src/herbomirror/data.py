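"""Reference composition measurements used by the worked examples.

Inositol and choline content (mg per g dry extract) measured in six
field-horsetail (Equisetum arvense) extracts of different geographic
origin, together with the media concentrations (ug/mL) reported for the
standard yeast-exposure dose of 2.5 mg extract per mL. The reported
ug/mL columns follow the two-decimal truncation convention of the
original assay report and serve as a cross-check for the dose
arithmetic in :mod:`herbomirror.assays`.
"""

from __future__ import annotations

import pandas as pd

YEAST_DOSE_MG_PER_ML = 2.5

_ROWS = [
    # sample, inositol mg/g, reported inositol ug/mL, choline mg/g, reported choline ug/mL
    ("USA #2", "219.83", "549.57", "13.22", "33.05"),
    ("USA #6", "27.90", "69.75", "13.71", "34.27"),
    ("USA #7", "10.27", "25.67", "7.69", "19.22"),
    ("CHINA #8", "43.33", "108.32", "13.17", "32.92"),
    ("EUROPE #11", "6.23", "15.57", "9.69", "24.22"),
    ("INDIA #13", "75.70", "189.25", "5.17", "12.92"),
]


def inositol_choline_table() -> pd.DataFrame:
    """Composition table as a DataFrame indexed by sample.

    Columns: ``inositol_mg_g``, ``inositol_ug_ml_reported``,
    ``choline_mg_g``, ``choline_ug_ml_reported``. The mg/g columns are the
    measurements; the ug/mL columns are the reported media concentrations
    at the 2.5 mg/mL dose.
    """
    df = pd.DataFrame(
        _ROWS,
        columns=[
            "sample",
            "inositol_mg_g",
            "inositol_ug_ml_reported",
            "choline_mg_g",
            "choline_ug_ml_reported",
        ],
    ).set_index("sample")
    return df.astype(float)


def inositol_choline_strings() -> list[tuple[str, str, str, str, str]]:
    """The same table with exact decimal strings (for Decimal arithmetic)."""
    return list(_ROWS)
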