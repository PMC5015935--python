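"""Published reference inputs.

The recombination-assay count table below is the published readout of the
11-clone barcode-ORF recombination assay that this package's default switch
rates are calibrated against: for each sublibrary design, barcodes were
PCR-recovered either from cells transduced with pooled-packaged virus
(``recombination_test``, where RT template switching can uncouple pairs) or
from pooled gDNA of individually transduced lines (``pcr_control``, where
any apparent uncoupling would be a PCR artifact), and Sanger-sequenced.

These counts are *inputs*: measured and corrected frequencies are always
recomputed from them.
"""
from __future__ import annotations

import pandas as pd

__all__ = ["RECOMBINATION_ASSAY", "N_CLONES_SUBLIBRARY", "recombination_assay_table"]

#: Clones per assay sublibrary (equimolar).
N_CLONES_SUBLIBRARY = 11

_ROWS = [
    # design, homology_bp, condition, n_analyzed, n_recombined
    ("5BC", 720, "recombination_test", 65, 17),
    ("5BC", 720, "pcr_control", 33, 0),
    ("3BC", 96, "recombination_test", 55, 3),
    ("3BC", 96, "pcr_control", 20, 0),
]


def recombination_assay_table() -> pd.DataFrame:
    """The assay count table as a DataFrame (one row per design x condition)."""
    return pd.DataFrame(
        _ROWS, columns=["design", "homology_bp", "condition", "n_analyzed", "n_recombined"]
    )


RECOMBINATION_ASSAY = recombination_assay_table()
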