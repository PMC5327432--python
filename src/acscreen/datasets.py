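"""Bundled example data.

``load_strain_fpkm_table`` returns published per-gene FPKM values from a
red-scar vs white-scar Kanzawa spider mite (*Tetranychus kanzawai*) strain
comparison — detoxification genes (cytochrome P450, glutathione
S-transferase, carboxylesterase, ABC transporter) and heat-shock/chaperone
genes across four single-replicate libraries (strains R1, R2, W1, W2) —
together with the log2 fold-expression values as printed in the original
report (2-decimal strings; the em-dash marks a White FPKM of exactly 0).
Useful as a worked example of the fold-consensus arithmetic on real
screened genes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_strain_fpkm_table", "FOLD_COLUMNS", "FPKM_COLUMNS"]

FPKM_COLUMNS = ["fpkm_R1", "fpkm_R2", "fpkm_W1", "fpkm_W2"]
FOLD_COLUMNS = ["fold_R1_W1", "fold_R2_W1", "fold_R1_W2", "fold_R2_W2"]

#: (numerator sample, denominator sample) for each printed fold column.
FOLD_PAIRS = {
    "fold_R1_W1": ("fpkm_R1", "fpkm_W1"),
    "fold_R2_W1": ("fpkm_R2", "fpkm_W1"),
    "fold_R1_W2": ("fpkm_R1", "fpkm_W2"),
    "fold_R2_W2": ("fpkm_R2", "fpkm_W2"),
}


def load_strain_fpkm_table() -> pd.DataFrame:
    """The bundled strain-comparison FPKM table as a DataFrame.

    FPKM columns are floats (as printed, i.e. rounded to 2 decimals);
    fold columns stay strings because of the em-dash sentinel.
    """
    ref = resources.files("acscreen.data").joinpath("mite_strain_fpkm.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    for col in FPKM_COLUMNS:
        df[col] = df[col].astype(float)
    return df
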