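"""Bundled reference tables."""

from importlib import resources

import pandas as pd


def de_reference() -> pd.DataFrame:
    """Curated two-decimal log2 ratios (with published direction calls) of
    conserved soybean miRNAs across the four seed small-RNA libraries
    (MON89788, A3244, DP-3O5423xGTS 40-3-2, Jack), for the three comparisons
    MON/A32, DP3/JAC and A32/JAC.  Rows qualify at >100 raw reads and
    P < 0.001; the calls therefore depend only on the |log2| >= 1 gate.
    """
    with resources.files(__package__).joinpath("de_reference.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
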