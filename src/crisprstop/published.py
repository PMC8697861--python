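"""Packaged reference table of published PERV CRISPR-STOP guide designs.

The table lists the 26 Target-AID guides designed against the gag, pol and
env genes of the three PERV subtypes: the 23-mer protospacer+PAM, the printed
editing window, the CDS position, the stop-route label and the per-subtype
presence calls. It is used to validate the editing-window geometry and as the
worked example in the analysis drivers.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

SUBTYPE_COLUMNS = ["perv_a", "perv_b", "perv_c"]


def load_perv_guides() -> pd.DataFrame:
    """The published PERV stop-guide table as a DataFrame (26 rows)."""
    path = files("crisprstop.data").joinpath("perv_stop_guides.tsv")
    with path.open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype=str)
    df["position"] = df["position"].astype(int)
    return df
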