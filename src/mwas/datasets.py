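"""Bundled worked-example data."""

from importlib import resources

import pandas as pd

__all__ = ["load_published_rows"]


def load_published_rows() -> pd.DataFrame:
    """Published blood and brain methylome-wide scan rows.

    Per-probe top-mQTL records (effect allele, frequencies, p-values and
    the SMR effect/SE/p triple with HEIDI results) from published
    Alzheimer's disease scans, used as inputs for worked examples and
    internal-consistency checks.  mQTL p-values printed as 0 are stored
    as 1e-300.
    """
    with resources.files("mwas.data").joinpath("published_mwas_rows.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
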