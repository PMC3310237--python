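"""Packaged reference tables.

Published census tables for the tomato MULE TIR families: the
per-family copy/TSD/autonomy counts (59 families), the multi-TIR
element counts per architecture type, and the PM-ZIBP Pack-MULE
catalog (the family carrying a zinc-ion-binding-protein gene
fragment).  These serve as reference inputs for the report arithmetic
and as the shape templates for the pipeline's own TSV outputs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def tomato_family_census() -> pd.DataFrame:
    """Per-family copy number, TSD and autonomy counts and percentages.

    Includes the printed Total row (family == 'Total'); note its
    percentage columns are whole percents while per-family rows carry
    one decimal.
    """
    return _read("tomato_tir_family_census.tsv")


def tomato_multitir_census() -> pd.DataFrame:
    """Copies of multi-TIR elements per architecture type and TIR family."""
    return _read("tomato_multitir_census.tsv")


def pm_zibp_catalog() -> pd.DataFrame:
    """PM-ZIBP Pack-MULE catalog: 1-based inclusive coordinates, size,
    TSD sequence, and outer/inner TIR identities."""
    return _read("pm_zibp_catalog.tsv")
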