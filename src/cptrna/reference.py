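"""Loaders for the packaged published reference tables.

These tables carry literature-reported values for gymnosperm chloroplast
tRNAs — per-tRNA folding free energies by structural class, region-length
counts over the 1779-gene survey, and per-isotype transition/transversion
pattern entries.  They serve as worked-example inputs: the package's own
aggregation routines recompute the published summary statistics from them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cloverleaf import StructuralType
from .thermo import MFERecord

__all__ = [
    "load_reference_mfe",
    "load_reference_mfe_records",
    "load_reference_region_counts",
    "load_reference_substitution_rates",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("cptrna.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_reference_mfe() -> pd.DataFrame:
    """Per-tRNA published delta G values with structural class labels."""
    return _read("reference_mfe.tsv")


def load_reference_mfe_records() -> list[MFERecord]:
    df = load_reference_mfe()
    return [
        MFERecord(
            gene_id=f"{r.species}/{r.isotype}-{r.anticodon}",
            structural_type=StructuralType(r.structural_type),
            delta_g=float(r.delta_g),
            engine="published",
        )
        for r in df.itertuples()
    ]


def load_reference_region_counts() -> pd.DataFrame:
    """Published region-length counts (region, length, count)."""
    return _read("reference_region_counts.tsv")


def load_reference_substitution_rates() -> pd.DataFrame:
    """Published per-isotype (ts, tv) pattern entries on the x100 scale."""
    return _read("reference_substitution_rates.tsv")
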