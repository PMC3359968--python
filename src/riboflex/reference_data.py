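"""Bundled reference tables: published values used as *inputs* to worked examples.

Two small TSV tables ship with the package:

* ``s15_contact_residues_2avy.tsv`` -- the 27 rRNA-contacting residues of
  *E. coli* S15 in the 2AVY 30S structure (residue name and number), used
  by the side-chain class census worked example.
* ``anm_ef_reference.tsv`` -- published per-protein ANM enrichment factors
  and permutation p-values for the 19 small-subunit ribosomal proteins of
  *T. thermophilus* and *E. coli* (p-values below the permutation floor
  appear as ``<0.001``), used by the report module's aggregation checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_s15_contact_residues",
    "load_anm_ef_reference",
    "aggregate_ef_column",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("riboflex.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_s15_contact_residues() -> pd.DataFrame:
    """The 27 E. coli S15 contact residues (columns: residue_name, residue_seq)."""
    return _read("s15_contact_residues_2avy.tsv")


def load_anm_ef_reference() -> pd.DataFrame:
    """Published ANM enrichment factors/p-values per 30S protein and species."""
    return _read("anm_ef_reference.tsv")


def aggregate_ef_column(values) -> dict[str, float]:
    """Mean and median of an EF column, rounded to the table's two decimals."""
    s = pd.Series(list(values), dtype=float)
    return {"mean": round(float(s.mean()), 2), "median": round(float(s.median()), 2)}
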