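"""Bundled reference tables.

Three small published tables ship with the package: the survey of the 41
public *L. delbrueckii* assemblies (organism, strain, size, GC%, CDS count,
accession), the three subspecies-specific qPCR primer pairs, and the label
claims of 26 monitored probiotic/dairy products with the subspecies detected
in each.  They serve as desk-scale inputs for summary statistics, primer
evaluation and label-compliance reporting.
"""

from __future__ import annotations

import io
from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    text = resources.files("pangmark").joinpath(f"data/{name}").read_text()
    return pd.read_csv(io.StringIO(text), sep="\t")


def load_assembly_survey() -> pd.DataFrame:
    """The 41-assembly survey: one row per deposited genome."""
    return _read("ldelbrueckii_assemblies.tsv")


def load_published_primers() -> pd.DataFrame:
    """The three published subspecies primer pairs (name, forward, reverse, size)."""
    return _read("published_primers.tsv")


def load_product_claims() -> pd.DataFrame:
    """Monitored products: label claim text and detected subspecies (26 rows)."""
    return _read("product_claims.tsv")
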