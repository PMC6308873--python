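"""Bundled reference data for the Martinique green-turtle study system.

Three small published tables ship with the package:

* the Atlantic rookery × mtDNA-haplotype count table with the Martinique
  feeding-ground (``MT``) mixture row and 15 nesting-site source rows;
* the grouping of those rookeries into four Atlantic regions;
* per-individual movement summaries for the ten juveniles that migrated
  away from Martinique (locations, duration, path length, speed, body size).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .haplotypes import HaplotypeCountTable, read_count_table

__all__ = [
    "load_reference_counts",
    "load_region_map",
    "load_migrant_summaries",
    "data_path",
]


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(resources.files("mixedstock.data") / name)


def load_region_map() -> dict[str, str]:
    """Rookery → Atlantic-region labels (four regions, 15 rookeries)."""
    df = pd.read_csv(data_path("atlantic_regions.csv"))
    return dict(zip(df["population"], df["region"]))


def load_reference_counts(with_regions: bool = True) -> HaplotypeCountTable:
    """The bundled Atlantic haplotype count table, mixture ``MT``."""
    return read_count_table(
        data_path("atlantic_rookery_haplotypes.csv"),
        mixture_id="MT",
        region_map=load_region_map() if with_regions else None,
    )


def load_migrant_summaries() -> pd.DataFrame:
    """Published per-turtle movement summaries of the ten migrants."""
    return pd.read_csv(
        data_path("martinique_migrant_summaries.csv"), dtype={"track_id": str}
    )
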