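"""Haplotype count tables and pre-analysis exclusion rules.

A mixed-stock dataset is a populations × haplotypes matrix of non-negative
integer counts in which exactly one row is the *mixture* (the feeding-ground
aggregation) and every other row is a *source* (a nesting rookery).  Before
diversity statistics or mixed stock analysis are computed, haplotypes that
carry no information about source contributions are removed:

1. **orphans** — haplotypes seen in the mixture but in no source; they cannot
   be traced back to any rookery;
2. **source-only** haplotypes — seen at rookeries but absent from the
   mixture, hence uninformative about it;
3. optionally, **shared singletons** — haplotypes with exactly one copy in
   the mixture and exactly one copy summed across all sources, too rare to
   anchor an assignment;
4. an explicit manual exclusion list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeCountTable",
    "ExclusionReport",
    "read_count_table",
    "write_count_table",
    "apply_exclusion_rules",
]


@dataclass
class HaplotypeCountTable:
    """Populations × haplotypes integer count matrix with one mixture row.

    Parameters
    ----------
    population_ids : list of str
        Row labels; must be unique.
    haplotype_ids : list of str
        Column labels; must be unique.
    counts : (P, H) ndarray of int
        Non-negative haplotype counts.
    mixture_id : str
        The single population that is the mixed stock; all others are
        sources.
    region_map : dict, optional
        population_id → region label for the source populations.  When
        present it must cover every source.
    """

    population_ids: list[str]
    haplotype_ids: list[str]
    counts: np.ndarray
    mixture_id: str
    region_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.population_ids), len(self.haplotype_ids)):
            raise ValueError("counts shape does not match labels")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.population_ids)) != len(self.population_ids):
            raise ValueError("duplicate population labels")
        if len(set(self.haplotype_ids)) != len(self.haplotype_ids):
            raise ValueError("duplicate haplotype labels")
        if self.mixture_id not in self.population_ids:
            raise ValueError(f"unknown mixture_id {self.mixture_id!r}")
        if len(self.population_ids) < 2:
            raise ValueError("need at least one source population besides the mixture")
        # Source rows must be non-empty; the mixture row may be (prior-only MSA).
        for pid, row in zip(self.population_ids, self.counts):
            if pid != self.mixture_id and row.sum() == 0:
                raise ValueError(f"source population {pid!r} has zero total count")
        if self.region_map is not None:
            missing = [s for s in self.source_ids if s not in self.region_map]
            if missing:
                raise ValueError(f"region_map does not cover sources: {missing}")

    # -- convenience accessors -------------------------------------------

    @property
    def source_ids(self) -> list[str]:
        return [p for p in self.population_ids if p != self.mixture_id]

    @property
    def mixture_counts(self) -> np.ndarray:
        return self.counts[self.population_ids.index(self.mixture_id)]

    @property
    def source_counts(self) -> np.ndarray:
        """(S, H) counts of the source rows, in table order."""
        idx = [i for i, p in enumerate(self.population_ids) if p != self.mixture_id]
        return self.counts[idx]

    def row(self, population_id: str) -> np.ndarray:
        return self.counts[self.population_ids.index(population_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.population_ids, columns=self.haplotype_ids
        )


@dataclass
class ExclusionReport:
    """Which haplotypes each exclusion rule removed, and what remains."""

    excluded_orphans: list[str] = field(default_factory=list)
    excluded_unsampled: list[str] = field(default_factory=list)
    excluded_singletons: list[str] = field(default_factory=list)
    excluded_manual: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    @property
    def all_excluded(self) -> set[str]:
        return (
            set(self.excluded_orphans)
            | set(self.excluded_unsampled)
            | set(self.excluded_singletons)
            | set(self.excluded_manual)
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ExclusionReport":
        return cls(**json.loads(Path(path).read_text()))


def read_count_table(
    path: str | Path,
    mixture_id: str,
    region_map: dict[str, str] | None = None,
) -> HaplotypeCountTable:
    """Read a haplotype count CSV (first column ``population``, one column
    per haplotype) into a validated :class:`HaplotypeCountTable`.

    Raises ``ValueError`` on missing, negative or non-integer cells, on
    duplicate labels, and on an unknown ``mixture_id``.
    """
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("count table needs a population column plus haplotype columns")
    pops = df.iloc[:, 0].tolist()
    haps = [str(c) for c in df.columns[1:]]
    body = df.iloc[:, 1:]
    if body.isna().any().any():
        raise ValueError("count table has missing cells")
    values = body.to_numpy()
    if not np.all(values == np.floor(values.astype(float))):
        raise ValueError("counts must be integers")
    return HaplotypeCountTable(
        population_ids=pops,
        haplotype_ids=haps,
        counts=values.astype(np.int64),
        mixture_id=mixture_id,
        region_map=region_map,
    )


def write_count_table(table: HaplotypeCountTable, path: str | Path) -> None:
    """Write the CSV dialect read back by :func:`read_count_table`."""
    df = table.to_frame().reset_index(names="population")
    df.to_csv(path, index=False)


def apply_exclusion_rules(
    table: HaplotypeCountTable,
    manual: set[str] | None = None,
    singleton_rule: bool = True,
) -> tuple[HaplotypeCountTable, ExclusionReport]:
    """Apply the pre-analysis haplotype exclusion rules, in order.

    Rules (applied to the original table, in this order, each considering
    only haplotypes not yet excluded):

    1. orphans: count > 0 in the mixture, 0 in every source;
    2. source-only: count 0 in the mixture;
    3. shared singletons (if ``singleton_rule``): exactly one copy in the
       mixture and exactly one copy summed across all sources;
    4. ``manual`` labels.

    Returns the reduced table (original column order preserved, populations
    unchanged) and an :class:`ExclusionReport`.
    """
    manual = set(manual or ())
    unknown = manual - set(table.haplotype_ids)
    if unknown:
        raise ValueError(f"manual exclusion labels not in table: {sorted(unknown)}")

    mix = table.mixture_counts
    src_total = table.source_counts.sum(axis=0)

    report = ExclusionReport()
    excluded: set[str] = set()
    for j, hap in enumerate(table.haplotype_ids):
        if mix[j] > 0 and src_total[j] == 0:
            report.excluded_orphans.append(hap)
            excluded.add(hap)
    for j, hap in enumerate(table.haplotype_ids):
        if hap not in excluded and mix[j] == 0:
            report.excluded_unsampled.append(hap)
            excluded.add(hap)
    if singleton_rule:
        for j, hap in enumerate(table.haplotype_ids):
            if hap not in excluded and mix[j] == 1 and src_total[j] == 1:
                report.excluded_singletons.append(hap)
                excluded.add(hap)
    for hap in table.haplotype_ids:
        if hap in manual and hap not in excluded:
            report.excluded_manual.append(hap)
            excluded.add(hap)

    keep = [j for j, hap in enumerate(table.haplotype_ids) if hap not in excluded]
    report.retained = [table.haplotype_ids[j] for j in keep]
    if not report.retained or table.mixture_counts[keep].sum() == 0:
        raise ValueError("exclusion rules left the mixture row empty")

    reduced = HaplotypeCountTable(
        population_ids=list(table.population_ids),
        haplotype_ids=report.retained,
        counts=table.counts[:, keep].copy(),
        mixture_id=table.mixture_id,
        region_map=dict(table.region_map) if table.region_map else None,
    )
    return reduced, report
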