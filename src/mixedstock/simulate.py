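"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a pure function of (parameters, seed) using numpy's
PCG64 ``default_rng``; draws are consumed in the documented order so runs
are bit-reproducible.  Alongside its data, every generator returns a
:class:`SyntheticTruth` carrying the generating parameters (true mixing
proportions, true haplotype frequencies, planted outlier labels), so that
recovery tests assert against recorded truth rather than re-deriving it.

What the generators emulate:

* ``simulate_rookeries`` — rookery haplotype count tables with the skew
  typical of mtDNA control-region data (one to three common haplotypes,
  several rare private ones) via low-concentration Dirichlet frequencies;
* ``simulate_mixture`` — a feeding-ground sample drawn from known rookery
  contributions θ and the rookeries' *true* frequencies;
* ``simulate_sequences`` — aligned haplotype sequences as an ancestral
  sequence plus per-haplotype substitutions at distinct sites;
* ``simulate_track`` — an Argos/GPS-like correlated random walk at a 15-min
  cadence with planted on-land points, speed-outlier jumps, and class-Z
  labels at stated rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeCountTable
from .popgen import SequenceSet
from .tracks import EARTH_RADIUS_KM, LandMask, Track, TrackPoint

__all__ = [
    "SyntheticTruth",
    "TABLE1_SOURCE_SIZES",
    "simulate_rookeries",
    "simulate_mixture",
    "simulate_sequences",
    "make_coastal_mask",
    "simulate_track",
    "paper_scale_scenario",
]

# Source-sample sizes matching the bundled Atlantic reference table's rows
# (AV..ST), so the default synthetic MSA scenario has the same scale.
TABLE1_SOURCE_SIZES = (30, 36, 32, 22, 22, 19, 23, 13, 127, 43, 86, 70, 214, 45, 14)

MIXTURE_ID = "MIX"


@dataclass
class SyntheticTruth:
    """Generating parameters recorded for recovery tests."""

    seed: int
    true_theta: np.ndarray | None = None  # simplex over sources
    true_freqs: np.ndarray | None = None  # (S, H)
    outlier_labels: dict[str, list[int]] = field(default_factory=dict)
    ancestral_sequence: str | None = None
    mutation_positions: dict[str, list[int]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "true_theta": None
            if self.true_theta is None
            else list(map(float, self.true_theta)),
            "true_freqs": None
            if self.true_freqs is None
            else np.asarray(self.true_freqs).tolist(),
            "outlier_labels": self.outlier_labels,
            "ancestral_sequence": self.ancestral_sequence,
            "mutation_positions": self.mutation_positions,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            seed=d["seed"],
            true_theta=None if d["true_theta"] is None else np.array(d["true_theta"]),
            true_freqs=None if d["true_freqs"] is None else np.array(d["true_freqs"]),
            outlier_labels={k: list(v) for k, v in d["outlier_labels"].items()},
            ancestral_sequence=d["ancestral_sequence"],
            mutation_positions={k: list(v) for k, v in d["mutation_positions"].items()},
        )


# ---------------------------------------------------------------------------
# genetics generators
# ---------------------------------------------------------------------------

def simulate_rookeries(
    n_sources: int,
    n_haplotypes: int,
    n_per_source=None,
    concentration: float = 0.3,
    seed: int = 0,
) -> tuple[HaplotypeCountTable, SyntheticTruth]:
    """Rookery count table with Dirichlet-multinomial structure.

    Per source s, frequencies q_s ~ Dirichlet(concentration, …) then counts
    ~ Multinomial(n_per_source[s], q_s).  The default concentration 0.3
    yields the strong skew of real control-region tables.  The returned
    table includes an all-zero mixture row (``MIX``) that
    :func:`simulate_mixture` fills in.  Draw order: per source, first the
    Dirichlet (one ``rng.dirichlet``), then the multinomial.
    """
    if n_sources < 1 or n_haplotypes < 2:
        raise ValueError("need n_sources >= 1 and n_haplotypes >= 2")
    if n_per_source is None:
        n_per_source = [50] * n_sources
    elif np.isscalar(n_per_source):
        n_per_source = [int(n_per_source)] * n_sources
    if len(n_per_source) != n_sources:
        raise ValueError("n_per_source length must equal n_sources")
    if min(n_per_source) < 1:
        raise ValueError("each source needs at least one individual")

    rng = np.random.default_rng(seed)
    freqs = np.empty((n_sources, n_haplotypes))
    counts = np.empty((n_sources, n_haplotypes), dtype=np.int64)
    for s in range(n_sources):
        freqs[s] = rng.dirichlet(np.full(n_haplotypes, concentration))
        counts[s] = rng.multinomial(n_per_source[s], freqs[s])

    pops = [MIXTURE_ID] + [f"R{s + 1:02d}" for s in range(n_sources)]
    haps = [f"H{h + 1:02d}" for h in range(n_haplotypes)]
    table = HaplotypeCountTable(
        population_ids=pops,
        haplotype_ids=haps,
        counts=np.vstack([np.zeros(n_haplotypes, dtype=np.int64), counts]),
        mixture_id=MIXTURE_ID,
    )
    return table, SyntheticTruth(seed=seed, true_freqs=freqs)


def simulate_mixture(
    table: HaplotypeCountTable,
    truth: SyntheticTruth,
    true_theta,
    n_mix: int,
    seed: int = 0,
) -> tuple[HaplotypeCountTable, SyntheticTruth]:
    """Fill the mixture row by sampling individuals from known origins.

    Each of the ``n_mix`` individuals draws a source from ``true_theta``
    and then a haplotype from that source's TRUE frequency vector (recorded
    in ``truth``, not the observed counts).  Draw order: one multinomial
    over sources, then one multinomial per source over haplotypes.
    """
    if n_mix < 1:
        raise ValueError("n_mix must be at least 1")
    theta = np.asarray(true_theta, dtype=float)
    S = len(table.source_ids)
    if theta.shape != (S,) or not np.isclose(theta.sum(), 1.0) or np.any(theta < 0):
        raise ValueError("true_theta must be a simplex over the table's sources")
    if truth.true_freqs is None or truth.true_freqs.shape[0] != S:
        raise ValueError("truth lacks true source frequencies for this table")

    rng = np.random.default_rng(seed)
    per_source = rng.multinomial(n_mix, theta)
    mix = np.zeros(len(table.haplotype_ids), dtype=np.int64)
    for s in range(S):
        if per_source[s]:
            mix += rng.multinomial(per_source[s], truth.true_freqs[s])

    counts = table.counts.copy()
    counts[table.population_ids.index(table.mixture_id)] = mix
    out = HaplotypeCountTable(
        population_ids=list(table.population_ids),
        haplotype_ids=list(table.haplotype_ids),
        counts=counts,
        mixture_id=table.mixture_id,
        region_map=dict(table.region_map) if table.region_map else None,
    )
    new_truth = SyntheticTruth(
        seed=seed, true_theta=theta, true_freqs=truth.true_freqs
    )
    return out, new_truth


def simulate_sequences(
    n_haplotypes: int,
    length: int,
    n_mutations_range: tuple[int, int] = (1, 8),
    seed: int = 0,
    haplotype_ids=None,
) -> tuple[SequenceSet, SyntheticTruth]:
    """Aligned haplotype sequences from one ancestor plus substitutions.

    Each haplotype differs from the random ancestral sequence at k sites,
    k drawn uniformly from ``n_mutations_range`` (inclusive), placed at
    distinct positions with a random different base; so the haplotype-to-
    ancestor p-distance is exactly k/length.  Truth records the ancestor
    and every mutated position.
    """
    if length < 10:
        raise ValueError("alignment length must be at least 10")
    lo, hi = n_mutations_range
    if lo < 0 or hi < lo:
        raise ValueError("invalid n_mutations_range")
    if hi > length:
        raise ValueError("more mutations than sites")
    if haplotype_ids is None:
        haplotype_ids = [f"H{h + 1:02d}" for h in range(n_haplotypes)]
    if len(haplotype_ids) != n_haplotypes:
        raise ValueError("haplotype_ids length mismatch")

    bases = np.array(list("ACGT"))
    rng = np.random.default_rng(seed)
    ancestor = "".join(rng.choice(bases, size=length))
    seqs: dict[str, str] = {}
    positions: dict[str, list[int]] = {}
    for hap in haplotype_ids:
        k = int(rng.integers(lo, hi + 1))
        sites = rng.choice(length, size=k, replace=False)
        seq = list(ancestor)
        for site in sites:
            alternatives = [b for b in "ACGT" if b != seq[site]]
            seq[site] = alternatives[rng.integers(3)]
        seqs[hap] = "".join(seq)
        positions[hap] = sorted(int(s) for s in sites)

    truth = SyntheticTruth(
        seed=seed, ancestral_sequence=ancestor, mutation_positions=positions
    )
    return SequenceSet(seqs), truth


# ---------------------------------------------------------------------------
# telemetry generators
# ---------------------------------------------------------------------------

def make_coastal_mask(
    lon_min: float = -70.0,
    lon_max: float = -46.0,
    lat_min: float = 8.0,
    lat_max: float = 20.0,
    cell_size: float = 0.1,
    coast_lon: float = -48.0,
) -> LandMask:
    """Rectangular ocean with a land strip east of ``coast_lon`` —
    a deliberately simple synthetic coastline for filter tests."""
    ncols = int(round((lon_max - lon_min) / cell_size))
    nrows = int(round((lat_max - lat_min) / cell_size))
    grid = np.zeros((nrows, ncols), dtype=bool)
    first_land_col = int(np.ceil((coast_lon - lon_min) / cell_size))
    grid[:, first_land_col:] = True
    return LandMask(grid=grid, xll=lon_min, yll=lat_min, cell_size=cell_size)


def simulate_track(
    n_points: int = 500,
    start: tuple[float, float] = (-61.0, 14.5),
    base_speed_kmh: float = 5.0,
    interval_min: float = 15.0,
    outlier_rate: float = 0.08,
    land_rate: float = 0.51,
    classZ_rate: float = 0.001,
    mask: LandMask | None = None,
    vmax_kmh: float = 10.0,
    track_id: str = "SIM1",
    seed: int = 0,
    start_time: str = "2015-06-01T00:00:00Z",
) -> tuple[Track, SyntheticTruth]:
    """Correlated random walk with planted filter targets.

    The clean path moves at ``base_speed_kmh`` with small heading noise at a
    fixed cadence.  Disjoint point sets (never the first point) are then
    corrupted: *speed outliers* are displaced by twenty ``vmax``-intervals
    (a ~50 km teleport at the defaults, the signature of a bad Argos fix)
    so the jump from any nearby retained point — even across a run of a
    dozen removed land points — still exceeds ``vmax``; *land points*
    are teleported to random land-cell centers of ``mask``; *class-Z points*
    keep their position but get location class Z.  Truth lists the planted
    indices under ``outlier_labels`` keys ``"land"``, ``"speed"``, ``"classZ"``.

    Default rates mirror the error budget reported for shore-proximate
    Argos tracking (51% on land, 8% speed outliers, 0.1% class Z).
    """
    for name, r in (("outlier_rate", outlier_rate), ("land_rate", land_rate),
                    ("classZ_rate", classZ_rate)):
        if not (0.0 <= r < 1.0):
            raise ValueError(f"{name} must be in [0, 1)")
    if land_rate > 0 and (mask is None or not mask.grid.any()):
        raise ValueError("land_rate > 0 requires a mask containing land cells")
    if n_points < 2:
        raise ValueError("need at least 2 points")

    rng = np.random.default_rng(seed)
    dt_h = interval_min / 60.0
    step_km = base_speed_kmh * dt_h
    deg_per_km_lat = 360.0 / (2.0 * np.pi * EARTH_RADIUS_KM)

    # 1) clean correlated random walk (heading draws first)
    lon = np.empty(n_points)
    lat = np.empty(n_points)
    lon[0], lat[0] = start
    heading = rng.uniform(0.0, 2.0 * np.pi)
    for i in range(1, n_points):
        heading += rng.normal(0.0, 0.4)
        dlat = step_km * np.cos(heading) * deg_per_km_lat
        dlon = (
            step_km * np.sin(heading) * deg_per_km_lat
            / max(np.cos(np.radians(lat[i - 1])), 1e-6)
        )
        lon[i] = lon[i - 1] + dlon
        lat[i] = lat[i - 1] + dlat

    # 2) choose disjoint corruption index sets (draw order: land, speed, Z)
    n_land = int(round(land_rate * n_points))
    n_speed = int(round(outlier_rate * n_points))
    n_z = int(round(classZ_rate * n_points))
    candidates = rng.permutation(np.arange(1, n_points))
    land_idx = sorted(int(i) for i in candidates[:n_land])
    speed_idx = sorted(int(i) for i in candidates[n_land:n_land + n_speed])
    z_idx = sorted(int(i) for i in candidates[n_land + n_speed:n_land + n_speed + n_z])

    # 3) apply corruptions
    if n_land:
        land_cells = np.argwhere(mask.grid)
        pick = land_cells[rng.integers(len(land_cells), size=n_land)]
        for k, i in enumerate(land_idx):
            lon[i], lat[i] = mask.cell_center(pick[k][0], pick[k][1])
    jump_km = 20.0 * vmax_kmh * dt_h
    for i in speed_idx:
        ang = rng.uniform(0.0, 2.0 * np.pi)
        lon[i] += jump_km * np.sin(ang) * deg_per_km_lat / max(
            np.cos(np.radians(lat[i])), 1e-6
        )
        lat[i] += jump_km * np.cos(ang) * deg_per_km_lat

    classes = np.array(["G"] * n_points, dtype=object)
    classes[z_idx] = "Z"

    t0 = pd.Timestamp(start_time)
    points = [
        TrackPoint(
            track_id=track_id,
            timestamp=t0 + pd.Timedelta(minutes=interval_min * i),
            lon=float(lon[i]),
            lat=float(lat[i]),
            loc_class=str(classes[i]),
            source="GPS",
        )
        for i in range(n_points)
    ]
    truth = SyntheticTruth(
        seed=seed,
        outlier_labels={"land": land_idx, "speed": speed_idx, "classZ": z_idx},
    )
    return Track(track_id, points), truth


# ---------------------------------------------------------------------------
# canonical scenario
# ---------------------------------------------------------------------------

def paper_scale_scenario(
    seed: int = 0,
    true_theta=None,
) -> tuple[HaplotypeCountTable, SyntheticTruth]:
    """Synthetic MSA scenario sized like the Atlantic reference dataset:
    15 sources with its row totals, 10 haplotypes, mixture of 40.

    ``true_theta`` defaults to a contribution vector concentrated on the
    first few sources (0.3, 0.2, 0.15, then the rest uniform)."""
    S = len(TABLE1_SOURCE_SIZES)
    if true_theta is None:
        rest = (1.0 - 0.65) / (S - 3)
        true_theta = np.array([0.3, 0.2, 0.15] + [rest] * (S - 3))
    table, truth = simulate_rookeries(
        n_sources=S,
        n_haplotypes=10,
        n_per_source=list(TABLE1_SOURCE_SIZES),
        concentration=0.3,
        seed=seed,
    )
    return simulate_mixture(table, truth, true_theta, n_mix=40, seed=seed + 1)
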