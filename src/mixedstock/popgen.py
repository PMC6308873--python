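"""Population-genetic summary statistics on haplotype frequency data.

Implements the within-population diversity estimators (Nei's unbiased gene
diversity Hs with its sampling variance, and nucleotide diversity π from an
aligned haplotype set), the Tamura–Nei (TN93) corrected distance between
aligned sequences, a two-population AMOVA fixation index ΦST with a
pluggable haplotype distance matrix, and a permutation test of
differentiation that shuffles individuals between the two populations.

All estimators operate on haplotype *count vectors* plus, where molecular
information is needed, a :class:`SequenceSet` mapping haplotype labels to
aligned control-region sequences.  Gaps (``-``) and ambiguous bases (``N``)
are handled by pairwise deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .haplotypes import HaplotypeCountTable

__all__ = [
    "SequenceSet",
    "DiversityResult",
    "PairwiseStructure",
    "SaturatedDistanceError",
    "gene_diversity",
    "nucleotide_diversity",
    "p_distance",
    "tamura_nei_distance",
    "distance_matrix",
    "pairwise_phi_st",
    "permutation_test",
]

_VALID = set("ACGT")


class SaturatedDistanceError(ValueError):
    """TN93 correction undefined: a logarithm argument is non-positive."""


@dataclass
class SequenceSet:
    """Aligned haplotype sequences over the alphabet {A, C, G, T, -, N}."""

    sequences: dict[str, str]
    alignment_length: int = 0

    def __post_init__(self) -> None:
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("sequences are not aligned to equal length")
        if lengths:
            L = lengths.pop()
            if self.alignment_length and self.alignment_length != L:
                raise ValueError("alignment_length disagrees with sequences")
            self.alignment_length = L
        bad = {
            c for s in self.sequences.values() for c in s if c not in "ACGT-N"
        }
        if bad:
            raise ValueError(f"invalid characters in alignment: {sorted(bad)}")

    def __getitem__(self, haplotype_id: str) -> str:
        return self.sequences[haplotype_id]

    def __contains__(self, haplotype_id: str) -> bool:
        return haplotype_id in self.sequences

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SequenceSet":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not seqs:
            raise ValueError(f"no sequences in {path}")
        return cls(seqs)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(s), id=h, description="") for h, s in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass
class DiversityResult:
    population_id: str
    n: int
    hs: float
    hs_sd: float
    pi: float | None = None
    pi_sd: float | None = None


@dataclass
class PairwiseStructure:
    pop_a: str
    pop_b: str
    phi_st: float
    p_value: float | None = None
    n_permutations: int = 0


# ---------------------------------------------------------------------------
# diversity estimators
# ---------------------------------------------------------------------------

def gene_diversity(counts: Sequence[int]) -> tuple[float, float]:
    """Nei's unbiased gene diversity and the SD of its sampling variance.

    Hs = n/(n-1) · (1 − Σ pᵢ²), with variance

        V(Hs) = 2/(n(n−1)) · {2(n−2)[Σpᵢ³ − (Σpᵢ²)²] + Σpᵢ² − (Σpᵢ²)²}.

    ``counts`` is the haplotype count vector of one population; n = Σcounts
    must be at least 2.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0) or not np.all(c == np.floor(c)):
        raise ValueError("counts must be non-negative integers")
    n = c.sum()
    if n < 2:
        raise ValueError("gene diversity needs a sample of at least 2")
    p = c / n
    s2 = float((p**2).sum())
    s3 = float((p**3).sum())
    hs = n / (n - 1.0) * (1.0 - s2)
    var = 2.0 / (n * (n - 1.0)) * (2.0 * (n - 2.0) * (s3 - s2**2) + s2 - s2**2)
    return hs, math.sqrt(max(var, 0.0))


def _comparable(a: str, b: str) -> tuple[str, str]:
    """Pairwise deletion: keep sites where both bases are unambiguous."""
    pairs = [(x, y) for x, y in zip(a, b) if x in _VALID and y in _VALID]
    if not pairs:
        raise ValueError("no comparable sites between sequences")
    return "".join(x for x, _ in pairs), "".join(y for _, y in pairs)


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing sites among pairwise-comparable sites."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    a, b = _comparable(seq_a.upper(), seq_b.upper())
    return sum(x != y for x, y in zip(a, b)) / len(a)


def nucleotide_diversity(
    counts: Mapping[str, int] | Sequence[int],
    seqs: SequenceSet,
    haplotype_ids: Sequence[str] | None = None,
) -> tuple[float, float]:
    """Nucleotide diversity π per site, with its standard deviation.

    π = n/(n−1) · Σ_{i<j} 2 pᵢ pⱼ dᵢⱼ where dᵢⱼ is the per-site proportion
    of differences between haplotypes i and j (pairwise deletion).  The SD
    comes from Nei's total variance of π,

        V(π) = (n+1)/(3(n−1)L) · π + 2(n²+n+3)/(9n(n−1)) · π².

    ``counts`` may be a mapping haplotype → count or a count vector paired
    with ``haplotype_ids``.
    """
    if isinstance(counts, Mapping):
        items = [(h, int(c)) for h, c in counts.items() if c > 0]
    else:
        if haplotype_ids is None:
            raise ValueError("haplotype_ids required with a plain count vector")
        items = [(h, int(c)) for h, c in zip(haplotype_ids, counts) if c > 0]
    missing = [h for h, _ in items if h not in seqs]
    if missing:
        raise ValueError(f"counted haplotypes without sequences: {missing}")
    n = sum(c for _, c in items)
    if n < 2:
        raise ValueError("nucleotide diversity needs a sample of at least 2")
    L = seqs.alignment_length

    pi = 0.0
    for i in range(len(items)):
        hi, ci = items[i]
        for j in range(i + 1, len(items)):
            hj, cj = items[j]
            pi += 2.0 * (ci / n) * (cj / n) * p_distance(seqs[hi], seqs[hj])
    pi *= n / (n - 1.0)
    var = (n + 1.0) / (3.0 * (n - 1.0) * L) * pi + (
        2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    ) * pi**2
    return pi, math.sqrt(max(var, 0.0))


# ---------------------------------------------------------------------------
# Tamura–Nei (TN93) distance
# ---------------------------------------------------------------------------

def tamura_nei_distance(seq_a: str, seq_b: str) -> float:
    """TN93 corrected distance between two aligned sequences.

    Separates purine (A↔G) and pyrimidine (C↔T) transitions from
    transversions, with base frequencies estimated from the compared sites
    of the pair.  Raises :class:`SaturatedDistanceError` when a logarithm
    argument is non-positive (distance saturated) and ``ValueError`` when no
    comparable sites remain.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    a, b = _comparable(seq_a.upper(), seq_b.upper())
    L = len(a)
    pooled = a + b
    freq = {c: pooled.count(c) / (2 * L) for c in "ACGT"}
    gA, gC, gG, gT = freq["A"], freq["C"], freq["G"], freq["T"]
    gR, gY = gA + gG, gC + gT

    p1 = sum({x, y} == {"A", "G"} for x, y in zip(a, b)) / L
    p2 = sum({x, y} == {"C", "T"} for x, y in zip(a, b)) / L
    q = (
        sum(x != y and ({x, y} not in ({"A", "G"}, {"C", "T"})) for x, y in zip(a, b))
        / L
    )
    if p1 == 0.0 and p2 == 0.0 and q == 0.0:
        return 0.0

    # Degenerate base composition (a frequency class absent) falls back to
    # the terms that remain defined; a fully absent class contributes no
    # substitutions of that type.
    k1 = 2.0 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2.0 * gC * gT / gY if gY > 0 else 0.0
    k3 = 2.0 * (gR * gY - (gA * gG * gY / gR if gR > 0 else 0.0)
                - (gC * gT * gR / gY if gY > 0 else 0.0))

    d = 0.0
    if k1 > 0:
        w1 = 1.0 - p1 / k1 - q / (2.0 * gR)
        if w1 <= 0.0:
            raise SaturatedDistanceError("purine-transition term saturated")
        d -= k1 * math.log(w1)
    elif p1 > 0:
        raise SaturatedDistanceError("purine transitions without purine pairs")
    if k2 > 0:
        w2 = 1.0 - p2 / k2 - q / (2.0 * gY)
        if w2 <= 0.0:
            raise SaturatedDistanceError("pyrimidine-transition term saturated")
        d -= k2 * math.log(w2)
    elif p2 > 0:
        raise SaturatedDistanceError("pyrimidine transitions without pyrimidine pairs")
    if gR > 0 and gY > 0:
        w3 = 1.0 - q / (2.0 * gR * gY)
        if w3 <= 0.0:
            raise SaturatedDistanceError("transversion term saturated")
        d -= k3 * math.log(w3)
    elif q > 0:
        raise SaturatedDistanceError("transversions with degenerate composition")
    return max(d, 0.0)


def distance_matrix(
    haplotype_ids: Sequence[str],
    seqs: SequenceSet | None = None,
    method: str = "tn93",
) -> np.ndarray:
    """Symmetric haplotype distance matrix.

    ``method`` is ``"identity"`` (0/1), ``"p"`` or ``"tn93"``; the latter
    two require ``seqs``.
    """
    H = len(haplotype_ids)
    D = np.zeros((H, H))
    if method == "identity":
        D[~np.eye(H, dtype=bool)] = 1.0
        return D
    if seqs is None:
        raise ValueError(f"method {method!r} requires sequences")
    fn = {"p": p_distance, "tn93": tamura_nei_distance}[method]
    for i in range(H):
        for j in range(i + 1, H):
            D[i, j] = D[j, i] = fn(seqs[haplotype_ids[i]], seqs[haplotype_ids[j]])
    return D


# ---------------------------------------------------------------------------
# two-population AMOVA ΦST and permutation test
# ---------------------------------------------------------------------------

def _resolve_dist(table: HaplotypeCountTable, dist) -> np.ndarray:
    if isinstance(dist, str):
        if dist != "identity":
            raise ValueError("dist must be a matrix or 'identity'")
        return distance_matrix(table.haplotype_ids, method="identity")
    D = np.asarray(dist, dtype=float)
    H = len(table.haplotype_ids)
    if D.shape != (H, H):
        raise ValueError("distance matrix shape does not match haplotypes")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    return D


def _phi_st_from_counts(
    xa: np.ndarray, xb: np.ndarray, D2: np.ndarray, clamp: bool
) -> float:
    """ΦST of a two-group AMOVA from haplotype counts and squared distances."""
    na, nb = xa.sum(), xb.sum()
    if na == 0 or nb == 0:
        raise ValueError("a population has zero sample size")
    N = na + nb
    tot = xa + xb
    ssd_total = float(tot @ D2 @ tot) / (2.0 * N)
    ssd_within = float(xa @ D2 @ xa) / (2.0 * na) + float(xb @ D2 @ xb) / (2.0 * nb)
    ssd_among = ssd_total - ssd_within
    df_within = N - 2
    if df_within <= 0:
        raise ValueError("need more than one individual per test")
    sigma_w = ssd_within / df_within
    n_c = (N - (na**2 + nb**2) / N) / 1.0  # k - 1 = 1 group df
    sigma_a = (ssd_among / 1.0 - sigma_w) / n_c
    denom = sigma_a + sigma_w
    if denom == 0.0:
        return 0.0
    phi = sigma_a / denom
    return max(phi, 0.0) if clamp else phi


def pairwise_phi_st(
    table: HaplotypeCountTable,
    pop_a: str,
    pop_b: str,
    dist="identity",
    clamp_negative: bool = False,
) -> float:
    """AMOVA fixation index ΦST between two populations of the table.

    Haplotype distances enter as squared Euclidean-type distances in the
    sums of squares (``dist`` entries are linear distances; the identity
    matrix gives the frequency-only FST analogue).  Negative estimates are
    reported as computed unless ``clamp_negative``.
    """
    D = _resolve_dist(table, dist)
    xa = table.row(pop_a).astype(float)
    xb = table.row(pop_b).astype(float)
    return _phi_st_from_counts(xa, xb, D**2, clamp_negative)


def permutation_test(
    table: HaplotypeCountTable,
    pop_a: str,
    pop_b: str,
    dist="identity",
    n_perm: int = 99_999,
    seed: int | None = None,
) -> PairwiseStructure:
    """Permutation p-value for ΦST(pop_a, pop_b).

    Individuals are pooled and reallocated between the two populations,
    holding sample sizes fixed; p = (1 + #{ΦST* ≥ ΦST_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    D2 = _resolve_dist(table, dist) ** 2
    xa = table.row(pop_a).astype(np.int64)
    xb = table.row(pop_b).astype(np.int64)
    observed = _phi_st_from_counts(xa.astype(float), xb.astype(float), D2, False)

    pool = np.repeat(np.arange(len(table.haplotype_ids)), xa + xb)
    na = int(xa.sum())
    H = len(table.haplotype_ids)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        ca = np.bincount(perm[:na], minlength=H).astype(float)
        cb = np.bincount(perm[na:], minlength=H).astype(float)
        if _phi_st_from_counts(ca, cb, D2, False) >= observed - 1e-12:
            hits += 1
    p = (1.0 + hits) / (n_perm + 1.0)
    return PairwiseStructure(pop_a, pop_b, observed, p, n_perm)


def diversity_table(
    table: HaplotypeCountTable, seqs: SequenceSet | None = None
) -> list[DiversityResult]:
    """Per-population Hs (and π when sequences are supplied)."""
    out = []
    for pid in table.population_ids:
        counts = table.row(pid)
        hs, hs_sd = gene_diversity(counts)
        pi = pi_sd = None
        if seqs is not None:
            pi, pi_sd = nucleotide_diversity(counts, seqs, table.haplotype_ids)
        out.append(DiversityResult(pid, int(counts.sum()), hs, hs_sd, pi, pi_sd))
    return out
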