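"""Bayesian many-to-one mixed stock analysis (MSA).

Estimates the contribution vector θ of S source rookeries to a single
mixed-stock sample from mtDNA haplotype frequencies, with the standard
conjugate latent-assignment Gibbs sampler (Pella & Masuda style):

* z_i — latent source of mixture individual i, drawn ∝ θ_s · q_s[h(i)];
* q_s — haplotype frequencies of source s, Dirichlet(source counts +
  pseudocount + counts of mixture individuals currently assigned to s);
* θ  — Dirichlet(prior concentration + assignment counts).

Priors default to θ ~ Dirichlet(1/S, …, 1/S) — every rookery equally
likely to contribute a priori — and a 1/H pseudocount on source haplotype
frequencies.  Multiple chains start from overdispersed θ values and
convergence is checked per source with the Gelman–Rubin potential scale
reduction factor; values below 1.2 are conventionally acceptable.

Because mixture individuals sharing a haplotype are exchangeable, the
z-step draws one multinomial per haplotype (column order) rather than one
categorical per individual; the target distribution is identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeCountTable

__all__ = [
    "MsaConfig",
    "MsaResult",
    "fit_msa",
    "gelman_rubin",
    "aggregate_regions",
]

CONVERGENCE_THRESHOLD = 1.2


@dataclass
class MsaConfig:
    """Sampler settings.

    ``theta_prior``/``freq_prior`` of ``None`` mean the defaults 1/S and
    1/H resolved against the table at fit time.  ``init_mode``
    "overdispersed" starts each chain with θ mass 0.9 on a different
    randomly chosen source (required for a meaningful Gelman–Rubin check);
    "uniform" starts every chain at θ = 1/S.
    """

    n_chains: int = 4
    n_iter: int = 25_000
    n_burnin: int | None = None  # default: n_iter // 2
    thinning: int = 5
    theta_prior: float | None = None
    freq_prior: float | None = None
    seed: int = 0
    init_mode: str = "overdispersed"

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.n_burnin is None:
            self.n_burnin = self.n_iter // 2
        if not (0 <= self.n_burnin < self.n_iter):
            raise ValueError("n_burnin must be in [0, n_iter)")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.theta_prior is not None and self.theta_prior <= 0:
            raise ValueError("theta_prior must be positive")
        if self.freq_prior is not None and self.freq_prior <= 0:
            raise ValueError("freq_prior must be positive")
        if self.init_mode not in ("overdispersed", "uniform"):
            raise ValueError("init_mode must be 'overdispersed' or 'uniform'")


@dataclass
class MsaResult:
    """Posterior draws and summaries of the source-contribution vector θ."""

    source_ids: list[str]
    draws: np.ndarray  # (n_chains, n_draws, S)
    theta_mean: np.ndarray
    theta_median: np.ndarray
    theta_ci95: np.ndarray  # (S, 2)
    shrink: np.ndarray  # per-source Gelman–Rubin PSRF
    region_contributions: dict[str, dict[str, float]] = field(default_factory=dict)
    config: MsaConfig | None = None

    @property
    def converged(self) -> bool:
        return bool(np.all(self.shrink < CONVERGENCE_THRESHOLD))

    def pooled_draws(self) -> np.ndarray:
        """(n_chains · n_draws, S) draws with chains concatenated."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": self.source_ids,
                "mean": self.theta_mean,
                "median": self.theta_median,
                "ci2.5": self.theta_ci95[:, 0],
                "ci97.5": self.theta_ci95[:, 1],
                "shrink": self.shrink,
            }
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema": "mixedstock.msa_result/1",
            "sources": self.source_ids,
            "theta_mean": self.theta_mean.tolist(),
            "theta_median": self.theta_median.tolist(),
            "theta_ci95": self.theta_ci95.tolist(),
            "shrink": self.shrink.tolist(),
            "converged": self.converged,
            "region_contributions": self.region_contributions,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def dump_draws(self, path: str | Path) -> None:
        """Flat CSV of retained draws: chain, draw, source, value."""
        C, Nd, S = self.draws.shape
        chain = np.repeat(np.arange(C), Nd * S)
        draw = np.tile(np.repeat(np.arange(Nd), S), C)
        source = np.tile(self.source_ids, C * Nd)
        pd.DataFrame(
            {"chain": chain, "draw": draw, "source": source,
             "value": self.draws.ravel()}
        ).to_csv(path, index=False)


def gelman_rubin(chains: np.ndarray) -> float:
    """Gelman–Rubin potential scale reduction factor of a scalar quantity.

    ``chains`` is (m, n): m ≥ 2 chains of n ≥ 2 draws each.  With W the mean
    within-chain variance and B the between-chain variance (n · variance of
    chain means), the PSRF is sqrt(((n−1)/n · W + B/n) / W).  Returns 1.0
    when every chain is identical and constant (W = B = 0) and +inf when
    chains are internally constant but disagree.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValueError("chains must be a 2-D (m, n) array of equal-length chains")
    m, n = x.shape
    if m < 2:
        raise ValueError("need at least 2 chains")
    if n < 2:
        raise ValueError("chains must have length >= 2")
    W = x.var(axis=1, ddof=1).mean()
    B = n * x.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0 if B == 0.0 else float("inf")
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


def _run_chain(
    mix_counts: np.ndarray,
    src_counts: np.ndarray,
    alpha: float,
    beta: float,
    n_iter: int,
    n_burnin: int,
    thinning: int,
    theta0: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    S, H = src_counts.shape
    n_mix = int(mix_counts.sum())
    theta = theta0.copy()
    q_base = src_counts + beta  # Dirichlet params before assignment counts
    q = q_base / q_base.sum(axis=1, keepdims=True)

    kept = []
    for it in range(n_iter):
        # z-step: allocate mixture individuals to sources, one multinomial
        # per haplotype column (individuals with equal haplotype are
        # exchangeable).
        A = np.zeros((S, H))
        if n_mix:
            P = theta[:, None] * q
            for h in range(H):
                m_h = mix_counts[h]
                if m_h:
                    col = P[:, h]
                    A[:, h] = rng.multinomial(m_h, col / col.sum())
        # θ-step
        g = rng.gamma(alpha + A.sum(axis=1))
        theta = g / g.sum()
        # q-step
        G = rng.gamma(q_base + A)
        q = G / G.sum(axis=1, keepdims=True)
        if it >= n_burnin and (it - n_burnin) % thinning == 0:
            kept.append(theta)
    return np.asarray(kept)


def fit_msa(table: HaplotypeCountTable, config: MsaConfig | None = None) -> MsaResult:
    """Fit the many-to-one MSA to a (reduced) haplotype count table.

    The table must already have passed the exclusion rules: every mixture
    haplotype must occur in at least one source.  An empty mixture row is
    allowed and returns the prior.  With a single source, θ = 1 in every
    draw by construction.
    """
    config = config or MsaConfig()
    src = table.source_counts.astype(float)
    mix = table.mixture_counts.astype(np.int64)
    S, H = src.shape
    orphan = (mix > 0) & (src.sum(axis=0) == 0)
    assert not orphan.any(), "mixture haplotype absent from all sources; run exclusions"

    alpha = config.theta_prior if config.theta_prior is not None else 1.0 / S
    beta = config.freq_prior if config.freq_prior is not None else 1.0 / H

    root = np.random.SeedSequence(config.seed)
    chain_seeds = root.spawn(config.n_chains)
    init_rng = np.random.default_rng(root.spawn(1)[0])

    chains = []
    for c in range(config.n_chains):
        if config.init_mode == "overdispersed" and S > 1:
            theta0 = np.full(S, 0.1 / (S - 1))
            theta0[init_rng.integers(S)] = 0.9
        else:
            theta0 = np.full(S, 1.0 / S)
        chains.append(
            _run_chain(
                mix, src, alpha, beta,
                config.n_iter, config.n_burnin, config.thinning,
                theta0, np.random.default_rng(chain_seeds[c]),
            )
        )
    draws = np.stack(chains)  # (C, Nd, S)

    pooled = draws.reshape(-1, S)
    ci = np.percentile(pooled, [2.5, 97.5], axis=0).T
    if S > 1:
        shrink = np.array([gelman_rubin(draws[:, :, s]) for s in range(S)])
    else:
        shrink = np.ones(1)

    result = MsaResult(
        source_ids=table.source_ids,
        draws=draws,
        theta_mean=pooled.mean(axis=0),
        theta_median=np.median(pooled, axis=0),
        theta_ci95=ci,
        shrink=shrink,
        config=config,
    )
    if table.region_map:
        result.region_contributions = aggregate_regions(result, table.region_map)
    return result


def aggregate_regions(
    result: MsaResult, region_map: Mapping[str, str]
) -> dict[str, dict[str, float]]:
    """Posterior summaries of per-region contribution sums.

    θ draws are summed over each region's sources draw by draw, then
    summarized; region means therefore sum to 1.  Regions named in the map
    but owning no source get an exact 0.  Raises on a source the map does
    not cover.
    """
    uncovered = [s for s in result.source_ids if s not in region_map]
    if uncovered:
        raise ValueError(f"region_map does not cover sources: {uncovered}")
    regions: dict[str, list[int]] = {}
    for idx, s in enumerate(result.source_ids):
        regions.setdefault(region_map[s], []).append(idx)
    for r in region_map.values():  # empty regions allowed, reported as 0
        regions.setdefault(r, [])

    pooled = result.pooled_draws()
    out: dict[str, dict[str, float]] = {}
    for region, idx in regions.items():
        if idx:
            sums = pooled[:, idx].sum(axis=1)
            lo, hi = np.percentile(sums, [2.5, 97.5])
            out[region] = {
                "mean": float(sums.mean()),
                "median": float(np.median(sums)),
                "ci2.5": float(lo),
                "ci97.5": float(hi),
            }
        else:
            out[region] = {"mean": 0.0, "median": 0.0, "ci2.5": 0.0, "ci97.5": 0.0}
    return out
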