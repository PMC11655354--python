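"""Synthetic amplicon communities with planted response strategies.

The generator emulates the structure the per-taxon mixed models assume: each
taxon has a baseline relative abundance, country- and site-level random
intercepts, and — for (taxon, treatment) pairs carrying a planted strategy —
a displacement of relative abundance at S1 (``impact_effect``) that then
changes linearly with days since disturbance (``recovery_slope``).  Counts
are drawn at a sample-specific library size with gamma-weighted multinomial
noise, giving negative-binomial-like overdispersion per feature while row
sums equal the drawn library size exactly.

Planting is compensated: a planted taxon's expected proportion is set to
baseline + impact + slope*day (clipped at 0) and the unplanted taxa are
rescaled to keep the composition summing to one, so the planted displacement
is exact in expectation rather than diluted by renormalization.

Phylogenetic structure: ``simulate_tree_and_effects`` draws a birth-death
tree and per-taxon impact effects from a multivariate normal whose
covariance is the lambda-scaled Brownian tip covariance — lambda = 1 gives
pure Brownian effects, lambda = 0 independent noise.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from ..phylo import tree_vcv

__all__ = [
    "StrategySpec",
    "CommunitySimParams",
    "simulate_tree_and_effects",
    "simulate_asv_counts",
    "strategies_from_effects",
]


@dataclass(frozen=True)
class StrategySpec:
    """Planted response of one taxon to one treatment: S1 displacement of
    relative abundance (proportion units) and its change per day."""

    taxon_id: str
    treatment: str
    impact_effect: float = 0.0
    recovery_slope: float = 0.0


@dataclass
class CommunitySimParams:
    """Knobs of the community generator; defaults are the desk-scale study
    conditions (200 taxa, lognormal baseline abundances, modest country/site
    structure, lognormal library sizes around 10k reads)."""

    n_taxa: int = 200
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.5
    country_sd: float = 0.15  # relative (multiplicative) intercept scales
    site_sd: float = 0.10
    overdispersion: float = 0.05  # gamma-weight variance; 0 -> multinomial
    library_size_median: int = 10_000
    library_size_log_sd: float = 0.25
    phylo_signal_lambda: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.phylo_signal_lambda <= 1.0:
            raise ValueError("phylo_signal_lambda must be in [0, 1]")
        for name in ("country_sd", "site_sd", "overdispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.library_size_median <= 0:
            raise ValueError("library size must be positive")


def simulate_tree_and_effects(
    n_taxa: int,
    lam: float,
    seed: int,
    effect_sd: float = 0.02,
    n_traits: int = 1,
    birth_rate: float = 1.0,
    death_rate: float = 0.2,
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Birth-death tree plus per-taxon effect vectors with phylogenetic
    signal ``lam``.

    Effects are multivariate normal with covariance
    ``effect_sd^2 * (lam * C_offdiag + diag(C))`` for the Brownian tip
    covariance C (depths normalized to 1): lam = 1 is pure Brownian motion on
    the tree, lam = 0 independent white noise of the same marginal variance.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_taxa,
        rng=random.Random(int(seed)),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1:04d}"
    tips, c = tree_vcv(tree)
    c = c / np.max(np.diagonal(c))  # unit depth so effect_sd is the tip scale
    v = lam * c
    np.fill_diagonal(v, np.diagonal(c))
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(v + 1e-10 * np.eye(len(tips)))
    effects = effect_sd * (chol @ rng.standard_normal((len(tips), n_traits)))
    cols = [f"effect_{j + 1}" for j in range(n_traits)]
    return tree, pd.DataFrame(effects, index=tips, columns=cols)


def strategies_from_effects(
    effects: pd.Series, treatment: str, slope_fraction: float = -1 / 26
) -> list[StrategySpec]:
    """Turn a per-taxon effect vector into strategy specs for one treatment,
    with a recovery slope proportional to the impact (default: full linear
    recovery by S4, 26 days)."""
    return [
        StrategySpec(taxon, treatment, float(e), float(e) * slope_fraction)
        for taxon, e in effects.items()
    ]


def simulate_asv_counts(
    metadata: pd.DataFrame,
    strategies: list[StrategySpec],
    params: CommunitySimParams,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw a samples x taxa count table for the microcosm metadata.

    ``metadata`` needs columns sample_id, country, site, treatment, day
    (initial samples: treatment NA, treated as control at day 0).  Returns
    the count table (index sample_id) and a ground-truth ledger holding every
    planted quantity.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    taxa = [f"t{i + 1:04d}" for i in range(params.n_taxa)]
    known = set(taxa)
    for s in strategies:
        if s.taxon_id not in known:
            raise ValueError(f"strategy references unknown taxon {s.taxon_id!r}")

    base = rng.lognormal(params.baseline_log_mean, params.baseline_log_sd, params.n_taxa)
    base = base / base.sum()

    countries = sorted(metadata["country"].dropna().unique())
    sites = sorted(metadata["site"].dropna().unique())
    country_fx = {
        c: rng.normal(0.0, params.country_sd, params.n_taxa) for c in countries
    }
    site_fx = {s: rng.normal(0.0, params.site_sd, params.n_taxa) for s in sites}

    planted: dict[str, dict[int, tuple[float, float]]] = {}
    for s in strategies:
        planted.setdefault(s.treatment, {})[taxa.index(s.taxon_id)] = (
            s.impact_effect,
            s.recovery_slope,
        )

    n = len(metadata)
    counts = np.zeros((n, params.n_taxa), dtype=np.int64)
    lib_sizes = np.maximum(
        1,
        np.round(
            rng.lognormal(
                np.log(params.library_size_median), params.library_size_log_sd, n
            )
        ).astype(np.int64),
    )

    for row, (_, rec) in enumerate(metadata.iterrows()):
        p = base * np.exp(country_fx[rec["country"]] + site_fx[rec["site"]])
        p = p / p.sum()
        treatment = rec.get("treatment")
        if isinstance(treatment, str) and treatment in planted:
            day = rec.get("day")
            day = 0.0 if pd.isna(day) else float(day)
            q = p.copy()
            shifted = planted[treatment]
            for idx, (impact, slope) in shifted.items():
                q[idx] = max(0.0, p[idx] + impact + slope * day)
            others = np.ones(params.n_taxa, dtype=bool)
            others[list(shifted)] = False
            rest_target = 1.0 - q[~others].sum()
            rest_base = p[others].sum()
            if rest_target <= 0 or rest_base <= 0:
                q = np.clip(q, 0.0, None)
            else:
                q[others] *= rest_target / rest_base
            p = q / q.sum()
        if p.sum() <= 0:
            raise ValueError(f"all expected proportions zero in sample {rec['sample_id']}")
        if params.overdispersion > 0:
            shape = 1.0 / params.overdispersion
            w = p * rng.gamma(shape, 1.0 / shape, params.n_taxa)
            if w.sum() <= 0:  # pragma: no cover - degenerate draw
                w = p
            p = w / w.sum()
        counts[row] = rng.multinomial(lib_sizes[row], p)

    table = pd.DataFrame(counts, index=metadata["sample_id"].to_numpy(), columns=taxa)
    truth = {
        "taxa": taxa,
        "baseline_proportions": dict(zip(taxa, base.tolist())),
        "strategies": [
            {
                "taxon_id": s.taxon_id,
                "treatment": s.treatment,
                "impact_effect": s.impact_effect,
                "recovery_slope": s.recovery_slope,
            }
            for s in strategies
        ],
        "phylo_signal_lambda": params.phylo_signal_lambda,
        "library_sizes": dict(zip(table.index.tolist(), lib_sizes.tolist())),
        "params": {
            k: getattr(params, k)
            for k in (
                "n_taxa",
                "baseline_log_mean",
                "baseline_log_sd",
                "country_sd",
                "site_sd",
                "overdispersion",
                "library_size_median",
                "library_size_log_sd",
                "rng_seed",
            )
        },
    }
    return table, truth
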