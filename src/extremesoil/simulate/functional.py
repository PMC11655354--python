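"""Synthetic functional-gene profiles over a 4-level nested hierarchy.

Emulates shotgun-metagenome functional annotation against a SEED-like
classification: proteins nest in level3 in level2 in level1 categories.
Per-sample compositions are Dirichlet-multinomial (gamma-weighted
multinomial) around a baseline, and planted shifts displace the proportion of
a chosen category under a chosen treatment at S1, optionally decaying
linearly to zero by S4 (a resilient shift) or persisting (a stable one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FunctionalShift",
    "make_hierarchy",
    "simulate_functional_profiles",
]


@dataclass(frozen=True)
class FunctionalShift:
    """Planted displacement of one category's summed proportion under one
    treatment; ``resilient`` shifts decay linearly to 0 by ``recovery_day``."""

    category: str
    level: str  # level1 | level2 | level3 | protein
    treatment: str
    delta: float
    resilient: bool = False
    recovery_day: float = 26.0


def make_hierarchy(
    n_level1: int = 6, n_level2: int = 2, n_level3: int = 2, n_proteins: int = 2
) -> pd.DataFrame:
    """Balanced 4-level hierarchy table (one row per protein; columns
    protein, level3, level2, level1).  Defaults give 48 proteins in 6
    top-level categories."""
    rows = []
    for a in range(n_level1):
        l1 = f"L1_{a + 1:02d}"
        for b in range(n_level2):
            l2 = f"{l1}.L2_{b + 1}"
            for c in range(n_level3):
                l3 = f"{l2}.L3_{c + 1}"
                for d in range(n_proteins):
                    rows.append(
                        {"protein": f"{l3}.P{d + 1}", "level3": l3, "level2": l2, "level1": l1}
                    )
    return pd.DataFrame(rows)


def members_of(hierarchy: pd.DataFrame, category: str, level: str) -> list[str]:
    if level not in ("level1", "level2", "level3", "protein"):
        raise ValueError(f"unknown hierarchy level {level!r}")
    sel = hierarchy[hierarchy[level] == category]
    if sel.empty:
        raise ValueError(f"unknown category {category!r} at {level}")
    return sel["protein"].tolist()


def simulate_functional_profiles(
    metadata: pd.DataFrame,
    hierarchy: pd.DataFrame,
    shifts: list[FunctionalShift],
    seed: int = 0,
    library_size_median: int = 50_000,
    library_size_log_sd: float = 0.2,
    overdispersion: float = 0.02,
    baseline_log_sd: float = 0.8,
) -> tuple[pd.DataFrame, dict]:
    """Draw a samples x proteins count table plus ground-truth ledger.

    Compositional planting mirrors the amplicon generator: member proteins of
    a shifted category are moved to (baseline + delta * decay) proportionally
    to their baseline share of the category, non-members are rescaled so the
    composition still sums to one.  Shifts that would push a proportion below
    zero are clipped with a warning.
    """
    for col in ("protein", "level3", "level2", "level1"):
        if col not in hierarchy.columns:
            raise ValueError(f"hierarchy lacks column {col!r}")
    rng = np.random.default_rng(seed)
    proteins = hierarchy["protein"].tolist()
    k = len(proteins)
    base = rng.lognormal(0.0, baseline_log_sd, k)
    base = base / base.sum()

    shift_members = []
    for s in shifts:
        idx = [proteins.index(p) for p in members_of(hierarchy, s.category, s.level)]
        shift_members.append((s, np.array(idx)))

    n = len(metadata)
    lib = np.maximum(
        1,
        np.round(
            rng.lognormal(np.log(library_size_median), library_size_log_sd, n)
        ).astype(np.int64),
    )
    counts = np.zeros((n, k), dtype=np.int64)
    for row, (_, rec) in enumerate(metadata.iterrows()):
        p = base.copy()
        treatment = rec.get("treatment")
        day = rec.get("day")
        day = 0.0 if pd.isna(day) else float(day)
        touched = np.zeros(k, dtype=bool)
        for s, idx in shift_members:
            if not isinstance(treatment, str) or treatment != s.treatment:
                continue
            decay = max(0.0, 1.0 - day / s.recovery_day) if s.resilient else 1.0
            cat_base = base[idx].sum()
            target = cat_base + s.delta * decay
            if target < 0:
                warnings.warn(
                    f"shift on {s.category} clips below zero; truncated", stacklevel=2
                )
                target = 0.0
            p[idx] = base[idx] * (target / cat_base if cat_base > 0 else 0.0)
            touched[idx] = True
        if touched.any():
            rest_target = 1.0 - p[touched].sum()
            rest_base = base[~touched].sum()
            if rest_target > 0 and rest_base > 0:
                p[~touched] = base[~touched] * rest_target / rest_base
            p = np.clip(p, 0.0, None)
            p = p / p.sum()
        if overdispersion > 0:
            shape = 1.0 / overdispersion
            w = p * rng.gamma(shape, 1.0 / shape, k)
            p = w / w.sum() if w.sum() > 0 else p
        counts[row] = rng.multinomial(lib[row], p)

    table = pd.DataFrame(counts, index=metadata["sample_id"].to_numpy(), columns=proteins)
    truth = {
        "baseline_proportions": dict(zip(proteins, base.tolist())),
        "shifts": [
            {
                "category": s.category,
                "level": s.level,
                "treatment": s.treatment,
                "delta": s.delta,
                "resilient": s.resilient,
                "recovery_day": s.recovery_day,
            }
            for s in shifts
        ],
        "library_sizes": dict(zip(table.index.tolist(), lib.tolist())),
    }
    return table, truth
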