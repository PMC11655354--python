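"""Shared helpers: seed fan-out, table IO."""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed (< 2**31) from a global seed.

    Uses SHA-256 of ``"<seed>:<stage>"`` so stage seeds are decorrelated and
    stable across platforms and Python hash randomization.
    """
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_for(global_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(global_seed, stage))


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
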