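"""Community-level beta-diversity statistics.

Counts are held as pandas DataFrames with samples as the index and features
(ASVs or functional categories) as columns; library sizes are the row sums.
The analysis chain mirrors standard practice for sequencing count tables:
rarefy to a common depth, Hellinger-transform (square root of relative
abundance), compute Bray-Curtis dissimilarities, then partition or test the
distance structure with permutation methods (PERMANOVA with sequential
sums of squares; Mantel rank correlation between distance matrices).

Community resistance and resilience are defined as the *negative* Bray-Curtis
dissimilarity between each disturbed sample and its paired control from the
same site at the same sampling time — at S1 (end of disturbance) the score is
resistance, at S4 (26 days after) it is resilience.  High dissimilarity means
low resistance/resilience; a score of 0 is maximal, -1 minimal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "MantelResult",
    "hellinger_transform",
    "rarefy_counts",
    "bray_curtis_matrix",
    "permanova",
    "mantel_test",
    "community_resistance_resilience",
    "NEG_LOG_EPS",
]

NEG_LOG_EPS = 1e-6  # pseudo-dissimilarity inside -log(BC + eps); handles BC = 0


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix keyed by sample ids.

    Undefined pairs (both profiles empty) may be NaN in permissive mode.
    """

    ids: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape disagrees with ids")
        if np.nanmax(np.abs(np.diagonal(self.data))) > 1e-12:
            raise ValueError("nonzero diagonal")
        finite = np.isfinite(self.data)
        if not np.allclose(
            self.data[finite & finite.T], self.data.T[finite & finite.T], atol=1e-12
        ):
            raise ValueError("asymmetric distance matrix")

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def filter(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(tuple(ids), self.data[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.ids), columns=list(self.ids))


@dataclass
class PermanovaResult:
    terms: list[str]
    df: list[int]
    ss: list[float]
    r2: list[float]
    pseudo_f: list[float]
    p: list[float]
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "df": self.df,
                "SS": self.ss,
                "R2": self.r2,
                "F": self.pseudo_f,
                "p": self.p,
            }
        )


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    method: str = "spearman"


def hellinger_transform(table: pd.DataFrame) -> pd.DataFrame:
    """sqrt(count / library size) per entry; rows then have unit sum of squares."""
    counts = table.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    row_sums = counts.sum(axis=1)
    if (row_sums <= 0).any():
        bad = table.index[row_sums <= 0].tolist()
        raise ValueError(f"empty sample rows: {bad}")
    return pd.DataFrame(
        np.sqrt(counts / row_sums[:, None]), index=table.index, columns=table.columns
    )


def rarefy_counts(
    table: pd.DataFrame,
    depth: int,
    seed: int | np.random.Generator = 0,
    drop_small: bool = False,
) -> pd.DataFrame:
    """Subsample each row without replacement to exactly ``depth`` reads.

    Multivariate-hypergeometric draw per sample (a single draw; draws are not
    averaged).  Samples below ``depth`` raise unless ``drop_small``, in which
    case they are dropped with a warning.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    counts = table.to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("rarefaction requires integer counts")
        counts = counts.astype(np.int64)
    lib = counts.sum(axis=1)
    small = lib < depth
    if small.any():
        bad = table.index[small].tolist()
        if not drop_small:
            raise ValueError(f"samples below depth {depth}: {bad}")
        warnings.warn(f"dropping {len(bad)} samples below depth {depth}", stacklevel=2)
        table = table.loc[~small]
        counts = counts[~small]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def bray_curtis_matrix(
    matrix: pd.DataFrame, strict: bool = True
) -> DistanceMatrix:
    """Pairwise Bray-Curtis: BC(x, y) = sum|x-y| / sum(x+y).

    Pairs of all-zero rows are undefined; they raise in strict mode and are
    NaN otherwise.
    """
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("Bray-Curtis requires non-negative entries")
    dm = squareform(pdist(values, metric="braycurtis"))
    empty = values.sum(axis=1) == 0
    if empty.sum() >= 2:
        if strict:
            raise ValueError(
                f"undefined Bray-Curtis between all-zero samples: "
                f"{matrix.index[empty].tolist()}"
            )
        mask = np.outer(empty, empty)
        np.fill_diagonal(mask, False)
        dm[mask] = np.nan
    return DistanceMatrix(tuple(matrix.index), dm)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = int((np.abs(np.diagonal(r)) > 1e-10 * max(1.0, np.abs(r[0, 0]))).sum())
    q = q[:, :rank]
    return q @ q.T


def _term_design(factors: pd.DataFrame, term: str) -> np.ndarray:
    """Design columns for one term; 'a:b' denotes an interaction."""
    parts = term.split(":")
    cols = []
    for part in parts:
        col = factors[part]
        if col.nunique() < 2:
            raise ValueError(f"constant factor {part!r}")
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            cols.append(pd.get_dummies(col, prefix=part, dtype=float))
        else:
            cols.append(col.astype(float).to_frame(part))
    out = cols[0]
    for nxt in cols[1:]:
        out = pd.DataFrame(
            {
                f"{c1}:{c2}": out[c1].to_numpy() * nxt[c2].to_numpy()
                for c1 in out.columns
                for c2 in nxt.columns
            },
            index=out.index,
        )
    return out.to_numpy(dtype=float)


def permanova(
    dist: DistanceMatrix,
    factors: pd.DataFrame,
    terms: list[str],
    n_permutations: int = 999,
    seed: int | np.random.Generator = 0,
    strata: str | None = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA with sequential (Type-I) sums of
    squares, partitioning the Gower-centred inner-product matrix of ``dist``
    by the model terms in order.

    ``factors`` is indexed (or indexable) by the distance matrix ids.  Terms
    are column names, optionally 'a:b' interactions.  p-values come from free
    permutation of sample labels, p = (1 + #{F* >= F}) / (1 + n_permutations);
    ``strata`` restricts permutations to shuffle within levels of that column.
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    if not np.isfinite(dist.data).all():
        raise ValueError("permanova requires a fully defined distance matrix")
    factors = factors.loc[list(dist.ids)]
    n = len(dist.ids)
    g = _gower_center(dist.data)
    ss_total = float(np.trace(g))

    designs = [np.ones((n, 1))]
    dfs = []
    hats = [_hat(designs[0])]
    for term in terms:
        designs.append(np.hstack([designs[-1], _term_design(factors, term)]))
        h = _hat(designs[-1])
        hats.append(h)
        dfs.append(int(round(np.trace(h) - np.trace(hats[-2]))))
    df_res = n - int(round(np.trace(hats[-1])))
    if df_res <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")

    def term_stats(gmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tr = np.array([float(np.sum(h * gmat)) for h in hats])
        ss = np.diff(tr)
        ss_res = float(np.trace(gmat)) - tr[-1]
        f = (ss / np.array(dfs)) / (ss_res / df_res)
        return ss, f

    ss_obs, f_obs = term_stats(g)
    ss_res = ss_total - ss_obs.sum()

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    if strata is not None:
        groups = [np.flatnonzero(factors[strata].to_numpy() == lev)
                  for lev in pd.unique(factors[strata])]
    for _ in range(n_permutations):
        if strata is None:
            p = rng.permutation(n)
        else:
            p = np.arange(n)
            for idx in groups:
                p[idx] = idx[rng.permutation(len(idx))]
        _, f_perm = term_stats(g[np.ix_(p, p)])
        exceed += f_perm >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_permutations)

    return PermanovaResult(
        terms=list(terms) + ["residual"],
        df=dfs + [df_res],
        ss=list(ss_obs) + [ss_res],
        r2=[s / ss_total for s in ss_obs] + [ss_res / ss_total],
        pseudo_f=list(f_obs) + [np.nan],
        p=list(pvals) + [np.nan],
        n_permutations=n_permutations,
    )


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int | np.random.Generator = 0,
    method: str = "spearman",
) -> MantelResult:
    """Two-tailed Mantel test between two distance matrices on the same
    samples: correlation of the lower triangles, significance by simultaneous
    row/column permutation of the second matrix.

    Spearman by default.  Permuting rows/columns of a distance matrix leaves
    the multiset of off-diagonal values unchanged, so ranks are assigned once
    and re-gathered per permutation, which keeps the permutation loop cheap.
    """
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices must share sample ids")
    if len(d1.ids) < 4:
        raise ValueError("mantel test needs at least 4 samples")
    d2 = d2.filter(d1.ids)
    n = len(d1.ids)
    iu = np.triu_indices(n, k=1)

    def flat(values: np.ndarray) -> np.ndarray:
        v = values[iu]
        if method == "spearman":
            v = rankdata(v)
        elif method != "pearson":
            raise ValueError(f"unknown method {method!r}")
        return v

    x = flat(d1.data)
    x = (x - x.mean()) / x.std()
    y_full = d2.data.copy()
    if method == "spearman":
        # rank the condensed entries once, spread back to square form
        y_sq = squareform(rankdata(y_full[iu]))
    else:
        y_sq = y_full
    y = y_sq[iu]
    y = (y - y.mean()) / y.std()
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("degenerate (constant) distance matrix")
    r_obs = float(x @ y) / len(x)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        p = rng.permutation(n)
        yp = y_sq[np.ix_(p, p)][iu]
        yp = (yp - yp.mean()) / yp.std()
        if abs(float(x @ yp) / len(x)) >= abs(r_obs) - 1e-12:
            exceed += 1
    return MantelResult(
        r=r_obs,
        p=(1.0 + exceed) / (1.0 + n_permutations),
        n_permutations=n_permutations,
        method=method,
    )


def community_resistance_resilience(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    samplings: tuple[str, ...] = ("S1", "S4"),
    transform: str = "hellinger",
    eps: float = NEG_LOG_EPS,
) -> pd.DataFrame:
    """Per-sample community resistance (S1) / resilience (S4) scores.

    For every disturbed sample at the requested samplings, the score is minus
    the Bray-Curtis dissimilarity to the control sample from the same site at
    the same sampling.  Also returns the -log(BC + eps) variant used as the
    response of the predictive model.  Samples without a control pair are
    skipped with a warning.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    meta = meta.loc[meta.index.intersection(table.index)]
    mat = hellinger_transform(table) if transform == "hellinger" else table
    dm = bray_curtis_matrix(mat, strict=False)
    pos = {sid: k for k, sid in enumerate(dm.ids)}

    rows = []
    kind_of = {samplings[0]: "resistance"}
    if len(samplings) > 1:
        kind_of[samplings[-1]] = "resilience"
    controls = meta[meta["treatment"] == "control"]
    for sid, rec in meta.iterrows():
        if rec["treatment"] in (None, "control") or pd.isna(rec["treatment"]):
            continue
        if rec["sampling"] not in samplings:
            continue
        pair = controls[
            (controls["site"] == rec["site"]) & (controls["sampling"] == rec["sampling"])
        ]
        if pair.empty:
            warnings.warn(f"no control pair for {sid}; skipped", stacklevel=2)
            continue
        bc = dm.data[pos[sid], pos[pair.index[0]]]
        rows.append(
            {
                "sample_id": sid,
                "control_id": pair.index[0],
                "country": rec["country"],
                "site": rec["site"],
                "treatment": rec["treatment"],
                "sampling": rec["sampling"],
                "kind": kind_of.get(rec["sampling"], "other"),
                "score": -bc,
                "neg_log_score": -np.log(bc + eps),
            }
        )
    return pd.DataFrame(rows)
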