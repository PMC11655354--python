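"""Predicting community resistance/resilience from initial soil and climate
properties.

The response is the -log-transformed Bray-Curtis dissimilarity of a
disturbed sample's functional profile from its paired control; predictors
are the 20 standardized initial properties plus treatment and sampling
indicators.  An ensemble-of-trees regressor (any object with fit/predict;
default sklearn RandomForestRegressor with a third of the features per
split) is evaluated by grouped cross-validation over the design's split
spaces — training on two sites per country and testing on the third, or
training on a subset of countries — so that test sites are never seen in
training.  Partial-dependence profiles and Spearman property-response
correlation maps summarize which initial properties carry the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import pearsonr, spearmanr

__all__ = [
    "standardize_predictors",
    "ResistanceForestCV",
    "ForestCVResults",
    "partial_dependence",
    "PDProfile",
    "property_response_correlations",
    "CorrelationGrid",
]


def standardize_predictors(
    table: pd.DataFrame, property_columns: list[str]
) -> pd.DataFrame:
    """z-score the property columns (sample SD, ddof=1) over the full table;
    non-property columns (treatment, sampling, site ids) pass through."""
    out = table.copy()
    for col in property_columns:
        x = out[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"constant predictor column {col!r}")
        out[col] = (x - x.mean()) / sd
    return out


def _default_regressor(n_trees: int, n_features: int, seed: int):
    from sklearn.ensemble import RandomForestRegressor

    return RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max(1, n_features // 3),
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


@dataclass
class ForestCVResults:
    r2: pd.Series  # per-split test R^2
    site_predictions: pd.DataFrame  # site, treatment, sampling, observed, mean predicted
    correlations: pd.DataFrame  # per (treatment, sampling) Pearson r of obs vs mean pred
    n_splits_requested: int
    n_splits_fitted: int
    feature_columns: list[str]

    @property
    def mean_r2(self) -> float:
        return float(self.r2.mean())

    @property
    def sd_r2(self) -> float:
        return float(self.r2.std(ddof=1)) if len(self.r2) > 1 else 0.0

    def summary(self) -> str:
        lines = [
            f"Grouped cross-validation over {self.n_splits_fitted} splits "
            f"(of {self.n_splits_requested} available)",
            f"  test R^2: {self.mean_r2:.3f} +/- {self.sd_r2:.3f}",
            "  Pearson r (observed vs mean predicted) per perturbation:",
        ]
        for _, row in self.correlations.iterrows():
            lines.append(
                f"    {row['treatment']:>8} {row['sampling']}: r = {row['r']:.3f}"
            )
        return "\n".join(lines)


class ResistanceForestCV:
    """Grouped cross-validation of a tree-ensemble resistance model.

    Parameters
    ----------
    table : DataFrame
        One row per (site, treatment, sampling) with the standardized
        properties, categorical ``treatment`` and ``sampling`` columns, a
        ``site`` column, and the response.
    response : str
        Response column name.
    splits : list of (train_sites, test_sites)
        From :func:`extremesoil.design.enumerate_site_splits` (site ids) or
        country splits mapped to sites.
    regressor_factory : callable(seed) -> estimator, optional
        Anything with fit(X, y)/predict(X); defaults to a random forest with
        ``n_trees`` trees and a third of the features per split.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        response: str,
        splits: list[tuple[tuple[str, ...], tuple[str, ...]]],
        property_columns: list[str] | None = None,
        n_trees: int = 500,
        regressor_factory=None,
        seed: int = 0,
    ):
        if response not in table.columns:
            raise ValueError(f"response column {response!r} missing")
        self.table = table.reset_index(drop=True)
        self.response = response
        self.splits = list(splits)
        known_sites = set(self.table["site"])
        for train, test in self.splits:
            unknown = (set(train) | set(test)) - known_sites
            if unknown:
                raise ValueError(f"split references unknown sites {sorted(unknown)}")
        if property_columns is None:
            property_columns = [
                c
                for c in table.columns
                if c not in (response, "site", "treatment", "sampling", "country")
                and np.issubdtype(table[c].dtype, np.number)
            ]
        self.property_columns = property_columns
        self.n_trees = n_trees
        self.seed = seed
        self.regressor_factory = regressor_factory

        x = self.table[property_columns].copy()
        for cat in ("treatment", "sampling"):
            if cat in self.table.columns:
                x = pd.concat(
                    [x, pd.get_dummies(self.table[cat], prefix=cat, dtype=float)], axis=1
                )
        self.x = x
        self.y = self.table[response].to_numpy(dtype=float)

    def _make_regressor(self, seed: int):
        if self.regressor_factory is not None:
            return self.regressor_factory(seed)
        return _default_regressor(self.n_trees, self.x.shape[1], seed)

    def fit(self, split_budget: int | None = 200) -> ForestCVResults:
        """Fit one model per split (a seeded subsample of ``split_budget``
        splits when more are available) and score each test set.

        R^2 per split is 1 - SSE/SST on the held-out sites.  The train/test
        site sets are asserted disjoint for every split fitted.
        """
        rng = np.random.default_rng(self.seed)
        splits = self.splits
        if split_budget is not None and len(splits) > split_budget:
            pick = rng.choice(len(splits), size=split_budget, replace=False)
            splits = [splits[i] for i in sorted(pick)]
        site = self.table["site"].to_numpy()
        r2s = []
        pred_rows = []
        for k, (train_sites, test_sites) in enumerate(splits):
            overlap = set(train_sites) & set(test_sites)
            if overlap:
                raise AssertionError(f"train/test leakage at split {k}: {overlap}")
            tr = np.isin(site, train_sites)
            te = np.isin(site, test_sites)
            if not tr.any() or not te.any():
                continue
            model = self._make_regressor(int(rng.integers(2**31)))
            model.fit(self.x.to_numpy()[tr], self.y[tr])
            pred = model.predict(self.x.to_numpy()[te])
            obs = self.y[te]
            sse = float(((obs - pred) ** 2).sum())
            sst = float(((obs - obs.mean()) ** 2).sum())
            r2s.append(1.0 - sse / sst if sst > 0 else np.nan)
            for idx, yhat in zip(np.flatnonzero(te), pred):
                pred_rows.append({"row": idx, "split": k, "pred": yhat})

        preds = pd.DataFrame(pred_rows)
        mean_pred = preds.groupby("row")["pred"].mean()
        sp = self.table.loc[mean_pred.index, ["site", "treatment", "sampling"]].copy()
        sp["observed"] = self.y[mean_pred.index]
        sp["mean_predicted"] = mean_pred.to_numpy()
        corr_rows = []
        for (treatment, sampling), sub in sp.groupby(["treatment", "sampling"]):
            if len(sub) >= 3 and sub["observed"].std() > 0 and sub["mean_predicted"].std() > 0:
                r, p = pearsonr(sub["observed"], sub["mean_predicted"])
            else:
                r, p = np.nan, np.nan
            corr_rows.append(
                {"treatment": treatment, "sampling": sampling, "r": r, "p": p,
                 "n": len(sub)}
            )
        return ForestCVResults(
            r2=pd.Series(r2s, name="test_r2"),
            site_predictions=sp.reset_index(drop=True),
            correlations=pd.DataFrame(corr_rows),
            n_splits_requested=len(self.splits),
            n_splits_fitted=len(r2s),
            feature_columns=list(self.x.columns),
        )


@dataclass
class PDProfile:
    variable: str
    grid: np.ndarray
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.variable: self.grid, "partial_dependence": self.values})


def partial_dependence(
    model, table: pd.DataFrame, variable: str, grid_size: int = 20
) -> PDProfile:
    """Average prediction as one variable sweeps its observed range, other
    predictors held at their observed values (the standard partial-dependence
    construction)."""
    if variable not in table.columns:
        raise ValueError(f"unknown variable {variable!r}")
    x = table.to_numpy(dtype=float)
    j = list(table.columns).index(variable)
    grid = np.linspace(table[variable].min(), table[variable].max(), grid_size)
    values = np.empty(grid_size)
    for g, v in enumerate(grid):
        xg = x.copy()
        xg[:, j] = v
        values[g] = float(np.mean(model.predict(xg)))
    return PDProfile(variable, grid, values)


@dataclass
class CorrelationGrid:
    rho: pd.DataFrame  # properties x response columns, rows cluster-ordered
    flagged: pd.DataFrame  # cells where rho is undefined

    def to_frame(self) -> pd.DataFrame:
        return self.rho


def property_response_correlations(
    properties: pd.DataFrame,
    scores: pd.DataFrame,
    score_col: str = "score",
    min_pairs: int = 4,
) -> CorrelationGrid:
    """Spearman rho between each initial property (site-level) and the
    resistance/resilience score per (treatment, kind).

    Rows (properties) are ordered by complete-linkage hierarchical clustering
    of their correlation profiles (Euclidean distance), mirroring how such
    heatmaps are usually displayed.  Cells with fewer than ``min_pairs``
    paired observations or an all-tied vector are NaN and flagged.
    """
    cols = []
    for (treatment, kind), sub in scores.groupby(["treatment", "kind"]):
        cols.append((f"{treatment}:{kind}", sub))
    rho = pd.DataFrame(index=properties.columns, columns=[c for c, _ in cols], dtype=float)
    flagged = pd.DataFrame(False, index=rho.index, columns=rho.columns)
    for name, sub in cols:
        merged = sub.merge(
            properties, left_on="site", right_index=True, how="inner"
        )
        for prop in properties.columns:
            x = merged[prop].to_numpy(dtype=float)
            y = merged[score_col].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < min_pairs or len(set(x[ok])) < 2 or len(set(y[ok])) < 2:
                rho.loc[prop, name] = np.nan
                flagged.loc[prop, name] = True
                continue
            r, _ = spearmanr(x[ok], y[ok])
            rho.loc[prop, name] = r
    profiles = rho.fillna(0.0).to_numpy()
    if len(rho) > 2:
        order = leaves_list(linkage(profiles, method="complete", metric="euclidean"))
        rho = rho.iloc[order]
        flagged = flagged.iloc[order]
    return CorrelationGrid(rho=rho, flagged=flagged)
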