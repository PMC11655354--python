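"""Response of functional-gene categories to disturbance.

Functional profiles are counts of reads per protein in a 4-level nested
classification (level1 ⊃ level2 ⊃ level3 ⊃ protein).  For a category at a
chosen level, one linear mixed model is fitted to the arcsine-square-root
transformed proportions of its member proteins:

    asin(sqrt(p)) ~ treatment + day + treatment:day
    random intercepts: country, site, each nested sub-level, protein
    residual variance: per-country multipliers (iteratively reweighted)

The treatment coefficients are the category's displacement from control at
S1 on the transformed scale (resistance); the treatment:day coefficients are
its recovery slopes (resilience).  Treatment-versus-control contrasts are
adjusted for the contrast family with Dunnett's test (Monte-Carlo max-|t|),
and omnibus p-values are corrected across the categories of a level with
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "arcsine_sqrt_proportions",
    "aggregate_to_level",
    "FunctionLMM",
    "FunctionLMMResults",
    "fit_function_model",
    "dunnett_adjust",
    "bh_fdr",
    "functional_impact_table",
    "count_significant_by_parent",
]

_LEVELS = ("level1", "level2", "level3", "protein")


def aggregate_to_level(
    table: pd.DataFrame, hierarchy: pd.DataFrame, level: str
) -> pd.DataFrame:
    """Sum protein counts up to ``level`` (identity for level='protein')."""
    if level not in _LEVELS:
        raise ValueError(f"unknown level {level!r}")
    if level == "protein":
        return table.copy()
    parent = hierarchy.set_index("protein")[level]
    return table.T.groupby(parent.loc[table.columns]).sum().T


def arcsine_sqrt_proportions(
    table: pd.DataFrame, hierarchy: pd.DataFrame, level: str = "level1"
) -> pd.DataFrame:
    """asin(sqrt(p)) of per-sample category proportions at ``level``.

    Proportions are category counts over the total sample count, so a
    level's proportions are the sums of its members' proportions.
    """
    lib = table.sum(axis=1).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("samples with zero total counts")
    agg = aggregate_to_level(table, hierarchy, level)
    p = agg.to_numpy(dtype=float) / lib[:, None]
    if (p < 0).any() or (p > 1 + 1e-12).any():
        raise ValueError("proportions outside [0, 1]")
    return pd.DataFrame(
        np.arcsin(np.sqrt(np.clip(p, 0.0, 1.0))), index=agg.index, columns=agg.columns
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def dunnett_adjust(
    estimates,
    covariance,
    df: float = np.inf,
    n_draws: int = 200_000,
    seed: int = 0,
) -> np.ndarray:
    """Family-wise adjusted p-values for treatment-versus-control contrasts.

    Monte-Carlo evaluation of P(max_i |t*_i| >= |t_obs_j|) under the joint
    null, with t* drawn from the estimated contrast correlation (multivariate
    t when ``df`` is finite).  Adjusted values are clipped to be no smaller
    than the raw two-tailed p.
    """
    est = np.asarray(estimates, dtype=float)
    cov = np.atleast_2d(np.asarray(covariance, dtype=float))
    if est.size == 0:
        raise ValueError("need at least one contrast")
    se = np.sqrt(np.diagonal(cov))
    if not np.isfinite(se).all() or (se <= 0).any():
        raise ValueError("invalid contrast covariance")
    corr = cov / np.outer(se, se)
    if est.size > 1 and np.linalg.eigvalsh(corr).min() < 1e-10:
        raise ValueError("singular contrast covariance")
    try:
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(est)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular contrast covariance") from exc
    t_obs = est / se
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, len(est))) @ chol.T
    if np.isfinite(df):
        z /= np.sqrt(rng.chisquare(df, n_draws) / df)[:, None]
        p_raw = 2 * stats.t.sf(np.abs(t_obs), df)
    else:
        p_raw = 2 * stats.norm.sf(np.abs(t_obs))
    max_abs = np.abs(z).max(axis=1)
    adj = np.array([(max_abs >= abs(t)).mean() for t in t_obs])
    adj = np.maximum(np.maximum(adj, p_raw), 1.0 / n_draws)
    return np.minimum(adj, 1.0)


@dataclass
class FunctionLMMResults:
    category: str
    level: str
    impacts: pd.DataFrame  # index treatment: delta, se, p_raw, p_dunnett
    slopes: pd.DataFrame  # index treatment: delta, se, p_raw, p_dunnett
    omnibus_chi2: float
    omnibus_p: float
    converged: bool
    country_multipliers: dict

    def summary(self) -> str:
        head = (
            f"Functional category {self.category} ({self.level}); "
            f"omnibus treatment p = {self.omnibus_p:.4g}"
            if self.converged
            else f"Functional category {self.category}: model did not converge"
        )
        parts = [head]
        if self.converged:
            parts += ["impacts (S1 displacement):", self.impacts.round(5).to_string(),
                      "slopes (per day):", self.slopes.round(6).to_string()]
        return "\n".join(parts)


class FunctionLMM:
    """Mixed model for one functional category.

    Observations are the transformed proportions of the category's member
    proteins in every metagenome sample; random intercepts cover country,
    site, every sub-level of the hierarchy strictly between the modelled
    level and protein, and protein itself (levels with a single member
    collapse out).  Per-country residual variance multipliers are estimated
    from residual magnitudes in two reweighting passes.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        metadata: pd.DataFrame,
        hierarchy: pd.DataFrame,
        category: str,
        level: str = "level1",
        weight_iterations: int = 2,
        dunnett_draws: int = 200_000,
        seed: int = 0,
    ):
        if level not in _LEVELS:
            raise ValueError(f"unknown level {level!r}")
        members = hierarchy[hierarchy[level] == category]
        if members.empty:
            raise ValueError(f"unknown category {category!r} at {level}")
        meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
        meta = meta.loc[meta.index.intersection(table.index)]
        meta = meta[meta["treatment"].notna()]
        lib = table.loc[meta.index].sum(axis=1).to_numpy(dtype=float)

        sub_levels = [
            lv for lv in _LEVELS[_LEVELS.index(level) + 1 :]
            if members[lv].nunique() > 1
        ]
        rows = []
        for j, protein in enumerate(members["protein"]):
            y = np.arcsin(
                np.sqrt(table.loc[meta.index, protein].to_numpy(dtype=float) / lib)
            )
            block = {
                "y": y,
                "treatment": meta["treatment"].to_numpy(),
                "day": meta["day"].to_numpy(dtype=float),
                "country": meta["country"].to_numpy(),
                "site": meta["site"].to_numpy(),
            }
            for lv in sub_levels:
                block[lv] = members.iloc[j][lv]
            rows.append(pd.DataFrame(block))
        self.data = pd.concat(rows, ignore_index=True)
        self.sub_levels = sub_levels
        self.category = category
        self.level = level
        self.weight_iterations = weight_iterations
        self.dunnett_draws = dunnett_draws
        self.seed = seed
        self.treatments = sorted(
            t for t in self.data["treatment"].unique() if t != "control"
        )

    def _fit_once(self, w: np.ndarray):
        d = self.data
        inv_w = 1.0 / w
        frame = pd.DataFrame({"inv_w": inv_w})
        xcols = ["x_int"]
        frame["x_int"] = inv_w
        for t in self.treatments:
            frame[f"imp_{t}"] = (d["treatment"] == t).to_numpy(dtype=float) * inv_w
            xcols.append(f"imp_{t}")
        frame["x_day"] = d["day"].to_numpy() * inv_w
        xcols.append("x_day")
        for t in self.treatments:
            frame[f"slp_{t}"] = (
                (d["treatment"] == t).to_numpy(dtype=float) * d["day"].to_numpy() * inv_w
            )
            xcols.append(f"slp_{t}")
        frame["ystar"] = d["y"].to_numpy() * inv_w
        for col in ("country", "site", *self.sub_levels):
            frame[col] = d[col].to_numpy()
        vc = {"country": "0 + C(country):inv_w", "site": "0 + C(site):inv_w"}
        for lv in self.sub_levels:
            vc[lv] = f"0 + C({lv}):inv_w"
        formula = "ystar ~ 0 + " + " + ".join(xcols)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = MixedLM.from_formula(
                formula, frame, groups=np.ones(len(frame)), vc_formula=vc
            )
            res = model.fit(reml=True, method="lbfgs", maxiter=500)
            if not res.converged:  # quasi-Newton can stall near a boundary
                res = model.fit(reml=True, method="powell", maxiter=400)
        return res, xcols

    def fit(self) -> FunctionLMMResults:
        d = self.data
        w = np.ones(len(d))
        mult: dict = {}
        try:
            for it in range(self.weight_iterations + 1):
                res, xcols = self._fit_once(w)
                if it < self.weight_iterations:
                    resid = np.asarray(res.resid) * w
                    by_country = (
                        pd.Series(np.abs(resid)).groupby(d["country"].to_numpy()).mean()
                    )
                    m = (by_country / by_country.mean()).clip(0.25, 4.0)
                    mult = m.to_dict()
                    w = d["country"].map(m).to_numpy()
        except (np.linalg.LinAlgError, ValueError):
            empty = pd.DataFrame(
                index=self.treatments, columns=["delta", "se", "p_raw", "p_dunnett"],
                dtype=float,
            )
            return FunctionLMMResults(
                self.category, self.level, empty, empty.copy(), np.nan, np.nan, False, {}
            )
        params = pd.Series(np.asarray(res.fe_params), index=xcols)
        bse = pd.Series(np.asarray(res.bse_fe), index=xcols)
        cov = pd.DataFrame(
            np.asarray(res.cov_params())[: len(xcols), : len(xcols)],
            index=xcols, columns=xcols,
        )
        converged = bool(res.converged) and np.isfinite(bse.to_numpy()).all()
        df_resid = max(len(d) - len(xcols), 1)

        def block(prefix: str, offset: int) -> pd.DataFrame:
            names = [f"{prefix}_{t}" for t in self.treatments]
            est = params[names].to_numpy()
            c = cov.loc[names, names].to_numpy()
            se = bse[names].to_numpy()
            p_raw = 2 * stats.t.sf(np.abs(est / se), df_resid)
            adj = dunnett_adjust(
                est, c, df=df_resid, n_draws=self.dunnett_draws,
                seed=self.seed + offset,
            )
            return pd.DataFrame(
                {"delta": est, "se": se, "p_raw": p_raw, "p_dunnett": adj},
                index=pd.Index(self.treatments, name="treatment"),
            )

        impacts = block("imp", 1)
        slopes = block("slp", 2)
        imp_names = [f"imp_{t}" for t in self.treatments]
        est = params[imp_names].to_numpy()
        cinv = np.linalg.pinv(cov.loc[imp_names, imp_names].to_numpy())
        chi2_stat = float(est @ cinv @ est)
        omnibus_p = float(stats.chi2.sf(chi2_stat, df=len(est)))
        return FunctionLMMResults(
            self.category, self.level, impacts, slopes, chi2_stat, omnibus_p,
            converged, mult,
        )


def fit_function_model(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    hierarchy: pd.DataFrame,
    category: str,
    level: str = "level1",
    **kwargs,
) -> FunctionLMMResults:
    return FunctionLMM(table, metadata, hierarchy, category, level, **kwargs).fit()


def functional_impact_table(
    fits: list[FunctionLMMResults], alpha: float = 0.05
) -> pd.DataFrame:
    """Per category x treatment summary: displacement, SE, Dunnett p,
    BH-FDR-adjusted omnibus q (across the categories of the level), and a
    direction flag (up/down when Dunnett p <= alpha and omnibus q <= alpha,
    else ns).  Non-converged categories appear with converged=False."""
    ok = [f for f in fits if f.converged]
    q_by_cat = {}
    if ok:
        qs = bh_fdr([f.omnibus_p for f in ok])
        q_by_cat = {f.category: q for f, q in zip(ok, qs)}
    rows = []
    for f in fits:
        for t in f.impacts.index:
            row = f.impacts.loc[t]
            q = q_by_cat.get(f.category, np.nan)
            if not f.converged or not np.isfinite(row["delta"]):
                direction = "failed"
            elif row["p_dunnett"] <= alpha and q <= alpha:
                direction = "up" if row["delta"] > 0 else "down"
            else:
                direction = "ns"
            rows.append(
                {
                    "category": f.category,
                    "level": f.level,
                    "treatment": t,
                    "delta": row["delta"],
                    "se": row["se"],
                    "p_dunnett": row["p_dunnett"],
                    "q_omnibus": q,
                    "direction": direction,
                    "converged": f.converged,
                }
            )
    return pd.DataFrame(rows)


def count_significant_by_parent(
    impact_table: pd.DataFrame, hierarchy: pd.DataFrame, parent_level: str = "level1"
) -> pd.DataFrame:
    """Number of significantly responding members per higher-level category.

    ``impact_table`` comes from :func:`functional_impact_table` computed at a
    level below ``parent_level`` (typically protein); a member counts when
    its direction is up or down.  Returns parent x treatment counts.
    """
    child_level = impact_table["level"].iloc[0]
    if child_level == parent_level:
        raise ValueError("impact table is already at the parent level")
    parent_of = hierarchy.drop_duplicates(child_level).set_index(child_level)[
        parent_level
    ]
    tab = impact_table.copy()
    tab["parent"] = tab["category"].map(parent_of)
    sig = tab[tab["direction"].isin(["up", "down"])]
    out = (
        sig.groupby(["parent", "treatment"]).size().rename("n_significant").reset_index()
    )
    return out
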