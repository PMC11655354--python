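"""Per-taxon disturbance models and ecological response strategies.

Each taxon's relative abundance across the microcosms is modelled with a
linear mixed-effects model

    y ~ treatment + day + treatment:day,   random intercepts: country, site

where y is relative abundance (count over un-rarefied library size), the
treatment coefficients are displacements from control at S1 (day 0 is the
end of the disturbance) and the treatment:day coefficients are recovery
slopes.  Residual heteroscedasticity is handled by an iteratively estimated
variance function: residual SD = (a + b / sqrt(library size)) times a
per-sampling multiplier, folded into the fit as row weights.

The sign and Wald significance (two-tailed, alpha = 0.05, uncorrected) of
the displacement and slope coefficients classify each taxon x treatment into
a response-strategy grid: significantly impacted taxa are stable, resilient
(slope opposing the impact) or diverging (slope reinforcing it); unimpacted
taxa with a significant slope are late responders; taxa with neither are
fully resistant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "TaxonLMM",
    "TaxonLMMResults",
    "StrategyCall",
    "classify_strategy",
    "fit_all_taxa",
    "strategy_census",
    "STRATEGY_LABELS",
]

STRATEGY_LABELS = (
    "positive impact, stable",
    "positive impact, resilient",
    "positive impact, diverging",
    "negative impact, stable",
    "negative impact, resilient",
    "negative impact, diverging",
    "late positive",
    "late negative",
    "fully resistant",
    "model failed",
)


@dataclass(frozen=True)
class StrategyCall:
    taxon_id: str
    treatment: str
    impact: str  # negative | none | positive
    dynamics: str  # stable | resilient | diverging | late_positive | late_negative | none
    label: str
    converged: bool


@dataclass
class TaxonLMMResults:
    """Per-treatment displacement (beta) and slope estimates for one taxon."""

    taxon_id: str
    coef: pd.DataFrame  # index treatment; beta, se, p, slope, slope_se, slope_p
    converged: bool
    random_effects_used: bool
    variance_function: dict
    alpha: float = 0.05

    def classify(self, treatment: str, alpha: float | None = None) -> StrategyCall:
        alpha = self.alpha if alpha is None else alpha
        if not self.converged or treatment not in self.coef.index:
            return StrategyCall(self.taxon_id, treatment, "none", "none",
                                "model failed", False)
        row = self.coef.loc[treatment]
        return classify_strategy(
            self.taxon_id, treatment,
            row["beta"], row["p"], row["slope"], row["slope_p"], alpha,
        )

    def summary(self) -> str:
        lines = [f"Taxon response model: {self.taxon_id} "
                 f"({'converged' if self.converged else 'NOT converged'})"]
        if self.converged:
            lines.append(self.coef.round(5).to_string())
        return "\n".join(lines)


def classify_strategy(
    taxon_id: str,
    treatment: str,
    beta: float,
    p_beta: float,
    slope: float,
    p_slope: float,
    alpha: float = 0.05,
) -> StrategyCall:
    """Deterministic mapping from coefficient signs/significance to the
    strategy grid (total over all sign x significance combinations)."""
    impacted = p_beta <= alpha
    sloped = p_slope <= alpha
    if impacted:
        impact = "positive" if beta > 0 else "negative"
        if not sloped:
            dynamics = "stable"
        elif np.sign(slope) == np.sign(beta):
            dynamics = "diverging"
        else:
            dynamics = "resilient"
        label = f"{impact} impact, {dynamics}"
    else:
        impact = "none"
        if sloped:
            dynamics = "late_positive" if slope > 0 else "late_negative"
            label = dynamics.replace("_", " ")
        else:
            dynamics = "none"
            label = "fully resistant"
    return StrategyCall(taxon_id, treatment, impact, dynamics, label, True)


class TaxonLMM:
    """Mixed model for one taxon's relative abundance.

    Parameters
    ----------
    table : DataFrame
        Samples x taxa counts (un-rarefied).
    metadata : DataFrame
        Sample table with sample_id, country, site, treatment, sampling, day;
        initial samples (treatment NA) are excluded from the fit.
    taxon_id : str
    depth_variance : bool
        Estimate the depth/sampling variance function (two reweighting
        passes); disable for the homoscedastic closed-form limit.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        metadata: pd.DataFrame,
        taxon_id: str,
        alpha: float = 0.05,
        depth_variance: bool = True,
        weight_iterations: int = 2,
    ):
        if taxon_id not in table.columns:
            raise KeyError(f"taxon {taxon_id!r} not in table")
        meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
        meta = meta.loc[meta.index.intersection(table.index)]
        meta = meta[meta["treatment"].notna()]
        self.taxon_id = taxon_id
        self.alpha = alpha
        self.depth_variance = depth_variance
        self.weight_iterations = weight_iterations if depth_variance else 0

        depth = table.loc[meta.index].sum(axis=1).to_numpy(dtype=float)
        frame = pd.DataFrame(
            {
                "y": table.loc[meta.index, taxon_id].to_numpy(dtype=float) / depth,
                "treatment": meta["treatment"].to_numpy(),
                "day": meta["day"].to_numpy(dtype=float),
                "sampling": meta["sampling"].to_numpy(),
                "country": meta["country"].to_numpy(),
                "site": meta["site"].to_numpy(),
                "depth": depth,
            }
        )
        self.frame = frame.reset_index(drop=True)
        self.treatments = sorted(t for t in frame["treatment"].unique() if t != "control")
        ok_countries = (
            frame.groupby("country")["site"].nunique() >= 2
        )
        self.random_effects_ok = frame["country"].nunique() >= 2 and ok_countries.sum() >= 2

    # -- design ----------------------------------------------------------
    def _design(self) -> tuple[np.ndarray, list[str]]:
        f = self.frame
        cols = [np.ones(len(f))]
        names = ["intercept"]
        for t in self.treatments:
            cols.append((f["treatment"] == t).to_numpy(dtype=float))
            names.append(f"impact[{t}]")
        cols.append(f["day"].to_numpy())
        names.append("day")
        for t in self.treatments:
            cols.append((f["treatment"] == t).to_numpy(dtype=float) * f["day"].to_numpy())
            names.append(f"slope[{t}]")
        return np.column_stack(cols), names

    def _fit_once(self, x, names, w):
        """One weighted fit; rows scaled by 1/w so residual variance is
        proportional to w^2, with random-effect designs scaled alike (an
        exact reparametrization of the heteroscedastic model)."""
        f = self.frame
        inv_w = 1.0 / w
        data = pd.DataFrame(x * inv_w[:, None], columns=[f"x{i}" for i in range(x.shape[1])])
        data["ystar"] = f["y"].to_numpy() * inv_w
        data["inv_w"] = inv_w
        data["site"] = f["site"].to_numpy()
        data["country"] = f["country"].to_numpy()
        formula = "ystar ~ 0 + " + " + ".join(data.columns[: x.shape[1]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            if self.random_effects_ok:
                model = MixedLM.from_formula(
                    formula,
                    data,
                    groups="country",
                    re_formula="0 + inv_w",
                    vc_formula={"site": "0 + C(site):inv_w"},
                )
            else:
                model = MixedLM.from_formula(
                    formula, data, groups=np.ones(len(data)), re_formula="0 + inv_w"
                )
            res = model.fit(reml=True, method="lbfgs", maxiter=500)
            if not res.converged:  # quasi-Newton can stall near a boundary
                res = model.fit(reml=True, method="powell", maxiter=400)
        return res

    def _variance_weights(self, resid: np.ndarray) -> tuple[np.ndarray, dict]:
        f = self.frame
        a_b, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(f)), 1.0 / np.sqrt(f["depth"].to_numpy())]),
            np.abs(resid),
            rcond=None,
        )
        floor = 0.05 * np.abs(resid).mean() + 1e-12
        sd = np.maximum(
            a_b[0] + a_b[1] / np.sqrt(f["depth"].to_numpy()), floor
        )
        by_sampling = pd.Series(np.abs(resid)).groupby(f["sampling"].to_numpy()).mean()
        ref = by_sampling.get("S1", by_sampling.iloc[0])
        mult = (by_sampling / max(ref, 1e-12)).clip(0.25, 4.0)
        w = sd * f["sampling"].map(mult).to_numpy()
        w = w / w.mean()
        return w, {
            "a": float(a_b[0]),
            "b": float(a_b[1]),
            "sampling_multipliers": mult.to_dict(),
        }

    # -- public ----------------------------------------------------------
    def fit(self) -> TaxonLMMResults:
        f = self.frame
        empty_coef = pd.DataFrame(
            index=self.treatments,
            columns=["beta", "se", "p", "slope", "slope_se", "slope_p"],
            dtype=float,
        )
        if len(f) == 0 or float(np.var(f["y"])) == 0.0:
            return TaxonLMMResults(
                self.taxon_id, empty_coef, False, False, {}, self.alpha
            )
        x, names = self._design()
        w = np.ones(len(f))
        vf: dict = {}
        res = None
        try:
            for it in range(self.weight_iterations + 1):
                res = self._fit_once(x, names, w)
                if it < self.weight_iterations:
                    resid = np.asarray(res.resid) * w  # back to the raw scale
                    w, vf = self._variance_weights(resid)
        except (np.linalg.LinAlgError, ValueError):
            return TaxonLMMResults(
                self.taxon_id, empty_coef, False, self.random_effects_ok, {}, self.alpha
            )
        params = np.asarray(res.fe_params)
        bse = np.asarray(res.bse_fe)
        pvals = np.asarray(res.pvalues)[: len(params)]
        ok = bool(res.converged) and np.isfinite(bse).all() and (bse > 0).all()
        if not ok:
            return TaxonLMMResults(
                self.taxon_id, empty_coef, False, self.random_effects_ok, vf, self.alpha
            )
        by_name = {n: (params[i], bse[i], pvals[i]) for i, n in enumerate(names)}
        coef = pd.DataFrame(
            {
                "beta": [by_name[f"impact[{t}]"][0] for t in self.treatments],
                "se": [by_name[f"impact[{t}]"][1] for t in self.treatments],
                "p": [by_name[f"impact[{t}]"][2] for t in self.treatments],
                "slope": [by_name[f"slope[{t}]"][0] for t in self.treatments],
                "slope_se": [by_name[f"slope[{t}]"][1] for t in self.treatments],
                "slope_p": [by_name[f"slope[{t}]"][2] for t in self.treatments],
            },
            index=pd.Index(self.treatments, name="treatment"),
        )
        return TaxonLMMResults(
            self.taxon_id, coef, True, self.random_effects_ok, vf, self.alpha
        )


def fit_all_taxa(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    taxa: list[str] | None = None,
    alpha: float = 0.05,
    depth_variance: bool = True,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Fit every (or the ``top_n`` most abundant) taxa; one row per taxon x
    treatment with displacement/slope estimates and the convergence flag."""
    if taxa is None:
        taxa = list(table.columns)
        if top_n is not None:
            order = table.sum(axis=0).sort_values(ascending=False)
            taxa = order.index[:top_n].tolist()
    rows = []
    for taxon in taxa:
        res = TaxonLMM(table, metadata, taxon, alpha=alpha, depth_variance=depth_variance).fit()
        if res.converged:
            for t, row in res.coef.iterrows():
                rows.append({"taxon": taxon, "treatment": t, **row.to_dict(),
                             "converged": True})
        else:
            for t in sorted(set(metadata["treatment"].dropna()) - {"control"}):
                rows.append({"taxon": taxon, "treatment": t, "beta": np.nan,
                             "se": np.nan, "p": np.nan, "slope": np.nan,
                             "slope_se": np.nan, "slope_p": np.nan,
                             "converged": False})
    return pd.DataFrame(rows)


def calls_from_fits(
    fits: pd.DataFrame, alpha: float = 0.05, fdr: bool = False
) -> list[StrategyCall]:
    """Classify every fitted taxon x treatment.

    ``fdr=True`` applies Benjamini-Hochberg across taxa (within treatment,
    separately for displacement and slope p-values) before thresholding —
    off by default, matching the uncorrected per-taxon convention.
    """
    if fdr:
        from statsmodels.stats.multitest import multipletests

        fits = fits.copy()
        for treatment, idx in fits.groupby("treatment").groups.items():
            for col in ("p", "slope_p"):
                ok = fits.loc[idx, col].notna()
                if ok.any():
                    fits.loc[idx[ok], col] = multipletests(
                        fits.loc[idx[ok], col], method="fdr_bh"
                    )[1]
    calls = []
    for _, r in fits.iterrows():
        if not r["converged"]:
            calls.append(StrategyCall(r["taxon"], r["treatment"], "none", "none",
                                      "model failed", False))
        else:
            calls.append(
                classify_strategy(r["taxon"], r["treatment"], r["beta"], r["p"],
                                  r["slope"], r["slope_p"], alpha)
            )
    return calls


def strategy_census(calls: list[StrategyCall]) -> pd.DataFrame:
    """Counts and proportions of each strategy per treatment.

    Proportions are over converged calls; model failures are tallied in a
    separate row with NaN proportion.
    """
    if not calls:
        raise ValueError("no strategy calls to summarize")
    df = pd.DataFrame(
        {
            "treatment": [c.treatment for c in calls],
            "label": [c.label for c in calls],
            "converged": [c.converged for c in calls],
        }
    )
    rows = []
    for treatment, sub in df.groupby("treatment"):
        ok = sub[sub["converged"]]
        counts = ok["label"].value_counts()
        for label in STRATEGY_LABELS[:-1]:
            c = int(counts.get(label, 0))
            rows.append(
                {
                    "treatment": treatment,
                    "strategy": label,
                    "count": c,
                    "proportion": c / len(ok) if len(ok) else np.nan,
                }
            )
        rows.append(
            {
                "treatment": treatment,
                "strategy": "model failed",
                "count": int((~sub["converged"]).sum()),
                "proportion": np.nan,
            }
        )
    return pd.DataFrame(rows)
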