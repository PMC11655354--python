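"""Synthetic site covariates, the true resistance surface, and soil-function
measurements.

Covariates mimic the 20 initial soil/climate properties used by the
predictive model: four temperature variables, four precipitation variables,
eight carbon/nitrogen variables, three water-holding variables, and pH.
Properties are drawn at site level with a country-level shared component
(sites of one country resemble each other) and within-group correlation (the
four temperature variables track a common latent climate factor, etc.).

The true resistance surface is what the predictive model must recover: a
stated deterministic function of the covariates — by default linear terms
plus one interaction, with the heat-resistance term increasing in the
mean-annual-temperature analogue (warm-origin soils withstand heat better) —
plus Gaussian noise.

Soil-function measurements (4 enzyme activities, 8 substrate-induced
respiration rates, 4 C/N pools, 3 greenhouse-gas fluxes) are a linear map of
the functional-category composition plus noise, so a Mantel test between the
two blocks has a planted positive signal whenever loadings are nonzero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "PROPERTY_GROUPS",
    "MEASUREMENT_FAMILIES",
    "property_names",
    "default_effect_map",
    "simulate_covariates",
    "simulate_soil_functions",
    "make_loading_matrix",
]

PROPERTY_GROUPS = {"temperature": 4, "precipitation": 4, "carbon_nitrogen": 8,
                   "water_holding": 3, "ph": 1}

MEASUREMENT_FAMILIES = {"enzyme": 4, "substrate_use": 8, "carbon_nitrogen": 4,
                        "gas_flux": 3}


def property_names() -> list[str]:
    names = []
    for group, count in PROPERTY_GROUPS.items():
        if count == 1:
            names.append(group)
        else:
            names.extend(f"{group}_{i + 1}" for i in range(count))
    return names


def default_effect_map() -> dict:
    """Linear coefficients (per treatment, on standardized properties) plus
    one interaction driving the true resistance surface.  heat depends
    positively on temperature_1 (the mean-annual-temperature analogue),
    drought on precipitation_1, and one temperature x water-holding
    interaction is included."""
    return {
        "heat": {"temperature_1": 0.6, "carbon_nitrogen_1": 0.2},
        "drought": {"precipitation_1": -0.4, "water_holding_1": 0.3},
        "flood": {"water_holding_2": -0.3, "precipitation_2": 0.2},
        "freeze": {"temperature_2": -0.4},
        "interactions": [("heat", "temperature_1", "water_holding_1", 0.2)],
    }


def simulate_covariates(
    metadata: pd.DataFrame,
    effect_map: dict | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    country_share: float = 0.5,
    group_corr: float = 0.5,
    samplings: tuple[str, ...] = ("S1", "S4"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Site-level covariate table and the true resistance/resilience surface.

    Returns ``(covariates, truth)``: covariates indexed by site with exactly
    20 property columns; truth has one row per (site, treatment, sampling)
    with the noiseless deterministic response plus Gaussian noise of sd
    ``noise_sd`` (``noise_sd=0`` gives the exact surface).
    """
    if effect_map is None:
        effect_map = default_effect_map()
    names = property_names()
    if len(names) != 20:  # pragma: no cover - structural guard
        raise ValueError("expected exactly 20 properties")
    rng = np.random.default_rng(seed)

    site_meta = (
        metadata[["country", "site"]].drop_duplicates().sort_values(["country", "site"])
    )
    sites = site_meta["site"].tolist()
    countries = site_meta["country"].tolist()
    uniq_countries = sorted(set(countries))

    values = np.empty((len(sites), 20))
    col = 0
    for group, count in PROPERTY_GROUPS.items():
        country_latent = {c: rng.standard_normal() for c in uniq_countries}
        site_latent = np.array(
            [
                np.sqrt(country_share) * country_latent[c]
                + np.sqrt(1 - country_share) * rng.standard_normal()
                for c in countries
            ]
        )
        for _ in range(count):
            own = rng.standard_normal(len(sites))
            values[:, col] = np.sqrt(group_corr) * site_latent + np.sqrt(1 - group_corr) * own
            col += 1
    covariates = pd.DataFrame(values, index=pd.Index(sites, name="site"), columns=names)

    z = (covariates - covariates.mean()) / covariates.std(ddof=1)
    treatments = sorted(
        t for t in metadata["treatment"].dropna().unique() if t != "control"
    )
    rows = []
    for treatment in treatments:
        lin = np.zeros(len(sites))
        for prop, coef in effect_map.get(treatment, {}).items():
            lin = lin + coef * z[prop].to_numpy()
        for t2, p1, p2, coef in effect_map.get("interactions", []):
            if t2 == treatment:
                lin = lin + coef * z[p1].to_numpy() * z[p2].to_numpy()
        for sampling in samplings:
            # resilience (later sampling) relaxes toward 0: communities recover
            scale = 1.0 if sampling == samplings[0] else 0.6
            noiseless = scale * lin
            noisy = noiseless + rng.normal(0.0, noise_sd, len(sites))
            for site, mu, y in zip(sites, noiseless, noisy):
                rows.append(
                    {
                        "site": site,
                        "treatment": treatment,
                        "sampling": sampling,
                        "true_response": mu,
                        "response": y,
                    }
                )
    truth = pd.DataFrame(rows)
    return covariates, truth


def make_loading_matrix(
    categories: list[str], seed: int = 0, density: float = 0.5, scale: float = 1.0
) -> pd.DataFrame:
    """Random sparse loadings mapping functional categories to the 19
    soil-function measurements (columns grouped 4/8/4/3)."""
    rng = np.random.default_rng(seed)
    cols = []
    for family, count in MEASUREMENT_FAMILIES.items():
        cols.extend(f"{family}_{i + 1}" for i in range(count))
    load = rng.normal(0.0, scale, (len(categories), len(cols)))
    load *= rng.random((len(categories), len(cols))) < density
    return pd.DataFrame(load, index=categories, columns=cols)


def simulate_soil_functions(
    functional_table: pd.DataFrame,
    loading: pd.DataFrame,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Measurements = (per-sample category proportions) @ loading + noise.

    ``loading`` rows must match the functional table's columns exactly; its
    19 columns are the measured variables (4 enzymes, 8 substrate-use, 4
    C/N, 3 gas fluxes).
    """
    if list(loading.index) != list(functional_table.columns):
        raise ValueError("loading matrix rows must match functional categories")
    if loading.shape[1] != sum(MEASUREMENT_FAMILIES.values()):
        raise ValueError(
            f"loading matrix must have {sum(MEASUREMENT_FAMILIES.values())} columns"
        )
    rng = np.random.default_rng(seed)
    counts = functional_table.to_numpy(dtype=float)
    props = counts / counts.sum(axis=1, keepdims=True)
    meas = props @ loading.to_numpy() + rng.normal(
        0.0, noise_sd, (len(functional_table), loading.shape[1])
    )
    return pd.DataFrame(meas, index=functional_table.index, columns=loading.columns)
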