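"""Factorial microcosm experimental design and cross-validation split spaces.

The study design is a full factorial: soils from ``n`` countries, three
replicate sites per country, each site's soil split across five climatic
treatments (control, drought, flood, freeze, heat) and destructively sampled
at four times (S1 = end of disturbance, then 1, 8 and 26 days after).  At the
default scale that is 10 x 3 x 5 x 4 = 600 microcosms, plus one "initial"
(pre-treatment) sample per site.

Exclusion rules are declarative data, not code: the default set drops the ten
Russian S2 microcosms (insufficient soil) for every assay and the two Spanish
sites ES1/ES3 for sequencing assays (low DNA yield).

Cross-validation split spaces for the predictive model are enumerated here:
site-level splits (one of the three sites per country held out; 3^k splits
for k complete countries) and country-level splits (all subsets of size
``n_train`` held in).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import pandas as pd
import yaml

__all__ = [
    "TreatmentSpec",
    "SamplingSpec",
    "ExclusionRule",
    "ExperimentDesign",
    "SampleRecord",
    "DEFAULT_TREATMENTS",
    "DEFAULT_SAMPLINGS",
    "DEFAULT_COUNTRIES",
    "DEFAULT_EXCLUSIONS",
    "ASSAYS",
    "build_design",
    "apply_exclusions",
    "enumerate_site_splits",
    "enumerate_country_splits",
    "design_from_yaml",
    "records_to_frame",
]

ASSAYS = ("amplicon", "metagenome", "soil_function")


class DesignError(ValueError):
    """Invalid experimental-design specification."""


@dataclass(frozen=True)
class TreatmentSpec:
    """A climatic treatment: incubation temperature (degC) and soil moisture
    (% of water-holding capacity)."""

    name: str
    temperature: float
    moisture: float


@dataclass(frozen=True)
class SamplingSpec:
    """A destructive-harvest time, in days after the end of the disturbance."""

    label: str
    days_after_disturbance: int


DEFAULT_TREATMENTS = (
    TreatmentSpec("control", 18.0, 60.0),
    TreatmentSpec("drought", 18.0, 10.0),
    TreatmentSpec("flood", 18.0, 100.0),
    TreatmentSpec("freeze", -20.0, 60.0),
    TreatmentSpec("heat", 35.0, 60.0),
)

DEFAULT_SAMPLINGS = (
    SamplingSpec("S1", 0),
    SamplingSpec("S2", 1),
    SamplingSpec("S3", 8),
    SamplingSpec("S4", 26),
)

DEFAULT_COUNTRIES = ("AT", "DE", "EE", "ES", "FR", "GR", "IE", "RU", "SE", "UK")


@dataclass(frozen=True)
class ExclusionRule:
    """Drop design cells matching every non-None field.

    ``assay=None`` matches all assays, and likewise for the other fields, so
    e.g. ``ExclusionRule(country="RU", sampling="S2")`` removes all Russian S2
    microcosms from every assay.
    """

    country: str | None = None
    site: str | None = None
    treatment: str | None = None
    sampling: str | None = None
    assay: str | None = None

    def matches(self, rec: "SampleRecord") -> bool:
        return (
            (self.country is None or rec.country == self.country)
            and (self.site is None or rec.site == self.site)
            and (self.treatment is None or rec.treatment == self.treatment)
            and (self.sampling is None or rec.sampling == self.sampling)
            and (self.assay is None or rec.assay == self.assay)
        )


# Ten Russian S2 microcosms (two sites x five treatments; all assays) and the
# Spanish sites 1 and 3 for sequencing assays.  Which two of the three Russian
# sites lost their S2 pots is not on record; the first two are used so that the
# arithmetic (600 - 10 = 590) holds — override via ExperimentDesign.exclusions.
DEFAULT_EXCLUSIONS = (
    ExclusionRule(country="RU", site="RU1", sampling="S2"),
    ExclusionRule(country="RU", site="RU2", sampling="S2"),
    ExclusionRule(country="ES", site="ES1", assay="amplicon"),
    ExclusionRule(country="ES", site="ES3", assay="amplicon"),
    ExclusionRule(country="ES", site="ES1", assay="metagenome"),
    ExclusionRule(country="ES", site="ES3", assay="metagenome"),
)


@dataclass(frozen=True)
class SampleRecord:
    """One physical sample: a microcosm harvest, or a pre-treatment (initial)
    soil sample when ``treatment`` and ``sampling`` are None."""

    sample_id: str
    country: str
    site: str
    treatment: str | None
    sampling: str | None
    day: int | None
    assay: str

    @property
    def is_initial(self) -> bool:
        return self.treatment is None


@dataclass
class ExperimentDesign:
    countries: tuple[str, ...]
    sites_per_country: dict[str, tuple[str, ...]]
    treatments: tuple[TreatmentSpec, ...] = DEFAULT_TREATMENTS
    samplings: tuple[SamplingSpec, ...] = DEFAULT_SAMPLINGS
    exclusions: tuple[ExclusionRule, ...] = ()
    _records: list[SampleRecord] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        tnames = [t.name for t in self.treatments]
        if len(set(tnames)) != len(tnames):
            raise DesignError("duplicate treatment names")
        slabels = [s.label for s in self.samplings]
        if len(set(slabels)) != len(slabels):
            raise DesignError("duplicate sampling labels")
        days = [s.days_after_disturbance for s in self.samplings]
        if days != sorted(days) or len(set(days)) != len(days):
            raise DesignError("sampling days must be strictly increasing")

    @property
    def day_of(self) -> dict[str, int]:
        return {s.label: s.days_after_disturbance for s in self.samplings}

    def microcosm_records(self, assay: str = "amplicon") -> list[SampleRecord]:
        return [r for r in self._records if r.assay == assay and not r.is_initial]

    def initial_records(self, assay: str = "amplicon") -> list[SampleRecord]:
        return [r for r in self._records if r.assay == assay and r.is_initial]

    def records(self, assay: str = "amplicon") -> list[SampleRecord]:
        return [r for r in self._records if r.assay == assay]


def build_design(
    n_countries: int = 10,
    n_sites: int = 3,
    treatments: tuple[TreatmentSpec, ...] = DEFAULT_TREATMENTS,
    samplings: tuple[SamplingSpec, ...] = DEFAULT_SAMPLINGS,
    countries: tuple[str, ...] | None = None,
    assays: tuple[str, ...] = ASSAYS,
) -> ExperimentDesign:
    """Build the factorial design and all sample records.

    Returns an :class:`ExperimentDesign` whose records comprise one microcosm
    per (country, site, treatment, sampling) cell and one initial sample per
    site, replicated across assays.  Sample ids are deterministic
    ``country_site_treatment_sampling`` concatenations so that re-runs are
    bit-identical.
    """
    if n_countries < 1 or n_sites < 1 or not treatments or not samplings:
        raise DesignError("counts must be >= 1")
    if countries is None:
        if n_countries <= len(DEFAULT_COUNTRIES):
            countries = DEFAULT_COUNTRIES[:n_countries]
        else:
            countries = tuple(f"C{i:02d}" for i in range(n_countries))
    elif len(countries) != n_countries:
        raise DesignError("countries list length disagrees with n_countries")

    sites_per_country = {c: tuple(f"{c}{j + 1}" for j in range(n_sites)) for c in countries}

    design = ExperimentDesign(
        countries=tuple(countries),
        sites_per_country=sites_per_country,
        treatments=tuple(treatments),
        samplings=tuple(samplings),
    )
    day_of = design.day_of
    records: list[SampleRecord] = []
    for assay in assays:
        for c in countries:
            for site in sites_per_country[c]:
                records.append(
                    SampleRecord(f"{site}_initial_{assay}", c, site, None, None, None, assay)
                )
                for t in treatments:
                    for s in samplings:
                        records.append(
                            SampleRecord(
                                f"{site}_{t.name}_{s.label}_{assay}",
                                c,
                                site,
                                t.name,
                                s.label,
                                day_of[s.label],
                                assay,
                            )
                        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):  # pragma: no cover - defensive
        raise DesignError("sample ids collide")
    design._records = records
    return design


def apply_exclusions(
    records: list[SampleRecord], rules: tuple[ExclusionRule, ...] | list[ExclusionRule]
) -> list[SampleRecord]:
    """Remove records matched by any exclusion rule (idempotent).

    A rule matching zero records emits a warning, not an error: rule sets are
    shared across assays and scales and may legitimately be vacuous for one.
    """
    kept = list(records)
    for rule in rules:
        matched = [r for r in kept if rule.matches(r)]
        if not matched:
            warnings.warn(f"exclusion rule matched no records: {rule}", stacklevel=2)
        kept = [r for r in kept if not rule.matches(r)]
    return kept


def _retained_sites(design: ExperimentDesign, assay: str) -> dict[str, list[str]]:
    with warnings.catch_warnings():
        # rule sets span assays; vacuous matches for this assay are expected
        warnings.simplefilter("ignore", UserWarning)
        retained = apply_exclusions(design.records(assay), design.exclusions)
    out: dict[str, list[str]] = {c: [] for c in design.countries}
    for c in design.countries:
        sites = set(r.site for r in retained if r.country == c)
        out[c] = sorted(sites)
    return out


def enumerate_site_splits(
    design: ExperimentDesign, assay: str = "metagenome"
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All held-out-site splits: for every complete country (3 retained
    sites) choose one site for the test set; train on the other two.

    Countries left with fewer than three retained sites after exclusions do
    not enter the split space — their remaining sites join every training set
    and never appear in a test set.  The count is 3**k for k complete
    countries.
    """
    per_country = _retained_sites(design, assay)
    complete = {c: s for c, s in per_country.items() if len(s) == 3}
    extra_train = [s for c, sites in per_country.items() if len(sites) < 3 for s in sites]
    if not complete:
        raise DesignError("no country retains 3 sites; site-level splits undefined")
    countries = sorted(complete)
    splits = []
    for choice in itertools.product(*(complete[c] for c in countries)):
        test = tuple(choice)
        train = tuple(
            sorted(
                [s for c in countries for s in complete[c] if s not in choice] + extra_train
            )
        )
        splits.append((train, test))
    return splits


def enumerate_country_splits(
    design: ExperimentDesign, n_train: int
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All country-level splits: train on every subset of ``n_train``
    countries, test on the complement.  C(n_countries, n_train) splits."""
    countries = tuple(design.countries)
    if not 1 <= n_train < len(countries):
        raise DesignError(f"n_train must be in [1, {len(countries) - 1}]")
    splits = []
    for train in itertools.combinations(countries, n_train):
        test = tuple(c for c in countries if c not in train)
        splits.append((train, test))
    return splits


def records_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    """Sample metadata as a DataFrame (sample_id, country, site, treatment,
    sampling, day, assay); initial samples carry NA treatment/sampling."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "country": [r.country for r in records],
            "site": [r.site for r in records],
            "treatment": [r.treatment for r in records],
            "sampling": [r.sampling for r in records],
            "day": [r.day for r in records],
            "assay": [r.assay for r in records],
        }
    )


def design_from_yaml(path) -> ExperimentDesign:
    """Load a design (counts, treatments, samplings, exclusions) from YAML."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    treatments = tuple(
        TreatmentSpec(t["name"], t["temperature"], t["moisture"])
        for t in cfg.get("treatments", [t.__dict__ for t in DEFAULT_TREATMENTS])
    )
    samplings = tuple(
        SamplingSpec(s["label"], s["days_after_disturbance"])
        for s in cfg.get(
            "samplings",
            [{"label": s.label, "days_after_disturbance": s.days_after_disturbance}
             for s in DEFAULT_SAMPLINGS],
        )
    )
    design = build_design(
        n_countries=cfg.get("n_countries", 10),
        n_sites=cfg.get("n_sites", 3),
        treatments=treatments,
        samplings=samplings,
    )
    design.exclusions = tuple(
        ExclusionRule(**rule) for rule in cfg.get("exclusions", [])
    )
    known_sites = {s for sites in design.sites_per_country.values() for s in sites}
    for rule in design.exclusions:
        if rule.country is not None and rule.country not in design.countries:
            raise DesignError(f"exclusion references unknown country {rule.country!r}")
        if rule.site is not None and rule.site not in known_sites:
            raise DesignError(f"exclusion references unknown site {rule.site!r}")
    return design
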