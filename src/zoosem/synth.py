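"""Synthetic data with the statistical structure the analysis assumes.

Two levels:

* :func:`simulate_variables` draws institution-level variables directly from
  a standardized linear structural model (a coefficient matrix over named
  variables, exogenous correlation structure, residuals solved so every
  variable has unit total variance). :func:`default_attendance_config` and
  :func:`default_insitu_config` carry the published attendance-model and
  in situ-model direct standardized coefficients.

* :func:`simulate_holdings` builds a species-level holdings table (right-
  skewed log-normal body masses, negative abundance-body-mass relation,
  richness-area scaling, IUCN category mixture, country-level clustering) and
  then generates attendance and in situ project counts by feeding the derived
  composition metrics through the structural equations — so the composition
  module can be exercised end to end.

All draws are reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import HoldingsMatrix
from .exceptions import ConfigError
from .model import PathModelSpec

__all__ = [
    "StructuralConfig",
    "SimulatedVariables",
    "simulate_variables",
    "default_attendance_config",
    "default_insitu_config",
    "ATTENDANCE_EDGES",
    "INSITU_EDGES",
    "HoldingsSimConfig",
    "simulate_holdings",
]


#: Published direct standardized coefficients of the attendance model
#: (outcome, predictor) -> coefficient.
ATTENDANCE_EDGES: dict[tuple[str, str], float] = {
    ("attendance", "total_animals"): 0.587,
    ("attendance", "pop_10km"): 0.444,
    ("attendance", "body_mass"): 0.340,
    ("attendance", "gdp"): 0.163,
    ("attendance", "dissimilarity"): 0.125,
    ("attendance", "mammal_richness"): 0.102,
    ("attendance", "species_richness"): -0.184,
    ("total_animals", "species_richness"): 0.759,
    ("total_animals", "area"): 0.309,
    ("total_animals", "gdp"): -0.136,
    ("total_animals", "body_mass"): -0.157,
    ("species_richness", "mammal_richness"): 0.790,
    ("species_richness", "area"): 0.096,
    ("species_richness", "body_mass"): -0.429,
    ("dissimilarity", "area"): 0.277,
    ("dissimilarity", "body_mass"): -0.593,
}

#: Additional direct coefficients of the in situ model (GDP dropped).
INSITU_EDGES: dict[tuple[str, str], float] = {
    ("in_situ", "attendance"): 0.583,
    ("in_situ", "threatened_prop"): 0.189,
    ("in_situ", "area"): 0.169,
}

_ATTENDANCE_VARIABLES = (
    "body_mass",
    "area",
    "gdp",
    "pop_10km",
    "mammal_richness",
    "species_richness",
    "dissimilarity",
    "total_animals",
    "attendance",
)


@dataclass(frozen=True)
class StructuralConfig:
    """A standardized linear structural model used as a data generator.

    ``edges`` maps (outcome, predictor) to the standardized direct
    coefficient. ``exog_corr`` is the correlation matrix of the exogenous
    variables (identity when omitted — the published tables do not report
    exogenous correlations). Residual variances are solved recursively so
    every variable has unit total variance; a coefficient set that would need
    a negative residual variance is rejected, never rescaled silently.
    """

    variables: tuple[str, ...]
    edges: dict[tuple[str, str], float]
    exog_corr: pd.DataFrame | None = None
    n: int = 458
    n_clusters: int = 58
    seed: int | None = None

    def spec(self) -> PathModelSpec:
        return PathModelSpec(self.variables, tuple(self.edges.keys()))

    def coefficient_matrix(self) -> pd.DataFrame:
        A = pd.DataFrame(
            0.0, index=list(self.variables), columns=list(self.variables)
        )
        for (out, pred), val in self.edges.items():
            A.loc[out, pred] = val
        return A

    def exogenous_correlation(self) -> pd.DataFrame:
        exo = list(self.spec().exogenous)
        if self.exog_corr is None:
            return pd.DataFrame(np.eye(len(exo)), index=exo, columns=exo)
        C = self.exog_corr.loc[exo, exo]
        if not np.allclose(C, C.T):
            raise ConfigError("exogenous correlation matrix must be symmetric")
        if np.linalg.eigvalsh(C.to_numpy()).min() <= 0:
            raise ConfigError("exogenous correlation matrix must be positive definite")
        return C

    def implied_moments(self) -> tuple[pd.DataFrame, pd.Series]:
        """Model-implied covariance (unit variances by construction) and the
        solved residual variances of the endogenous variables."""
        spec = self.spec()
        order = spec.topological_order()
        C = pd.DataFrame(0.0, index=order, columns=order)
        exo_corr = self.exogenous_correlation()
        for a in spec.exogenous:
            for b in spec.exogenous:
                C.loc[a, b] = exo_corr.loc[a, b]
        resid = {}
        done = list(spec.exogenous)
        for v in order:
            if v not in spec.endogenous:
                continue
            parents = list(spec.parents(v))
            a = np.array([self.edges[(v, p)] for p in parents])
            Cpp = C.loc[parents, parents].to_numpy()
            explained = float(a @ Cpp @ a)
            psi = 1.0 - explained
            if psi <= 0:
                raise ConfigError(
                    f"residual variance of {v!r} solves to {psi:.4f} <= 0; "
                    "coefficients incompatible with unit total variance"
                )
            resid[v] = psi
            for w in done:
                cov = float(a @ C.loc[parents, w].to_numpy())
                C.loc[v, w] = C.loc[w, v] = cov
            C.loc[v, v] = 1.0
            done.append(v)
        C = C.loc[list(self.variables), list(self.variables)]
        return C, pd.Series(resid, name="residual_variance")

    def residual_variances(self) -> pd.Series:
        return self.implied_moments()[1]


@dataclass
class SimulatedVariables:
    """Raw (pre-standardization) draws plus a cluster (country) label per row."""

    data: pd.DataFrame
    clusters: pd.Series
    config: StructuralConfig


def simulate_variables(config: StructuralConfig, seed: int | None = None) -> SimulatedVariables:
    """Draw n rows from the structural model.

    Exogenous variables come from the configured correlation structure;
    endogenous variables are built in topological order as their linear
    structural combination plus an independent Gaussian residual with the
    solved variance, so every column has unit population variance.
    """
    seed = seed if seed is not None else config.seed
    rng = np.random.default_rng(seed)
    spec = config.spec()
    _, resid = config.implied_moments()  # validates feasibility
    exo = list(spec.exogenous)
    corr = config.exogenous_correlation().to_numpy()
    L = np.linalg.cholesky(corr)
    draws = pd.DataFrame(
        (rng.standard_normal((config.n, len(exo))) @ L.T), columns=exo
    )
    for v in spec.topological_order():
        if v in draws.columns:
            continue
        parents = list(spec.parents(v))
        a = np.array([config.edges[(v, p)] for p in parents])
        mean = draws[parents].to_numpy() @ a
        draws[v] = mean + rng.normal(0.0, math.sqrt(resid[v]), size=config.n)
    clusters = pd.Series(
        rng.integers(0, config.n_clusters, size=config.n), name="country"
    ).map(lambda i: f"c{i:02d}")
    return SimulatedVariables(draws[list(config.variables)], clusters, config)


def default_attendance_config(n: int = 458, seed: int | None = None) -> StructuralConfig:
    """The attendance-model graph with its published direct standardized
    coefficients (458 institutions, 58 countries)."""
    return StructuralConfig(
        variables=_ATTENDANCE_VARIABLES,
        edges=dict(ATTENDANCE_EDGES),
        n=n,
        n_clusters=58,
        seed=seed,
    )


def default_insitu_config(n: int = 119, seed: int | None = None) -> StructuralConfig:
    """The in situ-model graph: the attendance structure without GDP (the
    published subset covers four countries, too few to support it) plus the
    in situ equation (attendance 0.583, threatened proportion 0.189, area
    0.169)."""
    edges = {
        (out, pred): val
        for (out, pred), val in ATTENDANCE_EDGES.items()
        if pred != "gdp" and out != "gdp"
    }
    edges.update(INSITU_EDGES)
    variables = tuple(
        v for v in _ATTENDANCE_VARIABLES if v != "gdp"
    )
    variables = variables[:1] + ("threatened_prop",) + variables[1:] + ("in_situ",)
    return StructuralConfig(
        variables=variables,
        edges=edges,
        n=n,
        n_clusters=4,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# species-level holdings generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HoldingsSimConfig:
    """Controls for the species-level generator.

    Defaults mirror the study conditions: 458 institutions in 58 countries
    drawing on a pool of 4822 vertebrate species. Body masses are log-normal
    (median ~300 g, broad spread across classes); per-species abundances fall
    with body mass through a negative elasticity; per-institution richness
    scales with area on a power law; IUCN categories follow a fixed mixture.
    """

    n_institutions: int = 458
    n_countries: int = 58
    pool_size: int = 4822
    class_mix: dict = field(
        default_factory=lambda: {
            "Mammalia": 0.25,
            "Aves": 0.45,
            "Reptilia": 0.20,
            "Amphibia": 0.10,
        }
    )
    iucn_probs: dict = field(
        default_factory=lambda: {
            "LC": 0.55,
            "NT": 0.08,
            "VU": 0.10,
            "EN": 0.08,
            "CR": 0.05,
            "DD": 0.04,
            "NE": 0.10,
        }
    )
    mass_meanlog: float = math.log(300.0)   # grams
    mass_sdlog: float = 2.3
    mass_missing_rate: float = 0.12         # species needing taxonomy fallback
    abundance_elasticity: float = -0.20     # d log abundance / d log mass
    abundance_scale: float = 4.0            # mean extra individuals at median mass
    area_meanlog: float = math.log(15.0)    # hectares
    area_sdlog: float = 1.0
    richness_coef: float = 60.0
    richness_exponent: float = 0.25
    richness_noise_sd: float = 0.30
    area_abundance_exponent: float = 0.30   # larger grounds, more individuals/species
    # institutions deviate from the mainstream collection by specialising on
    # small-bodied species: the specialisation strength (>= 0) lowers the mean
    # body mass, raises dissimilarity, and buys extra richness (capacity)
    mass_preference_mean: float = 0.30
    mass_preference_sd: float = 0.25
    mass_richness_tradeoff: float = 1.0
    attendance_meanlog: float = math.log(400_000.0)
    attendance_sdlog: float = 1.0
    insitu_fraction: float = 119 / 458
    insitu_meanlog: float = math.log(12.0)
    insitu_sdlog: float = 0.8
    seed: int | None = None

    def validate(self) -> None:
        for name, probs in (("class_mix", self.class_mix), ("iucn_probs", self.iucn_probs)):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} probabilities must sum to 1")
        max_rich = self.richness_coef * math.exp(
            self.richness_exponent * (self.area_meanlog + 3 * self.area_sdlog)
            + 3 * self.richness_noise_sd
            + self.mass_richness_tradeoff
            * (self.mass_preference_mean + 3 * self.mass_preference_sd)
        )
        if max_rich > self.pool_size:
            raise ConfigError(
                "richness-area scaling can exceed the species pool; "
                "increase pool_size or lower richness_coef"
            )


def _species_pool(cfg: HoldingsSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.pool_size
    classes = rng.choice(
        list(cfg.class_mix), size=n, p=np.array(list(cfg.class_mix.values()))
    )
    iucn = rng.choice(
        list(cfg.iucn_probs), size=n, p=np.array(list(cfg.iucn_probs.values()))
    )
    mass = rng.lognormal(cfg.mass_meanlog, cfg.mass_sdlog, size=n)
    # synthetic taxonomy: ~4 species per genus, ~4 genera per family,
    # ~4 families per order, nested within class
    genus_ids = rng.integers(0, max(n // 4, 1), size=n)
    species = pd.DataFrame(
        {
            "species_id": [f"sp{i:05d}" for i in range(n)],
            "vclass": classes,
            "iucn": iucn,
            "body_mass_g": mass,
        }
    )
    species["genus"] = [f"{c[:3].lower()}_g{g:04d}" for c, g in zip(classes, genus_ids)]
    species["family"] = [f"{c[:3].lower()}_f{g // 4:04d}" for c, g in zip(classes, genus_ids)]
    species["order"] = [f"{c[:3].lower()}_o{g // 16:04d}" for c, g in zip(classes, genus_ids)]
    missing = rng.random(n) < cfg.mass_missing_rate
    # keep at least one known mass per order so the taxonomy fallback always
    # terminates (mirrors a reference compiled at the order level)
    for _, idx in species.groupby("order").groups.items():
        idx = np.asarray(idx)
        if missing[idx].all():
            missing[idx[0]] = False
    species.loc[missing, "body_mass_g"] = np.nan
    return species


def simulate_holdings(
    config: HoldingsSimConfig | None = None,
    structural: StructuralConfig | None = None,
    seed: int | None = None,
) -> tuple[HoldingsMatrix, pd.DataFrame]:
    """Generate a holdings table and an institution covariate table.

    Composition metrics are first realised from the species-level draws; the
    attendance column (and, for a subset of institutions, the in situ project
    count) is then generated from the standardized structural equations of the
    attendance/in situ models applied to those realised metrics, so that the
    full pipeline — metrics, standardization, fitting — can be run end to end
    against a known generating structure. Size-like covariates are written on
    their natural (exponentiated) scale; the pipeline log-transforms them
    back.

    Returns ``(HoldingsMatrix, institutions)`` where ``institutions`` has
    columns ``institution_id, country, attendance, area_ha, gdp,
    national_population, pop_10km, in_situ_projects`` (the last is blank
    outside the in situ subset).
    """
    cfg = config if config is not None else HoldingsSimConfig()
    cfg.validate()
    struct = structural if structural is not None else default_attendance_config()
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)

    species = _species_pool(cfg, rng)
    mass_filled = species["body_mass_g"].to_numpy().copy()
    nan = np.isnan(mass_filled)
    mass_filled[nan] = np.exp(cfg.mass_meanlog)  # selection weight fallback only
    log_rel_mass = np.log(mass_filled) - cfg.mass_meanlog

    n_inst = cfg.n_institutions
    countries = pd.DataFrame(
        {
            "country": [f"c{i:02d}" for i in range(cfg.n_countries)],
            "gdp": rng.lognormal(math.log(5e11), 1.2, size=cfg.n_countries),
            "national_population": rng.lognormal(math.log(3e7), 1.1, size=cfg.n_countries),
        }
    )
    inst = pd.DataFrame(
        {
            "institution_id": [f"zoo{i:04d}" for i in range(n_inst)],
            "country": rng.choice(countries["country"], size=n_inst),
            "area_ha": rng.lognormal(cfg.area_meanlog, cfg.area_sdlog, size=n_inst),
            "pop_10km": rng.lognormal(math.log(8e5), 0.9, size=n_inst),
        }
    ).merge(countries, on="country", how="left")
    inst = inst.set_index("institution_id", drop=False)

    # mainstream institutions sample the pool nearly uniformly (holding the
    # heavy flagship species among everything else); specialists tilt into the
    # numerous small-bodied taxa, making their collections lighter, more
    # distinctive, and — through the capacity trade-off — richer
    preference = -np.clip(
        rng.normal(cfg.mass_preference_mean, cfg.mass_preference_sd, size=n_inst),
        0.0,
        None,
    )
    richness = np.clip(
        np.round(
            cfg.richness_coef
            * inst["area_ha"].to_numpy() ** cfg.richness_exponent
            * np.exp(-cfg.mass_richness_tradeoff * preference)
            * np.exp(rng.normal(0.0, cfg.richness_noise_sd, size=n_inst))
        ).astype(int),
        5,
        cfg.pool_size,
    )
    rel_area = inst["area_ha"].to_numpy() / math.exp(cfg.area_meanlog)

    counts = np.zeros((n_inst, cfg.pool_size), dtype=np.int64)
    for i in range(n_inst):
        w = np.exp(preference[i] * log_rel_mass)
        w /= w.sum()
        chosen = rng.choice(cfg.pool_size, size=richness[i], replace=False, p=w)
        lam = (
            cfg.abundance_scale
            * rel_area[i] ** cfg.area_abundance_exponent
            * np.exp(cfg.abundance_elasticity * log_rel_mass[chosen])
        )
        counts[i, chosen] = 1 + rng.poisson(lam)

    keep = counts.sum(axis=0) > 0
    counts_df = pd.DataFrame(
        counts[:, keep],
        index=inst["institution_id"],
        columns=species["species_id"].to_numpy()[keep],
    )
    holdings = HoldingsMatrix(counts_df, species.set_index("species_id"))

    # derived metrics -> structural equations -> attendance / in situ
    from .composition import compute_profiles, resolve_masses

    resolved = resolve_masses(holdings, species.reset_index(drop=True))
    filled = holdings.species.copy()
    filled["body_mass_g"] = resolved
    holdings = HoldingsMatrix(holdings.counts, filled)
    profiles = compute_profiles(holdings)

    z = {}

    def zscore(x):
        x = np.asarray(x, dtype=float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0.0:
            return np.zeros_like(x)  # degenerate configs (e.g. equal masses)
        return (x - x.mean()) / sd

    z["total_animals"] = zscore(np.log(profiles["total_animals"]))
    z["species_richness"] = zscore(np.log(profiles["species_richness"]))
    z["mammal_richness"] = zscore(np.log1p(profiles["mammal_species_richness"]))
    z["body_mass"] = zscore(np.log(profiles["mean_body_mass"]))
    z["dissimilarity"] = zscore(profiles["mean_dissimilarity"])
    z["threatened_prop"] = zscore(profiles["threatened_proportion"])
    z["area"] = zscore(np.log(inst["area_ha"]))
    z["gdp"] = zscore(np.log(inst["gdp"]))
    z["pop_10km"] = zscore(np.log(inst["pop_10km"]))

    att = struct.edges
    resid_att = 1.0 - sum(
        v**2 for (out, _), v in att.items() if out == "attendance"
    )
    resid_att = max(resid_att, 0.05)  # metrics correlate; keep noise positive
    z_att = sum(
        val * z[pred] for (out, pred), val in att.items() if out == "attendance"
    ) + rng.normal(0.0, math.sqrt(resid_att), size=n_inst)
    inst["attendance"] = np.round(
        np.exp(cfg.attendance_meanlog + cfg.attendance_sdlog * zscore(z_att))
    ).astype(np.int64)

    n_insitu = int(round(cfg.insitu_fraction * n_inst))
    subset = np.sort(rng.choice(n_inst, size=n_insitu, replace=False))
    ins = INSITU_EDGES
    z_att_real = zscore(np.log(inst["attendance"]))
    z_insitu = (
        ins[("in_situ", "attendance")] * z_att_real
        + ins[("in_situ", "threatened_prop")] * z["threatened_prop"]
        + ins[("in_situ", "area")] * z["area"]
    )
    resid_ins = max(1.0 - sum(v**2 for v in ins.values()), 0.05)
    z_insitu = z_insitu + rng.normal(0.0, math.sqrt(resid_ins), size=n_inst)
    projects = np.round(
        np.exp(cfg.insitu_meanlog + cfg.insitu_sdlog * zscore(z_insitu))
    ).astype(np.int64)
    in_situ = np.full(n_inst, np.nan)
    in_situ[subset] = projects[subset]
    inst["in_situ_projects"] = in_situ

    cols = [
        "institution_id",
        "country",
        "attendance",
        "area_ha",
        "gdp",
        "national_population",
        "pop_10km",
        "in_situ_projects",
    ]
    return holdings, inst[cols].reset_index(drop=True)
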