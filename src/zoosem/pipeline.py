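"""End-to-end orchestration: raw tables -> composition metrics -> standardized
analysis frame -> stepwise model search -> effect decomposition -> report.

Two published analyses are wired up: the attendance model (all institutions)
and the in situ model (the subset reporting field-project counts, with GDP
dropped and the attendance-side structure frozen). Size-like variables
(attendance, counts, area, GDP, populations, body mass) enter the models on
the natural-log scale; proportions and dissimilarity enter raw. Everything is
deterministic given the inputs, configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .composition import HoldingsMatrix, compute_profiles, resolve_masses
from .effects import EffectsTable, MediationResult, mediation_test, total_effects
from .exceptions import DataError
from .fitting import FitResult, cluster_robust_se, standardize
from .model import PathModelSpec, parse_model_spec
from .search import SearchResult, SearchThresholds, run_search, validate_subsets

log = logging.getLogger("zoosem")

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "default_attendance_meta_model",
    "build_analysis_table",
    "run_attendance_analysis",
    "run_insitu_analysis",
    "parse_model_spec",
]

#: model variable -> (institutions/profiles column, transform)
VARIABLE_TABLE = {
    "attendance": ("attendance", "log"),
    "total_animals": ("total_animals", "log"),
    "species_richness": ("species_richness", "log"),
    "mammal_richness": ("mammal_species_richness", "log1p"),
    "body_mass": ("mean_body_mass", "log"),
    "dissimilarity": ("mean_dissimilarity", "raw"),
    "diversity": ("brillouin", "raw"),
    "threatened_prop": ("threatened_proportion", "raw"),
    "area": ("area_ha", "log"),
    "gdp": ("gdp", "log"),
    "national_population": ("national_population", "log"),
    "pop_10km": ("pop_10km", "log"),
    "in_situ": ("in_situ_projects", "log1p"),
}

_INSTITUTION_COLUMNS = {
    "institution_id",
    "country",
    "attendance",
    "area_ha",
    "gdp",
    "national_population",
    "pop_10km",
}


@dataclass(frozen=True)
class AnalysisConfig:
    seed: int | None = None
    mode: str = "abundance"                 # or "presence"
    thresholds: SearchThresholds = SearchThresholds()
    cluster_se: bool = False
    run_subset_validation: bool = False
    n_subsets: int = 4
    subset_size: int = 200


@dataclass
class AnalysisReport:
    """Everything one analysis produced, regenerable from inputs + metadata."""

    kind: str
    profiles: pd.DataFrame
    table: pd.DataFrame               # standardized analysis frame
    clusters: pd.Series
    dropped: list[str]
    fit: FitResult
    effects: EffectsTable
    search: SearchResult | None
    mediation: list[MediationResult]
    subset_validation: pd.DataFrame | None
    metadata: dict

    def fit_json(self) -> dict:
        return {
            "chi2": self.fit.chi2,
            "df": self.fit.df,
            "p": self.fit.pvalue,
            "cfi": self.fit.cfi,
            "srmr": self.fit.srmr,
            "aic": self.fit.aic,
            "aicc": self.fit.aicc,
            "n": self.fit.n,
            "k": self.fit.n_free,
            "r2": self.fit.r2,
        }

    def payload(self) -> str:
        """Canonical JSON payload of every number in the report (used for the
        determinism guarantee: same inputs + config + seed => same bytes)."""
        body = {
            "kind": self.kind,
            "metadata": self.metadata,
            "fit": self.fit_json(),
            "coefficients": self.fit.params.to_dict(orient="records"),
            "effects": self.effects.to_frame().to_dict(orient="records"),
            "mediation": [
                {
                    "chain": list(m.chain),
                    "estimate": m.estimate,
                    "se": m.se,
                    "z": m.z,
                    "pvalue": m.pvalue,
                    "method": m.method,
                }
                for m in self.mediation
            ],
            "profiles": self.profiles.round(12).to_dict(orient="index"),
            "dropped": self.dropped,
        }
        return json.dumps(body, sort_keys=True, indent=2, allow_nan=True)

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.profiles.to_csv(outdir / "profiles.csv")
        self.fit.params.to_csv(outdir / "coefficients.csv", index=False)
        self.effects.to_frame().to_csv(outdir / "effects.csv", index=False)
        (outdir / "fit.json").write_text(
            json.dumps(self.fit_json(), sort_keys=True, indent=2) + "\n"
        )
        (outdir / "model.txt").write_text(self.fit.spec.to_text())
        (outdir / "graph.dot").write_text(model_to_dot(self.fit.spec, self.fit))
        if self.search is not None:
            (outdir / "trace.json").write_text(self.search.trace.to_json() + "\n")
        if self.mediation:
            pd.DataFrame(
                [
                    {
                        "chain": " -> ".join(m.chain),
                        "estimate": m.estimate,
                        "se": m.se,
                        "z": m.z,
                        "pvalue": m.pvalue,
                        "method": m.method,
                    }
                    for m in self.mediation
                ]
            ).to_csv(outdir / "mediation.csv", index=False)
        if self.subset_validation is not None:
            self.subset_validation.to_csv(outdir / "subsets.csv", index=False)
        (outdir / "metadata.json").write_text(
            json.dumps(self.metadata, sort_keys=True, indent=2) + "\n"
        )
        return outdir


def model_to_dot(spec: PathModelSpec, fit: FitResult | None = None) -> str:
    """Graphviz DOT export of the model graph (predictor -> outcome), edge
    labels = standardized coefficients when a fit is supplied."""
    lines = ["digraph model {", "  rankdir=LR;"]
    for v in spec.variables:
        lines.append(f'  "{v}";')
    for out, pred in spec.edges:
        if fit is not None:
            label = f' [label="{fit.A_std.loc[out, pred]:.3f}"]'
        else:
            label = ""
        lines.append(f'  "{pred}" -> "{out}"{label};')
    lines.append("}")
    return "\n".join(lines) + "\n"


def default_attendance_meta_model() -> PathModelSpec:
    """The shipped a priori attendance meta-model (superset of admissible
    pathways, to be pruned by the search)."""
    text = resources.files("zoosem").joinpath("specs/attendance_meta.txt").read_text()
    return parse_model_spec(text)


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------


def _load_holdings(holdings) -> HoldingsMatrix:
    if isinstance(holdings, HoldingsMatrix):
        return holdings
    return HoldingsMatrix.from_csv(holdings)


def _load_institutions(institutions) -> pd.DataFrame:
    if not isinstance(institutions, pd.DataFrame):
        institutions = pd.read_csv(institutions)
    missing = _INSTITUTION_COLUMNS - set(institutions.columns)
    if missing:
        raise DataError(f"institutions table missing columns: {sorted(missing)}")
    return institutions.set_index("institution_id", drop=False)


def build_analysis_table(
    holdings,
    institutions,
    *,
    mode: str = "abundance",
    variables: list[str] | None = None,
    mass_reference: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, list[str]]:
    """Compute profiles, join covariates and apply the variable transforms.

    Returns ``(raw_model_table, profiles, countries, dropped_ids)``. Raises a
    reconciliation error when the two input tables disagree on institution
    ids; rows with missing or non-positive values in required covariates are
    dropped and listed in ``dropped_ids``.
    """
    hm = _load_holdings(holdings)
    inst = _load_institutions(institutions)
    only_holdings = sorted(set(hm.institutions) - set(inst.index))
    only_covariates = sorted(set(inst.index) - set(hm.institutions))
    if only_holdings or only_covariates:
        raise DataError(
            "institution ids do not reconcile; "
            f"holdings-only: {only_holdings}; covariates-only: {only_covariates}"
        )
    masses = resolve_masses(hm, mass_reference)
    filled = hm.species.copy()
    filled["body_mass_g"] = masses
    hm = HoldingsMatrix(hm.counts, filled)
    profiles = compute_profiles(hm, mode=mode)
    joined = profiles.join(inst.drop(columns=["institution_id"]))

    wanted = variables if variables is not None else [
        v for v in VARIABLE_TABLE if v != "in_situ"
    ]
    out = pd.DataFrame(index=joined.index)
    for var in wanted:
        src, tf = VARIABLE_TABLE[var]
        col = pd.to_numeric(joined[src], errors="coerce")
        if tf == "log":
            col = col.where(col > 0)
            out[var] = np.log(col)
        elif tf == "log1p":
            col = col.where(col >= 0)
            out[var] = np.log1p(col)
        else:
            out[var] = col
    required = [v for v in out.columns if v != "in_situ"]
    ok = out[required].notna().all(axis=1)
    dropped = sorted(out.index[~ok])
    if dropped:
        log.info("dropping %d institutions with incomplete covariates: %s",
                 len(dropped), dropped)
    out = out[ok]
    return out, profiles, joined.loc[ok, "country"], dropped


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------


def _metadata(config: AnalysisConfig, fit: FitResult, dropped, extra=None) -> dict:
    md = {
        "software": f"zoosem {__version__}",
        "seed": config.seed,
        "mode": config.mode,
        "thresholds": {
            "mi_add": config.thresholds.mi_add,
            "p_remove": config.thresholds.p_remove,
            "delta_aicc": config.thresholds.delta_aicc,
        },
        "n": fit.n,
        "variables": list(fit.spec.variables),
        "dropped_institutions": list(dropped),
    }
    if extra:
        md.update(extra)
    return md


def run_attendance_analysis(
    holdings,
    institutions,
    meta_model: PathModelSpec | str | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> AnalysisReport:
    """The attendance analysis: profiles -> covariates -> standardize ->
    stepwise search from the a priori meta-model -> effect decomposition."""
    if meta_model is None:
        meta = default_attendance_meta_model()
    elif isinstance(meta_model, PathModelSpec):
        meta = meta_model
    elif isinstance(meta_model, (str, Path)) and "\n" not in str(meta_model):
        meta = PathModelSpec.from_file(meta_model)
    else:
        meta = parse_model_spec(str(meta_model))
    if config.mode == "presence" and "total_animals" in meta.variables:
        # with presence-only data the animal count duplicates species richness
        meta = meta.drop_variable("total_animals")

    raw, profiles, countries, dropped = build_analysis_table(
        holdings, institutions, mode=config.mode, variables=list(meta.variables)
    )
    data = standardize(raw[list(meta.variables)], clusters=countries)
    result = run_search(meta, data, thresholds=config.thresholds, mandatory=("attendance",))
    fit = result.fit
    if config.cluster_se:
        fit.params = cluster_robust_se(fit, countries.loc[data.data.index])
    effects = total_effects(fit)
    subsets = None
    if config.run_subset_validation:
        subsets = validate_subsets(
            result.spec,
            data,
            n_subsets=config.n_subsets,
            subset_size=min(config.subset_size, data.n),
            seed=config.seed,
        )
    return AnalysisReport(
        kind="attendance",
        profiles=profiles,
        table=data.data,
        clusters=countries,
        dropped=dropped,
        fit=fit,
        effects=effects,
        search=result,
        mediation=[],
        subset_validation=subsets,
        metadata=_metadata(
            config, fit, dropped,
            {"selection_decisive": result.selection.decisive,
             "selection_delta_aicc": result.selection.delta,
             "loop_detected": result.trace.loop_detected},
        ),
    )


#: candidate direct predictors of in situ activity in the in situ search
INSITU_CANDIDATES = (
    ("in_situ", "attendance"),
    ("in_situ", "threatened_prop"),
    ("in_situ", "area"),
)


def insitu_spec_from_attendance(attendance_spec: PathModelSpec) -> PathModelSpec:
    """Build the most complete in situ starting model: the attendance-model
    structure with GDP dropped, plus all candidate in situ pathways."""
    edges = [
        (out, pred)
        for out, pred in attendance_spec.edges
        if "gdp" not in (out, pred)
    ]
    variables = [v for v in attendance_spec.variables if v != "gdp"]
    for extra in ("threatened_prop", "in_situ"):
        if extra not in variables:
            variables.append(extra)
    edges += [e for e in INSITU_CANDIDATES if e not in edges]
    return PathModelSpec(tuple(variables), tuple(edges))


def run_insitu_analysis(
    holdings,
    institutions,
    attendance_model: PathModelSpec | AnalysisReport | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> AnalysisReport:
    """The in situ analysis on the subset of institutions reporting project
    counts: GDP and country are dropped, the attendance-side edge structure is
    taken from the best attendance model (coefficients re-estimated on the
    subset), and only the in situ pathways are searched. Mediation tests are
    run on every mediated pathway into in situ via attendance."""
    if attendance_model is None:
        att_spec = default_attendance_meta_model()  # searched superset
    elif isinstance(attendance_model, AnalysisReport):
        att_spec = attendance_model.fit.spec
    else:
        att_spec = attendance_model
    if config.mode == "presence" and "total_animals" in att_spec.variables:
        att_spec = att_spec.drop_variable("total_animals")

    inst = _load_institutions(institutions)
    if "in_situ_projects" not in inst.columns:
        raise DataError("institutions table has no in_situ_projects column")
    subset = inst[inst["in_situ_projects"].notna()]
    if subset.empty:
        raise DataError("no institutions report in situ projects")
    hm = _load_holdings(holdings)
    keep = [i for i in hm.institutions if i in set(subset.index)]
    hm = HoldingsMatrix(hm.counts.loc[keep], hm.species)

    start = insitu_spec_from_attendance(att_spec)
    raw, profiles, countries, dropped = build_analysis_table(
        hm, subset.loc[keep], mode=config.mode, variables=list(start.variables)
    )
    raw = raw[raw["in_situ"].notna()]
    countries = countries.loc[raw.index]
    data = standardize(raw[list(start.variables)], clusters=countries)

    protected = [e for e in start.edges if e not in INSITU_CANDIDATES]
    result = run_search(
        start,
        data,
        whitelist=list(INSITU_CANDIDATES),
        thresholds=config.thresholds,
        protected=protected,
        mandatory=("in_situ",),
    )
    fit = result.fit
    if config.cluster_se:
        fit.params = cluster_robust_se(fit, countries)
    effects = total_effects(fit)

    # test every mediated pathway into in situ that runs through attendance
    mediation = []
    if ("in_situ", "attendance") in fit.spec.edges:
        import networkx as nx

        g = fit.spec.graph()
        chains = set()
        for v in fit.spec.variables:
            if v in ("attendance", "in_situ"):
                continue
            for path in nx.all_simple_paths(g, v, "in_situ"):
                if len(path) >= 3 and path[-2] == "attendance":
                    chains.add(tuple(path))
        for chain in sorted(chains):
            mediation.append(mediation_test(fit, chain))

    return AnalysisReport(
        kind="insitu",
        profiles=profiles,
        table=data.data,
        clusters=countries,
        dropped=dropped,
        fit=fit,
        effects=effects,
        search=result,
        mediation=mediation,
        subset_validation=None,
        metadata=_metadata(
            config, fit, dropped,
            {"attendance_structure": [list(e) for e in protected]},
        ),
    )
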