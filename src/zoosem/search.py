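"""Stepwise structure search for path models.

The a priori meta-model (theory-derived superset of admissible pathways) is
refined by alternating two phases until a fixed point:

* forward: among whitelisted candidate edges, add the one with the highest
  modification index, while any exceeds the chi-square(1) criterion of 3.84;
* backward: remove the edge with the highest Wald p value, while any exceeds
  0.05 (edges whose removal would isolate a variable are skipped and
  recorded).

Every model visited along the way joins a candidate pool; the final model is
the pool's AICc minimum, flagged "decisive" only when it beats the runner-up
by more than two AICc units. The search never invents an edge outside the
whitelist, is deterministic given the data and whitelist (ties break
lexicographically), and detects revisited models by hashing their edge sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError
from .fitting import FitResult, fit_path_model, modification_indices, standardize
from .model import Edge, PathModelSpec

__all__ = [
    "SearchThresholds",
    "SearchStep",
    "SearchTrace",
    "Candidate",
    "SelectionResult",
    "SearchResult",
    "forward_step",
    "backward_step",
    "select_by_aicc",
    "run_search",
    "validate_subsets",
]


@dataclass(frozen=True)
class SearchThresholds:
    mi_add: float = 3.84      # chi-square(1) 0.05 critical value for additions
    p_remove: float = 0.05    # Wald p threshold for deletions
    delta_aicc: float = 2.0   # decisiveness margin for final selection


@dataclass
class SearchStep:
    action: str                    # "add" | "remove" | "stop" | "skip"
    phase: str                     # "forward" | "backward"
    edge: Edge | None
    statistic: str                 # "mi" | "p" | ""
    value: float | None
    chi2: float | None = None
    df: int | None = None
    aicc: float | None = None
    cfi: float | None = None
    srmr: float | None = None
    note: str = ""


@dataclass
class SearchTrace:
    steps: list[SearchStep] = field(default_factory=list)
    loop_detected: bool = False

    def record(self, step: SearchStep) -> None:
        self.steps.append(step)

    def to_json(self, **kwargs) -> str:
        payload = {
            "loop_detected": self.loop_detected,
            "steps": [
                {**asdict(s), "edge": list(s.edge) if s.edge else None}
                for s in self.steps
            ],
        }
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(payload, **kwargs)


@dataclass
class Candidate:
    spec: PathModelSpec
    fit: FitResult

    @property
    def aicc(self) -> float:
        return self.fit.aicc


@dataclass
class SelectionResult:
    selected: Candidate
    decisive: bool
    delta: float                   # AICc gap to the runner-up (inf if alone)
    contenders: list[Candidate]    # models within delta_aicc of the best


def _fill(step: SearchStep, fit: FitResult) -> SearchStep:
    step.chi2, step.df = fit.chi2, fit.df
    step.aicc, step.cfi, step.srmr = fit.aicc, fit.cfi, fit.srmr
    return step


def forward_step(
    spec: PathModelSpec,
    data,
    whitelist: Sequence[Edge],
    *,
    thresholds: SearchThresholds = SearchThresholds(),
    fit: FitResult | None = None,
) -> tuple[PathModelSpec | None, SearchStep]:
    """One forward addition: free the admissible whitelisted edge with the
    highest modification index strictly above the threshold; ``(None, stop)``
    when no candidate qualifies."""
    base = fit if fit is not None else fit_path_model(spec, data, se=False)
    candidates = [e for e in whitelist if e not in spec.edges]
    if not candidates:
        return None, _fill(
            SearchStep("stop", "forward", None, "", None, note="whitelist exhausted"),
            base,
        )
    table = modification_indices(spec, data, candidates, fit=base)
    ok = table[table["admissible"] & (table["mi"] > thresholds.mi_add)]
    if ok.empty:
        return None, _fill(
            SearchStep(
                "stop", "forward", None, "mi", None,
                note=f"no admissible MI above {thresholds.mi_add}",
            ),
            base,
        )
    best = ok.iloc[0]
    new_spec = spec.with_edge(best["lhs"], best["rhs"])
    new_fit = fit_path_model(new_spec, data, se=False)
    return new_spec, _fill(
        SearchStep("add", "forward", (best["lhs"], best["rhs"]), "mi", float(best["mi"])),
        new_fit,
    )


def backward_step(
    spec: PathModelSpec,
    data,
    *,
    thresholds: SearchThresholds = SearchThresholds(),
    protected: Iterable[Edge] = (),
    mandatory: Iterable[str] = (),
    fit: FitResult | None = None,
) -> tuple[PathModelSpec | None, list[SearchStep]]:
    """One backward deletion: drop the edge with the highest p value strictly
    above the threshold; ``(None, [stop])`` when all edges are supported.

    ``protected`` edges are never candidates for removal (the in situ analysis
    freezes the attendance-side structure this way). A removal that would
    leave a ``mandatory`` variable without any edge is recorded and skipped;
    other variables may lose their last pathway, in which case they stay in
    the model as members of the saturated exogenous block.
    """
    base = fit if fit is not None else fit_path_model(spec, data, se=True)
    protected = set(protected)
    edges = base.edge_table()
    edges = edges[[(r["lhs"], r["rhs"]) not in protected for _, r in edges.iterrows()]]
    weak = edges[edges["pvalue"] > thresholds.p_remove]
    if weak.empty:
        return None, [
            _fill(
                SearchStep(
                    "stop", "backward", None, "p", None,
                    note=f"all retained edges at p <= {thresholds.p_remove}",
                ),
                base,
            )
        ]
    weak = weak.sort_values(["pvalue", "lhs", "rhs"], ascending=[False, True, True])
    mandatory = set(mandatory)
    steps: list[SearchStep] = []
    for _, row in weak.iterrows():
        edge = (row["lhs"], row["rhs"])
        new_spec = spec.without_edge(*edge)
        lost = set(new_spec.isolated()) - set(spec.isolated())
        if lost & mandatory:
            steps.append(
                _fill(
                    SearchStep(
                        "skip", "backward", edge, "p", float(row["pvalue"]),
                        note=f"would disconnect mandatory variable(s) {sorted(lost & mandatory)}",
                    ),
                    base,
                )
            )
            continue
        new_fit = fit_path_model(new_spec, data, se=False)
        steps.append(
            _fill(
                SearchStep("remove", "backward", edge, "p", float(row["pvalue"])),
                new_fit,
            )
        )
        return new_spec, steps
    return None, steps  # every weak edge was unremovable


def select_by_aicc(
    candidates: Sequence[Candidate],
    *,
    delta_aicc: float = 2.0,
) -> SelectionResult:
    """Minimum-AICc selection with a decisiveness flag: decisive only when the
    winner beats the nearest competitor by more than ``delta_aicc`` units."""
    if not candidates:
        raise ValueError("no candidate models to select from")
    ranked = sorted(range(len(candidates)), key=lambda i: (candidates[i].aicc, i))
    best = candidates[ranked[0]]
    if len(candidates) == 1:
        return SelectionResult(best, True, float("inf"), [best])
    delta = candidates[ranked[1]].aicc - best.aicc
    contenders = [candidates[i] for i in ranked if candidates[i].aicc - best.aicc <= delta_aicc]
    return SelectionResult(best, bool(delta > delta_aicc), float(delta), contenders)


@dataclass
class SearchResult:
    spec: PathModelSpec           # AICc-selected model
    fit: FitResult                # refit of the selection with standard errors
    trace: SearchTrace
    candidates: list[Candidate]
    selection: SelectionResult
    final_spec: PathModelSpec     # fixed point of the add/remove phases


def run_search(
    meta_model: PathModelSpec,
    data,
    whitelist: Sequence[Edge] | None = None,
    *,
    thresholds: SearchThresholds = SearchThresholds(),
    protected: Iterable[Edge] = (),
    mandatory: Iterable[str] = (),
    max_steps: int = 200,
) -> SearchResult:
    """Full stepwise search from an a priori meta-model.

    Forward additions run to exhaustion, then backward deletions to
    exhaustion, repeating until neither phase changes the model (or a visited
    model recurs, which sets ``trace.loop_detected``). Every distinct model
    visited is a candidate; the returned model is the AICc minimum of the
    pool. The whitelist defaults to the meta-model's own edge set.
    """
    whitelist = list(whitelist) if whitelist is not None else list(meta_model.edges)
    whitelist = sorted(set(whitelist))
    trace = SearchTrace()
    spec = meta_model
    fit = fit_path_model(spec, data, se=True)
    visited: dict[frozenset, int] = {spec.edge_set(): 0}
    candidates: list[Candidate] = [Candidate(spec, fit)]

    def note_model(s: PathModelSpec) -> bool:
        """Register a model; True if it was seen before (loop)."""
        key = s.edge_set()
        if key in visited:
            return True
        visited[key] = len(candidates)
        candidates.append(Candidate(s, fit_path_model(s, data, se=False)))
        return False

    steps_taken = 0
    while steps_taken < max_steps:
        changed = False
        # forward phase to exhaustion
        while steps_taken < max_steps:
            new_spec, step = forward_step(spec, data, whitelist, thresholds=thresholds)
            trace.record(step)
            steps_taken += 1
            if new_spec is None:
                break
            if note_model(new_spec):
                trace.loop_detected = True
                spec = new_spec
                break
            spec = new_spec
            changed = True
        if trace.loop_detected:
            break
        # backward phase to exhaustion
        while steps_taken < max_steps:
            new_spec, steps = backward_step(
                spec, data, thresholds=thresholds, protected=protected,
                mandatory=mandatory,
            )
            for s in steps:
                trace.record(s)
            steps_taken += 1
            if new_spec is None:
                break
            if note_model(new_spec):
                trace.loop_detected = True
                spec = new_spec
                break
            spec = new_spec
            changed = True
        if trace.loop_detected or not changed:
            break

    selection = select_by_aicc(candidates, delta_aicc=thresholds.delta_aicc)
    chosen = selection.selected.spec
    final_fit = fit_path_model(chosen, data, se=True)
    return SearchResult(
        spec=chosen,
        fit=final_fit,
        trace=trace,
        candidates=candidates,
        selection=selection,
        final_spec=spec,
    )


def validate_subsets(
    spec: PathModelSpec,
    data,
    *,
    n_subsets: int = 4,
    subset_size: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Refit the model on seeded random subsets (without replacement) and
    summarise how stable each parameter is across them.

    Returns one row per free parameter with the per-subset estimates, their
    range, and the coefficient of variation (sd/|mean|; NaN when the mean is
    zero). Each subset is re-standardized before fitting, mirroring the full
    pipeline.
    """
    frame = data.data if hasattr(data, "data") else pd.DataFrame(data)
    n = len(frame)
    if subset_size > n:
        raise DataError(f"subset_size {subset_size} exceeds n={n}")
    rng = np.random.default_rng(seed)
    estimates = {}
    for s in range(n_subsets):
        rows = rng.choice(n, size=subset_size, replace=False)
        sub = standardize(frame.iloc[np.sort(rows)][list(spec.variables)])
        refit = fit_path_model(spec, sub, se=False)
        estimates[f"subset_{s + 1}"] = refit.params["estimate"].to_numpy()
    base = fit_path_model(spec, frame, se=False)
    out = base.params[["lhs", "op", "rhs"]].copy()
    for name, vals in estimates.items():
        out[name] = vals
    mat = out[[c for c in out.columns if c.startswith("subset_")]].to_numpy()
    out["range"] = mat.max(axis=1) - mat.min(axis=1)
    mean = mat.mean(axis=1)
    if mat.shape[1] > 1:
        sd = mat.std(axis=1, ddof=1)
    else:
        sd = np.full(mat.shape[0], np.nan)  # a lone subset has no spread
    with np.errstate(divide="ignore", invalid="ignore"):
        out["cv"] = np.where(np.abs(mean) > 0, sd / np.abs(mean), np.nan)
    return out
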