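"""Direct / indirect / total standardized effect decomposition.

For a recursive model with standardized coefficient matrix ``A`` (entry
``[outcome, predictor]``), the total effect of every variable on every other
is ``(I - A)^{-1} - I``: the sum over all directed paths of the product of the
path coefficients. Indirect = total - direct. A path-enumeration oracle and a
product-of-coefficients (delta-method) mediation test live here too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import SpecificationError
from .fitting import FitResult
from .model import PathModelSpec

__all__ = ["EffectsTable", "total_effects", "enumerate_paths", "mediation_test", "MediationResult"]


def _coef_matrix(source) -> pd.DataFrame:
    """Coerce a FitResult / DataFrame / (spec, coefficients) into the square
    standardized coefficient matrix A[outcome, predictor]."""
    if isinstance(source, FitResult):
        return source.A_std
    if isinstance(source, pd.DataFrame):
        if list(source.index) != list(source.columns):
            raise ValueError("coefficient matrix must be square with matching labels")
        return source
    raise TypeError(f"cannot extract a coefficient matrix from {type(source)!r}")


def _check_acyclic(A: pd.DataFrame) -> None:
    g = nx.DiGraph(
        (pred, out)
        for out in A.index
        for pred in A.columns
        if A.loc[out, pred] != 0.0
    )
    if not nx.is_directed_acyclic_graph(g):
        raise SpecificationError("coefficient matrix is not acyclic")


@dataclass
class EffectsTable:
    """Direct, indirect and total standardized effects for every ordered
    (cause, outcome) pair. ``total = direct + indirect`` exactly; effects of a
    variable on itself are zero."""

    direct: pd.DataFrame    # [outcome, cause]
    indirect: pd.DataFrame
    total: pd.DataFrame

    def effect(self, cause: str, outcome: str) -> dict[str, float]:
        return {
            "direct": float(self.direct.loc[outcome, cause]),
            "indirect": float(self.indirect.loc[outcome, cause]),
            "total": float(self.total.loc[outcome, cause]),
        }

    def total_effect(self, cause: str, outcome: str) -> float:
        return float(self.total.loc[outcome, cause])

    def to_frame(self) -> pd.DataFrame:
        """Long table with one row per ordered (cause, outcome) pair."""
        rows = []
        for outcome in self.total.index:
            for cause in self.total.columns:
                if cause == outcome:
                    continue
                rows.append(
                    {
                        "cause": cause,
                        "outcome": outcome,
                        "direct": float(self.direct.loc[outcome, cause]),
                        "indirect": float(self.indirect.loc[outcome, cause]),
                        "total": float(self.total.loc[outcome, cause]),
                    }
                )
        return pd.DataFrame(rows)


def total_effects(source) -> EffectsTable:
    """Decompose effects from a fitted model or a coefficient matrix.

    ``source`` may be a :class:`FitResult` (its standardized coefficients are
    used) or a square coefficient DataFrame ``A[outcome, predictor]``.
    """
    A = _coef_matrix(source)
    _check_acyclic(A)
    vars_ = list(A.index)
    M = A.to_numpy(dtype=float)
    T = np.linalg.inv(np.eye(len(vars_)) - M) - np.eye(len(vars_))
    total = pd.DataFrame(T, index=vars_, columns=vars_)
    direct = A.astype(float)
    return EffectsTable(direct=direct, indirect=total - direct, total=total)


def enumerate_paths(source, cause: str, outcome: str) -> list[tuple[tuple[str, ...], float]]:
    """Every simple directed path from cause to outcome with its coefficient
    product. The sum over paths equals the matrix total effect — this is the
    brute-force oracle for :func:`total_effects`. Empty list when no path
    exists.
    """
    if isinstance(source, PathModelSpec):
        raise TypeError("enumerate_paths needs coefficients; pass a FitResult or matrix")
    A = _coef_matrix(source)
    _check_acyclic(A)
    g = nx.DiGraph()
    g.add_nodes_from(A.index)
    for out in A.index:
        for pred in A.columns:
            if A.loc[out, pred] != 0.0:
                g.add_edge(pred, out, weight=float(A.loc[out, pred]))
    if cause not in g or outcome not in g:
        raise KeyError(f"unknown variable {cause!r} or {outcome!r}")
    results = []
    for path in nx.all_simple_paths(g, cause, outcome):
        prod = 1.0
        for a, b in zip(path[:-1], path[1:]):
            prod *= g.edges[a, b]["weight"]
        results.append((tuple(path), prod))
    results.sort(key=lambda item: item[0])
    return results


@dataclass(frozen=True)
class MediationResult:
    chain: tuple[str, ...]
    estimate: float
    se: float
    z: float
    pvalue: float
    method: str = "delta"


def mediation_test(
    fit: FitResult,
    chain: Sequence[str],
    *,
    method: str = "delta",
    n_boot: int = 2000,
    seed: int | None = None,
) -> MediationResult:
    """Product-of-coefficients test for one mediated pathway.

    ``chain`` is the ordered variable sequence ``(cause, mediator..., outcome)``
    with at least three variables; each consecutive pair must be an edge of
    the fitted model. The default is the first-order delta-method (Sobel-type)
    test: estimate = product of the chain coefficients, variance =
    ``sum_j (prod_{i!=j} b_i)^2 se_j^2``, two-sided normal p value. The z
    statistic is invariant to a sign flip of the whole chain.

    ``method="bootstrap"`` refits the model on seeded nonparametric resamples
    of the rows and uses the empirical distribution of the product.
    """
    chain = tuple(chain)
    if len(chain) < 3:
        raise SpecificationError("a mediated pathway needs at least three variables")
    links = list(zip(chain[:-1], chain[1:]))
    for pred, out in links:
        if (out, pred) not in fit.spec.edges:
            raise SpecificationError(f"chain edge {out} ~ {pred} absent from model")

    ests, ses = [], []
    for pred, out in links:
        row = fit.edge_estimate(out, pred)
        ests.append(float(row["estimate"]))
        ses.append(float(row["se"]))
    b = np.array(ests)
    s = np.array(ses)
    product = float(np.prod(b))

    if method == "delta":
        var = 0.0
        for j in range(len(b)):
            others = np.prod(np.delete(b, j))
            var += others**2 * s[j] ** 2
        se = float(np.sqrt(var))
        z = product / se if se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        return MediationResult(chain, product, se, z, p, "delta")

    if method == "bootstrap":
        from .fitting import fit_path_model

        if fit.data is None:
            raise ValueError("bootstrap mediation needs the fitted data")
        rng = np.random.default_rng(seed)
        n = len(fit.data)
        draws = np.empty(n_boot)
        for r in range(n_boot):
            rows = rng.integers(0, n, size=n)
            refit = fit_path_model(fit.spec, fit.data.iloc[rows], se=False)
            prod = 1.0
            for pred, out in links:
                prod *= float(refit.A.loc[out, pred])
            draws[r] = prod
        se = float(draws.std(ddof=1))
        z = product / se if se > 0 else np.nan
        tail = min((draws <= 0).mean(), (draws >= 0).mean())
        p = min(2 * tail, 1.0)
        return MediationResult(chain, product, se, z, float(p), "bootstrap")

    raise ValueError(f"unknown method {method!r}")
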