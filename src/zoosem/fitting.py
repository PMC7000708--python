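"""Maximum-likelihood estimation of observed-variable path models.

The model implies a covariance matrix through the network formulation

    Sigma(theta) = (I - A)^{-1} Psi (I - A)^{-T}

where ``A[outcome, predictor]`` holds the regression coefficients and ``Psi``
the free exogenous (co)variances and residual (co)variances. Parameters
minimise the Wishart discrepancy

    F_ML = ln|Sigma| + tr(S Sigma^{-1}) - ln|S| - p

against the sample covariance ``S`` (n-1 denominator). For a recursive model
with uncorrelated residuals the minimiser is available in closed form: each
endogenous equation is the least-squares regression on its parents computed
from ``S``, and the exogenous block of ``Psi`` equals the corresponding block
of ``S``. That fast path is used whenever no residual covariance is declared;
otherwise a quasi-Newton optimiser with an analytic gradient takes over
(started from the closed-form solution).

Conventions (documented so results can be reconciled with other software):
the model chi-square is ``T = (n-1) F_ML``; standard errors come from the
curvature of ``F_ML`` at the optimum, ``acov = (2/(n-1)) H^{-1}``; AIC is on
the chi-square (-2 log-likelihood relative to saturated) scale, ``AIC = T +
2k``, so differences between nested models are invariant to the saturated
constant; ``AICc = AIC + 2k(k+1)/(n-k-1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import ConvergenceError, DataError, DegenerateInputError
from .model import PathModelSpec

__all__ = [
    "StandardizedDataset",
    "standardize",
    "FitResult",
    "fit_path_model",
    "fit_baseline_model",
    "fit_indices",
    "modification_indices",
    "cluster_robust_se",
]


@dataclass
class StandardizedDataset:
    """Numeric table with columns z-scored (mean 0, sd 1, n-1 denominator),
    plus an optional cluster label (country) per row."""

    data: pd.DataFrame
    clusters: pd.Series | None = None

    def __post_init__(self):
        if self.clusters is not None and len(self.clusters) != len(self.data):
            raise ValueError("clusters must align with data rows")

    @property
    def n(self) -> int:
        return len(self.data)


def standardize(table: pd.DataFrame, clusters: pd.Series | None = None) -> StandardizedDataset:
    """Z-score every column with the sample (n-1) standard deviation.

    Raises :class:`DegenerateInputError` naming the column if any column is
    constant, and :class:`DataError` on missing values.
    """
    if table.isna().any().any():
        bad = sorted(table.columns[table.isna().any()])
        raise DataError(f"missing values in columns {bad}")
    sd = table.std(ddof=1)
    constant = sd[(sd == 0) | sd.isna()].index.tolist()
    if constant:
        raise DegenerateInputError(f"constant column(s): {constant}")
    z = (table - table.mean()) / sd
    cl = None
    if clusters is not None:
        cl = pd.Series(clusters).reset_index(drop=True)
        cl.index = z.index
    return StandardizedDataset(z, cl)


# ---------------------------------------------------------------------------
# parameter bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _ParamMap:
    """Maps the free-parameter vector theta onto the (A, Psi) matrices."""

    variables: tuple[str, ...]
    betas: tuple[tuple[int, int], ...]        # (outcome idx, predictor idx)
    psis: tuple[tuple[int, int], ...]         # (i, j) with i >= j; i==j variance

    @property
    def k(self) -> int:
        return len(self.betas) + len(self.psis)

    def build(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = len(self.variables)
        A = np.zeros((p, p))
        Psi = np.zeros((p, p))
        nb = len(self.betas)
        for (i, j), val in zip(self.betas, theta[:nb]):
            A[i, j] = val
        for (i, j), val in zip(self.psis, theta[nb:]):
            Psi[i, j] = Psi[j, i] = val
        return A, Psi


def _param_map(spec: PathModelSpec) -> _ParamMap:
    vars_ = spec.variables
    idx = {v: i for i, v in enumerate(vars_)}
    betas = tuple((idx[out], idx[pred]) for out, pred in spec.edges)
    exo = spec.exogenous
    psis: list[tuple[int, int]] = []
    # residual variances of endogenous variables, in variable order
    for v in spec.endogenous:
        psis.append((idx[v], idx[v]))
    # exogenous variances then the saturated exogenous covariance block
    for v in exo:
        psis.append((idx[v], idx[v]))
    auto = set()
    for a_i in range(len(exo)):
        for b_i in range(a_i + 1, len(exo)):
            i, j = sorted((idx[exo[a_i]], idx[exo[b_i]]), reverse=True)
            psis.append((i, j))
            auto.add((i, j))
    # declared extra covariances (residual covariances), skipping duplicates of
    # the automatic exogenous block
    for a, b in spec.covariances:
        i, j = sorted((idx[a], idx[b]), reverse=True)
        if (i, j) not in auto:
            psis.append((i, j))
    return _ParamMap(vars_, betas, tuple(psis))


def _has_residual_covariances(spec: PathModelSpec) -> bool:
    exo = set(spec.exogenous)
    return any(not ({a, b} <= exo) for a, b in spec.covariances)


# ---------------------------------------------------------------------------
# discrepancy function
# ---------------------------------------------------------------------------


def _implied_sigma(A: np.ndarray, Psi: np.ndarray) -> np.ndarray:
    p = A.shape[0]
    B = np.linalg.inv(np.eye(p) - A)
    return B @ Psi @ B.T


def _fml(S: np.ndarray, logdet_S: float, Sigma: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf
    p = S.shape[0]
    val = logdet + float(np.trace(np.linalg.solve(Sigma, S))) - logdet_S - p
    return max(val, 0.0) if val > -1e-8 else val


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    k = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    fx = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * fx + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Everything estimated for one path model on one dataset."""

    spec: PathModelSpec
    n: int
    params: pd.DataFrame          # lhs, op, rhs, estimate, se, z, pvalue, std_estimate
    A: pd.DataFrame               # coefficient matrix [outcome, predictor]
    A_std: pd.DataFrame           # standardized coefficient matrix
    psi: pd.DataFrame
    sigma: pd.DataFrame           # model-implied covariance
    sample_cov: pd.DataFrame
    fml: float
    chi2: float
    df: int
    pvalue: float
    baseline_chi2: float
    baseline_df: int
    cfi: float
    srmr: float
    aic: float
    aicc: float
    n_free: int
    r2: dict[str, float]
    data: pd.DataFrame | None = None
    clusters: pd.Series | None = None
    converged: bool = True
    theta: np.ndarray | None = None
    param_map: _ParamMap | None = None

    def edge_estimate(self, outcome: str, predictor: str) -> pd.Series:
        hit = self.params[
            (self.params["op"] == "~")
            & (self.params["lhs"] == outcome)
            & (self.params["rhs"] == predictor)
        ]
        if hit.empty:
            raise KeyError(f"edge {outcome} ~ {predictor} not in model")
        return hit.iloc[0]

    def edge_table(self) -> pd.DataFrame:
        return self.params[self.params["op"] == "~"].reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            f"Path model fit (n={self.n}, k={self.n_free})",
            f"  chi2({self.df}) = {self.chi2:.3f}, p = {self.pvalue:.4f}"
            if self.df > 0
            else f"  chi2({self.df}) = {self.chi2:.3f} (saturated)",
            f"  CFI = {self.cfi:.3f}  SRMR = {self.srmr:.4f}  AICc = {self.aicc:.2f}",
        ]
        for v, r in self.r2.items():
            lines.append(f"  R2[{v}] = {r:.3f}")
        return "\n".join(lines)


def _as_frame(data) -> tuple[pd.DataFrame, pd.Series | None]:
    if isinstance(data, StandardizedDataset):
        return data.data, data.clusters
    return pd.DataFrame(data), None


def fit_path_model(
    spec: PathModelSpec,
    data,
    *,
    se: bool = True,
    clusters: pd.Series | None = None,
) -> FitResult:
    """Fit a recursive path model by maximum likelihood.

    ``data`` is a :class:`StandardizedDataset` or any numeric DataFrame whose
    columns include every model variable. Set ``se=False`` to skip the
    (numeric-Hessian) standard errors when only the discrepancy is needed —
    the stepwise search uses this for its many throwaway refits.
    """
    frame, ds_clusters = _as_frame(data)
    clusters = clusters if clusters is not None else ds_clusters
    missing = [v for v in spec.variables if v not in frame.columns]
    if missing:
        raise DataError(f"data lacks model variables: {missing}")
    X = frame[list(spec.variables)]
    n, p = X.shape
    S = X.cov().to_numpy()
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0 or not np.isfinite(logdet_S):
        raise DataError("sample covariance matrix is singular")

    pmap = _param_map(spec)
    k = pmap.k
    if n <= k + 1:
        raise DataError(
            f"n={n} must exceed the number of free parameters plus one (k={k}) "
            "for estimation and AICc"
        )
    idx = {v: i for i, v in enumerate(spec.variables)}

    theta = np.zeros(k)
    # closed-form start: per-equation least squares on S, exogenous block = S
    nb = len(pmap.betas)
    beta_vals = {}
    for y in spec.endogenous:
        pa = [idx[v] for v in spec.parents(y)]
        b = np.linalg.solve(S[np.ix_(pa, pa)], S[pa, idx[y]])
        for pos, j in enumerate(pa):
            beta_vals[(idx[y], j)] = b[pos]
    for t, key in enumerate(pmap.betas):
        theta[t] = beta_vals[key]
    exo = set(idx[v] for v in spec.exogenous)
    for t, (i, j) in enumerate(pmap.psis):
        if i == j and i not in exo:  # residual variance
            y = i
            pa = [idx[v] for v in spec.parents(spec.variables[i])]
            b = np.array([beta_vals[(y, j2)] for j2 in pa])
            theta[nb + t] = S[y, y] - S[y, pa] @ b
        elif i in exo and j in exo:
            theta[nb + t] = S[i, j]
        else:
            theta[nb + t] = 0.0  # declared residual covariance

    def objective(th: np.ndarray) -> float:
        A, Psi = pmap.build(th)
        return _fml(S, logdet_S, _implied_sigma(A, Psi))

    converged = True
    if _has_residual_covariances(spec):
        theta, converged = _optimize(objective, theta, pmap, S, logdet_S)

    A, Psi = pmap.build(theta)
    Sigma = _implied_sigma(A, Psi)
    fml = objective(theta)
    if not np.isfinite(fml):
        raise ConvergenceError("implied covariance not positive definite at solution")

    chi2 = max((n - 1) * fml, 0.0)
    df = p * (p + 1) // 2 - k
    if df < 0:
        raise DataError(f"negative degrees of freedom (k={k} > {p*(p+1)//2})")
    pvalue = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")

    # independence baseline: diagonal Sigma with free variances
    fml0 = float(np.log(np.diag(S)).sum() - logdet_S)
    chi2_0 = max((n - 1) * fml0, 0.0)
    df0 = p * (p - 1) // 2

    denom = max(chi2_0 - df0, chi2 - df, 0.0)
    cfi = 1.0 - (max(chi2 - df, 0.0) / denom if denom > 0 else 0.0)

    sd = np.sqrt(np.diag(S))
    resid = (S - Sigma) / np.outer(sd, sd)
    iu = np.triu_indices(p)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))

    aic = chi2 + 2 * k
    aicc = aic + 2 * k * (k + 1) / (n - k - 1)

    sig_sd = np.sqrt(np.diag(Sigma))
    A_std = A * np.outer(1.0 / sig_sd, sig_sd)
    r2 = {
        v: float(1.0 - Psi[idx[v], idx[v]] / Sigma[idx[v], idx[v]])
        for v in spec.endogenous
    }

    se_vec = np.full(k, np.nan)
    if se:
        H = _numeric_hessian(objective, theta)
        try:
            acov = 2.0 / (n - 1) * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            acov = 2.0 / (n - 1) * np.linalg.pinv(H)
        diag = np.diag(acov).copy()
        diag[diag < 0] = np.nan
        se_vec = np.sqrt(diag)

    rows = []
    for t, (i, j) in enumerate(pmap.betas):
        est = theta[t]
        s_ = se_vec[t]
        z = est / s_ if s_ and np.isfinite(s_) and s_ > 0 else np.nan
        rows.append(
            {
                "lhs": spec.variables[i],
                "op": "~",
                "rhs": spec.variables[j],
                "estimate": est,
                "se": s_,
                "z": z,
                "pvalue": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                "std_estimate": A_std[i, j],
            }
        )
    for t, (i, j) in enumerate(pmap.psis):
        est = theta[nb + t]
        s_ = se_vec[nb + t]
        z = est / s_ if s_ and np.isfinite(s_) and s_ > 0 else np.nan
        rows.append(
            {
                "lhs": spec.variables[i],
                "op": "~~",
                "rhs": spec.variables[j],
                "estimate": est,
                "se": s_,
                "z": z,
                "pvalue": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                "std_estimate": est / (sig_sd[i] * sig_sd[j]),
            }
        )
    params = pd.DataFrame(rows)

    vars_ = list(spec.variables)
    return FitResult(
        spec=spec,
        n=n,
        params=params,
        A=pd.DataFrame(A, index=vars_, columns=vars_),
        A_std=pd.DataFrame(A_std, index=vars_, columns=vars_),
        psi=pd.DataFrame(Psi, index=vars_, columns=vars_),
        sigma=pd.DataFrame(Sigma, index=vars_, columns=vars_),
        sample_cov=pd.DataFrame(S, index=vars_, columns=vars_),
        fml=fml,
        chi2=chi2,
        df=df,
        pvalue=pvalue,
        baseline_chi2=chi2_0,
        baseline_df=df0,
        cfi=cfi,
        srmr=srmr,
        aic=aic,
        aicc=aicc,
        n_free=k,
        r2=r2,
        data=X,
        clusters=clusters,
        converged=converged,
        theta=theta,
        param_map=pmap,
    )


def _optimize(objective, theta0, pmap: _ParamMap, S, logdet_S):
    """Quasi-Newton minimisation of F_ML with an analytic gradient."""
    nb = len(pmap.betas)
    p = len(pmap.variables)
    I = np.eye(p)

    def grad(th):
        A, Psi = pmap.build(th)
        try:
            B = np.linalg.inv(I - A)
        except np.linalg.LinAlgError:
            return np.zeros_like(th)
        Sigma = B @ Psi @ B.T
        try:
            Sinv = np.linalg.inv(Sigma)
        except np.linalg.LinAlgError:
            return np.zeros_like(th)
        W = Sinv - Sinv @ S @ Sinv
        g = np.empty_like(th)
        M1 = Sigma @ W @ B          # for beta gradients
        M2 = B.T @ W @ B            # for psi gradients
        for t, (i, j) in enumerate(pmap.betas):
            g[t] = 2.0 * M1[j, i]
        for t, (i, j) in enumerate(pmap.psis):
            g[nb + t] = M2[i, j] if i == j else 2.0 * M2[i, j]
        return g

    bounds = [(None, None)] * nb + [
        ((1e-10, None) if i == j else (None, None)) for (i, j) in pmap.psis
    ]
    res = optimize.minimize(
        objective,
        theta0,
        jac=grad,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 5000, "ftol": 1e-13, "gtol": 1e-9},
    )
    if not np.isfinite(res.fun):
        raise ConvergenceError(f"optimiser diverged: {res.message}")
    # the line search can stall at machine precision; judge by the gradient
    converged = bool(res.success) or float(np.abs(grad(res.x)).max()) < 1e-6
    return res.x, converged


def fit_baseline_model(data, variables: Sequence[str]) -> dict:
    """Independence model (all variables mutually uncorrelated, variances
    free): the incremental-fit reference point."""
    frame, _ = _as_frame(data)
    X = frame[list(variables)]
    n, p = X.shape
    S = X.cov().to_numpy()
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise DataError("sample covariance matrix is singular")
    fml0 = float(np.log(np.diag(S)).sum() - logdet_S)
    return {"fml": fml0, "chi2": max((n - 1) * fml0, 0.0), "df": p * (p - 1) // 2, "n": n, "k": p}


def fit_indices(fit: FitResult, baseline: dict | None = None) -> dict:
    """Fit indices for a fitted model against an independence baseline.

    When ``baseline`` is omitted the baseline computed during fitting is used.
    ``baseline`` may be the dict from :func:`fit_baseline_model` (it must be
    fitted on the same data).
    """
    T, df, n, k = fit.chi2, fit.df, fit.n, fit.n_free
    T0 = baseline["chi2"] if baseline else fit.baseline_chi2
    df0 = baseline["df"] if baseline else fit.baseline_df
    denom = max(T0 - df0, T - df, 0.0)
    cfi = 1.0 - (max(T - df, 0.0) / denom if denom > 0 else 0.0)
    if n <= k + 1:
        raise DataError(f"AICc undefined for n={n} <= k+1={k + 1}")
    aic = T + 2 * k
    return {
        "chi2": T,
        "df": df,
        "pvalue": fit.pvalue,
        "cfi": cfi,
        "srmr": fit.srmr,
        "aic": aic,
        "aicc": aic + 2 * k * (k + 1) / (n - k - 1),
    }


# ---------------------------------------------------------------------------
# modification indices
# ---------------------------------------------------------------------------


def modification_indices(
    spec: PathModelSpec,
    data,
    whitelist: Sequence[tuple[str, str]],
    *,
    fit: FitResult | None = None,
) -> pd.DataFrame:
    """Expected chi-square improvement from freeing each candidate edge.

    Computed as the exact likelihood-ratio drop from a single-edge refit (not
    the score-test approximation), so the conventional 3.84 cut-off is a true
    1-df likelihood-ratio threshold. Candidates already in the model are
    ignored; candidates that would create a cycle are listed as inadmissible
    with a reason rather than silently skipped. Sorted by MI, descending
    (ties broken lexicographically by edge for determinism).
    """
    base = fit if fit is not None else fit_path_model(spec, data, se=False)
    rows = []
    for outcome, predictor in whitelist:
        if (outcome, predictor) in spec.edges:
            continue
        if outcome == predictor or spec.would_cycle(outcome, predictor):
            rows.append(
                {
                    "lhs": outcome,
                    "rhs": predictor,
                    "mi": np.nan,
                    "admissible": False,
                    "reason": "would create a cycle",
                }
            )
            continue
        trial = spec.with_edge(outcome, predictor)
        refit = fit_path_model(trial, data, se=False)
        rows.append(
            {
                "lhs": outcome,
                "rhs": predictor,
                "mi": max(base.chi2 - refit.chi2, 0.0),
                "admissible": True,
                "reason": "",
            }
        )
    table = pd.DataFrame(rows, columns=["lhs", "rhs", "mi", "admissible", "reason"])
    return table.sort_values(
        ["admissible", "mi", "lhs", "rhs"], ascending=[False, False, True, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# cluster-robust standard errors
# ---------------------------------------------------------------------------


def cluster_robust_se(fit: FitResult, clusters: pd.Series | None = None) -> pd.DataFrame:
    """Sandwich standard errors aggregating score contributions within
    clusters (institutions within countries). Point estimates are unchanged;
    only the ``se``, ``z`` and ``pvalue`` columns differ from ``fit.params``.

    With every row its own cluster this reduces to the conventional robust
    (heteroskedasticity-consistent) sandwich.
    """
    if fit.data is None or fit.theta is None or fit.param_map is None:
        raise ValueError("fit must carry its data (se=True fit_path_model result)")
    cl = clusters if clusters is not None else fit.clusters
    if cl is None:
        raise ValueError("no cluster labels supplied")
    cl = pd.Series(np.asarray(cl))
    if cl.nunique() < 2:
        raise DataError("cluster-robust errors require at least two clusters")

    pmap = fit.param_map
    X = fit.data.to_numpy() - fit.data.to_numpy().mean(axis=0)
    p = X.shape[1]
    I = np.eye(p)
    labels = cl.to_numpy()
    groups = [np.flatnonzero(labels == g) for g in pd.unique(labels)]
    C_groups = [X[g].T @ X[g] for g in groups]
    n_groups = [len(g) for g in groups]
    nb = len(pmap.betas)

    def cluster_scores(th: np.ndarray) -> np.ndarray:
        A, Psi = pmap.build(th)
        B = np.linalg.inv(I - A)
        Sigma = B @ Psi @ B.T
        Sinv = np.linalg.inv(Sigma)
        out = np.empty((len(groups), pmap.k))
        for gi, (Cg, ng) in enumerate(zip(C_groups, n_groups)):
            Wg = ng * Sinv - Sinv @ Cg @ Sinv
            M1 = Sigma @ Wg @ B
            M2 = B.T @ Wg @ B
            for t, (i, j) in enumerate(pmap.betas):
                out[gi, t] = -M1[j, i]
            for t, (i, j) in enumerate(pmap.psis):
                out[gi, nb + t] = -0.5 * M2[i, j] if i == j else -M2[i, j]
        return out

    def neg_loglik(th: np.ndarray) -> float:
        A, Psi = pmap.build(th)
        Sigma = _implied_sigma(A, Psi)
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            return np.inf
        C = X.T @ X
        return 0.5 * (X.shape[0] * logdet + float(np.trace(np.linalg.solve(Sigma, C))))

    G_scores = cluster_scores(fit.theta)
    G = G_scores.T @ G_scores
    H = _numeric_hessian(neg_loglik, fit.theta)
    Hinv = np.linalg.pinv(H)
    acov = Hinv @ G @ Hinv
    diag = np.diag(acov).copy()
    diag[diag < 0] = np.nan
    se = np.sqrt(diag)

    params = fit.params.copy()
    params["se"] = se
    params["z"] = params["estimate"] / params["se"]
    params["pvalue"] = 2 * stats.norm.sf(np.abs(params["z"]))
    return params
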