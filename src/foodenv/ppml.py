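"""Poisson pseudo-maximum-likelihood with high-dimensional fixed effects.

Fits an exponential conditional-mean model for a non-negative outcome with
tract and year fixed effects absorbed by weighted alternating projections
inside an iteratively re-weighted least-squares loop, with step-halving,
singleton/separation dropping and tract-clustered sandwich standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import norm

__all__ = [
    "PanelSpec",
    "PPMLFit",
    "drop_singletons_and_separated",
    "fit_ppml_hdfe",
    "cluster_robust_se",
    "run_model_suite",
]

OUTER_TOL = 1e-9
INNER_TOL = 1e-10
MAX_OUTER = 200
MAX_INNER = 10_000


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


class EmptyPanelError(ValueError):
    pass


@dataclass(frozen=True)
class PanelSpec:
    """Declarative description of one two-way fixed-effects model."""

    outcome: str
    regressors: tuple[str, ...]
    fe: tuple[str, ...] = ("tract_id", "year")
    cluster: str = "tract_id"
    subset: str = "all"  # all | metro | nonmetro


@dataclass
class PPMLFit:
    params: pd.Series
    se: pd.Series
    zstat: pd.Series
    pvalues: pd.Series
    n_obs: int
    n_singletons_dropped: int
    n_separated_dropped: int
    deviance: float
    pseudo_r2: float
    iterations: int
    converged: bool
    dropped_collinear: tuple[str, ...] = ()
    n_clusters: int = 0
    deviance_trace: tuple[float, ...] = ()  # one entry per outer iteration
    # internals needed to recompute sandwich variances
    _X_absorbed: np.ndarray = field(default=None, repr=False)
    _residual: np.ndarray = field(default=None, repr=False)
    _weights: np.ndarray = field(default=None, repr=False)
    _cluster_ids: np.ndarray = field(default=None, repr=False)
    _mu: np.ndarray = field(default=None, repr=False)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self._mu

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.se, "z": self.zstat, "p": self.pvalues}
        )


def drop_singletons_and_separated(
    panel: pd.DataFrame,
    outcome: str,
    fe: Sequence[str] = ("tract_id", "year"),
) -> tuple[pd.DataFrame, int, int]:
    """Iteratively remove observations that carry no identifying variation.

    Two rules are applied to a fixed point: (a) singletons — observations
    alone in one of their fixed-effect groups; (b) separated — observations
    in a fixed-effect group whose outcome is identically zero, whose group
    intercept diverges to -inf under the log link.
    """
    df = panel
    n_singletons = 0
    n_separated = 0
    while True:
        changed = False
        for col in fe:
            sizes = df.groupby(col)[col].transform("size")
            mask = sizes <= 1
            if mask.any():
                n_singletons += int(mask.sum())
                df = df[~mask]
                changed = True
        for col in fe:
            if df.empty:
                break
            gmax = df.groupby(col)[outcome].transform("max")
            mask = gmax <= 0
            if mask.any():
                n_separated += int(mask.sum())
                df = df[~mask]
                changed = True
        if not changed:
            break
    if df.empty:
        raise EmptyPanelError("no identifying variation: panel empty after dropping")
    return df.copy(), n_singletons, n_separated


def _absorb(
    v: np.ndarray,
    groups: list[np.ndarray],
    group_sizes: list[int],
    w: np.ndarray,
    tol: float = INNER_TOL,
) -> np.ndarray:
    """Weighted within-transform: iterated demeaning over each fixed-effect
    dimension until the largest subtracted group mean is below ``tol``."""
    v = np.array(v, dtype=float, copy=True)
    if not groups:
        return v
    single = v.ndim == 1
    if single:
        v = v[:, None]
    wsums = [np.bincount(g, weights=w, minlength=m) for g, m in zip(groups, group_sizes)]
    for _ in range(MAX_INNER):
        delta = 0.0
        for g, ws, m in zip(groups, wsums, group_sizes):
            for k in range(v.shape[1]):
                means = np.bincount(g, weights=w * v[:, k], minlength=m) / ws
                v[:, k] -= means[g]
                delta = max(delta, float(np.max(np.abs(means))))
        if delta < tol:
            break
    else:
        raise ConvergenceError("fixed-effect projection did not converge", [])
    return v[:, 0] if single else v


def _independent_columns(
    X_absorbed: np.ndarray, orig_norms: np.ndarray, tol: float = 1e-7
) -> list[int]:
    """Indices of columns with identifying variation left after absorption,
    chosen greedily in column order (modified Gram-Schmidt): a column is
    dropped when its part orthogonal to the kept columns is below ``tol``
    relative to its pre-absorption norm."""
    keep: list[int] = []
    basis: list[np.ndarray] = []
    for j in range(X_absorbed.shape[1]):
        v = X_absorbed[:, j].astype(float).copy()
        for q in basis:
            v -= (q @ v) * q
        norm = np.linalg.norm(v)
        if orig_norms[j] > 0 and norm > tol * orig_norms[j]:
            keep.append(j)
            basis.append(v / norm)
    return keep


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(ylogy - (y - mu)))


def fit_ppml_hdfe(
    panel: pd.DataFrame,
    spec: PanelSpec,
    drop: bool = True,
    max_iter: int = MAX_OUTER,
    tol: float = OUTER_TOL,
) -> PPMLFit:
    """Solve the Poisson pseudo-likelihood score equations
    sum_i (y_i - exp(x_i beta + fe_i)) x_i = 0 by IRLS with fixed effects
    absorbed from the working response and regressors at every iteration.

    Collinear regressors (after absorption) are dropped with a warning.
    Deviance is kept non-increasing by step-halving; outer convergence is
    declared when the relative deviance change falls below ``tol``.
    """
    df = panel
    n_singletons = n_separated = 0
    if drop and spec.fe:
        df, n_singletons, n_separated = drop_singletons_and_separated(df, spec.outcome, spec.fe)
    if df.empty:
        raise EmptyPanelError("empty panel")

    y = df[spec.outcome].to_numpy(dtype=float)
    if np.any(y < 0):
        raise ValueError(f"outcome {spec.outcome!r} has negative values")
    if np.all(y == 0):
        raise EmptyPanelError("outcome identically zero")

    names = list(spec.regressors)
    if spec.fe:
        X = df[names].to_numpy(dtype=float)
    else:
        X = np.column_stack([df[names].to_numpy(dtype=float), np.ones(len(df))]) if names else np.ones(
            (len(df), 1)
        )
        names = names + ["const"]
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite regressor values")

    groups, sizes = [], []
    for col in spec.fe:
        codes, uniq = pd.factorize(df[col], sort=True)
        groups.append(codes)
        sizes.append(len(uniq))

    # collinearity screen on the absorbed regressors; greedy in column
    # order so later duplicates are the ones dropped
    dropped: tuple[str, ...] = ()
    if X.shape[1]:
        X0 = _absorb(X, groups, sizes, np.ones(len(df)))
        keep = _independent_columns(X0, np.linalg.norm(X, axis=0))
        if len(keep) < X.shape[1]:
            dropped = tuple(names[j] for j in range(X.shape[1]) if j not in set(keep))
            warnings.warn(f"dropping collinear regressors: {dropped}", stacklevel=2)
            X = X[:, keep]
            names = [names[j] for j in keep]

    mu = (y + y.mean()) / 2.0
    eta = np.log(mu)
    dev = _deviance(y, mu)
    trace = [dev]
    beta = np.zeros(X.shape[1])
    converged = False
    Xt = X
    w = mu

    for it in range(1, max_iter + 1):
        w = mu
        z = eta + (y - mu) / mu
        zt = _absorb(z, groups, sizes, w)
        Xt = _absorb(X, groups, sizes, w) if X.shape[1] else np.empty((len(y), 0))
        if Xt.shape[1]:
            xtw = Xt * w[:, None]
            A = xtw.T @ Xt
            b = xtw.T @ zt
            d = np.sqrt(np.diag(A))
            d[d <= 0] = 1.0
            try:
                beta = linalg.solve(A / np.outer(d, d), b / d, assume_a="pos") / d
            except linalg.LinAlgError:
                beta = linalg.lstsq(np.sqrt(w)[:, None] * Xt, np.sqrt(w) * zt)[0]
            resid = zt - Xt @ beta
        else:
            resid = zt
        eta_candidate = z - resid
        if it == 1:
            # the starting mean is not a model fit, so the first step may
            # legitimately raise the deviance; accept it unconditionally
            eta_new = eta_candidate
            mu_new = np.exp(np.clip(eta_new, -700, 700))
            dev_new = _deviance(y, mu_new)
        else:
            step = 1.0
            for _ in range(50):
                eta_new = eta + step * (eta_candidate - eta)
                mu_new = np.exp(np.clip(eta_new, -700, 700))
                dev_new = _deviance(y, mu_new)
                if (np.isfinite(dev_new) and dev_new <= dev * (1 + 1e-12)) or step < 1e-8:
                    break
                step /= 2.0
        rel = abs(dev - dev_new) / max(abs(dev), 1e-12)
        eta, mu, dev = eta_new, mu_new, dev_new
        trace.append(dev)
        if rel < tol and it >= 2:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations", trace)

    tiny = mu < 1e-12
    if tiny.any():
        warnings.warn(
            f"{int(tiny.sum())} observations have fitted means < 1e-12 "
            "(possible residual separation)",
            stacklevel=2,
        )

    cluster_ids = df[spec.cluster].to_numpy() if spec.cluster in df.columns else np.arange(len(df))
    fit = PPMLFit(
        params=pd.Series(beta, index=names),
        se=pd.Series(np.nan, index=names),
        zstat=pd.Series(np.nan, index=names),
        pvalues=pd.Series(np.nan, index=names),
        n_obs=len(df),
        n_singletons_dropped=n_singletons,
        n_separated_dropped=n_separated,
        deviance=dev,
        pseudo_r2=float(np.corrcoef(y, mu)[0, 1] ** 2) if np.std(mu) > 0 else 0.0,
        iterations=it,
        converged=converged,
        dropped_collinear=dropped,
        n_clusters=int(pd.factorize(df[spec.cluster])[1].size) if spec.cluster in df.columns else len(df),
        deviance_trace=tuple(trace),
        _X_absorbed=Xt,
        _residual=y - mu,
        _weights=w,
        _cluster_ids=cluster_ids,
        _mu=mu,
    )
    if Xt.shape[1]:
        se = cluster_robust_se(fit)
        fit.se = se
        fit.zstat = fit.params / se
        fit.pvalues = pd.Series(2.0 * norm.sf(np.abs(fit.zstat)), index=names)
    return fit


def cluster_robust_se(fit: PPMLFit, cluster_ids: np.ndarray | None = None) -> pd.Series:
    """Cluster-robust sandwich standard errors.

    bread = (X~' W X~)^-1 with the absorbed regressors X~ and IRLS weights
    W; meat = sum over clusters of the outer products of cluster-summed
    scores (y - mu) x~; a G/(G-1) small-sample factor is applied.
    """
    Xt = fit._X_absorbed
    if Xt is None or Xt.shape[1] == 0:
        raise ValueError("fit carries no regressors")
    ids = fit._cluster_ids if cluster_ids is None else np.asarray(cluster_ids)
    codes, uniq = pd.factorize(ids)
    n_clusters = len(uniq)
    if n_clusters < 2:
        raise ValueError("need at least two clusters")

    scores = Xt * fit._residual[:, None]
    cluster_scores = np.zeros((n_clusters, Xt.shape[1]))
    np.add.at(cluster_scores, codes, scores)
    meat = cluster_scores.T @ cluster_scores
    A = (Xt * fit._weights[:, None]).T @ Xt
    d = np.sqrt(np.diag(A))
    d[d <= 0] = 1.0
    bread = linalg.inv(A / np.outer(d, d)) / np.outer(d, d)
    vcov = (n_clusters / (n_clusters - 1)) * bread @ meat @ bread
    return pd.Series(np.sqrt(np.diag(vcov)), index=fit.params.index)


CONTROLS = ("log_population", "pct_bachelor", "poverty_rate")
RACE_REGRESSORS = ("pct_white", "pct_black", "pct_asian")
SVI_SUBTHEMES = ("svi_ses", "svi_household", "svi_minority_language", "svi_housing_transport")


def _subset(panel: pd.DataFrame, which: str) -> pd.DataFrame:
    if which == "all":
        return panel
    if which == "metro":
        return panel[panel["metro"].astype(bool)]
    if which == "nonmetro":
        return panel[~panel["metro"].astype(bool)]
    raise ValueError(f"unknown subset {which!r}")


def join_panel(indices_panel: pd.DataFrame, attrs: pd.DataFrame) -> pd.DataFrame:
    """Join the indices panel to tract-year attributes and derive
    ``log_population``."""
    attrs = attrs.copy()
    attrs["tract_id"] = attrs["tract_id"].astype(str)
    panel = indices_panel.copy()
    panel["tract_id"] = panel["tract_id"].astype(str)
    merged = panel.merge(attrs, on=["tract_id", "year"], how="inner", validate="one_to_one")
    merged["log_population"] = np.log(merged["population"].astype(float))
    return merged


def run_model_suite(
    indices_panel: pd.DataFrame,
    attrs: pd.DataFrame,
    outcomes: Sequence[str] = ("mrfei", "hhi"),
    include_svi: bool = True,
) -> pd.DataFrame:
    """Run the full model grid and return a tidy coefficient table.

    Baseline grid: outcomes x {race model, Hispanic model} x
    {all, metro, nonmetro}; SVI variants (overall score, four sub-themes)
    are fitted on the full sample only.
    """
    panel = join_panel(indices_panel, attrs)
    specs: list[tuple[str, PanelSpec]] = []
    for outcome in outcomes:
        for model, regs in (("race", RACE_REGRESSORS), ("hispanic", ("pct_hispanic",))):
            for subset in ("all", "metro", "nonmetro"):
                specs.append(
                    (
                        f"{outcome}-{model}-{subset}",
                        PanelSpec(outcome, tuple(regs) + CONTROLS, subset=subset),
                    )
                )
        if include_svi:
            specs.append(
                (f"{outcome}-svi_overall-all", PanelSpec(outcome, ("svi_overall",) + CONTROLS))
            )
            specs.append(
                (f"{outcome}-svi_subthemes-all", PanelSpec(outcome, SVI_SUBTHEMES + CONTROLS))
            )

    rows = []
    for model_id, spec in specs:
        sub = _subset(panel, spec.subset)
        if sub.empty:
            warnings.warn(f"model {model_id}: empty subset, skipped", stacklevel=2)
            continue
        try:
            fit = fit_ppml_hdfe(sub, spec)
        except (EmptyPanelError, ConvergenceError, ValueError, linalg.LinAlgError) as exc:
            warnings.warn(f"model {model_id}: {exc}", stacklevel=2)
            continue
        for term in fit.params.index:
            rows.append(
                {
                    "model_id": model_id,
                    "outcome": spec.outcome,
                    "subset": spec.subset,
                    "term": term,
                    "estimate": fit.params[term],
                    "se": fit.se[term],
                    "z": fit.zstat[term],
                    "p": fit.pvalues[term],
                    "n_obs": fit.n_obs,
                    "n_singletons_dropped": fit.n_singletons_dropped,
                    "n_separated_dropped": fit.n_separated_dropped,
                    "pseudo_r2": fit.pseudo_r2,
                }
            )
    return pd.DataFrame(rows)
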