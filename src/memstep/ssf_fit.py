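"""Conditional-logistic step-selection fitting and post-processing.

A step-selection model assigns each observed step a *stratum*: the used
endpoint plus J matched available endpoints sharing the same start and time.
The continuous normalizer over the spatial domain is approximated by this
discretized choice set, so the likelihood is a stratified softmax

    loglik(beta) = sum_strata [ eta_used - log sum_candidates exp(eta) ],
    eta = beta' x,

which is concave in beta. It is maximized here by Newton's method with
analytic gradient and Hessian (affine-invariant, so raw covariate scales —
e.g. TSLV in days and its square — need no standardization). The covariance
is the inverse observed information at the optimum, giving Wald intervals.

Post-processing: relative selection strength RSS(x1, x2) = exp(beta'(x1-x2)),
the ratio of selection weights between two locations all else equal, and the
TSLV vertex -b_lin/(2 b_quad), the time-since-last-visit at which selection
for revisiting peaks when modeled with linear + quadratic terms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Stratum",
    "Term",
    "FitResult",
    "build_design",
    "clogit_loglik",
    "fit_clogit",
    "rss",
    "tslv_optimum",
    "design_matrix",
]

META_COLS = ("stratum_id", "candidate_id", "used")


@dataclass
class Stratum:
    """One choice set: exactly one used candidate plus J available candidates.

    ``covariates`` maps term name -> array of length J+1 over candidates;
    ``used_index`` marks the observed step's position (conventionally 0).
    All candidates share the stratum time ``t`` and start location.
    """

    stratum_id: int
    t: float
    covariates: dict[str, np.ndarray]
    used_index: int = 0

    def n_candidates(self) -> int:
        return len(next(iter(self.covariates.values())))


@dataclass(frozen=True)
class Term:
    """A model term; ``quadratic=True`` expands to columns name and name_sq."""

    name: str
    quadratic: bool = False


@dataclass
class FitResult:
    """Fitted coefficients, covariance, and fit diagnostics."""

    beta: pd.Series
    vcov: pd.DataFrame
    loglik: float
    converged: bool
    n_strata: int
    n_iter: int = 0
    diagnostic: str = ""

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov.values)), index=self.beta.index)

    def wald_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        from scipy import stats as _st

        z = _st.norm.ppf(0.5 + level / 2)
        b, s = self.beta[name], self.se[name]
        return (b - z * s, b + z * s)

    def to_json(self, path=None) -> str:
        obj = {
            "beta": self.beta.to_dict(),
            "se": self.se.to_dict(),
            "vcov": {"names": list(self.beta.index), "matrix": self.vcov.values.tolist()},
            "loglik": self.loglik,
            "converged": self.converged,
            "n_strata": self.n_strata,
            "n_iter": self.n_iter,
            "diagnostic": self.diagnostic,
        }
        s = json.dumps(obj, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            obj = json.load(fh)
        names = obj["vcov"]["names"]
        return cls(
            beta=pd.Series(obj["beta"]).reindex(names),
            vcov=pd.DataFrame(np.array(obj["vcov"]["matrix"]), index=names, columns=names),
            loglik=obj["loglik"],
            converged=obj["converged"],
            n_strata=obj["n_strata"],
            n_iter=obj.get("n_iter", 0),
            diagnostic=obj.get("diagnostic", ""),
        )


def build_design(strata: Sequence[Stratum], terms: Sequence[Term | str]) -> pd.DataFrame:
    """Flatten strata into the design table: one row per candidate.

    Columns: stratum_id, candidate_id, used flag, then one column per term
    (quadratic terms expand to ``name`` and ``name_sq`` with name_sq = name**2
    rowwise). Errors if a covariate is missing for any stratum, or if a term
    is constant within every stratum (the conditional likelihood cannot
    identify it).
    """
    terms = [Term(t) if isinstance(t, str) else t for t in terms]
    if not terms:
        raise ValueError("need at least one term")
    rows = {"stratum_id": [], "candidate_id": [], "used": []}
    cols: dict[str, list] = {}
    for term in terms:
        cols[term.name] = []
        if term.quadratic:
            cols[term.name + "_sq"] = []
    for s in strata:
        n = s.n_candidates()
        for term in terms:
            if term.name not in s.covariates:
                raise ValueError(f"stratum {s.stratum_id}: missing covariate {term.name!r}")
            v = np.asarray(s.covariates[term.name], dtype=float)
            if v.shape != (n,):
                raise ValueError(f"stratum {s.stratum_id}: term {term.name!r} has wrong length")
            cols[term.name].extend(v)
            if term.quadratic:
                cols[term.name + "_sq"].extend(v * v)
        rows["stratum_id"].extend([s.stratum_id] * n)
        rows["candidate_id"].extend(range(n))
        rows["used"].extend(1 if i == s.used_index else 0 for i in range(n))
    df = pd.DataFrame({**rows, **cols})
    _check_estimable(df)
    return df


def _term_columns(design: pd.DataFrame) -> list[str]:
    return [c for c in design.columns if c not in META_COLS]


def _check_estimable(design: pd.DataFrame) -> None:
    grp = design.groupby("stratum_id")
    for col in _term_columns(design):
        within = grp[col].transform(lambda v: v.nunique())
        if (within <= 1).all():
            raise ValueError(
                f"term {col!r} is constant within every stratum and cannot be estimated "
                "by the conditional likelihood"
            )


def design_matrix(design: pd.DataFrame):
    """(X, used mask, group start indices) with rows grouped by stratum."""
    cols = _term_columns(design)
    df = design.sort_values(["stratum_id", "candidate_id"], kind="stable")
    X = df[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariate values in design")
    used = df["used"].to_numpy(dtype=int)
    sid = df["stratum_id"].to_numpy()
    _, starts, counts = np.unique(sid, return_index=True, return_counts=True)
    if not np.all(np.add.reduceat(used, starts) == 1):
        raise ValueError("each stratum must contain exactly one used candidate")
    return X, used.astype(bool), starts, counts, cols


def _stratum_logsumexp(eta: np.ndarray, starts: np.ndarray, counts: np.ndarray):
    """Per-stratum logsumexp of eta and per-row softmax probabilities."""
    gmax = np.maximum.reduceat(eta, starts)
    shift = np.repeat(gmax, counts)
    e = np.exp(eta - shift)
    denom = np.add.reduceat(e, starts)
    lse = gmax + np.log(denom)
    probs = e / np.repeat(denom, counts)
    return lse, probs


def clogit_loglik(beta, design: pd.DataFrame) -> float:
    """Conditional-logistic log-likelihood of ``beta`` on a design table.

    Computed with per-stratum log-sum-exp stabilization; invariant to adding
    a stratum-constant to all candidates' linear predictors.
    """
    X, used, starts, counts, cols = design_matrix(design)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (len(cols),):
        raise ValueError(f"beta length {beta.size} != {len(cols)} term columns {cols}")
    eta = X @ beta
    lse, _ = _stratum_logsumexp(eta, starts, counts)
    return float(np.sum(eta[used]) - np.sum(lse))


def _loglik_grad_hess(beta, X, used, starts, counts):
    eta = X @ beta
    lse, w = _stratum_logsumexp(eta, starts, counts)
    ll = float(np.sum(eta[used]) - np.sum(lse))
    wX = w[:, None] * X
    xbar = np.add.reduceat(wX, starts, axis=0)  # (S, p) expected covariates
    grad = X[used].sum(axis=0) - xbar.sum(axis=0)
    info = X.T @ wX - xbar.T @ xbar  # observed information (= -Hessian)
    return ll, grad, info


def fit_clogit(
    design: pd.DataFrame,
    start: Optional[np.ndarray] = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FitResult:
    """Maximize the conditional-logistic likelihood by damped Newton iteration.

    Deterministic given the data and start (default 0). Convergence is
    declared when the gradient's max-norm falls below ``tol`` or the
    (affine-invariant) Newton decrement becomes negligible, whichever
    happens first — the latter matters when covariate columns have wildly
    different scales (days vs days squared). Perfect
    separation (a term's used value always extremal) sends coefficients to
    infinity; it is detected by diverging coefficients with a non-vanishing
    gradient and flagged via ``converged=False`` and ``diagnostic`` rather
    than raised. A singular information matrix at the optimum is an error.
    """
    X, used, starts, counts, cols = design_matrix(design)
    p = len(cols)
    beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    if beta.shape != (p,):
        raise ValueError(f"start length {beta.size} != {p} terms")
    S = len(starts)

    ll, grad, info = _loglik_grad_hess(beta, X, used, starts, counts)
    n_iter = 0
    diagnostic = ""
    converged = False
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(info, grad, rcond=None)[0]
        # affine-invariant stop: the Newton decrement is insensitive to the
        # (possibly wild) relative scaling of covariate columns
        decrement = 0.5 * float(grad @ delta)
        if 0.0 <= decrement < 1e-12 * (1.0 + abs(ll)):
            converged = True
            break
        # cap the step to keep exp() finite on wild covariate scales
        mx = np.max(np.abs(delta))
        if not np.isfinite(mx):
            diagnostic = "Newton step not finite (degenerate information matrix)"
            break
        if mx > 10.0:
            delta *= 10.0 / mx
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new, grad_new, info_new = _loglik_grad_hess(cand, X, used, starts, counts)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:
            diagnostic = "line search failed to improve the likelihood"
            break
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
    else:
        n_iter = max_iter
    if not converged and np.max(np.abs(grad)) < tol:
        converged = True
    if converged and ll > -1e-6 * S:
        # a perfect fit (every used probability ~1) is only attained in the
        # limit |beta| -> inf: complete separation, not a genuine optimum
        converged = False
        worst = cols[int(np.argmax(np.abs(beta)))]
        diagnostic = (
            f"possible complete separation: likelihood saturated (loglik {ll:.3g}) "
            f"with coefficient {worst!r} at {beta[int(np.argmax(np.abs(beta)))]:.3g}"
        )
    if not converged and not diagnostic:
        if np.max(np.abs(beta)) > 25 or ll > -1e-6 * S:
            worst = cols[int(np.argmax(np.abs(beta)))]
            diagnostic = (
                f"possible complete separation: coefficient {worst!r} diverging "
                f"(|beta| up to {np.max(np.abs(beta)):.3g}, loglik {ll:.3g})"
            )
        else:
            diagnostic = f"did not converge in {max_iter} iterations (|grad| = {np.max(np.abs(grad)):.3g})"

    if converged:
        try:
            vcov = np.linalg.inv(info)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError("singular information matrix at the optimum") from e
        if np.any(np.diag(vcov) < 0):
            raise np.linalg.LinAlgError("information matrix not positive definite at the optimum")
        vcov = (vcov + vcov.T) / 2
    else:
        vcov = np.full((p, p), np.nan)

    return FitResult(
        beta=pd.Series(beta, index=cols),
        vcov=pd.DataFrame(vcov, index=cols, columns=cols),
        loglik=ll,
        converged=converged,
        n_strata=S,
        n_iter=n_iter,
        diagnostic=diagnostic,
    )


def rss(x1, x2, fit: FitResult, interval: bool = False, level: float = 0.95):
    """Relative selection strength exp(beta'(x1 - x2)) between two locations.

    ``x1``/``x2`` are covariate vectors (array-likes in the fit's term order,
    or dicts keyed by term name). With ``interval=True`` also returns the
    Wald interval computed on the log scale from the fit covariance.
    """
    names = list(fit.beta.index)

    def _vec(x):
        if isinstance(x, dict):
            missing = [n for n in names if n not in x]
            if missing:
                raise ValueError(f"covariate vector missing terms {missing}")
            return np.array([float(x[n]) for n in names])
        v = np.asarray(x, dtype=float)
        if v.shape != (len(names),):
            raise ValueError(f"covariate vector length {v.size} != {len(names)} fit terms")
        return v

    d = _vec(x1) - _vec(x2)
    log_rss = float(fit.beta.values @ d)
    if not interval:
        return math.exp(log_rss)
    from scipy import stats as _st

    var = float(d @ fit.vcov.values @ d)
    z = _st.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(max(var, 0.0))
    return math.exp(log_rss), math.exp(log_rss - half), math.exp(log_rss + half)


def tslv_optimum(fit: FitResult, linear: str = "tslv", quadratic: str = "tslv_sq") -> float:
    """TSLV (days) at which the quadratic selection term peaks: -b_lin/(2 b_quad).

    Requires a concave profile (negative quadratic coefficient); otherwise
    there is no interior maximum and an error is raised.
    """
    for name in (linear, quadratic):
        if name not in fit.beta.index:
            raise ValueError(f"fit has no term {name!r}")
    b1, b2 = float(fit.beta[linear]), float(fit.beta[quadratic])
    if b2 >= 0:
        raise ValueError(f"quadratic coefficient {b2:.4g} >= 0: no interior maximum")
    return -b1 / (2.0 * b2)
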