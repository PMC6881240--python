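"""Full-information maximum likelihood estimation of path models.

The observed variables are modeled as multivariate normal with
model-implied moments ``mu(theta)``, ``Sigma(theta)`` from the RAM
algebra (see :mod:`lcsm.model`).  With incomplete rows, the likelihood is
evaluated pattern-wise: rows are grouped by missingness pattern and each
group contributes the normal log-density of its observed subvector under
the marginal implied moments — full-information maximum likelihood
(FIML), consistent under missing-at-random.

The objective and its analytic gradient are evaluated per pattern and
then assembled per free parameter through the chain rule; the gradient of
the log-likelihood with respect to the implied moments is aggregated over
patterns once, after which each parameter's derivative costs only a few
vector products.  Optimization is quasi-Newton (L-BFGS-B) from
deterministic moment-based starting values; standard errors come from the
inverse observed information (numerical Hessian of the analytic
gradient).

Negative variance estimates (Heywood cases) are flagged and can be fixed
to zero and refit on request, mirroring common practice for boundary
solutions in growth and change-score models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, stats

from .data import LongitudinalTable, as_table
from .model import Cell, PathModel

__all__ = [
    "FitResult",
    "implied_moments",
    "fiml_loglik",
    "fit",
    "saturated_and_null_fits",
    "modification_indices",
]

_LOG2PI = math.log(2.0 * math.pi)
_PENALTY = 1.0e8


# ----------------------------------------------------------------------
# missingness patterns
# ----------------------------------------------------------------------
@dataclass
class _Pattern:
    idx: np.ndarray  # observed column indices
    n: int
    xbar: np.ndarray
    S: np.ndarray  # biased within-pattern covariance


def _make_patterns(X: np.ndarray) -> list[_Pattern]:
    mask = ~np.isnan(X)
    if not mask.any(axis=1).all():
        raise ValueError("rows with no observed values must be dropped first")
    uniq, inv = np.unique(mask, axis=0, return_inverse=True)
    pats = []
    for k in range(uniq.shape[0]):
        idx = np.nonzero(uniq[k])[0]
        rows = X[inv == k][:, idx]
        n_p = rows.shape[0]
        xbar = rows.mean(axis=0)
        dev = rows - xbar
        pats.append(_Pattern(idx, n_p, xbar, dev.T @ dev / n_p))
    return pats


# ----------------------------------------------------------------------
# compiled model
# ----------------------------------------------------------------------
class CompiledModel:
    """Numeric view of a PathModel: theta vector <-> matrices, objective."""

    def __init__(self, model: PathModel):
        self.model = model
        self.n = model.n_variables
        self.p = model.n_observed
        cmap = model.constraint_map()
        self.param_names: list[str] = sorted(cmap)
        self.k = len(self.param_names)
        self.cells: list[list[Cell]] = [cmap[lab] for lab in self.param_names]
        n = self.n
        A0 = np.zeros((n, n))
        S0 = np.zeros((n, n))
        M0 = np.zeros(n)
        for (mat, i, j), e in model.cells():
            if isinstance(e, str):
                continue
            v = float(e)
            if mat == "A":
                A0[i, j] = v
            elif mat == "S":
                S0[i, j] = v
                S0[j, i] = v
            else:
                M0[i] = v
        self.A0, self.S0, self.M0 = A0, S0, M0
        # flattened cell index arrays for vectorized gradient assembly
        a_p, a_r, a_c = [], [], []
        sd_p, sd_r = [], []
        so_p, so_r, so_c = [], [], []
        m_p, m_r = [], []
        for a, cells in enumerate(self.cells):
            for mat, i, j in cells:
                if mat == "A":
                    a_p.append(a), a_r.append(i), a_c.append(j)
                elif mat == "S":
                    if i == j:
                        sd_p.append(a), sd_r.append(i)
                    else:
                        so_p.append(a), so_r.append(i), so_c.append(j)
                else:
                    m_p.append(a), m_r.append(i)
        ai = np.asarray
        self._a = (ai(a_p, int), ai(a_r, int), ai(a_c, int))
        self._sd = (ai(sd_p, int), ai(sd_r, int))
        self._so = (ai(so_p, int), ai(so_r, int), ai(so_c, int))
        self._m = (ai(m_p, int), ai(m_r, int))

    # -- theta <-> dict -------------------------------------------------
    def theta_from(self, estimates: Mapping[str, float]) -> np.ndarray:
        missing = [lab for lab in self.param_names if lab not in estimates]
        if missing:
            raise KeyError(f"estimates missing labels: {missing[:5]}...")
        return np.array([float(estimates[lab]) for lab in self.param_names])

    def estimates(self, theta: np.ndarray) -> dict[str, float]:
        return dict(zip(self.param_names, map(float, theta)))

    def _fill(self, theta: np.ndarray):
        A = self.A0.copy()
        S = self.S0.copy()
        M = self.M0.copy()
        for t, cells in zip(theta, self.cells):
            for mat, i, j in cells:
                if mat == "A":
                    A[i, j] = t
                elif mat == "S":
                    S[i, j] = t
                    S[j, i] = t
                else:
                    M[i] = t
        return A, S, M

    # -- implied moments ------------------------------------------------
    def moments(self, theta: np.ndarray):
        A, S, M = self._fill(theta)
        I_A = np.eye(self.n) - A
        try:
            B = np.linalg.inv(I_A)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                "structural misspecification: (I - A) is singular"
            ) from err
        C = B @ S @ B.T
        mu_full = B @ M
        p = self.p
        return C[:p, :p], mu_full[:p], B, C, mu_full

    # -- FIML objective -------------------------------------------------
    def loglik_grad(
        self,
        theta: np.ndarray,
        patterns: Sequence[_Pattern],
        want_grad: bool = True,
        violations: list | None = None,
    ):
        """Return (loglik, grad) under the pattern-marginalized normal."""
        p, n = self.p, self.n
        Sigma, mu, B, C, mu_full = self.moments(theta)
        G = np.zeros((p, p))
        gmu = np.zeros(p)
        ll = 0.0
        penalty = 0.0
        for pat in patterns:
            idx = pat.idx
            So = Sigma[np.ix_(idx, idx)]
            try:
                L = np.linalg.cholesky(So)
            except np.linalg.LinAlgError:
                w_min = float(np.linalg.eigvalsh(So).min())
                penalty += _PENALTY * (1.0 + abs(w_min))
                if violations is not None:
                    violations.append(
                        f"implied covariance not positive definite on pattern "
                        f"{idx.tolist()} (min eigenvalue {w_min:.3g})"
                    )
                continue
            k = idx.size
            logdet = 2.0 * float(np.log(np.diag(L)).sum())
            Sinv = sla.cho_solve((L, True), np.eye(k))
            d = pat.xbar - mu[idx]
            W = pat.S + np.outer(d, d)
            ll += -0.5 * pat.n * (k * _LOG2PI + logdet + float((Sinv * W).sum()))
            if want_grad:
                G[np.ix_(idx, idx)] += 0.5 * pat.n * (Sinv @ W @ Sinv - Sinv)
                gmu[idx] += pat.n * (Sinv @ d)
        ll -= penalty
        if not want_grad:
            return ll, None

        Bo = B[:p, :]
        Co = C[:p, :]
        GBo = G @ Bo  # (p, n)
        GCo = G @ Co  # (p, n)
        gB = gmu @ Bo  # (n,)
        grad = np.zeros(self.k)
        a_p, a_r, a_c = self._a
        if a_p.size:
            contrib = 2.0 * np.einsum(
                "pm,pm->m", Bo[:, a_r], GCo[:, a_c]
            ) + gB[a_r] * mu_full[a_c]
            np.add.at(grad, a_p, contrib)
        sd_p, sd_r = self._sd
        if sd_p.size:
            np.add.at(
                grad, sd_p, np.einsum("pm,pm->m", Bo[:, sd_r], GBo[:, sd_r])
            )
        so_p, so_r, so_c = self._so
        if so_p.size:
            np.add.at(
                grad, so_p,
                2.0 * np.einsum("pm,pm->m", Bo[:, so_r], GBo[:, so_c]),
            )
        m_p, m_r = self._m
        if m_p.size:
            np.add.at(grad, m_p, gB[m_r])
        return ll, grad

    def hessian(
        self,
        theta: np.ndarray,
        patterns,
        rel_step: float = 1e-5,
        scheme: str = "central",
    ):
        """Numerical Hessian of -loglik from the analytic gradient.

        "central" differences for standard errors; "forward" halves the
        cost for the optimizer's interior Newton steps.
        """
        k = self.k
        H = np.zeros((k, k))
        if scheme == "forward":
            _, g0 = self.loglik_grad(theta, patterns)
            step = 10.0 * rel_step
            for i in range(k):
                h = step * max(1.0, abs(theta[i]))
                tp = theta.copy()
                tp[i] += h
                _, gp = self.loglik_grad(tp, patterns)
                H[:, i] = -(gp - g0) / h
        else:
            for i in range(k):
                h = rel_step * max(1.0, abs(theta[i]))
                tp = theta.copy()
                tp[i] += h
                tm = theta.copy()
                tm[i] -= h
                _, gp = self.loglik_grad(tp, patterns)
                _, gm = self.loglik_grad(tm, patterns)
                H[:, i] = -(gp - gm) / (2.0 * h)
        return 0.5 * (H + H.T)


# ----------------------------------------------------------------------
# public moment/objective functions
# ----------------------------------------------------------------------
def implied_moments(model: PathModel, estimates: Mapping[str, float]):
    """Model-implied (covariance, mean) over the observed variables."""
    cm = CompiledModel(model)
    Sigma, mu, *_ = cm.moments(cm.theta_from(estimates))
    return Sigma, mu


def fiml_loglik(
    model: PathModel,
    estimates: Mapping[str, float],
    data,
    violations: list | None = None,
) -> float:
    """FIML log-likelihood of the data under the given estimates.

    Rows with no observed value among the model variables are excluded.
    Non-positive-definite implied pattern covariances yield a penalized
    value; messages are appended to ``violations`` when provided.
    """
    table = as_table(data).retained(model.observed_names)
    X = table.matrix(model.observed_names)
    cm = CompiledModel(model)
    ll, _ = cm.loglik_grad(
        cm.theta_from(estimates), _make_patterns(X), want_grad=False,
        violations=violations,
    )
    return ll


# ----------------------------------------------------------------------
# starting values
# ----------------------------------------------------------------------
def start_values(model: PathModel, table: LongitudinalTable) -> np.ndarray:
    """Deterministic moment-based starting values for every free label."""
    cm = CompiledModel(model)
    cols = {v: i for i, v in enumerate(model.observed_names)}
    X = table.matrix(model.observed_names)

    def col(v):
        return X[:, cols[v]]

    def smean(v):
        m = np.nanmean(col(v))
        return 0.0 if np.isnan(m) else float(m)

    def svar(v):
        s = np.nanvar(col(v))
        return 1.0 if not np.isfinite(s) or s <= 0 else float(s)

    def scov(v, w):
        a, b = col(v), col(w)
        m = ~(np.isnan(a) | np.isnan(b))
        if m.sum() < 3:
            return 0.0
        c = float(np.cov(a[m], b[m], bias=True)[0, 1])
        return c if np.isfinite(c) else 0.0

    theta = np.zeros(cm.k)
    for a, lab in enumerate(cm.param_names):
        hint = model.start_hints.get(lab)
        if hint is None:
            mat, i, j = cm.cells[a][0]
            theta[a] = 1.0 if (mat == "S" and i == j) else 0.0
            continue
        kind = hint[0]
        if kind == "value":
            theta[a] = hint[1]
        elif kind == "mean":
            theta[a] = smean(hint[1])
        elif kind == "var":
            theta[a] = hint[2] * svar(hint[1])
        elif kind == "cov":
            theta[a] = svar(hint[1]) if hint[1] == hint[2] else scov(hint[1], hint[2])
        elif kind == "covfrac":
            theta[a] = hint[3] * math.sqrt(svar(hint[1]) * svar(hint[2]))
        elif kind == "mean_diff":
            theta[a] = smean(hint[1]) - smean(hint[2])
        elif kind == "ols_slope":
            names, times = hint[1], np.asarray(hint[2], dtype=float)
            means = np.array([smean(v) for v in names])
            t_c = times - times.mean()
            denom = float(t_c @ t_c)
            theta[a] = float(t_c @ means / denom) if denom > 0 else 0.0
        else:  # pragma: no cover - builder/estimator contract
            raise ValueError(f"unknown start hint {hint!r}")
    return theta


# ----------------------------------------------------------------------
# fit result
# ----------------------------------------------------------------------
@dataclass
class FitResult:
    """Outcome of one maximum-likelihood model fit."""

    model: PathModel | None
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    log_likelihood: float
    n_used: int
    df: int
    converged: bool
    heywood_flags: list[str] = field(default_factory=list)
    n_params: int = 0
    data: LongitudinalTable | None = field(default=None, repr=False)
    hessian: np.ndarray | None = field(default=None, repr=False)
    mu: np.ndarray | None = field(default=None, repr=False)
    sigma: np.ndarray | None = field(default=None, repr=False)
    messages: list[str] = field(default_factory=list)

    def p_values(self) -> dict[str, float]:
        """Two-sided Wald p-values (estimate / SE against normal)."""
        out = {}
        for lab, est in self.estimates.items():
            se = self.standard_errors.get(lab)
            if se and se > 0:
                out[lab] = 2.0 * float(stats.norm.sf(abs(est / se)))
            else:
                out[lab] = float("nan")
        return out

    def parameter_table(self) -> pd.DataFrame:
        pv = self.p_values()
        return pd.DataFrame(
            {
                "estimate": pd.Series(self.estimates),
                "se": pd.Series(self.standard_errors),
                "p": pd.Series(pv),
            }
        )


# ----------------------------------------------------------------------
# model fitting
# ----------------------------------------------------------------------
def fit(
    model: PathModel,
    data,
    *,
    compute_se: bool = True,
    heywood_fix: bool = False,
    max_iter: int = 2000,
    start: Mapping[str, float] | None = None,
) -> FitResult:
    """Fit a path model to a longitudinal table by FIML.

    Optimization is L-BFGS-B with analytic gradients from deterministic
    moment-based starting values.  When ``heywood_fix`` is set, negative
    variance estimates are fixed to zero and the model refit (once);
    otherwise they are only flagged.
    """
    free_count, _, df = model.count_df()
    if df < 0:
        raise ValueError(f"model not identified: df = {df} < 0")
    table = as_table(data).retained(model.observed_names)
    X = table.matrix(model.observed_names)
    patterns = _make_patterns(X)
    cm = CompiledModel(model)
    theta0 = (
        cm.theta_from(start) if start is not None else start_values(model, table)
    )

    def objective(t):
        ll, g = cm.loglik_grad(t, patterns)
        return -ll, -g

    # stage 1: quasi-Newton warm start
    res = optimize.minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": min(600, max_iter), "maxfun": 20 * max_iter,
                 "ftol": 1e-11, "gtol": 1e-6, "maxcor": 30},
    )
    # stage 2: Newton polish with ridge-regularized numerical Hessian
    theta, ll, converged, note = _newton_polish(cm, res.x, patterns, objective)
    messages: list[str] = [] if converged else [f"optimizer: {note}"]

    heywood = _negative_variances(cm, theta)
    if heywood and heywood_fix:
        fixed = model
        for lab in heywood:
            fixed = fixed.fix(lab, 0.0)
        sub = fit(
            fixed,
            table,
            compute_se=compute_se,
            heywood_fix=False,
            max_iter=max_iter,
            start={
                lab: v
                for lab, v in cm.estimates(theta).items()
                if lab not in heywood
            },
        )
        sub.heywood_flags = heywood
        sub.messages.insert(
            0, f"negative variances fixed to zero and refit: {heywood}"
        )
        return sub
    if heywood:
        warnings.warn(
            f"negative variance estimates (Heywood case): {heywood}",
            stacklevel=2,
        )

    ses: dict[str, float] = {}
    H = None
    if compute_se and converged and cm.k > 0:
        H = cm.hessian(theta, patterns)
        try:
            cov = np.linalg.inv(H)
            diag = np.diag(cov)
            if np.all(np.isfinite(diag)):
                ses = {
                    lab: (math.sqrt(v) if v > 0 else float("nan"))
                    for lab, v in zip(cm.param_names, diag)
                }
            else:
                messages.append("information matrix produced non-finite SEs")
        except np.linalg.LinAlgError:
            messages.append("information matrix singular; no standard errors")

    Sigma, mu, *_ = cm.moments(theta)
    return FitResult(
        model=model,
        estimates=cm.estimates(theta),
        standard_errors=ses,
        log_likelihood=ll,
        n_used=table.n_rows,
        df=df,
        converged=converged,
        heywood_flags=heywood,
        n_params=free_count,
        data=table,
        hessian=H,
        mu=mu,
        sigma=Sigma,
        messages=messages,
    )


def _newton_polish(
    cm: CompiledModel,
    x: np.ndarray,
    patterns,
    objective,
    grad_tol: float = 1e-5,
    max_steps: int = 50,
):
    """Newton iterations from a warm start until the gradient max-norm
    falls below ``grad_tol``; the Hessian is ridge-regularized when not
    positive definite."""
    note = ""
    H = None
    stale = 99
    alpha = 1.0
    for _ in range(max_steps):
        f, g = objective(x)
        if np.abs(g).max() < grad_tol:
            return x, -f, True, note
        # refresh the (forward-difference) Hessian only when the previous
        # step struggled or the factorization has gone stale
        if H is None or stale >= 2 or alpha < 1.0:
            H = cm.hessian(x, patterns, scheme="forward")
            stale = 0
        else:
            stale += 1
        w_min = float(np.linalg.eigvalsh(H).min())
        ridge = (abs(w_min) + 1e-8) if w_min < 1e-10 else 0.0
        try:
            step = np.linalg.solve(H + ridge * np.eye(cm.k), -g)
        except np.linalg.LinAlgError:
            note = "singular Hessian during polish"
            return x, -f, False, note
        alpha = 1.0
        for _ in range(40):
            f2, _ = objective(x + alpha * step)
            if f2 < f:
                break
            alpha *= 0.5
        else:
            note = "no descent direction found"
            return x, -f, np.abs(g).max() < 1e-3, note
        x = x + alpha * step
    f, g = objective(x)
    note = f"gradient max-norm {np.abs(g).max():.3g} after polish"
    return x, -f, bool(np.abs(g).max() < 1e-3), note


def _negative_variances(cm: CompiledModel, theta: np.ndarray) -> list[str]:
    """Labels placed (only) on S-diagonal cells with negative estimates."""
    out = []
    for lab, t, cells in zip(cm.param_names, theta, cm.cells):
        if t < 0 and all(m == "S" and i == j for m, i, j in cells):
            out.append(lab)
    return out


# ----------------------------------------------------------------------
# saturated and null models
# ----------------------------------------------------------------------
def saturated_and_null_fits(data, variables: Sequence[str]):
    """ML fits of the saturated and independence models under FIML.

    The saturated model (free means, full covariance) is fit by EM over
    missingness patterns; the independence (null) model — free means and
    variances, zero covariances — factorizes per variable and is solved
    in closed form.
    """
    variables = list(variables)
    p = len(variables)
    if p < 2:
        raise ValueError("need at least two variables")
    table = as_table(data).retained(variables)
    X = table.matrix(variables)
    n = X.shape[0]
    patterns = _make_patterns(X)

    mu, Sigma, ll_sat, em_converged = _saturated_em(X, patterns)
    sat = FitResult(
        model=None,
        estimates={},
        standard_errors={},
        log_likelihood=ll_sat,
        n_used=n,
        df=0,
        converged=em_converged,
        n_params=p + p * (p + 1) // 2,
        mu=mu,
        sigma=Sigma,
    )

    ll_null = 0.0
    mu0 = np.zeros(p)
    var0 = np.zeros(p)
    for j in range(p):
        x = X[:, j]
        x = x[~np.isnan(x)]
        nv = x.size
        m = float(x.mean())
        v = float(x.var())  # ML (biased)
        v = max(v, 1e-12)
        mu0[j] = m
        var0[j] = v
        ll_null += -0.5 * nv * (_LOG2PI + math.log(v) + 1.0)
    null = FitResult(
        model=None,
        estimates={},
        standard_errors={},
        log_likelihood=ll_null,
        n_used=n,
        df=p * (p - 1) // 2,
        converged=True,
        n_params=2 * p,
        mu=mu0,
        sigma=np.diag(var0),
    )
    return sat, null


def _saturated_em(X, patterns, tol: float = 1e-9, max_iter: int = 10000):
    n, p = X.shape
    complete = all(pat.idx.size == p for pat in patterns)
    mu = np.nanmean(X, axis=0)
    if complete:
        dev = X - mu
        Sigma = dev.T @ dev / n
        ll = _mvn_ll(mu, Sigma, patterns)
        return mu, Sigma, ll, True
    Sigma = np.diag(np.maximum(np.nanvar(X, axis=0), 1e-6))
    ll_old = -np.inf
    for _ in range(max_iter):
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        for pat in patterns:
            o = pat.idx
            m = np.setdiff1d(np.arange(p), o, assume_unique=True)
            n_p = pat.n
            t1_o = n_p * pat.xbar
            t2_oo = n_p * (pat.S + np.outer(pat.xbar, pat.xbar))
            T1[o] += t1_o
            T2[np.ix_(o, o)] += t2_oo
            if m.size:
                Soo = Sigma[np.ix_(o, o)]
                Smo = Sigma[np.ix_(m, o)]
                Coef = Smo @ np.linalg.inv(Soo)
                a = mu[m] - Coef @ mu[o]
                Cv = Sigma[np.ix_(m, m)] - Coef @ Smo.T
                sum_xm = n_p * a + Coef @ t1_o
                cross = t2_oo @ Coef.T + np.outer(t1_o, a)  # sum x_o E[x_m]'
                mm = (
                    n_p * np.outer(a, a)
                    + np.outer(a, Coef @ t1_o)
                    + np.outer(Coef @ t1_o, a)
                    + Coef @ t2_oo @ Coef.T
                    + n_p * Cv
                )
                T1[m] += sum_xm
                T2[np.ix_(o, m)] += cross
                T2[np.ix_(m, o)] += cross.T
                T2[np.ix_(m, m)] += mm
        mu = T1 / n
        Sigma = T2 / n - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        ll = _mvn_ll(mu, Sigma, patterns)
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            return mu, Sigma, ll, True
        ll_old = ll
    return mu, Sigma, ll, False


def _mvn_ll(mu, Sigma, patterns) -> float:
    ll = 0.0
    for pat in patterns:
        o = pat.idx
        So = Sigma[np.ix_(o, o)]
        L = np.linalg.cholesky(So)
        logdet = 2.0 * float(np.log(np.diag(L)).sum())
        Sinv = sla.cho_solve((L, True), np.eye(o.size))
        d = pat.xbar - mu[o]
        W = pat.S + np.outer(d, d)
        ll += -0.5 * pat.n * (o.size * _LOG2PI + logdet + float((Sinv * W).sum()))
    return ll


# ----------------------------------------------------------------------
# modification indices
# ----------------------------------------------------------------------
def modification_indices(
    fit_result: FitResult,
    candidates: Sequence[Cell] | None = None,
) -> pd.DataFrame:
    """One-df score statistics for freeing fixed/constrained cells.

    For each candidate cell the model is extended by one free parameter
    at the cell's current value and the efficient score statistic
    ``g' I^{-1} g`` is computed at the restricted solution; it
    approximates the chi-square improvement from freeing that cell.
    Cells whose bordered information matrix is singular are skipped with
    a note.
    """
    if fit_result.model is None or fit_result.data is None:
        raise ValueError("modification indices need a converged model fit")
    if not fit_result.converged:
        raise ValueError("modification indices require a converged fit")
    model = fit_result.model
    cm = CompiledModel(model)
    table = fit_result.data
    X = table.matrix(model.observed_names)
    patterns = _make_patterns(X)
    theta = cm.theta_from(fit_result.estimates)
    H = fit_result.hessian
    if H is None:
        H = cm.hessian(theta, patterns)

    if candidates is None:
        candidates = _default_mi_candidates(model)

    rows = []
    names = model.variable_names
    for cell in candidates:
        mat, i, j = cell
        target = (
            f"{mat}[{names[i]},{names[j]}]" if mat != "M" else f"mean[{names[i]}]"
        )
        mi, epc, note = _score_statistic(model, cm, theta, H, patterns, cell)
        rows.append(
            {
                "matrix": mat,
                "row": names[i],
                "col": names[j],
                "target": target,
                "mi": mi,
                "epc": epc,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def _default_mi_candidates(model: PathModel) -> list[Cell]:
    """Intercept cells of observed variables held fixed or equality-shared."""
    cmap = model.constraint_map()
    multi = {lab for lab, cells in cmap.items() if len(cells) > 1}
    out = []
    for i in range(model.n_observed):
        e = model.M[i]
        if isinstance(e, str):
            if e in multi:
                out.append(("M", i, i))
        else:
            out.append(("M", i, i))
    return out


def _score_statistic(model, cm, theta, H, patterns, cell):
    entry = model.get(cell)
    if isinstance(entry, str):
        if len(model.constraint_map()[entry]) < 2:
            return float("nan"), float("nan"), "cell already free"
        value = float(theta[cm.param_names.index(entry)])
    else:
        value = float(entry)
    ext = model.free_cell(cell, "__cand__")
    cm2 = CompiledModel(ext)
    est = dict(zip(cm.param_names, theta))
    est["__cand__"] = value
    theta2 = cm2.theta_from(est)
    # arrange: base labels in base order, candidate last
    order = [cm2.param_names.index(lab) for lab in cm.param_names] + [
        cm2.param_names.index("__cand__")
    ]
    _, g2 = cm2.loglik_grad(theta2, patterns)
    g = g2[order]
    # bordered Hessian: new column via finite difference along the candidate
    c_idx = cm2.param_names.index("__cand__")
    h = 1e-5 * max(1.0, abs(value))
    tp = theta2.copy()
    tp[c_idx] += h
    tm = theta2.copy()
    tm[c_idx] -= h
    _, gp = cm2.loglik_grad(tp, patterns)
    _, gm = cm2.loglik_grad(tm, patterns)
    hcol = -(gp - gm)[order] / (2.0 * h)
    k = cm.k
    H2 = np.zeros((k + 1, k + 1))
    H2[:k, :k] = H
    H2[:, k] = hcol
    H2[k, :] = hcol
    try:
        delta = np.linalg.solve(H2, g)
    except np.linalg.LinAlgError:
        return float("nan"), float("nan"), "singular information"
    mi = float(g @ delta)
    if not np.isfinite(mi) or mi < 0:
        return float("nan"), float("nan"), "singular information"
    return mi, float(delta[-1]), ""
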