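"""Bernoulli-logit mixed models for crossed patient/rater designs.

The model for one outcome column is

    y_j | u ~ Bernoulli(logit^-1(eta_j)),
    eta_j = beta0 + beta_method * 1[instrument_j = 3DCAM]
            + b_{patient(j)} + c_{rater(j)} + d_{patient(j), instrument(j)},

with independent normal random effects b ~ N(0, s2_patient),
c ~ N(0, s2_rater), d ~ N(0, s2_interaction).  Estimation maximizes an
approximate marginal likelihood:

* adaptive Gauss-Hermite quadrature (tensor-product, centered and scaled at
  each patient's conditional mode) when only patient-level random effects
  are present, so the marginal likelihood factors over patients;
* a Laplace approximation when crossed rater effects make the integral
  non-factorable.

Variance components are optimized on the log-SD scale with a floor at
sigma = 1e-6; fits that hit the floor are reported with the component set
to 0 and a boundary flag.  Empirical-Bayes random-effect predictions are
posterior modes (the Laplace/AGQ centering locations).

:func:`marginal_loglik_bruteforce` is a deliberately expensive dense-grid
integrator over the random effects, kept independent of the quadrature code
paths so it can serve as a testing oracle on tiny fixtures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, sparse
from scipy.integrate import simpson
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .errors import (
    ConvergenceError,
    IntegrationDimensionError,
    SeparationError,
)
from .records import INSTRUMENTS

PATIENT = "patient_intercept"
RATER = "rater_intercept"
PATIENT_METHOD = "patient_by_method"
RANDOM_TERMS = (PATIENT, RATER, PATIENT_METHOD)

_SIGMA_FLOOR = 1e-6
#: an estimated SD below this is indistinguishable from zero on the logit
#: scale; such components are reported as 0 with a boundary flag
_BOUNDARY_SIGMA = 1e-2


@dataclass(frozen=True)
class GlmmSpec:
    """Which response to model and which effects to include."""

    response: str = "delirium"
    include_method: bool = True
    random_terms: tuple = (PATIENT, RATER, PATIENT_METHOD)

    def __post_init__(self):
        unknown = set(self.random_terms) - set(RANDOM_TERMS)
        if unknown:
            raise ValueError(f"unknown random term(s): {sorted(unknown)}")
        if PATIENT_METHOD in self.random_terms and PATIENT not in self.random_terms:
            raise ValueError(f"{PATIENT_METHOD} requires {PATIENT}")


@dataclass
class GlmmOptions:
    max_iter: int = 500
    loglik_rtol: float = 1e-8
    #: a fit is declared converged when the (projected) numeric gradient
    #: norm of the approximate marginal log-likelihood is below this.
    gradient_tol: float = 1e-3
    quadrature_order: int = 15
    #: per-dimension order for tensor AGQ when the patient block is
    #: multi-dimensional (patient intercept + patient-by-method).
    interaction_order: int = 5
    inner_tol: float = 1e-9
    approximation: str = "auto"  # auto | laplace | agq
    hessian_step: float = 5e-3
    sigma_init: float = 1.0


@dataclass
class FixedEffectTest:
    estimate: float
    std_error: float
    ci_low: float
    ci_high: float
    p_value: float
    level: float = 0.95


@dataclass
class GlmmFit:
    spec: GlmmSpec
    beta: dict                 # name -> estimate ("intercept", "method")
    beta_cov: np.ndarray
    variance_components: dict  # term -> sigma^2 (0.0 at the boundary)
    boundary: dict             # term -> bool
    eb_modes: dict             # term -> {level: mode}
    loglik: float
    converged: bool
    n_iter: int
    gradient_norm: float
    gradient_tol: float
    approximation: str
    n_obs: int
    n_dropped: int
    patients: tuple
    raters: tuple
    instruments: tuple
    log_sigma: dict = field(default_factory=dict)  # internal, pre-flooring


# ---------------------------------------------------------------------------
# design construction


class _Design:
    def __init__(self, table: pd.DataFrame, spec: GlmmSpec):
        sub = table.loc[table[spec.response].notna()].reset_index(drop=True)
        self.n_dropped = len(table) - len(sub)
        self.y = sub[spec.response].to_numpy(dtype=float)
        self.is3d = (sub["instrument"] == "3DCAM").to_numpy()
        self.instruments = tuple(sorted(sub["instrument"].unique()))
        self.beta_names = ["intercept"] + (
            ["method"] if spec.include_method else [])
        cols = [np.ones(len(sub))]
        if spec.include_method:
            cols.append(self.is3d.astype(float))
        self.X = np.column_stack(cols)
        self.p = self.X.shape[1]

        pat = pd.Categorical(sub["patient_id"])
        self.patients = tuple(pat.categories)
        self.patient_idx = np.asarray(pat.codes, dtype=int)
        rat = pd.Categorical(sub["rater_id"])
        self.raters = tuple(rat.categories)
        self.rater_idx = np.asarray(rat.codes, dtype=int)
        self.n_patients = len(self.patients)
        self.spec = spec

        # variance-parameter blocks in spec order
        self.terms = tuple(t for t in RANDOM_TERMS if t in spec.random_terms)

        # Laplace layout: one coefficient column per random-effect level
        offset = 0
        rows_all, cols_all = [], []
        var_group = []
        self.level_labels = {}
        for k, term in enumerate(self.terms):
            if term == PATIENT:
                idx, labels = self.patient_idx, list(self.patients)
            elif term == RATER:
                idx, labels = self.rater_idx, list(self.raters)
            else:  # PATIENT_METHOD: level = patient x instrument
                idx = self.patient_idx * 2 + self.is3d.astype(int)
                labels = [(p, inst) for p in self.patients
                          for inst in INSTRUMENTS]
            nlev = len(labels)
            rows_all.append(np.arange(len(sub)))
            cols_all.append(idx + offset)
            var_group.extend([k] * nlev)
            self.level_labels[term] = (offset, labels)
            offset += nlev
        self.q = offset
        self.var_group = np.asarray(var_group, dtype=int)
        if self.q:
            self.Z = sparse.csr_matrix(
                (np.ones(len(sub) * len(self.terms)),
                 (np.concatenate(rows_all), np.concatenate(cols_all))),
                shape=(len(sub), self.q))
        else:
            self.Z = None

        # patient-factored (AGQ) layout: per-patient random design T
        if RATER not in self.terms:
            tcols = []
            self.dim_group = []  # maps AGQ dim -> variance-parameter index
            for k, term in enumerate(self.terms):
                if term == PATIENT:
                    tcols.append(np.ones(len(sub)))
                    self.dim_group.append(k)
                elif term == PATIENT_METHOD:
                    tcols.append((~self.is3d).astype(float))
                    tcols.append(self.is3d.astype(float))
                    self.dim_group += [k, k]
            self.T = np.column_stack(tcols) if tcols else np.zeros((len(sub), 0))
            self.d = self.T.shape[1]
        else:
            self.T, self.d, self.dim_group = None, None, None


def _loglik_bernoulli(y, eta):
    # y*eta - log(1 + exp(eta)), stable for large |eta|
    return y * eta - np.logaddexp(0.0, eta)


# ---------------------------------------------------------------------------
# Laplace approximation


def _chol_spd(H):
    """Cholesky with escalating jitter; H is SPD up to roundoff."""
    jitter = 0.0
    for _ in range(8):
        try:
            return cho_factor(H + jitter * np.eye(len(H)), lower=True)
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10)
    raise np.linalg.LinAlgError("random-effect Hessian is not positive "
                                "definite")


def _laplace(design: _Design, beta, sig, u0, tol):
    """Approximate marginal loglik; returns (loglik, u_hat)."""
    dinv = 1.0 / np.maximum(sig[design.var_group], _SIGMA_FLOOR) ** 2
    eta0 = design.X @ beta
    Z, y = design.Z, design.y
    u = u0.copy()

    def pen_obj(uv, eta):
        return float(np.sum(_loglik_bernoulli(y, eta))
                     - 0.5 * np.sum(dinv * uv * uv))

    eta = eta0 + Z @ u
    f = pen_obj(u, eta)
    chol = None
    for _ in range(100):
        mu = expit(eta)
        g = Z.T @ (y - mu) - dinv * u
        if np.max(np.abs(g)) < tol:
            break
        W = mu * (1.0 - mu) + 1e-12
        H = (Z.T @ sparse.diags(W) @ Z).toarray()
        H[np.diag_indices_from(H)] += dinv
        chol = _chol_spd(H)
        step = cho_solve(chol, g)
        t = 1.0
        for _ in range(40):
            u_new = u + t * step
            eta_new = eta0 + Z @ u_new
            f_new = pen_obj(u_new, eta_new)
            if f_new >= f - 1e-13:
                break
            t *= 0.5
        if f_new < f - 1e-13:  # no ascent possible
            break
        u, eta, f = u_new, eta_new, f_new
    mu = expit(eta)
    W = mu * (1.0 - mu) + 1e-12
    H = (Z.T @ sparse.diags(W) @ Z).toarray()
    H[np.diag_indices_from(H)] += dinv
    chol = _chol_spd(H)
    logdet_H = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
    logdet_D = float(np.sum(np.log(
        np.maximum(sig[design.var_group], _SIGMA_FLOOR) ** 2)))
    ll = pen_obj(u, eta) - 0.5 * (logdet_D + logdet_H)
    return ll, u


# ---------------------------------------------------------------------------
# adaptive Gauss-Hermite (patient-factored structures)


def _agq_modes(design: _Design, beta, dvar, tol):
    """Batched per-patient posterior modes and Hessians."""
    y, T, pat = design.y, design.T, design.patient_idx
    P, d = design.n_patients, design.d
    eta0 = design.X @ beta
    u = np.zeros((P, d))
    dinv = 1.0 / dvar

    def per_patient_f(uv):
        eta = eta0 + np.einsum("nd,nd->n", T, uv[pat])
        ll = _loglik_bernoulli(y, eta)
        out = np.zeros(P)
        np.add.at(out, pat, ll)
        return out - 0.5 * np.sum(uv * uv * dinv, axis=1), eta

    f, eta = per_patient_f(u)
    for _ in range(100):
        mu = expit(eta)
        g = np.zeros((P, d))
        np.add.at(g, pat, T * (y - mu)[:, None])
        g -= u * dinv
        if np.max(np.abs(g)) < tol:
            break
        W = (mu * (1.0 - mu) + 1e-12)
        Hrec = W[:, None, None] * (T[:, :, None] * T[:, None, :])
        H = np.zeros((P, d, d))
        np.add.at(H, pat, Hrec)
        H += np.diag(dinv)[None, :, :]
        step = np.linalg.solve(H, g[:, :, None])[:, :, 0]
        t = np.ones(P)
        for _ in range(40):
            f_new, eta_new = per_patient_f(u + t[:, None] * step)
            bad = f_new < f - 1e-13
            if not bad.any():
                break
            t[bad] *= 0.5
        ok = f_new >= f - 1e-13
        u = u + np.where(ok, t, 0.0)[:, None] * step
        f, eta = per_patient_f(u)
    mu = expit(eta)
    W = (mu * (1.0 - mu) + 1e-12)
    Hrec = W[:, None, None] * (T[:, :, None] * T[:, None, :])
    H = np.zeros((P, d, d))
    np.add.at(H, pat, Hrec)
    H += np.diag(dinv)[None, :, :]
    return u, H


def _agq_loglik(design: _Design, beta, sig, order, inter_order, tol):
    """Adaptive tensor-product Gauss-Hermite marginal log-likelihood."""
    y, T, pat = design.y, design.T, design.patient_idx
    P, d = design.n_patients, design.d
    dvar = np.maximum(sig[design.dim_group], _SIGMA_FLOOR) ** 2
    eta0 = design.X @ beta
    u_hat, H = _agq_modes(design, beta, dvar, tol)

    K = order if d == 1 else inter_order
    z1, w1 = hermgauss(K)

    if d == 1:
        sd = 1.0 / np.sqrt(H[:, 0, 0])
        nodes = u_hat[:, 0:1] + np.sqrt(2.0) * sd[:, None] * z1[None, :]
        eta = eta0[:, None] + T[:, 0:1] * nodes[pat]
        ll_rec = _loglik_bernoulli(y[:, None], eta)
        Lpk = np.zeros((P, K))
        np.add.at(Lpk, pat, ll_rec)
        Lpk += norm.logpdf(nodes, scale=np.sqrt(dvar[0]))
        Lpk += np.log(w1)[None, :] + z1[None, :] ** 2
        ll_i = logsumexp(Lpk, axis=1) + 0.5 * np.log(2.0) + np.log(sd)
        return float(ll_i.sum()), u_hat

    L = np.linalg.cholesky(H)                      # (P, d, d)
    logdet_A = -np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
    Linv = np.linalg.inv(L)
    A = np.transpose(Linv, (0, 2, 1))              # A A^T = H^{-1}
    combos = np.array(list(itertools.product(range(K), repeat=d)))
    M = len(combos)
    logint = np.empty((P, M))
    logprior_const = -0.5 * np.sum(np.log(2 * np.pi * dvar))
    for m, combo in enumerate(combos):
        z = z1[combo]
        u = u_hat + np.sqrt(2.0) * np.einsum("pij,j->pi", A, z)
        eta = eta0 + np.einsum("nd,nd->n", T, u[pat])
        col = np.zeros(P)
        np.add.at(col, pat, _loglik_bernoulli(y, eta))
        col += logprior_const - 0.5 * np.sum(u * u / dvar, axis=1)
        col += np.sum(np.log(w1[combo])) + float(z @ z)
        logint[:, m] = col
    ll_i = logsumexp(logint, axis=1) + 0.5 * d * np.log(2.0) + logdet_A
    return float(ll_i.sum()), u_hat


# ---------------------------------------------------------------------------
# plain logistic (degenerate reduction, also used for starting values)


def _logistic_irls(X, y, max_iter=100, tol=1e-12, ridge=0.0):
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        g = X.T @ (y - mu) - ridge * beta
        W = mu * (1 - mu) + 1e-12
        H = X.T @ (X * W[:, None]) + ridge * np.eye(X.shape[1])
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


# ---------------------------------------------------------------------------
# fitting


def _check_preconditions(table, spec: GlmmSpec):
    y = table[spec.response].dropna()
    if y.nunique() < 2:
        raise SeparationError(
            f"response {spec.response!r} is constant; no information "
            "about the model parameters")
    if spec.include_method:
        insts = set(table["instrument"].unique())
        if insts != set(INSTRUMENTS):
            raise ValueError("method fixed effect requested but only "
                             f"instrument(s) {sorted(insts)} present")
        for inst in INSTRUMENTS:
            sub = table.loc[table["instrument"] == inst, spec.response].dropna()
            if sub.nunique() < 2:
                raise SeparationError(
                    f"response {spec.response!r} is constant within "
                    f"instrument {inst} (complete separation of the method "
                    "effect); the marginal likelihood has no interior "
                    "maximum")
    if table["patient_id"].nunique() < 2 and spec.random_terms:
        raise ValueError("need at least 2 patients")


def _numeric_gradient(fun, x, h=1e-4):
    g = np.zeros_like(x)
    for i in range(len(x)):
        hi = h * (1.0 + abs(x[i]))
        e = np.zeros_like(x)
        e[i] = hi
        g[i] = (fun(x + e) - fun(x - e)) / (2 * hi)
    return g


def _numeric_hessian(fun, x, h=5e-3):
    k = len(x)
    H = np.zeros((k, k))
    hs = h * (1.0 + np.abs(x))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = hs[i]
            ej = np.zeros(k); ej[j] = hs[j]
            if i == j:
                H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / hs[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    fun(x + ei + ej) - fun(x + ei - ej)
                    - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * hs[i] * hs[j])
    return H


def fit_glmm(table: pd.DataFrame, spec: GlmmSpec | None = None,
             options: GlmmOptions | None = None) -> GlmmFit:
    """Fit the mixed model by approximate marginal maximum likelihood.

    Chooses adaptive Gauss-Hermite quadrature when the random structure is
    patient-factored (no rater term), otherwise the Laplace approximation;
    ``options.approximation`` can force either.
    """
    spec = spec or GlmmSpec()
    options = options or GlmmOptions()
    _check_preconditions(table, spec)
    design = _Design(table, spec)
    nterms = len(design.terms)

    if nterms == 0:
        beta = _logistic_irls(design.X, design.y)
        eta = design.X @ beta
        mu = expit(eta)
        ll = float(np.sum(_loglik_bernoulli(design.y, eta)))
        W = mu * (1 - mu)
        cov = np.linalg.inv(design.X.T @ (design.X * W[:, None]))
        return GlmmFit(
            spec=spec, beta=dict(zip(design.beta_names, beta)),
            beta_cov=cov, variance_components={}, boundary={}, eb_modes={},
            loglik=ll, converged=True, n_iter=0, gradient_norm=0.0,
            gradient_tol=options.gradient_tol, approximation="none",
            n_obs=len(design.y), n_dropped=design.n_dropped,
            patients=design.patients, raters=design.raters,
            instruments=design.instruments)

    use_agq = (RATER not in design.terms) if options.approximation == "auto" \
        else (options.approximation == "agq")
    if use_agq and design.T is None:
        raise ValueError("AGQ requires a patient-factored random structure "
                         "(no rater term)")

    state = {"u": np.zeros(design.q) if design.Z is not None else None}

    def nll(params):
        beta = params[:design.p]
        sig = np.exp(params[design.p:])
        if use_agq:
            ll, _ = _agq_loglik(design, beta, sig, options.quadrature_order,
                                options.interaction_order, options.inner_tol)
        else:
            ll, u = _laplace(design, beta, sig, state["u"],
                             options.inner_tol)
            state["u"] = u
        return -ll

    beta0 = _logistic_irls(design.X, design.y, ridge=1e-8)
    bounds = [(None, None)] * design.p + \
        [(np.log(_SIGMA_FLOOR), np.log(50.0))] * nterms
    lb = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])
    ub = np.array([b[1] if b[1] is not None else np.inf for b in bounds])

    def optimize_from(sigma_init):
        x0 = np.concatenate([beta0, np.full(nterms, np.log(sigma_init))])
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": options.max_iter,
                     "ftol": options.loglik_rtol,
                     "gtol": 1e-7, "maxfun": 20 * options.max_iter})
        x, fbest, n_iter = res.x, res.fun, res.nit

        # damped Newton polish with numeric derivatives to tighten the
        # gradient norm beyond what L-BFGS-B's stopping rule guarantees
        for _ in range(10):
            g = _numeric_gradient(nll, x)
            free = ~((x <= lb + 1e-9) & (g > 0))
            if np.linalg.norm(g[free]) < options.gradient_tol / 10:
                break
            H = _numeric_hessian(nll, x, h=options.hessian_step)
            Hf = H[np.ix_(free, free)]
            try:
                w = np.linalg.eigvalsh(Hf)
                if w.min() <= 0:  # indefinite numeric Hessian: regularize
                    Hf = Hf + (abs(w.min()) + 1e-6) * np.eye(len(Hf))
                step = np.linalg.solve(Hf, g[free])
            except np.linalg.LinAlgError:
                break
            improved = False
            for t in (1.0, 0.5, 0.25, 0.1, 0.02):
                x_new = x.copy()
                x_new[free] -= t * step
                x_new = np.clip(x_new, lb, ub)
                f_new = nll(x_new)
                if f_new < fbest - 1e-12:
                    x, fbest = x_new, f_new
                    n_iter += 1
                    improved = True
                    break
            if not improved:
                break

        g = _numeric_gradient(nll, x)
        at_bound = (x <= lb + 1e-9) & (g > 0)  # pinned at the sigma floor
        grad_norm = float(np.linalg.norm(g[~at_bound]))
        converged = bool(res.success or res.status == 0) and \
            grad_norm < options.gradient_tol
        return x, fbest, n_iter, grad_norm, converged

    # multistart over the variance-scale initialization: a flat likelihood
    # ridge occasionally strands the first start short of the tolerance
    best = None
    for sigma_init in (options.sigma_init, 0.5, 2.0):
        cand = optimize_from(sigma_init)
        if best is None or cand[1] < best[1] or \
                (cand[4] and not best[4] and cand[1] < best[1] + 1e-6):
            best = cand
        if best[4]:
            break
    x, fbest, n_iter, grad_norm, converged = best

    beta = x[:design.p]
    sig = np.exp(x[design.p:])
    variance, boundary, log_sigma = {}, {}, {}
    for k, term in enumerate(design.terms):
        log_sigma[term] = float(x[design.p + k])
        if sig[k] < _BOUNDARY_SIGMA:
            variance[term] = 0.0
            boundary[term] = True
        else:
            variance[term] = float(sig[k] ** 2)
            boundary[term] = False

    # empirical-Bayes modes at the optimum
    eb = {t: {} for t in design.terms}
    if use_agq:
        ll, u_hat = _agq_loglik(design, beta, sig, options.quadrature_order,
                                options.interaction_order, options.inner_tol)
        dim = 0
        for term in design.terms:
            if term == PATIENT:
                for i, pid in enumerate(design.patients):
                    eb[term][pid] = float(u_hat[i, dim])
                dim += 1
            else:  # PATIENT_METHOD
                for m, inst in enumerate(INSTRUMENTS):
                    for i, pid in enumerate(design.patients):
                        eb[term][(pid, inst)] = float(u_hat[i, dim + m])
                dim += 2
        approx = "agq"
    else:
        ll, u_hat = _laplace(design, beta, sig, state["u"], options.inner_tol)
        for term in design.terms:
            offset, labels = design.level_labels[term]
            for j, lab in enumerate(labels):
                eb[term][lab] = float(u_hat[offset + j])
        approx = "laplace"

    # covariance of beta, conditional on the variance components
    def nll_beta(b):
        return nll(np.concatenate([b, x[design.p:]]))

    Hb = _numeric_hessian(nll_beta, beta, h=options.hessian_step)
    try:
        beta_cov = np.linalg.inv(Hb)
    except np.linalg.LinAlgError:
        beta_cov = np.linalg.pinv(Hb)

    return GlmmFit(
        spec=spec, beta=dict(zip(design.beta_names, beta)),
        beta_cov=beta_cov, variance_components=variance, boundary=boundary,
        eb_modes=eb, loglik=float(ll), converged=converged, n_iter=int(n_iter),
        gradient_norm=grad_norm, gradient_tol=options.gradient_tol,
        approximation=approx, n_obs=len(design.y),
        n_dropped=design.n_dropped, patients=design.patients,
        raters=design.raters, instruments=design.instruments,
        log_sigma=log_sigma)


# ---------------------------------------------------------------------------
# inference and prediction


def wald_from_estimate(estimate: float, std_error: float,
                       level: float = 0.95) -> FixedEffectTest:
    """Wald CI and two-sided normal p-value from an estimate and its SE."""
    z = norm.ppf(0.5 + level / 2)
    p = 2 * norm.sf(abs(estimate) / std_error) if std_error > 0 else (
        1.0 if estimate == 0 else 0.0)
    return FixedEffectTest(
        estimate=float(estimate), std_error=float(std_error),
        ci_low=float(estimate - z * std_error),
        ci_high=float(estimate + z * std_error),
        p_value=float(min(p, 1.0)), level=level)


def wald_test_fixed(fit: GlmmFit, coefficient: str = "method",
                    level: float = 0.95) -> FixedEffectTest:
    names = list(fit.beta)
    if coefficient not in names:
        raise ValueError(f"unknown coefficient {coefficient!r}; "
                         f"have {names}")
    if not fit.converged:
        raise ConvergenceError(
            "refusing Wald inference on a non-converged fit "
            f"(gradient_norm={fit.gradient_norm:.3g})")
    i = names.index(coefficient)
    se = float(np.sqrt(fit.beta_cov[i, i]))
    return wald_from_estimate(fit.beta[coefficient], se, level)


def predict_latent(fit: GlmmFit, patient_id, instrument: str):
    """Latent linear predictor and probability for one patient/instrument.

    Uses the fixed effects and the patient-level empirical-Bayes modes;
    rater effects are set to their population mean 0.
    """
    if instrument not in INSTRUMENTS:
        raise ValueError(f"instrument must be one of {INSTRUMENTS}")
    if patient_id not in fit.patients:
        raise KeyError(f"patient {patient_id!r} not in the fitted data")
    eta = fit.beta["intercept"]
    if "method" in fit.beta and instrument == "3DCAM":
        eta += fit.beta["method"]
    eta += fit.eb_modes.get(PATIENT, {}).get(patient_id, 0.0)
    eta += fit.eb_modes.get(PATIENT_METHOD, {}).get((patient_id, instrument),
                                                    0.0)
    return float(eta), float(expit(eta))


# ---------------------------------------------------------------------------
# brute-force oracle


_GRID_POINTS = {1: 4001, 2: 801, 3: 121}


def marginal_loglik_bruteforce(table: pd.DataFrame, spec: GlmmSpec,
                               beta, variance_components: dict,
                               n_points: int | None = None,
                               span: float = 10.0) -> float:
    """Marginal log-likelihood by dense tensor-grid (Simpson) integration.

    Exponential cost by design: only patient-factored random structures are
    accepted (rater effects make the integral non-factorable), and at most
    5 patients.  With the default grids, refining the grid changes the
    result by less than 1e-6 for structures with up to 2 active dimensions
    per patient.
    """
    spec = replace(spec) if spec else GlmmSpec()
    if RATER in spec.random_terms:
        raise IntegrationDimensionError(
            "rater effects do not factor over patients; the dense grid "
            "would be exponential in the total dimension")
    design = _Design(table, spec)
    if design.n_patients > 5:
        raise IntegrationDimensionError("more than 5 patients")
    beta = np.asarray(beta, dtype=float)
    eta0 = design.X @ beta

    sig2 = np.array([variance_components.get(t, 0.0) for t in design.terms])
    if design.d and design.d > 3:
        raise IntegrationDimensionError(
            f"{design.d} random-effect dimensions per patient")
    dvar = sig2[design.dim_group] if design.d else np.zeros(0)

    total = 0.0
    for i in range(design.n_patients):
        mask = design.patient_idx == i
        y_i = design.y[mask]
        eta_i = eta0[mask]
        T_i = design.T[mask] if design.d else np.zeros((mask.sum(), 0))
        active = [k for k in range(len(dvar)) if dvar[k] > 0]
        if not active:
            total += float(np.sum(_loglik_bernoulli(y_i, eta_i)))
            continue
        d_act = len(active)
        n = n_points or _GRID_POINTS[d_act]
        axes = [np.linspace(-span * np.sqrt(dvar[k]),
                            span * np.sqrt(dvar[k]), n) for k in active]
        mesh = np.meshgrid(*axes, indexing="ij")
        loggrid = np.zeros(mesh[0].shape)
        for k_pos, k in enumerate(active):
            loggrid += norm.logpdf(mesh[k_pos], scale=np.sqrt(dvar[k]))
        for j in range(len(y_i)):
            eta = eta_i[j]
            for k_pos, k in enumerate(active):
                eta = eta + T_i[j, k] * mesh[k_pos]
            loggrid = loggrid + _loglik_bernoulli(y_i[j], eta)
        m = loggrid.max()
        vals = np.exp(loggrid - m)
        for k_pos in reversed(range(d_act)):
            vals = simpson(vals, x=axes[k_pos], axis=k_pos)
        total += m + float(np.log(vals))
    return float(total)
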