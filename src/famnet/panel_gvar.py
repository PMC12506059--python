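"""Random-intercept panel graphical VAR estimated by FIML.

Model.  For family f with node vector of length p observed at waves
t = 0..W-1::

    y_ft = mu + b_f + x_ft
    b_f  ~ N(0, inv(K_between))          (stable family traits)
    x_ft = B x_f,t-1 + zeta_ft,  zeta_ft ~ N(0, inv(K_within))

``B[i, j]`` is the lag-1 effect of node j on node i (the directed
temporal network); the off-diagonals of K_within, scaled to partial
correlations, form the contemporaneous network; those of K_between the
between-family network.  Stationarity (spectral radius of B below 1)
gives the within-family process a stationary covariance S0 solving the
discrete Lyapunov identity S0 = B S0 B' + inv(K_within), and the
stacked nodes-by-waves observation is jointly Gaussian with block
covariance S0 (B')^h at lag h plus inv(K_between) in every block.

Estimation maximizes the full-information likelihood: each family
contributes the Gaussian density of its observed entries only (families
are grouped by missingness pattern; the result is identical regardless
of grouping).  Model search follows a saturated -> pruned -> step-up
protocol: Wald-nonsignificant edges are recursively fixed to zero, then
a stepwise-up search re-frees the edge with the strongest modification
index while the information criterion keeps improving.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, solve_discrete_lyapunov
from scipy.stats import norm

from famnet.synthetic_data import precision_to_pcor

logger = logging.getLogger("famnet.panel_gvar")

__all__ = [
    "PanelGVARParams", "EdgeConstraintSet", "ModelFit",
    "implied_moments", "fiml_loglik", "fit_panel_gvar", "prune", "stepup",
    "fit_indices", "model_selection_pipeline",
]

_PENALTY = 1e12
_RHO_MAX = 0.999


@dataclass
class PanelGVARParams:
    """Means, temporal matrix and the two precision matrices."""

    node_names: list
    mu: np.ndarray
    B: np.ndarray
    K_within: np.ndarray
    K_between: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.K_within = np.asarray(self.K_within, dtype=float)
        self.K_between = np.asarray(self.K_between, dtype=float)

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.B)).max())

    @property
    def contemporaneous_pcor(self) -> np.ndarray:
        return precision_to_pcor(self.K_within)

    @property
    def between_pcor(self) -> np.ndarray:
        return precision_to_pcor(self.K_between)


@dataclass
class EdgeConstraintSet:
    """Boolean free/fixed masks over B and the precision off-diagonals.

    True marks a free parameter.  Diagonals (and means and variances)
    are always free; the precision masks are symmetric.
    """

    B_free: np.ndarray
    K_within_free: np.ndarray
    K_between_free: np.ndarray

    def __post_init__(self) -> None:
        self.B_free = np.asarray(self.B_free, dtype=bool).copy()
        self.K_within_free = np.asarray(self.K_within_free, dtype=bool).copy()
        self.K_between_free = np.asarray(self.K_between_free, dtype=bool).copy()
        for m in (self.B_free, self.K_within_free, self.K_between_free):
            np.fill_diagonal(m, True)
        for name in ("K_within_free", "K_between_free"):
            m = getattr(self, name)
            if not np.array_equal(m, m.T):
                raise ValueError(f"{name} mask must be symmetric")

    @classmethod
    def saturated(cls, p: int) -> "EdgeConstraintSet":
        full = np.ones((p, p), dtype=bool)
        return cls(full.copy(), full.copy(), full.copy())

    @classmethod
    def independence(cls, p: int) -> "EdgeConstraintSet":
        eye = np.eye(p, dtype=bool)
        return cls(eye.copy(), eye.copy(), eye.copy())

    def copy(self) -> "EdgeConstraintSet":
        return EdgeConstraintSet(self.B_free.copy(), self.K_within_free.copy(),
                                 self.K_between_free.copy())


def _param_index(constraints: EdgeConstraintSet, p: int) -> list:
    """Ordered (block, i, j) labels of the free parameter vector."""
    index: list = [("mu", i, i) for i in range(p)]
    for i in range(p):
        for j in range(p):
            if constraints.B_free[i, j]:
                index.append(("B", i, j))
    for name, mask in (("Kw", constraints.K_within_free),
                       ("Kb", constraints.K_between_free)):
        for i in range(p):
            index.append((name, i, i))
        for i in range(p):
            for j in range(i + 1, p):
                if mask[i, j]:
                    index.append((name, i, j))
    return index


def _pack(params: PanelGVARParams, index: list) -> np.ndarray:
    take = {"mu": lambda i, j: params.mu[i], "B": lambda i, j: params.B[i, j],
            "Kw": lambda i, j: params.K_within[i, j],
            "Kb": lambda i, j: params.K_between[i, j]}
    return np.array([take[b](i, j) for b, i, j in index])


def _unpack(theta: np.ndarray, index: list, p: int, node_names: list) -> PanelGVARParams:
    mu = np.zeros(p)
    B = np.zeros((p, p))
    Kw = np.zeros((p, p))
    Kb = np.zeros((p, p))
    for val, (blk, i, j) in zip(theta, index):
        if blk == "mu":
            mu[i] = val
        elif blk == "B":
            B[i, j] = val
        elif blk == "Kw":
            Kw[i, j] = Kw[j, i] = val
        else:
            Kb[i, j] = Kb[j, i] = val
    return PanelGVARParams(node_names, mu, B, Kw, Kb)


def implied_moments(model, n_waves: int) -> tuple[np.ndarray, np.ndarray]:
    """Implied mean and covariance of the stacked waves-by-nodes vector.

    Accepts either :class:`PanelGVARParams` (precision parameterization)
    or a generator truth carrying ``sigma_zeta`` / ``sigma_between``
    covariances directly (which permits zero intercept variance).
    Stacking is wave-major: entries [wave 0 nodes..., wave 1 nodes...].
    """
    if hasattr(model, "sigma_zeta"):
        B = np.asarray(model.B, dtype=float)
        sigma_zeta = np.asarray(model.sigma_zeta, dtype=float)
        sigma_between = np.asarray(model.sigma_between, dtype=float)
        mu = np.asarray(model.mu, dtype=float)
    else:
        B = model.B
        sigma_zeta = np.linalg.inv(model.K_within)
        sigma_between = np.linalg.inv(model.K_between)
        mu = model.mu
    p = B.shape[0]
    rho = float(np.abs(np.linalg.eigvals(B)).max())
    if rho >= 1.0:
        raise ValueError(f"non-stationary temporal matrix (spectral radius {rho:.3f})")
    S0 = solve_discrete_lyapunov(B, sigma_zeta)
    W = int(n_waves)
    BT_pow = [np.linalg.matrix_power(B.T, h) for h in range(W)]
    Sigma = np.empty((W * p, W * p))
    for s in range(W):
        for t in range(s, W):
            blk = S0 @ BT_pow[t - s] + sigma_between
            Sigma[s * p:(s + 1) * p, t * p:(t + 1) * p] = blk
            if t != s:
                Sigma[t * p:(t + 1) * p, s * p:(s + 1) * p] = blk.T
    mean = np.tile(mu, W)
    return mean, Sigma


def _group_patterns(mask: np.ndarray) -> list:
    """Group family rows by identical missingness pattern."""
    patterns, inverse = np.unique(mask, axis=0, return_inverse=True)
    return [(patterns[g].astype(bool), np.where(inverse == g)[0])
            for g in range(len(patterns))]


def _check_min_waves(mask: np.ndarray, p: int) -> None:
    W = mask.shape[1] // p
    waves_obs = mask.reshape(-1, W, p).any(axis=2).sum(axis=1)
    bad = np.where(waves_obs < 2)[0]
    if len(bad):
        raise ValueError(
            f"{len(bad)} families have fewer than 2 observed waves "
            f"(first indices {bad[:5].tolist()}); exclude them upstream"
        )


def _loglik_grad_core(theta, index, p, W, Y, patterns, node_names,
                      want_grad=True):
    """FIML log-likelihood and its analytic gradient in the free vector.

    Non-PD precisions or near-unit spectral radius return a large
    negative penalty (optimizer line searches back off)."""
    model = _unpack(theta, index, p, node_names)
    B, Kw, Kb = model.B, model.K_within, model.K_between
    n_param = len(theta)
    rho = float(np.abs(np.linalg.eigvals(B)).max())
    if rho >= _RHO_MAX:
        val = -_PENALTY * (1.0 + rho - _RHO_MAX)
        return (val, np.zeros(n_param)) if want_grad else (val, None)
    try:
        cw = cho_factor(Kw)
        cb = cho_factor(Kb)
    except np.linalg.LinAlgError:
        val = -_PENALTY
        return (val, np.zeros(n_param)) if want_grad else (val, None)
    eye = np.eye(p)
    sigma_zeta = cho_solve(cw, eye)
    sigma_between = cho_solve(cb, eye)
    S0 = solve_discrete_lyapunov(B, sigma_zeta)
    BT_pow = [np.linalg.matrix_power(B.T, h) for h in range(W)]
    d = W * p
    Sigma = np.empty((d, d))
    for s in range(W):
        for t in range(s, W):
            blk = S0 @ BT_pow[t - s] + sigma_between
            Sigma[s * p:(s + 1) * p, t * p:(t + 1) * p] = blk
            if t != s:
                Sigma[t * p:(t + 1) * p, s * p:(s + 1) * p] = blk.T
    mean = np.tile(model.mu, W)

    ll = 0.0
    G = np.zeros((d, d)) if want_grad else None
    gm = np.zeros(d) if want_grad else None
    log2pi = np.log(2.0 * np.pi)
    for obs, rows in patterns:
        ix = np.where(obs)[0]
        ng = len(rows)
        So = Sigma[np.ix_(ix, ix)]
        try:
            cf = cho_factor(So)
        except np.linalg.LinAlgError:
            val = -_PENALTY
            return (val, np.zeros(n_param)) if want_grad else (val, None)
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        Xc = Y[np.ix_(rows, ix)] - mean[ix]
        A = cho_solve(cf, Xc.T)              # S_o^{-1} X'
        ll += -0.5 * (ng * (len(ix) * log2pi + logdet) + float((Xc.T * A).sum()))
        if want_grad:
            Sinv = cho_solve(cf, np.eye(len(ix)))
            Gi = -0.5 * (ng * Sinv - A @ A.T)
            G[np.ix_(ix, ix)] += Gi
            gm[ix] += A.sum(axis=1)

    if not want_grad:
        return ll, None

    # --- chain rule: G (dL/dSigma) and gm (dL/dmean) back to parameters ---
    Gb = G.reshape(W, p, W, p)
    d_mu = gm.reshape(W, p).sum(axis=0)
    M_between = Gb.sum(axis=(0, 2))                      # dL/d sigma_between
    dKb = -sigma_between @ ((M_between + M_between.T) / 2.0) @ sigma_between

    # lag-collected adjoints H_h = sum_s G[s, s+h]
    H = [sum(Gb[s, :, s + h, :] for s in range(W - h)) for h in range(W)]
    B_pow = [m.T for m in BT_pow]                        # B^h
    P = H[0].copy()
    for h in range(1, W):
        P += 2.0 * H[h] @ B_pow[h]
    P = (P + P.T) / 2.0
    Lam = solve_discrete_lyapunov(B.T, P)                # Lam = B' Lam B + P
    d_sigma_zeta = Lam
    dKw = -sigma_zeta @ ((d_sigma_zeta + d_sigma_zeta.T) / 2.0) @ sigma_zeta

    dB = 2.0 * Lam @ B @ S0                              # through the Lyapunov map
    for h in range(1, W):
        M = H[h].T @ S0
        for k in range(h):
            dB += 2.0 * BT_pow[k] @ M @ BT_pow[h - 1 - k]

    grad = np.empty(n_param)
    for k, (blk, i, j) in enumerate(index):
        if blk == "mu":
            grad[k] = d_mu[i]
        elif blk == "B":
            grad[k] = dB[i, j]
        elif blk == "Kw":
            grad[k] = dKw[i, i] if i == j else 2.0 * dKw[i, j]
        else:
            grad[k] = dKb[i, i] if i == j else 2.0 * dKb[i, j]
    return ll, grad


def fiml_loglik(params: PanelGVARParams, panel_wide, missing_mask=None) -> float:
    """Full-information Gaussian log-likelihood of a wide panel.

    ``panel_wide`` is (n_families, n_waves*p) wave-major with NaN for
    missing entries (or ``missing_mask`` False).  Every family must
    have at least two observed waves.
    """
    Y = np.asarray(panel_wide, dtype=float)
    p = params.n_nodes
    if Y.shape[1] % p:
        raise ValueError("panel width is not a multiple of the node count")
    W = Y.shape[1] // p
    mask = ~np.isnan(Y) if missing_mask is None else np.asarray(missing_mask, bool)
    _check_min_waves(mask, p)
    Yz = np.where(mask, Y, 0.0)
    patterns = _group_patterns(mask)
    index = _param_index(EdgeConstraintSet.saturated(p), p)
    theta = _pack(params, index)
    ll, _ = _loglik_grad_core(theta, index, p, W, Yz, patterns,
                              params.node_names, want_grad=False)
    return float(ll)


@dataclass
class ModelFit:
    """A fitted (possibly constrained) panel GVAR."""

    params: PanelGVARParams
    constraints: EdgeConstraintSet
    loglik: float
    n_free_parameters: int
    n_families: int
    aic: float
    bic: float
    se: np.ndarray
    wald_z: np.ndarray
    wald_p: np.ndarray
    param_index: list
    converged: bool
    grad_norm: float
    n_iter: int
    name: str = "model"
    rmsea: float | None = None
    cfi: float | None = None

    def param_table(self) -> pd.DataFrame:
        theta = _pack(self.params, self.param_index)
        rows = []
        for k, (blk, i, j) in enumerate(self.param_index):
            rows.append({
                "block": blk, "i": self.params.node_names[i],
                "j": self.params.node_names[j], "estimate": theta[k],
                "se": self.se[k], "z": self.wald_z[k], "p": self.wald_p[k],
            })
        return pd.DataFrame(rows)


def _prepare_panel(panel, node_names, waves=None):
    """Accept a SymptomPanel or a wide frame/array -> (Y, mask, W)."""
    from famnet.io import SymptomPanel
    if isinstance(panel, SymptomPanel):
        wide = panel.to_wide(nodes=node_names, waves=waves)
        Y = wide.to_numpy(dtype=float)
    else:
        Y = np.asarray(panel, dtype=float)
    p = len(node_names)
    if Y.shape[1] % p:
        raise ValueError("panel width is not a multiple of the node count")
    mask = ~np.isnan(Y)
    return Y, mask, Y.shape[1] // p


def _start_params(Y, mask, p, W, node_names, constraints) -> PanelGVARParams:
    Ym = np.where(mask, Y, np.nan)
    node_vals = Ym.reshape(-1, W, p)
    mu = np.nanmean(node_vals, axis=(0, 1))
    mu = np.where(np.isfinite(mu), mu, 0.0)
    var = np.nanvar(node_vals, axis=(0, 1))
    var = np.where(np.isfinite(var) & (var > 1e-8), var, 1.0)
    B = 0.2 * np.eye(p) * constraints.B_free
    Kw = np.diag(1.0 / (0.6 * var))
    Kb = np.diag(1.0 / (0.4 * var))
    return PanelGVARParams(node_names, mu, B, Kw, Kb)


def _standard_errors(fun_grad, theta, n_param):
    """Observed-information SEs from a central-difference Hessian of the
    analytic gradient."""
    H = np.empty((n_param, n_param))
    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    for k in range(n_param):
        tp = theta.copy(); tp[k] += h[k]
        tm = theta.copy(); tm[k] -= h[k]
        _, gp = fun_grad(tp)
        _, gm_ = fun_grad(tm)
        H[k] = (gp - gm_) / (2.0 * h[k])
    H = -(H + H.T) / 2.0                     # information = -Hessian of ll
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        diag = np.abs(np.diag(cov))
        logger.warning("information matrix not PD; pseudo-inverse SEs")
    return np.sqrt(diag)


def fit_panel_gvar(
    panel,
    node_names: list,
    constraints: EdgeConstraintSet | None = None,
    waves=None,
    start: PanelGVARParams | None = None,
    maxiter: int = 2000,
    gtol: float = 1e-5,
    compute_se: bool = True,
    name: str = "model",
) -> ModelFit:
    """Maximize the FIML likelihood over the free parameters.

    ``panel`` is a SymptomPanel or a wide (n_families, W*p) array with
    NaN for missing cells.  Families with fewer than two observed waves
    must be excluded upstream (error otherwise).
    """
    p = len(node_names)
    constraints = constraints.copy() if constraints else EdgeConstraintSet.saturated(p)
    Y, mask, W = _prepare_panel(panel, node_names, waves)
    _check_min_waves(mask, p)
    n_fam = Y.shape[0]
    index = _param_index(constraints, p)
    if n_fam < 5 * len(index):
        logger.warning("fit_panel_gvar: only %d families for %d free parameters",
                       n_fam, len(index))
    Yz = np.where(mask, Y, 0.0)
    patterns = _group_patterns(mask)
    if start is None:
        start = _start_params(Y, mask, p, W, node_names, constraints)
    theta0 = _pack(start, index)

    def negloglik_grad(theta):
        ll, g = _loglik_grad_core(theta, index, p, W, Yz, patterns, node_names)
        return -ll, -g

    res = optimize.minimize(
        negloglik_grad, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "maxfun": 5 * maxiter, "ftol": 1e-11,
                 "gtol": gtol},
    )
    theta = res.x
    ll, g = _loglik_grad_core(theta, index, p, W, Yz, patterns, node_names)
    grad_norm = float(np.max(np.abs(g)))
    # gradient is on the raw likelihood scale; normalize by N for a
    # size-independent convergence read
    converged = bool(res.success or grad_norm / max(n_fam, 1) < 1e-3)
    if not converged:
        logger.warning("fit_panel_gvar[%s]: not converged (grad %.3g, %s)",
                       name, grad_norm, res.message)
    k = len(index)
    if compute_se:
        se = _standard_errors(lambda t: _loglik_grad_core(
            t, index, p, W, Yz, patterns, node_names), theta, k)
    else:
        se = np.full(k, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = theta / se
    pvals = 2.0 * norm.sf(np.abs(z))
    params = _unpack(theta, index, p, list(node_names))
    return ModelFit(
        params=params, constraints=constraints, loglik=float(ll),
        n_free_parameters=k, n_families=n_fam,
        aic=float(-2 * ll + 2 * k), bic=float(-2 * ll + k * np.log(n_fam)),
        se=se, wald_z=z, wald_p=pvals, param_index=index,
        converged=converged, grad_norm=grad_norm,
        n_iter=int(res.nit), name=name,
    )


_OFFDIAG_BLOCKS = ("B", "Kw", "Kb")


def _offdiag_free(fitted: ModelFit) -> list:
    return [k for k, (blk, i, j) in enumerate(fitted.param_index)
            if blk in _OFFDIAG_BLOCKS and i != j]


def _apply_mask(constraints: EdgeConstraintSet, blk: str, i: int, j: int,
                free: bool) -> None:
    if blk == "B":
        constraints.B_free[i, j] = free
    elif blk == "Kw":
        constraints.K_within_free[i, j] = constraints.K_within_free[j, i] = free
    else:
        constraints.K_between_free[i, j] = constraints.K_between_free[j, i] = free


def prune(fitted: ModelFit, panel, alpha: float = 0.05, **fit_kw) -> tuple:
    """Recursively fix Wald-nonsignificant off-diagonal parameters to
    zero and refit until every remaining off-diagonal has p < alpha.

    Returns (constraints, pruned ModelFit).  Means, diagonals and
    variances are never pruned.  If a refit fails to converge the last
    converged model is returned flagged."""
    if not fitted.converged:
        raise ValueError("prune requires a converged input fit")
    current = fitted
    constraints = fitted.constraints.copy()
    node_names = fitted.params.node_names
    for _ in range(50):
        cand = [k for k in _offdiag_free(current)
                if not (current.wald_p[k] < alpha)]
        if not cand:
            break
        for k in cand:
            blk, i, j = current.param_index[k]
            _apply_mask(constraints, blk, i, j, False)
        nxt = fit_panel_gvar(panel, node_names, constraints=constraints,
                             start=current.params, name="pruned", **fit_kw)
        if not nxt.converged:
            logger.warning("prune: refit did not converge; returning last model")
            current = nxt
            break
        current = nxt
    return constraints, replace(current, name="pruned")


def _modification_indices(fitted: ModelFit, panel, node_names) -> list:
    """Score candidate currently-fixed off-diagonals at the restricted
    optimum: MI ~ g_k^2 / H_kk on the extended parameter vector, with
    |g_k| as fallback where the curvature is not usable."""
    p = len(node_names)
    Y, mask, W = _prepare_panel(panel, node_names)
    Yz = np.where(mask, Y, 0.0)
    patterns = _group_patterns(mask)
    sat_index = _param_index(EdgeConstraintSet.saturated(p), p)
    theta = _pack(fitted.params, sat_index)
    free_set = set(fitted.param_index)
    cand = [k for k, (blk, i, j) in enumerate(sat_index)
            if blk in _OFFDIAG_BLOCKS and i != j and sat_index[k] not in free_set]
    if not cand:
        return []
    _, g = _loglik_grad_core(theta, sat_index, p, W, Yz, patterns, node_names)
    out = []
    h = 1e-5
    for k in cand:
        tp = theta.copy(); tp[k] += h
        tm = theta.copy(); tm[k] -= h
        _, gp = _loglik_grad_core(tp, sat_index, p, W, Yz, patterns, node_names)
        _, gm_ = _loglik_grad_core(tm, sat_index, p, W, Yz, patterns, node_names)
        curv = -(gp[k] - gm_[k]) / (2 * h)   # observed information in k
        mi = g[k] ** 2 / curv if curv > 1e-8 else abs(g[k])
        out.append((mi, sat_index[k]))
    out.sort(key=lambda t: -t[0])
    return out


def stepup(
    pruned_fit: ModelFit, panel, criterion: str = "bic",
    max_steps: int = 50, **fit_kw,
) -> ModelFit:
    """Stepwise-up search: repeatedly free the fixed edge with the
    strongest modification index; keep the refit iff the information
    criterion improves, else stop."""
    if criterion not in ("bic", "aic"):
        raise ValueError("criterion must be 'bic' or 'aic'")
    if not pruned_fit.converged:
        raise ValueError("stepup requires a converged input fit")
    current = pruned_fit
    node_names = pruned_fit.params.node_names
    for _ in range(max_steps):
        scored = _modification_indices(current, panel, node_names)
        if not scored:
            break
        _, (blk, i, j) = scored[0]
        trial_constraints = current.constraints.copy()
        _apply_mask(trial_constraints, blk, i, j, True)
        trial = fit_panel_gvar(panel, node_names, constraints=trial_constraints,
                               start=current.params, name="stepup", **fit_kw)
        if getattr(trial, criterion) < getattr(current, criterion) and trial.converged:
            current = trial
        else:
            break
    return replace(current, name="stepup")


def fit_indices(fitted: ModelFit, saturated_fit: ModelFit,
                baseline_fit: ModelFit) -> dict:
    """RMSEA / CFI / AIC / BIC for a model nested under the saturated fit.

    T = 2 (ll_sat - ll_model); df = difference in free parameters;
    RMSEA = sqrt(max(0, T - df) / (df N)) (0 when df = 0); CFI uses the
    independence model (all off-diagonals zero) as baseline.
    """
    N = fitted.n_families
    T = 2.0 * (saturated_fit.loglik - fitted.loglik)
    df = saturated_fit.n_free_parameters - fitted.n_free_parameters
    Tb = 2.0 * (saturated_fit.loglik - baseline_fit.loglik)
    dfb = saturated_fit.n_free_parameters - baseline_fit.n_free_parameters
    rmsea = float(np.sqrt(max(0.0, T - df) / (df * N))) if df > 0 else 0.0
    denom = max(Tb - dfb, T - df, 0.0)
    cfi = 1.0 if denom == 0 else float(1.0 - max(0.0, T - df) / denom)
    cfi = min(max(cfi, 0.0), 1.0)
    return {"T": float(max(T, 0.0)), "df": int(df), "rmsea": rmsea, "cfi": cfi,
            "aic": fitted.aic, "bic": fitted.bic}


def _edge_lists(params: PanelGVARParams) -> dict:
    names = params.node_names
    temporal = []
    p = len(names)
    for i in range(p):
        for j in range(p):
            w = params.B[i, j]
            if w != 0:
                temporal.append({"from": names[j], "to": names[i], "weight": w})
    def _sym_edges(pcor):
        rows = []
        for i in range(p):
            for j in range(i + 1, p):
                if pcor[i, j] != 0:
                    rows.append({"node_a": names[i], "node_b": names[j],
                                 "weight": pcor[i, j]})
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])
    return {
        "temporal": pd.DataFrame(temporal, columns=["from", "to", "weight"]),
        "contemporaneous": _sym_edges(params.contemporaneous_pcor),
        "between": _sym_edges(params.between_pcor),
    }


def model_selection_pipeline(
    panel, node_names: list, alpha: float = 0.05, criterion: str = "bic",
    waves=None, **fit_kw,
) -> dict:
    """Run saturated -> prune -> step-up and assemble the report.

    Returns the three ModelFits, the AIC/BIC/RMSEA/CFI comparison table
    and the final directed temporal, contemporaneous and between-family
    edge lists."""
    p = len(node_names)
    try:
        saturated = fit_panel_gvar(panel, node_names, waves=waves,
                                   name="saturated", **fit_kw)
    except Exception as exc:
        raise RuntimeError(f"saturated stage failed: {exc}") from exc
    try:
        _, pruned = prune(saturated, panel, alpha=alpha, waves=waves, **fit_kw)
    except Exception as exc:
        raise RuntimeError(f"prune stage failed: {exc}") from exc
    try:
        final = stepup(pruned, panel, criterion=criterion, waves=waves, **fit_kw)
    except Exception as exc:
        raise RuntimeError(f"stepup stage failed: {exc}") from exc
    baseline = fit_panel_gvar(panel, node_names,
                              constraints=EdgeConstraintSet.independence(p),
                              waves=waves, compute_se=False, name="baseline",
                              **fit_kw)
    rows = []
    for m in (saturated, pruned, final):
        fi = fit_indices(m, saturated, baseline)
        rows.append({"model": m.name, "loglik": m.loglik,
                     "n_parameters": m.n_free_parameters, **fi})
    return {
        "saturated": saturated, "pruned": pruned, "final": final,
        "baseline": baseline,
        "comparison": pd.DataFrame(rows),
        "edges": _edge_lists(final.params),
    }
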