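"""Cross-sectional network estimation: nodewise lasso + AND rule.

Each node is regressed on all others with an L1 penalty after
z-standardization (the Gaussian special case of a mixed graphical
model).  An edge is retained only when both directed regressions select
it (AND rule); its weight is the mean of the two standardized
coefficients, which lies on the partial-correlation scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

logger = logging.getLogger("famnet.ggm")

__all__ = [
    "NetworkGraph", "GGMFit", "fit_nodewise_lasso", "and_rule_combine",
    "partial_correlation_matrix", "select_subgroup_networks",
]


@dataclass
class NetworkGraph:
    """Symmetric weighted network over named nodes with member labels.

    Weights are signed partial-correlation-scale edge weights; the
    diagonal is exactly zero.
    """

    node_names: list
    weights: np.ndarray
    communities: dict

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        p = len(self.node_names)
        if self.weights.shape != (p, p):
            raise ValueError("weights shape does not match node_names")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("weights diagonal must be exactly 0")
        if np.any(np.abs(self.weights) >= 1):
            raise ValueError("edge weights must have magnitude < 1")
        miss = [n for n in self.node_names if n not in self.communities]
        if miss:
            raise ValueError(f"nodes without community label: {miss}")

    def edge_list(self) -> pd.DataFrame:
        """Upper-triangle nonzero edges as a tidy table."""
        rows = []
        p = len(self.node_names)
        for i in range(p):
            for j in range(i + 1, p):
                w = self.weights[i, j]
                if w != 0:
                    a, b = self.node_names[i], self.node_names[j]
                    rows.append((a, b, w, self.communities[a] != self.communities[b]))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "is_bridge"])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.node_names:
            g.add_node(n, community=self.communities[n])
        for _, r in self.edge_list().iterrows():
            g.add_edge(r["node_a"], r["node_b"], weight=float(r["weight"]),
                       is_bridge=bool(r["is_bridge"]))
        return g


@dataclass
class GGMFit:
    """A fitted nodewise-lasso network plus the directed coefficients and
    per-node selected penalties needed to audit the AND rule."""

    network: NetworkGraph
    nodewise_coefficients: np.ndarray
    selected_penalties: np.ndarray
    n_samples: int
    standardization: pd.DataFrame
    config: dict = field(default_factory=dict)


def _validate_matrix(data: pd.DataFrame) -> np.ndarray:
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 columns")
    if np.isnan(X).any():
        raise ValueError("data contain missing values; impute or filter upstream")
    if n <= p:
        raise ValueError(f"n ({n}) must exceed the number of nodes ({p})")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(data.columns, sd) if s == 0]
        raise ValueError(f"constant column(s): {bad}")
    # exact duplicates would yield a spurious perfect edge, not information
    Xs = (X - X.mean(axis=0)) / sd
    gram = Xs.T @ Xs / n
    iu = np.triu_indices(p, 1)
    dup = np.abs(gram[iu]) > 1 - 1e-10
    if dup.any():
        k = np.argmax(dup)
        i, j = iu[0][k], iu[1][k]
        raise ValueError(
            f"columns {data.columns[i]!r} and {data.columns[j]!r} are duplicated"
        )
    return X


@njit(cache=True)
def _cd_path(G, c, alphas, tol, max_sweeps):
    """Lasso path by cyclic coordinate descent on the Gram matrix.

    G = X'X/n with unit diagonal (standardized predictors), c = X'y/n.
    Returns coefficients (d x n_alphas), warm-started along the
    descending alpha grid."""
    d = c.shape[0]
    n_a = alphas.shape[0]
    out = np.zeros((d, n_a))
    beta = np.zeros(d)
    resid_cor = c.copy()          # c - G beta
    for a in range(n_a):
        alpha = alphas[a]
        for _ in range(max_sweeps):
            delta = 0.0
            for k in range(d):
                old = beta[k]
                rho = resid_cor[k] + old   # G_kk = 1
                if rho > alpha:
                    new = rho - alpha
                elif rho < -alpha:
                    new = rho + alpha
                else:
                    new = 0.0
                if new != old:
                    step = new - old
                    for j in range(d):
                        resid_cor[j] -= G[j, k] * step
                    beta[k] = new
                    if abs(step) > delta:
                        delta = abs(step)
            if delta < tol:
                break
        out[:, a] = beta
    return out


def _ebic_select(Xo: np.ndarray, y: np.ndarray, gamma: float,
                 n_alphas: int, eps: float) -> tuple[float, np.ndarray]:
    """Per-node penalty selection by extended BIC over a log-spaced path."""
    n, d = Xo.shape
    G = Xo.T @ Xo / n
    c = Xo.T @ y / n
    alpha_max = np.abs(c).max()
    if alpha_max <= 0:
        return 1e-12, np.zeros(d)
    alphas = np.geomspace(alpha_max, alpha_max * eps, n_alphas)
    coefs = _cd_path(G, c, alphas, 1e-7, 1000)
    yty = float(y @ y) / n
    rss = n * (yty - 2.0 * c @ coefs + np.einsum("ka,kj,ja->a", coefs, G, coefs))
    k = (coefs != 0).sum(axis=0)
    ebic = n * np.log(np.maximum(rss, 1e-300) / n) + k * np.log(n) \
        + 2.0 * gamma * k * np.log(max(d, 1))
    best = int(np.argmin(ebic))
    return float(alphas[best]), coefs[:, best]


def fit_nodewise_lasso(
    data: pd.DataFrame,
    penalty_selection: str = "cv",
    communities: dict | None = None,
    seed: int | None = None,
    cv_folds: int = 10,
    ebic_gamma: float = 0.25,
    n_alphas: int = 50,
    alpha_min_ratio: float = 1e-3,
    threshold: str = "lw",
) -> GGMFit:
    """Fit the regularized partial-correlation network.

    Parameters
    ----------
    penalty_selection:
        ``"cv"`` — per-node 10-fold cross-validation (default) or
        ``"ebic"`` — extended BIC (gamma 0.25) over a log-spaced path.
    communities:
        node -> family-member map; inferred from ``c_/m_/f_`` prefixes
        when omitted, else every node is labelled ``"all"``.
    threshold:
        ``"lw"`` (default) additionally zeroes nodewise coefficients
        below the Loh–Wainwright bound sqrt(d_j log p / n) (d_j = the
        selected neighbourhood size), since cross-validated lasso alone
        over-selects; ``"none"`` disables it.
    """
    data = pd.DataFrame(data)
    X = _validate_matrix(data)
    names = list(data.columns)
    if communities is None:
        try:
            from famnet.synthetic_data import default_triad_communities
            communities = default_triad_communities(names)
        except ValueError:
            communities = {c: "all" for c in names}

    coefs, penalties, W = _fit_core(
        X, penalty_selection, seed, cv_folds, ebic_gamma, n_alphas,
        alpha_min_ratio, threshold)
    n, p = X.shape
    mean, sd = X.mean(axis=0), X.std(axis=0)
    net = NetworkGraph(node_names=names, weights=W, communities=communities)
    std = pd.DataFrame({"node": names, "mean": mean, "scale": sd})
    cfg = {"penalty_selection": penalty_selection, "cv_folds": cv_folds,
           "ebic_gamma": ebic_gamma, "n_alphas": n_alphas,
           "alpha_min_ratio": alpha_min_ratio, "threshold": threshold,
           "seed": seed}
    return GGMFit(network=net, nodewise_coefficients=coefs,
                  selected_penalties=penalties, n_samples=n,
                  standardization=std, config=cfg)


def _fit_core(X, penalty_selection, seed, cv_folds, ebic_gamma, n_alphas,
              alpha_min_ratio, threshold):
    """Array-level nodewise-lasso fit (no validation, no labels).

    Shared by the public estimator and the permutation/bootstrap loops
    so every refit runs the identical pipeline."""
    n, p = X.shape
    mean, sd = X.mean(axis=0), X.std(axis=0)
    Xs = (X - mean) / sd
    coefs = np.zeros((p, p))
    penalties = np.zeros(p)
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    node_seeds = ss.generate_state(p)
    for i in range(p):
        others = [j for j in range(p) if j != i]
        Xo, y = Xs[:, others], Xs[:, i]
        if penalty_selection == "cv":
            cv = KFold(n_splits=cv_folds, shuffle=True,
                       random_state=int(node_seeds[i] % (2 ** 31)))
            model = LassoCV(cv=cv, alphas=n_alphas, eps=alpha_min_ratio,
                            fit_intercept=False).fit(Xo, y)
            penalties[i] = model.alpha_
            beta = model.coef_
        elif penalty_selection == "ebic":
            penalties[i], beta = _ebic_select(Xo, y, ebic_gamma, n_alphas,
                                              alpha_min_ratio)
        else:
            raise ValueError(f"unknown penalty_selection {penalty_selection!r}")
        if threshold == "lw":
            d = max(int((beta != 0).sum()), 1)
            tau = np.sqrt(d * np.log(p) / n)
            beta = np.where(np.abs(beta) < tau, 0.0, beta)
        elif threshold != "none":
            raise ValueError(f"unknown threshold {threshold!r}")
        coefs[i, others] = beta
    W = and_rule_combine(coefs)
    np.clip(W, -0.999, 0.999, out=W)
    return coefs, penalties, W


def and_rule_combine(nodewise_coefficients: np.ndarray) -> np.ndarray:
    """Combine directed coefficients into a symmetric network.

    Edge (i, j) is kept only when both c[i][j] and c[j][i] are nonzero
    with the same sign; its weight is their mean.  Sign conflicts are
    zeroed with a logged warning.
    """
    C = np.asarray(nodewise_coefficients, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"coefficient matrix must be square, got {C.shape}")
    if np.any(np.diag(C) != 0):
        raise ValueError("coefficient diagonal must be 0")
    both = (C != 0) & (C.T != 0)
    same_sign = np.sign(C) == np.sign(C.T)
    conflict = both & ~same_sign
    if conflict.any():
        pairs = np.argwhere(np.triu(conflict, 1))
        logger.warning("AND rule: %d sign-conflicting pair(s) zeroed: %s",
                       len(pairs), pairs.tolist())
    W = np.where(both & same_sign, 0.5 * (C + C.T), 0.0)
    np.fill_diagonal(W, 0.0)
    return W


def partial_correlation_matrix(data: pd.DataFrame) -> np.ndarray:
    """Unregularized partial correlations from the inverse sample
    covariance: pcor(i, j) = -K_ij / sqrt(K_ii K_jj), zero diagonal."""
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n ({n}) must exceed the number of nodes ({p})")
    S = np.cov(X, rowvar=False)
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0 or logdet < -300:
        raise ValueError("sample covariance is singular")
    K = np.linalg.inv(S)
    d = np.sqrt(np.diag(K))
    pcor = -K / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    return pcor


def _age_band(age: float) -> str | None:
    if age < 10:
        return "<10"
    if age <= 12:
        return "10-12"
    if age <= 15:
        return "13-15"
    return None


def select_subgroup_networks(
    data: pd.DataFrame,
    grouping: str,
    node_columns: list | None = None,
    estimator_config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Partition families into subgroups and fit one network per group
    with identical settings.

    ``grouping`` is one of ``child_sex`` (column ``child_sex``),
    ``child_age_bands`` (column ``child_age``; bands <10, 10-12, 13-15)
    or ``income_tertiles`` (column ``income``; the top and bottom thirds
    by value are retained, the middle discarded).
    """
    estimator_config = dict(estimator_config or {})
    cov_cols = {"child_sex", "child_age", "income"}
    if node_columns is None:
        node_columns = [c for c in data.columns if c not in cov_cols]
    if grouping == "child_sex":
        col = "child_sex"
        groups = {str(v): data.index[data[col] == v] for v in data[col].unique()}
    elif grouping == "child_age_bands":
        bands = data["child_age"].map(_age_band)
        groups = {b: data.index[bands == b] for b in ("<10", "10-12", "13-15")
                  if (bands == b).any()}
    elif grouping == "income_tertiles":
        order = data["income"].sort_values(kind="stable").index
        m = len(order) // 3
        if m == 0:
            raise ValueError("too few families for income tertiles")
        groups = {"bottom_third": order[:m], "top_third": order[-m:]}
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    p = len(node_columns)
    small = {g: len(ix) for g, ix in groups.items() if len(ix) < p + 1}
    if small:
        raise ValueError(f"groups too small to fit a {p}-node network: {small}")
    return {
        g: fit_nodewise_lasso(data.loc[ix, node_columns], seed=seed,
                              **estimator_config)
        for g, ix in groups.items()
    }
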