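"""Permutation network comparison test (NCT) for two group networks.

The observed statistic per edge is E = |w1 - w2|.  A null distribution
is built by randomly reassigning rows to groups (original sizes kept)
and refitting both networks with the full estimation pipeline.  Raw
permutation p-values are Holm-adjusted across the tested edges, which
default to the union of bridge edges nonzero in either group.  Global
statistics — the maximum edge difference M and the global-strength
difference S — are computed alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from famnet.bridge import bridge_edges
from famnet.ggm import _fit_core, fit_nodewise_lasso

logger = logging.getLogger("famnet.nct")

__all__ = ["NCTResult", "nct_compare", "holm_correction",
           "edge_difference_report"]


@dataclass
class NCTResult:
    edges: list                       # (node_a, node_b) tuples tested
    observed_E: np.ndarray            # |w1 - w2| per tested edge
    w1: np.ndarray
    w2: np.ndarray
    perm_E: np.ndarray                # (n_perm, n_edges)
    p_raw: np.ndarray
    p_holm: np.ndarray
    observed_M: float                 # max |w1 - w2| over all edges
    observed_S: float                 # |global strength 1 - global strength 2|
    p_M: float
    p_S: float
    n_permutations: int
    seed: int | None
    communities: dict = field(default_factory=dict)


def holm_correction(pvalues) -> np.ndarray:
    """Bonferroni–Holm step-down adjustment, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, k in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[k]))
        adj[k] = running
    return adj


def _global_strength(W: np.ndarray) -> float:
    return float(np.abs(W[np.triu_indices(W.shape[0], 1)]).sum())


def nct_compare(
    data_g1: pd.DataFrame,
    data_g2: pd.DataFrame,
    estimator_config: dict | None = None,
    edges_of_interest: list | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> NCTResult:
    """Compare two group networks by permutation.

    ``edges_of_interest`` is a list of (node_a, node_b) pairs; by
    default the union of bridge edges that are nonzero in either
    observed group network.  p = (1 + #{perm E >= observed E}) /
    (1 + n_perm).
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20 for usable p-value resolution")
    estimator_config = dict(estimator_config or {})
    data_g1, data_g2 = pd.DataFrame(data_g1), pd.DataFrame(data_g2)
    if list(data_g1.columns) != list(data_g2.columns):
        raise ValueError("both groups must share the same node columns")
    names = list(data_g1.columns)
    idx = {n: i for i, n in enumerate(names)}

    fit1 = fit_nodewise_lasso(data_g1, **estimator_config)
    fit2 = fit_nodewise_lasso(data_g2, **estimator_config)
    W1, W2 = fit1.network.weights, fit2.network.weights
    communities = fit1.network.communities

    if edges_of_interest is None:
        e1, _ = bridge_edges(fit1.network)
        e2, _ = bridge_edges(fit2.network)
        pairs = {tuple(sorted(t)) for t in
                 list(map(tuple, e1[["node_a", "node_b"]].values)) +
                 list(map(tuple, e2[["node_a", "node_b"]].values))}
        edges_of_interest = sorted(pairs)
    edges_of_interest = [tuple(e) for e in edges_of_interest]
    eidx = np.array([(idx[a], idx[b]) for a, b in edges_of_interest], dtype=int
                    ).reshape(-1, 2)

    def edge_E(Wa, Wb):
        if len(eidx) == 0:
            return np.empty(0)
        return np.abs(Wa[eidx[:, 0], eidx[:, 1]] - Wb[eidx[:, 0], eidx[:, 1]])

    obs_E = edge_E(W1, W2)
    obs_M = float(np.max(np.abs(W1 - W2))) if names else 0.0
    obs_S = abs(_global_strength(W1) - _global_strength(W2))

    pooled = np.concatenate([data_g1.to_numpy(float), data_g2.to_numpy(float)])
    n1, n_tot = len(data_g1), len(pooled)
    rng = np.random.default_rng(seed)
    # resolve config once so every permutation refit runs the identical
    # estimation pipeline as the observed fits
    core_cfg = {k: fit1.config[k] for k in
                ("penalty_selection", "seed", "cv_folds", "ebic_gamma",
                 "n_alphas", "alpha_min_ratio", "threshold")}
    perm_E = np.empty((n_perm, len(eidx)))
    perm_M = np.empty(n_perm)
    perm_S = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n_tot)
        _, _, Wp1 = _fit_core(pooled[perm[:n1]], core_cfg["penalty_selection"],
                              core_cfg["seed"], core_cfg["cv_folds"],
                              core_cfg["ebic_gamma"], core_cfg["n_alphas"],
                              core_cfg["alpha_min_ratio"], core_cfg["threshold"])
        _, _, Wp2 = _fit_core(pooled[perm[n1:]], core_cfg["penalty_selection"],
                              core_cfg["seed"], core_cfg["cv_folds"],
                              core_cfg["ebic_gamma"], core_cfg["n_alphas"],
                              core_cfg["alpha_min_ratio"], core_cfg["threshold"])
        perm_E[b] = edge_E(Wp1, Wp2)
        perm_M[b] = np.max(np.abs(Wp1 - Wp2))
        perm_S[b] = abs(_global_strength(Wp1) - _global_strength(Wp2))

    if len(eidx):
        p_raw = (1.0 + (perm_E >= obs_E[None, :] - 1e-15).sum(axis=0)) / (1.0 + n_perm)
        p_holm = holm_correction(p_raw)
    else:
        p_raw = np.empty(0)
        p_holm = np.empty(0)
    p_M = (1.0 + (perm_M >= obs_M - 1e-15).sum()) / (1.0 + n_perm)
    p_S = (1.0 + (perm_S >= obs_S - 1e-15).sum()) / (1.0 + n_perm)

    w1 = W1[eidx[:, 0], eidx[:, 1]] if len(eidx) else np.empty(0)
    w2 = W2[eidx[:, 0], eidx[:, 1]] if len(eidx) else np.empty(0)
    return NCTResult(
        edges=edges_of_interest, observed_E=obs_E, w1=w1, w2=w2,
        perm_E=perm_E, p_raw=p_raw, p_holm=p_holm,
        observed_M=obs_M, observed_S=obs_S, p_M=p_M, p_S=p_S,
        n_permutations=n_perm, seed=seed, communities=dict(communities),
    )


def edge_difference_report(result: NCTResult, alpha: float = 0.05) -> pd.DataFrame:
    """One row per tested edge: endpoints, communities, group weights,
    E, raw and Holm p, significance flag (Holm p < alpha)."""
    rows = []
    for k, (a, b) in enumerate(result.edges):
        rows.append({
            "node_a": a, "node_b": b,
            "community_a": result.communities.get(a),
            "community_b": result.communities.get(b),
            "w_group1": result.w1[k], "w_group2": result.w2[k],
            "E": result.observed_E[k],
            "p_raw": result.p_raw[k], "p_holm": result.p_holm[k],
            "significant": bool(result.p_holm[k] < alpha),
        })
    cols = ["node_a", "node_b", "community_a", "community_b", "w_group1",
            "w_group2", "E", "p_raw", "p_holm", "significant"]
    return pd.DataFrame(rows, columns=cols)
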