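"""Synthetic family-triad data with known ground-truth network structure.

Two generating processes are provided:

* a Gaussian graphical model (GGM) over 9 subscale nodes — three child
  dimensions (internalising, externalising, prosocial) and three per
  parent (emotional symptoms, social dysfunction, loss of confidence) —
  for the cross-sectional arm; and
* a stationary lag-1 graphical VAR with a family random intercept over
  13 emotional-symptom item nodes (5 child + 4 per parent) for the
  longitudinal arm, with wave-level missing-completely-at-random
  attrition.

Ground truth is parameterized by precision / coefficient matrices (so
positive-definiteness and stationarity are enforceable); the
partial-correlation views are derived.  All generators are pure
functions of (arguments, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_discrete_lyapunov
from scipy.stats import norm

from famnet.io import PANEL_NODE_SCHEMA, SymptomPanel

logger = logging.getLogger("famnet.synthetic")

__all__ = [
    "GGMTruth", "GVARTruth", "FamilyPanelSpec",
    "make_ggm_truth", "family_triad_truth", "simulate_cross_sectional",
    "make_gvar_truth", "simulate_panel", "discretize_likert",
]


def _check_symmetric_pd(m: np.ndarray, name: str, strict: bool = True) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    eig = np.linalg.eigvalsh(m)
    if strict and eig.min() <= 0:
        raise ValueError(f"{name} must be positive definite (min eig {eig.min():.3g})")
    if not strict and eig.min() < -1e-10:
        raise ValueError(f"{name} must be positive semi-definite")


def precision_to_pcor(precision: np.ndarray) -> np.ndarray:
    """Partial correlations implied by a precision matrix, zero diagonal."""
    d = np.sqrt(np.diag(precision))
    pcor = -precision / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    return pcor


@dataclass
class GGMTruth:
    """Population cross-sectional network: a PD precision matrix over
    named nodes partitioned by family member."""

    node_names: list
    precision: np.ndarray
    communities: dict

    def __post_init__(self) -> None:
        self.precision = np.asarray(self.precision, dtype=float)
        _check_symmetric_pd(self.precision, "precision")
        if len(self.node_names) != self.precision.shape[0]:
            raise ValueError("node_names length does not match precision")
        miss = [n for n in self.node_names if n not in self.communities]
        if miss:
            raise ValueError(f"nodes without community label: {miss}")

    @property
    def partial_correlations(self) -> np.ndarray:
        return precision_to_pcor(self.precision)

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)


@dataclass
class GVARTruth:
    """Generating process of the longitudinal network: stationary VAR(1)
    deviations around a family-specific random intercept.

    ``B[i, j]`` is the effect of node j at wave t-1 on node i at wave t.
    """

    node_names: list
    mu: np.ndarray
    B: np.ndarray
    sigma_zeta: np.ndarray
    sigma_between: np.ndarray
    communities: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.sigma_zeta = np.asarray(self.sigma_zeta, dtype=float)
        self.sigma_between = np.asarray(self.sigma_between, dtype=float)
        rho = self.spectral_radius
        if rho >= 1.0:
            raise ValueError(f"temporal matrix not stationary (spectral radius {rho:.3f})")
        _check_symmetric_pd(self.sigma_zeta, "sigma_zeta", strict=True)
        _check_symmetric_pd(self.sigma_between, "sigma_between", strict=False)

    @property
    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.B)).max())

    @property
    def stationary_cov(self) -> np.ndarray:
        """Within-family stationary covariance S0 = B S0 B' + sigma_zeta."""
        return solve_discrete_lyapunov(self.B, self.sigma_zeta)


@dataclass(frozen=True)
class FamilyPanelSpec:
    """Sampling frame for the panel generator."""

    n_families: int
    n_waves: int
    missing_wave_rate: float = 0.0
    likert_levels: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.n_waves < 2:
            raise ValueError("n_waves must be >= 2")
        if not 0.0 <= self.missing_wave_rate <= 1.0:
            raise ValueError("missing_wave_rate must be in [0, 1]")
        if self.likert_levels == 1 or self.likert_levels < 0:
            raise ValueError("likert_levels must be 0 (continuous) or >= 2")


def default_triad_communities(node_names) -> dict:
    """Infer member labels from ``c_/m_/f_`` node-name prefixes."""
    prefix = {"c": "child", "m": "mother", "f": "father"}
    out = {}
    for n in node_names:
        p = n.split("_", 1)[0]
        if p not in prefix:
            raise ValueError(f"cannot infer member for node {n!r}")
        out[n] = prefix[p]
    return out


def make_ggm_truth(
    n_nodes: int,
    communities: dict | None = None,
    within_density: float = 0.6,
    between_density: float = 0.15,
    weight_range: tuple = (0.1, 0.35),
    seed: int | None = None,
    positive_fraction: float = 0.85,
) -> GGMTruth:
    """Random sparse PD precision with community-structured support.

    Off-diagonal support is drawn independently: node pairs within the
    same community connect with probability ``within_density``, pairs
    across communities with ``between_density``.  Edge magnitudes (on
    the partial-correlation scale, since the diagonal is 1) are uniform
    in ``weight_range``; signs are positive with probability
    ``positive_fraction`` (symptom networks are predominantly positive).
    Positive definiteness is repaired, if needed, by shrinking all
    off-diagonals (bounded retries).
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    for d, nm in ((within_density, "within_density"), (between_density, "between_density")):
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"{nm} must be in [0, 1]")
    lo, hi = weight_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("weight_range bounds must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if communities is None:
        names = [f"x{i}" for i in range(n_nodes)]
        communities = {n: "all" for n in names}
    else:
        names = list(communities)
        if len(names) != n_nodes:
            raise ValueError("communities must label exactly n_nodes nodes")
    K = np.eye(n_nodes)
    labels = [communities[n] for n in names]
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            dens = within_density if labels[i] == labels[j] else between_density
            if rng.random() < dens:
                w = rng.uniform(lo, hi)
                sign = 1.0 if rng.random() < positive_fraction else -1.0
                K[i, j] = K[j, i] = -sign * w  # pcor = -K_ij for unit diagonal
    for _ in range(60):
        if np.linalg.eigvalsh(K).min() > 1e-6:
            break
        off = K - np.diag(np.diag(K))
        K = np.eye(n_nodes) + 0.9 * off
    else:
        raise RuntimeError("could not repair precision to positive definite")
    return GGMTruth(node_names=names, precision=K, communities=dict(communities))


#: Node labels of the 9-dimension cross-sectional layout.
TRIAD_NODES = (
    "c_int", "c_ext", "c_pro",
    "m_emo", "m_sd", "m_lc",
    "f_emo", "f_sd", "f_lc",
)


def family_triad_truth(
    within: float = 0.3,
    parent_bridge: float = 0.15,
    mother_child_bridge: float = 0.12,
    father_child_bridge: float = 0.0,
) -> GGMTruth:
    """Fixed 9-node triad truth mirroring the qualitative structure of a
    family mental-health network: strong within-member edges, positive
    mother-father bridges, mother-child bridges (emotional symptoms and
    loss of confidence to child internalising/externalising), and — by
    default — no independent father-child association.

    The precision diagonal is 1, so every entry below IS the implied
    partial correlation (up to sign); diagonal dominance keeps it PD.
    """
    names = list(TRIAD_NODES)
    idx = {n: i for i, n in enumerate(names)}
    K = np.eye(9)

    def set_pcor(a, b, r):
        K[idx[a], idx[b]] = K[idx[b], idx[a]] = -r

    for m in ("c", "m", "f"):
        nodes = [n for n in names if n.startswith(m + "_")]
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                set_pcor(a, b, within)
    for dim in ("emo", "sd", "lc"):
        set_pcor(f"m_{dim}", f"f_{dim}", parent_bridge)
    if mother_child_bridge:
        set_pcor("m_emo", "c_int", mother_child_bridge)
        set_pcor("m_emo", "c_ext", mother_child_bridge)
        set_pcor("m_lc", "c_int", mother_child_bridge)
    if father_child_bridge:
        set_pcor("f_emo", "c_int", father_child_bridge)
    return GGMTruth(node_names=names, precision=K,
                    communities=default_triad_communities(names))


def discretize_likert(values, n_levels: int, thresholds=None) -> np.ndarray:
    """Map continuous values to ``{0, ..., n_levels-1}`` by thresholds.

    ``thresholds`` must be strictly increasing with length
    ``n_levels - 1``; the default is the equal-mass standard-normal
    quantiles.  A value maps to the count of thresholds strictly below it.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if thresholds is None:
        thresholds = norm.ppf(np.arange(1, n_levels) / n_levels)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.shape != (n_levels - 1,):
        raise ValueError(f"need {n_levels - 1} thresholds, got {thresholds.shape}")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    values = np.asarray(values, dtype=float)
    return (values[..., None] > thresholds).sum(axis=-1)


def simulate_cross_sectional(
    truth: GGMTruth, n: int, likert_levels: int = 0, seed: int | None = None,
) -> pd.DataFrame:
    """Draw n i.i.d. families from the zero-mean Gaussian implied by the
    truth precision; optionally Likert-discretize each standardized
    column by equal-mass standard-normal thresholds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cov = truth.covariance
    L = np.linalg.cholesky(cov)
    X = rng.standard_normal((n, len(truth.node_names))) @ L.T
    if likert_levels >= 2:
        sd = np.sqrt(np.diag(cov))
        X = discretize_likert(X / sd, likert_levels).astype(float)
    elif likert_levels != 0:
        raise ValueError("likert_levels must be 0 or >= 2")
    return pd.DataFrame(X, columns=truth.node_names)


def make_gvar_truth(
    n_nodes_per_member: dict | None = None,
    cross_member_paths=(),
    autoregression: float = 0.3,
    contemporaneous_cor: float = 0.3,
    between_variance: float = 0.4,
    innovation_variance: float = 1.0,
    mu=None,
    seed: int | None = None,
) -> GVARTruth:
    """Build a stationary GVAR truth over the 13-item triad layout.

    ``cross_member_paths`` is a sequence of ``(source, target, weight)``
    triples placed in B (target row, source column) on top of uniform
    positive autoregressions.  If the resulting spectral radius exceeds
    0.9 the whole matrix is rescaled to 0.9 (logged); weights that leave
    no stationary rescaling are rejected.

    Innovations are equicorrelated within a member at
    ``contemporaneous_cor``; the random-intercept covariance uses the
    same block structure scaled to ``between_variance`` (stable family
    traits carrying roughly a third of total variance by default).
    """
    if n_nodes_per_member is None:
        schema = PANEL_NODE_SCHEMA
    else:
        schema = {
            mem: tuple(f"{mem[0]}_{k}" for k in range(int(cnt)))
            if not isinstance(cnt, (list, tuple)) else tuple(cnt)
            for mem, cnt in n_nodes_per_member.items()
        }
    names = [n for mem in schema for n in schema[mem]]
    communities = {n: mem for mem in schema for n in schema[mem]}
    p = len(names)
    idx = {n: i for i, n in enumerate(names)}
    if not 0.0 <= autoregression < 1.0:
        raise ValueError("autoregression must be in [0, 1)")
    B = autoregression * np.eye(p)
    for src, tgt, w in cross_member_paths:
        if src not in idx or tgt not in idx:
            raise ValueError(f"unknown node in path {src!r} -> {tgt!r}")
        if not np.isfinite(w):
            raise ValueError(f"non-finite path weight for {src!r} -> {tgt!r}")
        B[idx[tgt], idx[src]] = w
    rho = float(np.abs(np.linalg.eigvals(B)).max())
    if not np.isfinite(rho):
        raise ValueError("requested weights cannot be made stationary")
    if rho > 0.9:
        logger.warning("rescaling temporal matrix: spectral radius %.3f -> 0.9", rho)
        B *= 0.9 / rho

    def _block_cov(var: float) -> np.ndarray:
        S = np.zeros((p, p))
        for mem in schema:
            ids = [idx[n] for n in schema[mem]]
            for a in ids:
                for b in ids:
                    S[a, b] = var * (1.0 if a == b else contemporaneous_cor)
        return S

    sigma_zeta = _block_cov(innovation_variance)
    sigma_between = _block_cov(between_variance) if between_variance > 0 else np.zeros((p, p))
    mu = np.zeros(p) if mu is None else np.asarray(mu, dtype=float)
    if mu.shape != (p,):
        raise ValueError(f"mu must have length {p}")
    return GVARTruth(node_names=names, mu=mu, B=B, sigma_zeta=sigma_zeta,
                     sigma_between=sigma_between, communities=communities)


def simulate_panel(
    truth: GVARTruth, spec: FamilyPanelSpec, burn_in: int = 50,
) -> SymptomPanel:
    """Simulate the family panel: per family an intercept
    ``N(mu, sigma_between)`` plus VAR(1) deviations with innovations
    ``N(0, sigma_zeta)``; ``burn_in`` initial waves are discarded so the
    recorded waves are (approximately) stationary.  Whole waves are then
    deleted completely at random at ``missing_wave_rate``; families left
    with fewer than two observed waves are flagged on the returned
    panel, not dropped."""
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    rng = np.random.default_rng(spec.seed)
    p = len(truth.node_names)
    nf, nw = spec.n_families, spec.n_waves
    Lb = np.linalg.cholesky(truth.sigma_between + 1e-12 * np.eye(p))
    Lz = np.linalg.cholesky(truth.sigma_zeta)
    intercepts = truth.mu + rng.standard_normal((nf, p)) @ Lb.T
    dev = rng.standard_normal((nf, p)) @ Lz.T  # wave-0 deviation = pure innovation
    waves = np.empty((nw, nf, p))
    BT = truth.B.T
    for t in range(burn_in + nw):
        if t > 0:
            dev = dev @ BT + rng.standard_normal((nf, p)) @ Lz.T
        if t >= burn_in:
            waves[t - burn_in] = dev
    obs = waves + intercepts[None, :, :]
    if spec.likert_levels >= 2:
        obs = discretize_likert(obs, spec.likert_levels).astype(float)
    observed_mask = rng.random((nf, nw)) >= spec.missing_wave_rate

    fam_ids = np.arange(nf)
    communities = truth.communities or default_triad_communities(truth.node_names)
    # long-format assembly, vectorized over (wave, family)
    recs = []
    for t in range(nw):
        keep = observed_mask[:, t]
        if not keep.any():
            continue
        fams = fam_ids[keep]
        vals = obs[t, keep, :]
        recs.append(pd.DataFrame({
            "family_id": np.repeat(fams, p),
            "wave": t,
            "member": np.tile([communities[n] for n in truth.node_names], len(fams)),
            "node": np.tile(truth.node_names, len(fams)),
            "value": vals.ravel(),
        }))
    if not recs:
        raise RuntimeError("all waves deleted; raise n_families or lower missing rate")
    data = pd.concat(recs, ignore_index=True)
    wave_counts = observed_mask.sum(axis=1)
    low = fam_ids[wave_counts < 2].tolist()
    if low:
        logger.warning("simulate_panel: %d families observed at <2 waves (flagged)",
                       len(low))
    return SymptomPanel(data, low_wave_families=low)
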