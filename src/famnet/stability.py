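"""Bootstrap accuracy and stability of estimated networks.

The central quantity is the correlation-stability (CS) coefficient: the
largest proportion of cases that can be dropped such that, with 95%
probability, the correlation between statistics computed on the reduced
sample and on the full sample stays above 0.70.  Values above 0.25 are
conventionally read as acceptable stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from famnet.bridge import bridge_strength
from famnet.ggm import GGMFit, fit_nodewise_lasso

logger = logging.getLogger("famnet.stability")

__all__ = [
    "BootstrapResult", "CSCoefficient", "edge_ci_bootstrap",
    "case_dropping_bootstrap", "cs_coefficient", "DEFAULT_DROP_GRID",
]

#: Default case-dropping grid: 5% to 75% in 5% steps.
DEFAULT_DROP_GRID = tuple(round(0.05 * k, 2) for k in range(1, 16))


@dataclass
class BootstrapResult:
    """Per-resample statistics from a bootstrap run.

    ``kind`` is ``nonparametric_edges`` (row resampling with
    replacement; ``statistics`` has shape (n_boot, n_stats)) or
    ``case_dropping`` (subsampling without replacement;
    ``correlations_with_original`` maps drop proportion -> array of
    per-resample correlations, NaN where undefined or failed).
    """

    kind: str
    statistic: str
    n_boot: int
    seed: int | None
    stat_names: list = field(default_factory=list)
    statistics: np.ndarray | None = None
    original: np.ndarray | None = None
    drop_proportions: tuple = ()
    correlations_with_original: dict = field(default_factory=dict)

    def quantile_table(self, qs=(0.05, 0.25, 0.5, 0.75, 0.95)) -> pd.DataFrame:
        """Correlation quantiles per drop proportion (case-dropping kind)."""
        rows = []
        for p in self.drop_proportions:
            cors = self.correlations_with_original[p]
            valid = cors[~np.isnan(cors)]
            row = {"drop_proportion": p, "n_valid": len(valid)}
            for q in qs:
                row[f"q{int(round(q * 100)):02d}"] = (
                    float(np.quantile(valid, q)) if len(valid) else np.nan
                )
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class CSCoefficient:
    """The CS coefficient for one statistic."""

    value: float
    statistic: str
    cor_threshold: float = 0.70
    confidence: float = 0.95

    @property
    def acceptable(self) -> bool:
        return self.value > 0.25


def _statistic_vector(fit: GGMFit, statistic: str) -> np.ndarray:
    W = fit.network.weights
    p = W.shape[0]
    iu = np.triu_indices(p, 1)
    if statistic == "edge_weights":
        return W[iu]
    if statistic == "strength":
        return np.abs(W).sum(axis=1)
    if statistic == "bridge_strength":
        return bridge_strength(fit.network).values
    raise ValueError(f"unknown statistic {statistic!r}")


def _refit(data: pd.DataFrame, rows: np.ndarray, estimator_config: dict,
           statistic: str) -> np.ndarray:
    for attempt in range(2):
        try:
            fit = fit_nodewise_lasso(data.iloc[rows], **estimator_config)
            return _statistic_vector(fit, statistic)
        except Exception as exc:  # retried once, then recorded missing
            if attempt == 1:
                logger.warning("bootstrap refit failed twice: %s", exc)
    return np.full(_n_stats(data, statistic), np.nan)


def _n_stats(data: pd.DataFrame, statistic: str) -> int:
    p = data.shape[1]
    return p * (p - 1) // 2 if statistic == "edge_weights" else p


def edge_ci_bootstrap(
    data: pd.DataFrame,
    estimator_config: dict | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    n_jobs: int = 1,
) -> BootstrapResult:
    """Nonparametric bootstrap of edge weights (rows resampled with
    replacement); companion accuracy analysis to the CS coefficient."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    estimator_config = dict(estimator_config or {})
    data = pd.DataFrame(data)
    n = len(data)
    full = fit_nodewise_lasso(data, **estimator_config)
    original = _statistic_vector(full, "edge_weights")
    rng = np.random.default_rng(seed)
    index_sets = [rng.integers(0, n, size=n) for _ in range(n_boot)]
    stats = Parallel(n_jobs=n_jobs)(
        delayed(_refit)(data, rows, estimator_config, "edge_weights")
        for rows in index_sets
    )
    names = [f"{a}--{b}" for k, a in enumerate(data.columns)
             for b in list(data.columns)[k + 1:]]
    return BootstrapResult(
        kind="nonparametric_edges", statistic="edge_weights", n_boot=n_boot,
        seed=seed, stat_names=names, statistics=np.array(stats),
        original=original,
    )


def edge_ci_table(result: BootstrapResult, level: float = 0.95) -> pd.DataFrame:
    """Percentile confidence intervals per edge from an edge bootstrap."""
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    S = result.statistics
    valid = ~np.isnan(S).all(axis=1)
    return pd.DataFrame({
        "edge": result.stat_names,
        "estimate": result.original,
        "ci_lower": np.nanquantile(S[valid], lo, axis=0),
        "ci_upper": np.nanquantile(S[valid], hi, axis=0),
    })


def case_dropping_bootstrap(
    data: pd.DataFrame,
    estimator_config: dict | None = None,
    statistic: str = "edge_weights",
    drop_proportions=DEFAULT_DROP_GRID,
    n_boot: int = 1000,
    seed: int | None = None,
    n_jobs: int = 1,
) -> BootstrapResult:
    """Person-dropping bootstrap: for each drop proportion p, draw
    ``n_boot`` subsamples of size round((1-p) n) without replacement,
    refit, and correlate the subsample statistic vector with the
    full-sample one.  Undefined correlations (constant vectors, failed
    refits) are recorded as NaN and excluded from quantiles downstream.
    """
    estimator_config = dict(estimator_config or {})
    data = pd.DataFrame(data)
    n, p_nodes = data.shape
    full = fit_nodewise_lasso(data, **estimator_config)
    original = _statistic_vector(full, statistic)
    rng = np.random.default_rng(seed)
    drop_proportions = tuple(drop_proportions)

    cors: dict = {}
    for prop in drop_proportions:
        m = int(round((1 - prop) * n))
        if m <= p_nodes:
            logger.warning("drop proportion %.2f leaves %d <= %d rows; skipped",
                           prop, m, p_nodes)
            cors[prop] = np.full(n_boot, np.nan)
            continue
        index_sets = [rng.permutation(n)[:m] for _ in range(n_boot)]
        stats = Parallel(n_jobs=n_jobs)(
            delayed(_refit)(data, rows, estimator_config, statistic)
            for rows in index_sets
        )
        out = np.full(n_boot, np.nan)
        for b, vec in enumerate(stats):
            if np.isnan(vec).any():
                continue
            if np.std(vec) == 0 or np.std(original) == 0:
                continue  # correlation undefined for constant vectors
            out[b] = np.corrcoef(vec, original)[0, 1]
        cors[prop] = out
    return BootstrapResult(
        kind="case_dropping", statistic=statistic, n_boot=n_boot, seed=seed,
        original=original, drop_proportions=drop_proportions,
        correlations_with_original=cors,
    )


def cs_coefficient(
    result: BootstrapResult,
    cor_threshold: float = 0.70,
    confidence: float = 0.95,
) -> CSCoefficient:
    """Largest drop proportion p such that the empirical
    (1 - confidence) quantile of correlations exceeds ``cor_threshold``
    at p *and at every smaller p* (prefix rule for non-monotone
    curves); 0 if none qualifies."""
    if result.kind != "case_dropping":
        raise ValueError("cs_coefficient requires a case_dropping result")
    grid = sorted(result.drop_proportions)
    if not grid:
        raise ValueError("empty drop-proportion grid")
    q = 1.0 - confidence
    value = 0.0
    for p in grid:
        cors = result.correlations_with_original[p]
        valid = cors[~np.isnan(cors)]
        if len(valid) == 0 or np.quantile(valid, q) <= cor_threshold:
            break
        value = p
    return CSCoefficient(value=value, statistic=result.statistic,
                         cor_threshold=cor_threshold, confidence=confidence)
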