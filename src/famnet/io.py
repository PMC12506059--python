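"""Panel ingestion, subscale construction and sampling-unit selection.

The canonical interchange format is a long-format table with one row per
(family, wave, member, node) observation::

    family_id,wave,member,node,value

``member`` is one of ``child``, ``mother``, ``father`` — the triad that
defines the community partition of every network downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("famnet.io")

VALID_MEMBERS = ("child", "mother", "father")

PANEL_COLUMNS = ["family_id", "wave", "member", "node", "value"]


@dataclass
class SymptomPanel:
    """Long-format symptom observations with role/wave metadata.

    Attributes
    ----------
    data:
        DataFrame with columns ``family_id, wave, member, node, value``.
    low_wave_families:
        Families flagged as having fewer than two observed waves (these
        are flagged, never silently dropped; see
        :func:`filter_longitudinal`).
    """

    data: pd.DataFrame
    low_wave_families: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"panel is missing columns {missing}")
        bad = set(self.data["member"].unique()) - set(VALID_MEMBERS)
        if bad:
            rows = self.data.index[self.data["member"].isin(bad)][:5].tolist()
            raise ValueError(
                f"unknown member label(s) {sorted(bad)} at rows {rows}; "
                f"expected one of {VALID_MEMBERS}"
            )
        dup = self.data.duplicated(subset=["family_id", "wave", "member", "node"])
        if dup.any():
            raise ValueError(
                f"duplicate (family, wave, member, node) rows at index "
                f"{self.data.index[dup][:5].tolist()}"
            )

    @property
    def families(self) -> np.ndarray:
        return np.sort(self.data["family_id"].unique())

    @property
    def waves(self) -> np.ndarray:
        return np.sort(self.data["wave"].unique())

    @property
    def nodes(self) -> list:
        return sorted(self.data["node"].unique())

    def node_communities(self) -> dict:
        """Map node name -> family member, derived from the long rows."""
        pairs = self.data[["node", "member"]].drop_duplicates()
        if pairs["node"].duplicated().any():
            dupnode = pairs.loc[pairs["node"].duplicated(), "node"].iloc[0]
            raise ValueError(f"node {dupnode!r} appears under multiple members")
        return dict(zip(pairs["node"], pairs["member"]))

    def waves_per_family(self) -> pd.Series:
        return self.data.groupby("family_id")["wave"].nunique()

    def to_wide(
        self,
        nodes: Sequence | None = None,
        waves: Sequence | None = None,
    ) -> pd.DataFrame:
        """Pivot to one row per family, columns ``(wave, node)`` wave-major.

        Cells not observed become NaN; this is the shape consumed by the
        FIML panel estimator.
        """
        nodes = list(nodes) if nodes is not None else self.nodes
        waves = list(waves) if waves is not None else list(self.waves)
        sub = self.data[self.data["node"].isin(nodes) & self.data["wave"].isin(waves)]
        wide = sub.pivot_table(
            index="family_id", columns=["wave", "node"], values="value",
            aggfunc="first",
        )
        cols = pd.MultiIndex.from_product([waves, nodes], names=["wave", "node"])
        return wide.reindex(columns=cols)

    def to_cross_section(self, wave) -> pd.DataFrame:
        """One row per family for a single wave, columns = nodes."""
        sub = self.data[self.data["wave"] == wave]
        return sub.pivot_table(index="family_id", columns="node", values="value",
                               aggfunc="first")


def read_panel(path) -> SymptomPanel:
    """Read a long-format panel CSV, validating header and member labels."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty panel file")
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return SymptomPanel(df[PANEL_COLUMNS + [c for c in df.columns if c not in PANEL_COLUMNS]])


def write_panel(panel: SymptomPanel, path) -> None:
    panel.data.to_csv(path, index=False)


@dataclass(frozen=True)
class SubscaleMap:
    """Named map subscale -> item names with expected item counts.

    Items must be disjoint across subscales within one instrument.
    """

    subscales: Mapping[str, tuple]

    def __post_init__(self) -> None:
        seen: dict = {}
        for name, items in self.subscales.items():
            for it in items:
                if it in seen:
                    raise ValueError(
                        f"item {it!r} appears in both {seen[it]!r} and {name!r}"
                    )
                seen[it] = name

    def items_for(self, subscale: str) -> tuple:
        return tuple(self.subscales[subscale])


def _items(prefix: str, idx: Sequence[int]) -> tuple:
    return tuple(f"{prefix}_{i:02d}" for i in idx)


#: SDQ (25 items, 3-point scale) collapsed to three broad child dimensions:
#: internalising = emotional + peer problems (10 items), externalising =
#: conduct + hyperactivity (10 items), prosocial reversed (5 items).
SDQ_SUBSCALES = SubscaleMap({
    "internalising": _items("sdq_emo", range(1, 6)) + _items("sdq_peer", range(1, 6)),
    "externalising": _items("sdq_con", range(1, 6)) + _items("sdq_hyp", range(1, 6)),
    "prosocial": _items("sdq_pro", range(1, 6)),
})

#: GHQ-12 three-factor split (Shevlin–Adamson): emotional symptoms
#: (items 2, 5, 6, 9), social dysfunction (1, 3, 4, 7, 8, 12) and loss of
#: confidence (10, 11).
GHQ_SUBSCALES = SubscaleMap({
    "emotional": _items("ghq", (2, 5, 6, 9)),
    "social_dysfunction": _items("ghq", (1, 3, 4, 7, 8, 12)),
    "loss_confidence": _items("ghq", (10, 11)),
})

#: Item nodes for the longitudinal (emotional-symptom) arm: the five SDQ
#: emotional items for the child and the four GHQ-12 emotional items for
#: each parent.
PANEL_NODE_SCHEMA = {
    "child": ("c_unhappy", "c_worry", "c_nervous", "c_fears", "c_somatic"),
    "mother": ("m_unhappy", "m_worry", "m_strain", "m_overwhelmed"),
    "father": ("f_unhappy", "f_worry", "f_strain", "f_overwhelmed"),
}


def aggregate_subscales(panel: SymptomPanel, subscale_map: SubscaleMap) -> SymptomPanel:
    """Sum item scores into subscale scores per (family, wave, member).

    Higher scores mean poorer mental health.  A cell missing any mapped
    item is complete-case missing: the subscale row is omitted (and
    counted in the log), never partially summed.
    """
    df = panel.data
    out_rows = []
    n_incomplete = 0
    for sub_name, items in subscale_map.subscales.items():
        sub = df[df["node"].isin(items)]
        if sub.empty:
            continue
        counts = sub.groupby(["family_id", "wave", "member"])["value"].agg(["size", "sum"])
        complete = counts["size"] == len(items)
        n_incomplete += int((~complete).sum())
        over = counts["size"] > len(items)
        if over.any():
            raise ValueError(
                f"subscale {sub_name!r}: more item rows than mapped items for "
                f"{counts.index[over][:3].tolist()}"
            )
        good = counts.loc[complete, "sum"].reset_index()
        good["node"] = sub_name
        good = good.rename(columns={"sum": "value"})
        out_rows.append(good[PANEL_COLUMNS])
    if n_incomplete:
        logger.warning("aggregate_subscales: %d incomplete cells set missing",
                       n_incomplete)
    # items not covered by the map pass through unchanged (identity behaviour)
    mapped_items = {it for items in subscale_map.subscales.values() for it in items}
    passthrough = df[~df["node"].isin(mapped_items)]
    if not passthrough.empty:
        out_rows.append(passthrough[PANEL_COLUMNS])
    out = pd.concat(out_rows, ignore_index=True) if out_rows else df.iloc[0:0]
    out = out.sort_values(["family_id", "wave", "member", "node"], kind="stable")
    return SymptomPanel(out.reset_index(drop=True))


def select_independent_observations(
    panel: SymptomPanel, unit: str = "family", seed: int | None = None,
) -> pd.DataFrame:
    """Select one wave per unit uniformly at random -> cross-sectional table.

    ``unit='family'`` keeps one wave per family.  ``unit='child'`` is the
    sensitivity variant that would keep one child per family; with the
    single-child triad panel used here both coincide at the family level.
    Returns a wide table (one row per family, columns = nodes).
    """
    if unit not in ("family", "child"):
        raise ValueError(f"unknown unit {unit!r}")
    rng = np.random.default_rng(seed)
    df = panel.data
    chosen = []
    for fam, waves in df.groupby("family_id")["wave"].unique().items():
        waves = np.sort(waves)
        w = waves[0] if len(waves) == 1 else waves[rng.integers(len(waves))]
        chosen.append((fam, w))
    keep = pd.DataFrame(chosen, columns=["family_id", "wave"])
    sub = df.merge(keep, on=["family_id", "wave"])
    wide = sub.pivot_table(index="family_id", columns="node", values="value",
                           aggfunc="first")
    wide.columns.name = None
    return wide


def filter_longitudinal(panel: SymptomPanel, min_waves: int = 2) -> SymptomPanel:
    """Drop families observed at fewer than ``min_waves`` waves."""
    counts = panel.waves_per_family()
    keep = counts.index[counts >= min_waves]
    dropped = counts.index.difference(keep)
    logger.info(
        "filter_longitudinal: %d of %d families retained (min_waves=%d, dropped %d)",
        len(keep), len(counts), min_waves, len(dropped),
    )
    out = panel.data[panel.data["family_id"].isin(keep)].reset_index(drop=True)
    return SymptomPanel(out)
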