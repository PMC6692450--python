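"""Turn raw experience-sampling (ESM) item panels into binary matrices.

The estimator consumes a T x n binary matrix (occasions x items) per
participant. Raw panels arrive on one of three scales and are reduced to
binary as follows:

* **binary** items pass through unchanged;
* **tri-state** items (0 = positive pole, 1 = neither, 2 = negative pole)
  are collapsed: by default "neither" joins the positive state, so
  {0, 1} -> 0 and {2} -> 1 (1 marks the negative/active state);
* **continuous 0-100** items are median-split per item per participant after
  recoding reversed (positively worded) items x -> 100 - x: strictly above
  the item median -> 1, at or below -> 0.

Missing cells are imputed by last observation carried forward (LOCF) per
item; leading occasions that are missing are dropped (they have no
predecessor). Participants are excluded when fewer than 5 occasions were
completed or when the rarer binary category holds less than 5% of all
responses (pooled over the participant's item x occasion cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ItemPanel",
    "PreprocessReport",
    "load_item_metadata",
    "collapse_tristate",
    "reverse_and_median_split",
    "kmeans_split",
    "impute_locf",
    "apply_exclusions",
    "to_counts",
    "preprocess_panel",
]

MIN_T = 5
MIN_CATEGORY_SHARE = 0.05
SCALES = ("binary", "tristate", "continuous")


@dataclass
class ItemPanel:
    """One participant's occasions-by-items response table.

    ``data`` is a DataFrame indexed by occasion (strictly increasing order),
    one column per item, NaN marking missing responses. ``scale`` declares
    the response scale shared by the items; ``reversed_items`` lists columns
    whose scores run opposite to the rest (relevant for continuous items).
    """

    participant: str
    data: pd.DataFrame
    scale: str = "binary"
    reversed_items: tuple = ()

    def __post_init__(self):
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        idx = np.asarray(self.data.index)
        if len(idx) > 1 and not np.all(idx[1:] > idx[:-1]):
            raise ValueError("occasions must be strictly ordered")
        unknown = set(self.reversed_items) - set(self.data.columns)
        if unknown:
            raise ValueError(f"reversed items not in panel: {sorted(unknown)}")

    @property
    def T(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]


@dataclass
class PreprocessReport:
    participant: str
    included: bool = field(init=False)
    exclusion_reason: str = "none"  # {none, too_few_measurements, insufficient_variance}
    imputed_cells: int = 0
    dropped_leading: int = 0
    T: int = 0
    n_items: int = 0

    def __post_init__(self):
        self.included = self.exclusion_reason == "none"

    def to_dict(self) -> dict:
        return {"participant": self.participant, "included": self.included,
                "exclusion_reason": self.exclusion_reason,
                "imputed_cells": self.imputed_cells,
                "dropped_leading": self.dropped_leading,
                "T": self.T, "n_items": self.n_items}


def load_item_metadata(name_or_path) -> dict:
    """Load packaged (``"ams"``/``"hnd"``) or user-supplied YAML item metadata."""
    if name_or_path in ("ams", "hnd"):
        ref = resources.files("meanfield_sca").joinpath(f"data/{name_or_path}_items.yaml")
        text = ref.read_text()
    else:
        with open(name_or_path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def collapse_tristate(panel: ItemPanel, collapse_with: str = "positive") -> ItemPanel:
    """Collapse tri-state responses to binary.

    Default maps the "neither" middle category onto the positive state:
    {0, 1} -> 0 and {2} -> 1. ``collapse_with="negative"`` instead maps
    {1, 2} -> 1. Missing cells stay missing.
    """
    if panel.scale != "tristate":
        raise ValueError("collapse_tristate requires a tri-state panel")
    vals = panel.data.to_numpy(dtype=float)
    observed = ~np.isnan(vals)
    if not np.isin(vals[observed], (0.0, 1.0, 2.0)).all():
        raise ValueError("tri-state responses must lie in {0, 1, 2}")
    if collapse_with == "positive":
        out = np.where(vals == 2.0, 1.0, 0.0)
    elif collapse_with == "negative":
        out = np.where(vals >= 1.0, 1.0, 0.0)
    else:
        raise ValueError("collapse_with must be 'positive' or 'negative'")
    out[~observed] = np.nan
    return ItemPanel(participant=panel.participant,
                     data=pd.DataFrame(out, index=panel.data.index,
                                       columns=panel.data.columns),
                     scale="binary")


def reverse_and_median_split(panel: ItemPanel) -> ItemPanel:
    """Median-split continuous 0-100 items after recoding reversed items.

    Reversed items are mapped x -> 100 - x first; then per item the
    participant-specific median is computed over observed values, and values
    strictly above the median become 1, all others (ties included) 0.
    A constant item therefore becomes all zeros.
    """
    if panel.scale != "continuous":
        raise ValueError("reverse_and_median_split requires a continuous panel")
    df = panel.data.astype(float).copy()
    vals = df.to_numpy()
    observed = ~np.isnan(vals)
    if np.any((vals[observed] < 0) | (vals[observed] > 100)):
        raise ValueError("continuous responses must lie in [0, 100]")
    for col in panel.reversed_items:
        df[col] = 100.0 - df[col]
    med = df.median(axis=0, skipna=True)
    out = (df > med).astype(float)
    out[df.isna()] = np.nan
    return ItemPanel(participant=panel.participant, data=out, scale="binary")


def kmeans_split(panel: ItemPanel, seed: int = 0) -> ItemPanel:
    """Alternative dichotomizer: 2-means per item, high cluster -> 1.

    Exposed behind the same interface as the median split; not the default.
    Reversed items are recoded x -> 100 - x first. Implemented as an exact
    1-D 2-means (threshold minimizing within-cluster sum of squares).
    """
    if panel.scale != "continuous":
        raise ValueError("kmeans_split requires a continuous panel")
    df = panel.data.astype(float).copy()
    for col in panel.reversed_items:
        df[col] = 100.0 - df[col]
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        x = df[col].to_numpy()
        obs = x[~np.isnan(x)]
        if len(obs) == 0 or np.ptp(obs) == 0:
            out[col] = np.where(np.isnan(x), np.nan, 0.0)
            continue
        srt = np.sort(obs)
        # exact 1-D 2-means: best split point between consecutive order stats
        best, thr = np.inf, srt[0]
        csum = np.cumsum(srt)
        csq = np.cumsum(srt ** 2)
        m = len(srt)
        for i in range(1, m):
            ss1 = csq[i - 1] - csum[i - 1] ** 2 / i
            ss2 = (csq[-1] - csq[i - 1]) - (csum[-1] - csum[i - 1]) ** 2 / (m - i)
            if ss1 + ss2 < best:
                best, thr = ss1 + ss2, 0.5 * (srt[i - 1] + srt[i])
        out[col] = np.where(np.isnan(x), np.nan, (x > thr).astype(float))
    return ItemPanel(participant=panel.participant, data=out, scale="binary")


def impute_locf(panel: ItemPanel, mode: str = "locf") -> tuple[ItemPanel, int, int]:
    """Impute missing cells; returns (panel, imputed_cells, dropped_leading).

    ``mode="locf"``: each missing cell takes the item's most recent observed
    value. Leading occasions where any item is still unobserved are dropped
    (no predecessor to carry forward). ``mode="drop"`` instead removes every
    occasion containing a missing response.
    """
    if panel.scale != "binary":
        raise ValueError("impute on the binary panel (dichotomize first)")
    df = panel.data.astype(float)
    if df.isna().all(axis=0).any():
        bad = [c for c in df.columns if df[c].isna().all()]
        raise ValueError(f"items entirely missing: {bad}")
    if mode == "drop":
        kept = df.dropna(axis=0)
        return (ItemPanel(panel.participant, kept, scale="binary"),
                0, panel.T - kept.shape[0])
    if mode != "locf":
        raise ValueError("mode must be 'locf' or 'drop'")
    first_obs = df.notna().to_numpy().argmax(axis=0)  # first observed row per item
    start = int(first_obs.max())
    trimmed = df.iloc[start:]
    missing_after = int(trimmed.isna().to_numpy().sum())
    filled = trimmed.ffill(axis=0)
    return (ItemPanel(panel.participant, filled, scale="binary"),
            missing_after, start)


def apply_exclusions(panel: ItemPanel, min_T: int = MIN_T,
                     min_category_share: float = MIN_CATEGORY_SHARE) -> PreprocessReport:
    """Exclusion rules for a complete binary panel.

    Excluded if fewer than ``min_T`` occasions, or if the rarer of the two
    binary categories holds less than ``min_category_share`` of all responses
    pooled over the participant's item x occasion cells.
    """
    if panel.scale != "binary":
        raise ValueError("exclusion rules apply to the binary panel")
    report = lambda reason: PreprocessReport(
        participant=panel.participant, exclusion_reason=reason,
        T=panel.T, n_items=panel.n_items)
    if panel.T < min_T:
        return report("too_few_measurements")
    vals = panel.data.to_numpy(dtype=float)
    vals = vals[~np.isnan(vals)]
    share_one = vals.mean() if len(vals) else 0.0
    if min(share_one, 1.0 - share_one) < min_category_share:
        return report("insufficient_variance")
    return report("none")


def to_counts(panel: ItemPanel) -> tuple[np.ndarray, np.ndarray]:
    """(count series, density series) over the panel's items, per occasion."""
    if panel.scale != "binary":
        raise ValueError("counts require a binary panel")
    vals = panel.data.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("panel still has missing cells; impute first")
    y = vals.sum(axis=1).astype(np.int64)
    return y, y / panel.n_items


def preprocess_panel(panel: ItemPanel, collapse_with: str = "positive",
                     dichotomizer: str = "median", missing: str = "locf",
                     min_T: int = MIN_T,
                     min_category_share: float = MIN_CATEGORY_SHARE):
    """Full per-participant preprocessing: dichotomize, impute, screen.

    Returns ``(binary_panel, report, counts, density)``; the last two are
    None when the participant is excluded.
    """
    if panel.scale == "tristate":
        binary = collapse_tristate(panel, collapse_with=collapse_with)
    elif panel.scale == "continuous":
        binary = (reverse_and_median_split(panel) if dichotomizer == "median"
                  else kmeans_split(panel))
    else:
        binary = panel
    binary, imputed, dropped = impute_locf(binary, mode=missing)
    rep = apply_exclusions(binary, min_T=min_T,
                           min_category_share=min_category_share)
    rep.imputed_cells, rep.dropped_leading = imputed, dropped
    if not rep.included:
        return binary, rep, None, None
    y, rho = to_counts(binary)
    return binary, rep, y, rho
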