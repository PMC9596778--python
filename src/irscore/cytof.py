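"""Mass-cytometry preprocessing arithmetic and cluster-frequency comparison.

Raw ion-count intensities are arcsinh-transformed with a small cofactor
(x -> asinh(x / cofactor), cofactor 5 by default), then each marker is
rescaled to [0, 1] with its 99th percentile as the maximum (extreme values
are clipped) and its observed minimum as the floor.  Event tables arrive as
CSV (event rows, marker columns, plus a sample_id column); clustering is
consumed as an input label column, never computed here.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .survival import two_group_test

logger = logging.getLogger(__name__)

_STATES = ("raw", "arcsinh", "rescaled")


@dataclass
class CytometryFrame:
    """Events x markers intensity matrix with per-event sample labels.

    ``transform_state`` moves only forward: raw -> arcsinh -> rescaled.
    """

    data: pd.DataFrame                       # events x markers
    sample_id: pd.Series                     # per event
    transform_state: str = "raw"
    flagged_markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.transform_state not in _STATES:
            raise ValueError(f"unknown transform state {self.transform_state!r}")
        if len(self.sample_id) != len(self.data):
            raise ValueError("sample_id length must match event count")
        self.sample_id = pd.Series(np.asarray(self.sample_id), index=self.data.index)

    @property
    def markers(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_events(self) -> int:
        return len(self.data)


def read_cytometry_csv(path: str | Path, sample_col: str = "sample_id") -> CytometryFrame:
    """CSV event table: marker columns + a sample_id column."""
    df = pd.read_csv(path)
    if sample_col not in df.columns:
        raise ValueError(f"{path}: missing {sample_col!r} column")
    sample = df[sample_col].astype(str)
    data = df.drop(columns=[sample_col]).astype(float)
    return CytometryFrame(data=data, sample_id=sample, transform_state="raw")


def _require_state(frame: CytometryFrame, state: str) -> None:
    if frame.transform_state != state:
        raise ValueError(
            f"expected a {state!r} frame, got {frame.transform_state!r} "
            "(transforms apply in order raw -> arcsinh -> rescaled)"
        )


def arcsinh_transform(frame: CytometryFrame, cofactor: float = 5.0) -> CytometryFrame:
    """Elementwise x -> asinh(x / cofactor)."""
    _require_state(frame, "raw")
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return CytometryFrame(data=np.arcsinh(frame.data / cofactor),
                          sample_id=frame.sample_id, transform_state="arcsinh")


def percentile_rescale(frame: CytometryFrame, p: float = 0.99) -> CytometryFrame:
    """Per-marker rescale to [0, 1] with the p-th percentile as the cap.

    cap = p-th percentile (linear interpolation between order statistics),
    floor = observed minimum; values are clipped to [floor, cap] then mapped
    linearly.  Markers with cap == floor become all-zero and are flagged.
    """
    _require_state(frame, "arcsinh")
    if not 0 < p <= 1:
        raise ValueError("percentile must be in (0, 1]")
    if len(frame.data) < 2:
        raise ValueError("need >= 2 events per marker to rescale")
    X = frame.data.to_numpy(dtype=float)
    cap = np.quantile(X, p, axis=0)          # linear-interpolation convention
    floor = X.min(axis=0)
    span = cap - floor
    flat = span <= 0
    span_safe = np.where(flat, 1.0, span)
    scaled = (np.clip(X, floor, cap) - floor) / span_safe
    scaled[:, flat] = 0.0
    flagged = list(frame.data.columns[flat])
    if flagged:
        logger.warning("constant markers rescaled to zero: %s", flagged)
    return CytometryFrame(data=pd.DataFrame(scaled, index=frame.data.index,
                                            columns=frame.data.columns),
                          sample_id=frame.sample_id, transform_state="rescaled",
                          flagged_markers=flagged)


def subsample_per_sample(frame: CytometryFrame, n_per_sample: int = 1000,
                         seed: int | np.random.Generator = 0) -> CytometryFrame:
    """Uniform without-replacement draw of n events per sample.

    Samples with fewer than n events contribute all their events (warning).
    Reproducible under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for sample in pd.unique(frame.sample_id):
        idx = np.flatnonzero((frame.sample_id == sample).to_numpy())
        if len(idx) < n_per_sample:
            logger.warning("sample %s has %d < %d events; taking all",
                           sample, len(idx), n_per_sample)
            keep.append(idx)
        else:
            keep.append(np.sort(rng.choice(idx, size=n_per_sample, replace=False)))
    sel = np.concatenate(keep) if keep else np.empty(0, dtype=int)
    return CytometryFrame(data=frame.data.iloc[sel].reset_index(drop=True),
                          sample_id=frame.sample_id.iloc[sel].reset_index(drop=True),
                          transform_state=frame.transform_state,
                          flagged_markers=list(frame.flagged_markers))


def cluster_frequencies(cluster_labels: pd.Series, sample_id: pd.Series) -> pd.DataFrame:
    """Samples x clusters frequency table within the declared parent
    population (rows sum to 1)."""
    if len(cluster_labels) != len(sample_id):
        raise ValueError("cluster and sample labels must align per event")
    tab = pd.crosstab(np.asarray(sample_id), np.asarray(cluster_labels))
    freq = tab.div(tab.sum(axis=1), axis=0)
    freq.index.name = "sample_id"
    freq.columns = freq.columns.astype(str)
    return freq


def cluster_frequency_compare(
    cluster_labels: pd.Series,
    sample_id: pd.Series,
    sample_groups: pd.Series,
    populations: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per-cluster frequency comparison between high and low groups.

    ``sample_groups`` maps sample ID -> "high"/"low" (>= 2 samples each).
    Composite populations (label unions, e.g. several T-cell clusters) may be
    declared via ``populations``; their per-sample frequency is the sum of
    the member-cluster frequencies.  Returns per-cluster group medians and
    the two-sided rank-sum p.
    """
    freq = cluster_frequencies(cluster_labels, sample_id)
    groups = sample_groups.loc[freq.index]
    for g in ("high", "low"):
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    if populations:
        for name, members in populations.items():
            missing = [m for m in members if m not in freq.columns]
            if missing:
                raise KeyError(f"population {name!r}: unknown clusters {missing}")
            freq[name] = freq[list(members)].sum(axis=1)
    rows = []
    for cluster in freq.columns:
        hi = freq.loc[groups == "high", cluster]
        lo = freq.loc[groups == "low", cluster]
        if hi.nunique() == 1 and lo.nunique() == 1 and hi.iloc[0] == lo.iloc[0]:
            p = 1.0  # identical constant frequencies carry no information
        else:
            p = two_group_test(hi, lo)
        rows.append({"cluster": cluster, "median_high": float(hi.median()),
                     "median_low": float(lo.median()), "p": p})
    return pd.DataFrame(rows).set_index("cluster")
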