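"""Marker-combination gating evaluation for the CIR-rich population.

Flow-cytometry sorting cannot gate on a t-SNE region, so the practical
question is which small marker combination best recovers the
co-inhibitory-receptor-rich (CIR-rich) cells.  Given per-cell log
intensities for the six markers (PD-1, LAG-3, TIGIT, TIM-3, CD49b, CCR5)
and the IL-10 reporter, this module thresholds each channel into
positivity calls, defines the CIR-rich reference population (positive on
all six markers by default), and scores every candidate marker subset —
AND-combined, optionally together with reporter positivity — by
sensitivity and specificity against that reference.

Because gates are conjunctions, adding a marker to a subset can only
shrink the predicted-positive set: sensitivity is non-increasing and
specificity non-decreasing along nested subsets.  That monotone trade-off
is the computational content behind choosing a three-channel gate
(reporter, CD49b, LAG-3) with high sensitivity at >90% specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .synthdata import MARKER_NAMES, REPORTER_NAME


@dataclass
class GateDefinition:
    """Per-channel positivity thresholds on the log-intensity scale."""

    thresholds: pd.Series
    method: str = "manual"
    params: dict = field(default_factory=dict)


def quantile_gates(
    t: pd.DataFrame, q: float = 0.8, channels: list | None = None
) -> GateDefinition:
    """Thresholds at the q-th intensity quantile of each channel."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    channels = list(channels) if channels is not None else _channels(t)
    thr = t[channels].quantile(q)
    return GateDefinition(thresholds=thr, method="quantile", params={"q": q})


def otsu_gates(t: pd.DataFrame, channels: list | None = None, bins: int = 128) -> GateDefinition:
    """Per-channel Otsu thresholds (maximal between-class variance)."""
    channels = list(channels) if channels is not None else _channels(t)
    thr = {}
    for ch in channels:
        x = t[ch].to_numpy(dtype=float)
        hist, edges = np.histogram(x, bins=bins)
        mids = 0.5 * (edges[:-1] + edges[1:])
        w = hist.astype(float)
        total = w.sum()
        cum_w = np.cumsum(w)
        cum_m = np.cumsum(w * mids)
        valid = (cum_w > 0) & (cum_w < total)
        m0 = np.where(valid, cum_m / np.maximum(cum_w, 1e-300), 0.0)
        m1 = np.where(valid, (cum_m[-1] - cum_m) / np.maximum(total - cum_w, 1e-300), 0.0)
        between = cum_w * (total - cum_w) * (m0 - m1) ** 2
        between[~valid] = -np.inf
        thr[ch] = float(mids[int(np.argmax(between))])
    return GateDefinition(thresholds=pd.Series(thr), method="otsu", params={"bins": bins})


def _channels(t: pd.DataFrame) -> list:
    return [c for c in t.columns if c != "true_rich"]


def call_positivity(t: pd.DataFrame, g: GateDefinition) -> pd.DataFrame:
    """Boolean cells x channels matrix: positive iff intensity > threshold."""
    missing = [ch for ch in g.thresholds.index if ch not in t.columns]
    if missing:
        raise KeyError(f"channels missing from the table: {missing}")
    channels = list(g.thresholds.index)
    return t[channels].gt(g.thresholds[channels], axis=1)


def define_cir_reference(calls: pd.DataFrame, min_markers: int = 6) -> pd.Series:
    """Reference CIR-rich call: positive on at least ``min_markers`` of the 6.

    The reporter channel is excluded from the reference; the reference is
    the deterministic gate-logic equivalent of the CIR-rich embedding region.
    """
    markers = [mk for mk in MARKER_NAMES if mk in calls.columns]
    if len(markers) != 6:
        raise KeyError(f"expected the 6 panel markers, found {markers}")
    if min_markers > 6:
        raise ValueError("min_markers cannot exceed the 6 panel markers")
    return (calls[markers].sum(axis=1) >= min_markers).rename("cir_rich")


@dataclass
class SubsetEvaluation:
    """Sensitivity/specificity per marker subset, ranked."""

    table: pd.DataFrame  # columns: subset, size, with_reporter, sensitivity, specificity, rank
    reference: str = "all-6 AND rule"


def evaluate_subsets(
    calls: pd.DataFrame,
    reference: pd.Series,
    subsets: list | None = None,
    include_reporter: bool = True,
    reporter: str = REPORTER_NAME,
) -> SubsetEvaluation:
    """Score marker subsets (AND gates) against the reference population.

    By default every non-empty subset of the six markers is evaluated, each
    combined with reporter positivity.  Sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP); subsets ranked by sensitivity, ties broken by
    specificity.
    """
    ref = reference.to_numpy(dtype=bool)
    if ref.all() or not ref.any():
        side = "all-true" if ref.all() else "all-false"
        raise ValueError(f"reference is {side}; sensitivity/specificity undefined")
    if subsets is None:
        markers = [mk for mk in MARKER_NAMES if mk in calls.columns]
        subsets = [
            list(c) for r in range(1, len(markers) + 1) for c in combinations(markers, r)
        ]
    rows = []
    for S in subsets:
        cols = list(S) + ([reporter] if include_reporter else [])
        missing = [c for c in cols if c not in calls.columns]
        if missing:
            raise KeyError(f"channels missing from calls: {missing}")
        pred = calls[cols].all(axis=1).to_numpy()
        tp = int((pred & ref).sum())
        fn = int((~pred & ref).sum())
        tn = int((~pred & ~ref).sum())
        fp = int((pred & ~ref).sum())
        rows.append(
            {
                "subset": tuple(S),
                "size": len(S),
                "with_reporter": include_reporter,
                "sensitivity": tp / (tp + fn),
                "specificity": tn / (tn + fp),
            }
        )
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["sensitivity", "specificity"], ascending=False, kind="stable"
    ).index
    table["rank"] = pd.Series(np.arange(1, len(table) + 1), index=order)
    return SubsetEvaluation(table=table.sort_values("rank").reset_index(drop=True))


def embed_marker_space(t: pd.DataFrame, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """2-D t-SNE of cells in six-marker log-intensity space (viSNE-style)."""
    from .cluster import embed_tsne
    from .normalize import LogExpressionMatrix

    markers = [mk for mk in MARKER_NAMES if mk in t.columns]
    if len(markers) != 6:
        raise KeyError(f"expected the 6 panel markers, found {markers}")
    if len(t) < 100:
        raise ValueError("need at least 100 cells for a marker-space embedding")
    logm = LogExpressionMatrix(
        values=t[markers].to_numpy(dtype=float).T,
        gene_ids=np.array(markers, dtype=object),
        cell_ids=t.index.to_numpy(),
        is_spike=np.zeros(6, dtype=bool),
        is_mito=np.zeros(6, dtype=bool),
    )
    return embed_tsne(logm, perplexity=min(perplexity, (len(t) - 1) / 3), seed=seed)
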