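"""Microstate parameter families, band power, and windowed feature tables.

Per analysis window and microstate class k the temporal/spatial parameters
are: occurrence (segments per second), mean duration (ms), coverage (time
fraction), per-class GEV, transition probabilities between classes, mean
GFP over the class's samples (microvolts) and the mean absolute spatial
correlation with the class template.  A K-class configuration yields
``4K + K^2`` temporal features plus ``2K`` spatial features per window;
band power adds ``bands x channels`` columns (5C for the five canonical
EEG rhythms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .backfit import LabelSequence, SegmentList, SmoothingParams, backfit, segmentize, smooth
from .cluster import TemplateSet
from .errors import ValidationError
from .io_model import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterSet",
    "DEFAULT_BANDS",
    "class_parameters",
    "transition_matrix",
    "windowed_feature_table",
    "band_power",
    "feature_column_names",
]

#: Canonical EEG rhythm bands (Hz).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}


@dataclass
class ParameterSet:
    """Per-class microstate parameters for one window.

    Arrays are length K (class k at index k-1); ``transition`` is K x K with
    zero diagonal and rows normalised where the class has outgoing
    transitions.  ``present`` flags classes that occur in the window; an
    absent class has all-zero parameters.
    """

    occurrence: np.ndarray
    duration_ms: np.ndarray
    coverage: np.ndarray
    gev: np.ndarray
    gfp: np.ndarray
    mspatcorr: np.ndarray
    transition: np.ndarray
    present: np.ndarray = field(default=None)

    @property
    def K(self) -> int:
        return self.occurrence.shape[0]


def class_parameters(seq: LabelSequence, segs: SegmentList, K: int) -> ParameterSet:
    """Compute the seven parameter families from a labelled window.

    Unassigned samples (label 0) are excluded from class statistics but the
    window length still includes them, so coverage sums to 1 only on fully
    labelled windows.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    labels = seq.labels
    n = labels.shape[0]
    window_s = n / seq.fs
    occurrence = np.zeros(K)
    duration = np.zeros(K)
    coverage = np.zeros(K)
    gev_k = np.zeros(K)
    gfp_k = np.zeros(K)
    mspat = np.zeros(K)
    denom = float(np.sum(seq.gfp**2))
    if denom == 0:
        raise ValidationError("all-zero GFP in window; parameters undefined")
    for k in range(1, K + 1):
        members = labels == k
        durs = [s.duration_ms for s in segs if s.label == k]
        if durs:
            occurrence[k - 1] = len(durs) / window_s
            duration[k - 1] = float(np.mean(durs))
        if np.any(members):
            coverage[k - 1] = members.sum() / n
            gev_k[k - 1] = float(
                np.sum(seq.corr[members] ** 2 * seq.gfp[members] ** 2) / denom
            )
            gfp_k[k - 1] = float(seq.gfp[members].mean())
            mspat[k - 1] = float(np.abs(seq.corr[members]).mean())
    present = occurrence > 0
    if not np.all(present):
        logger.debug("classes absent from window: %s", np.flatnonzero(~present) + 1)
    return ParameterSet(
        occurrence, duration, coverage, gev_k, gfp_k, mspat,
        transition_matrix(segs, K), present,
    )


def transition_matrix(segs: SegmentList, K: int) -> np.ndarray:
    """Row-stochastic transition probabilities between consecutive segments.

    Counts transitions between consecutive distinct-labelled segments
    (labels outside 1..K, e.g. unassigned runs, are skipped); the diagonal
    is zero by construction and rows without outgoing transitions stay
    all-zero.
    """
    counts = np.zeros((K, K))
    prev = None
    for seg in segs:
        if not 1 <= seg.label <= K:
            prev = None
            continue
        if prev is not None and prev != seg.label:
            counts[prev - 1, seg.label - 1] += 1
        prev = seg.label
    if len(segs) < 2:
        logger.warning("single-segment window: transition matrix is all zero")
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row_sums > 0, counts / row_sums, 0.0)
    return probs


def feature_column_names(K: int, include_spatial: bool = True) -> list[str]:
    """Column order of the per-window feature vector."""
    cols = (
        [f"occurrence_MS{k}" for k in range(1, K + 1)]
        + [f"duration_MS{k}" for k in range(1, K + 1)]
        + [f"coverage_MS{k}" for k in range(1, K + 1)]
        + [f"gev_MS{k}" for k in range(1, K + 1)]
        + [
            f"trans_MS{i}_MS{j}"
            for i in range(1, K + 1)
            for j in range(1, K + 1)
        ]
    )
    if include_spatial:
        cols += [f"gfp_MS{k}" for k in range(1, K + 1)]
        cols += [f"mspatcorr_MS{k}" for k in range(1, K + 1)]
    return cols


def _parameter_vector(p: ParameterSet, include_spatial: bool) -> np.ndarray:
    parts = [p.occurrence, p.duration_ms, p.coverage, p.gev, p.transition.ravel()]
    if include_spatial:
        parts += [p.gfp, p.mspatcorr]
    return np.concatenate(parts)


def windowed_feature_table(
    rec: Recording,
    templates: TemplateSet,
    window_s: float = 15.0,
    params: SmoothingParams | None = None,
    include_spatial: bool = True,
    polarity: str = "absolute",
) -> pd.DataFrame:
    """Per-window microstate feature table.

    Non-overlapping windows are cut from the start of the recording; an
    incomplete trailing window is dropped.  Each window independently runs
    backfit → smooth → segmentize → parameters.  Rows are windows, columns
    ``4K + K^2`` temporal (+ ``2K`` spatial) features; the window start time
    is kept in a ``t_start_s`` column.
    """
    win = int(round(window_s * rec.fs))
    if win < 2:
        raise ValidationError("window must contain at least 2 samples")
    n_windows = rec.n_samples // win
    if n_windows == 0:
        raise ValidationError(
            f"recording of {rec.duration_s:.1f} s has no complete "
            f"{window_s:g} s window"
        )
    params = params or SmoothingParams()
    K = templates.K
    cols = feature_column_names(K, include_spatial)
    rows = []
    for w in range(n_windows):
        sub = Recording(
            rec.data[:, w * win : (w + 1) * win],
            rec.fs,
            rec.channel_names,
            dict(rec.meta),
        )
        seq = smooth(backfit(sub, templates, polarity), templates, params)
        p = class_parameters(seq, segmentize(seq), K)
        rows.append(_parameter_vector(p, include_spatial))
    table = pd.DataFrame(rows, columns=cols)
    table.insert(0, "t_start_s", np.arange(n_windows) * win / rec.fs)
    logger.info("extracted %d windows x %d features", n_windows, len(cols))
    return table


def band_power(
    rec: Recording,
    bands: dict[str, tuple[float, float]] | None = None,
    segment_s: float = 2.0,
    overlap: float = 0.5,
) -> pd.DataFrame:
    """Mean band power per channel via Welch's averaged periodogram.

    Power in each band is the PSD integrated over the band (µV²), computed
    with ``segment_s``-second segments and fractional ``overlap``.  Returns
    a single-row DataFrame with ``len(bands) * C`` columns named
    ``<band>_<channel>``.
    """
    bands = bands or DEFAULT_BANDS
    nper = int(round(segment_s * rec.fs))
    if rec.n_samples < nper:
        raise ValidationError(
            f"recording shorter ({rec.n_samples} samples) than one spectral "
            f"segment ({nper} samples)"
        )
    for name, (lo, hi) in bands.items():
        if not 0 <= lo < hi or hi >= rec.fs / 2:
            raise ValidationError(f"band {name} edges must lie below Nyquist")
    freqs, psd = sps.welch(
        rec.data, fs=rec.fs, nperseg=nper, noverlap=int(nper * overlap), axis=1
    )
    out = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs <= hi)
        power = np.trapezoid(psd[:, sel], freqs[sel], axis=1)
        for c, ch in enumerate(rec.channel_names):
            out[f"{name}_{ch}"] = power[c]
    return pd.DataFrame([out])
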