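"""Backfitting templates to every sample, label smoothing and segmentation.

Backfitting converts the continuous EEG into a microstate label sequence:
each sample's average-referenced map gets the template with the highest
spatial correlation (absolute value by default, matching polarity-invariant
clustering).  Two smoothers clean the raw sequence: a windowed relabelling
that trades per-sample fit against label agreement within +/-b samples, and
a minimum-duration rule that dissolves segments shorter than a threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cluster import TemplateSet, _corr_matrix
from .errors import ValidationError
from .gfp import gfp_curve
from .io_model import Recording, common_average_reference

logger = logging.getLogger(__name__)

__all__ = [
    "LabelSequence",
    "SegmentList",
    "SmoothingParams",
    "backfit",
    "smooth_window",
    "reject_short_segments",
    "segmentize",
    "smooth",
]


@dataclass
class LabelSequence:
    """Per-sample microstate labels with fit diagnostics.

    ``labels`` are 1-based (0 = unassigned); ``corr`` is the signed
    correlation with the assigned template; ``gfp`` the per-sample global
    field power.  ``corr_all`` (N x K, optional) keeps the correlation with
    every template so later stages can re-assign samples.
    """

    labels: np.ndarray
    corr: np.ndarray
    gfp: np.ndarray
    fs: float
    corr_all: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.corr = np.asarray(self.corr, dtype=float)
        self.gfp = np.asarray(self.gfp, dtype=float)
        n = self.labels.shape[0]
        if self.corr.shape[0] != n or self.gfp.shape[0] != n:
            raise ValidationError("labels, corr and gfp must have equal length")
        if np.any(np.abs(self.corr) > 1 + 1e-9):
            raise ValidationError("correlations must lie in [-1, 1]")
        if not self.fs > 0:
            raise ValidationError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    def copy(self) -> "LabelSequence":
        return LabelSequence(
            self.labels.copy(),
            self.corr.copy(),
            self.gfp.copy(),
            self.fs,
            None if self.corr_all is None else self.corr_all.copy(),
        )


@dataclass
class Segment:
    label: int
    start: int
    end: int  # half-open
    duration_ms: float


class SegmentList(list):
    """Run-length view of a label sequence (list of :class:`Segment`)."""

    def expand(self, n: int | None = None) -> np.ndarray:
        """Reconstruct the per-sample label array."""
        total = n if n is not None else (self[-1].end if self else 0)
        out = np.zeros(total, dtype=int)
        for seg in self:
            out[seg.start : seg.end] = seg.label
        return out


@dataclass
class SmoothingParams:
    """Smoothing configuration.

    ``mode``: ``windowed`` (penalised relabelling), ``min_duration`` (short
    segment rejection) or ``none``.  ``b`` is the window half-width in
    samples, ``lam`` the agreement reward per matching neighbour,
    ``min_duration_ms`` the rejection threshold.
    """

    mode: str = "windowed"
    b: int = 3
    lam: float = 5.0
    min_duration_ms: float = 30.0
    max_smooth_iter: int = 1000

    def __post_init__(self) -> None:
        if self.mode not in ("windowed", "min_duration", "none"):
            raise ValidationError(f"unknown smoothing mode {self.mode!r}")
        if self.b < 1 or self.lam < 0 or self.min_duration_ms < 0:
            raise ValidationError("need b >= 1, lam >= 0, min_duration_ms >= 0")
        if self.max_smooth_iter < 1:
            raise ValidationError("max_smooth_iter must be >= 1")


def backfit(
    rec: Recording, templates: TemplateSet | np.ndarray, polarity: str = "absolute"
) -> LabelSequence:
    """Label every sample with its best-matching template.

    ``absolute`` mode (default) maximises |corr| — consistent with
    polarity-invariant clustering; ``signed`` maximises the signed
    correlation.  ``corr`` stores the winning signed value.  A zero map
    (all channels equal) inherits the previous sample's label with corr 0;
    a zero map at the very first sample gets label 0.
    """
    if polarity not in ("absolute", "signed"):
        raise ValidationError(f"unknown polarity mode {polarity!r}")
    tpl = templates.templates if isinstance(templates, TemplateSet) else templates
    tpl = np.atleast_2d(tpl)
    if rec.n_channels != tpl.shape[1]:
        raise ValidationError("recording and template channel counts differ")
    x = common_average_reference(rec.data).T  # N x C
    corr_all = _corr_matrix(x, tpl)
    score = np.abs(corr_all) if polarity == "absolute" else corr_all
    labels = np.argmax(score, axis=1) + 1
    corr = corr_all[np.arange(x.shape[0]), labels - 1]
    zero = np.linalg.norm(x, axis=1) == 0
    if np.any(zero):
        logger.warning("%d zero maps during backfit", int(zero.sum()))
        for n in np.flatnonzero(zero):
            labels[n] = labels[n - 1] if n > 0 else 0
            corr[n] = 0.0
    g = gfp_curve(rec)
    return LabelSequence(labels, corr, g.values, rec.fs, corr_all)


def _misfit(seq: LabelSequence) -> np.ndarray:
    """Per-sample, per-class fit cost 1 - corr^2 (polarity invariant)."""
    if seq.corr_all is None:
        raise ValidationError(
            "windowed smoothing needs corr_all; produce the sequence via backfit()"
        )
    return 1.0 - seq.corr_all**2


def _window_objective(labels: np.ndarray, misfit: np.ndarray, b: int, lam: float) -> float:
    """Total misfit minus lam * (# agreeing sample pairs within distance b).

    Each unordered pair is counted once, so relabelling one sample changes
    the objective by exactly the quantity the per-sample update minimises.
    """
    n = labels.shape[0]
    total = float(misfit[np.arange(n), labels - 1].sum())
    agree = 0
    for offset in range(1, b + 1):
        agree += int(np.sum(labels[:-offset] == labels[offset:]))
    return total - lam * agree


def smooth_window(
    seq: LabelSequence,
    templates: TemplateSet | np.ndarray | None = None,
    params: SmoothingParams | None = None,
) -> LabelSequence:
    """Windowed smoothing: iterative penalised relabelling.

    Each sweep relabels every sample to minimise ``misfit(n, k) - lam *
    (# samples with label k within +/-b, excluding n)``; boundary windows are
    truncated.  Sweeps repeat until the labels stop changing, the objective
    stops improving, or ``max_smooth_iter`` is hit (then the current state is
    returned with a warning).  ``templates`` is accepted for API symmetry;
    the correlations cached on the sequence are used.
    """
    params = params or SmoothingParams()
    misfit = _misfit(seq)
    labels = seq.labels.copy()
    n, K = misfit.shape
    b, lam = params.b, params.lam
    best_obj = _window_objective(labels, misfit, b, lam)
    converged = False
    for _ in range(params.max_smooth_iter):
        prev = labels.copy()
        for i in range(n):
            lo, hi = max(0, i - b), min(n, i + b + 1)
            window = labels[lo:hi]
            counts = np.bincount(window, minlength=K + 1)[1:]
            if labels[i] >= 1:
                counts[labels[i] - 1] -= 1  # exclude the sample itself
            cost = misfit[i] - lam * counts
            labels[i] = int(np.argmin(cost)) + 1
        if np.array_equal(labels, prev):
            converged = True
            break
        obj = _window_objective(labels, misfit, b, lam)
        if obj >= best_obj:  # keep the objective monotone; stop on stall
            labels = prev
            converged = True
            break
        best_obj = obj
    if not converged:
        logger.warning(
            "windowed smoothing hit max_smooth_iter=%d without converging",
            params.max_smooth_iter,
        )
    out = seq.copy()
    out.labels = labels
    out.corr = seq.corr_all[np.arange(n), labels - 1]
    return out


def segmentize(seq: LabelSequence) -> SegmentList:
    """Maximal runs of equal labels with durations in milliseconds."""
    labels = seq.labels
    if labels.size == 0:
        raise ValidationError("empty label sequence")
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [labels.size]))
    segs = SegmentList()
    for s, e in zip(starts, ends):
        segs.append(
            Segment(int(labels[s]), int(s), int(e), (e - s) / seq.fs * 1000.0)
        )
    return segs


def reject_short_segments(
    seq: LabelSequence, min_duration_ms: float | None = None
) -> LabelSequence:
    """Dissolve segments shorter than a duration threshold.

    The shortest offending segment is dissolved first: its samples join the
    left or right neighbouring segment's label, driven by which template
    correlates better (|corr|) with each sample's map, with a single
    left/right crossing enforced so that dissolving a segment always merges
    it into its neighbours (the segment count never increases).  This
    repeats until no segment is below threshold.  A sequence consisting of a
    single short segment is returned unchanged with a warning.
    """
    thr = 30.0 if min_duration_ms is None else float(min_duration_ms)
    if thr < 0:
        raise ValidationError("min_duration_ms must be >= 0")
    out = seq.copy()
    if thr == 0:
        return out
    while True:
        segs = segmentize(out)
        short = [
            (i, s) for i, s in enumerate(segs) if s.duration_ms < thr
        ]
        if not short:
            break
        if len(segs) == 1:
            logger.warning(
                "whole sequence shorter than %g ms; left unchanged", thr
            )
            break
        i, seg = min(short, key=lambda t: (t[1].duration_ms, t[0]))
        left = segs[i - 1].label if i > 0 else None
        right = segs[i + 1].label if i < len(segs) - 1 else None
        span = np.arange(seg.start, seg.end)
        if left is None:
            out.labels[span] = right
        elif right is None:
            out.labels[span] = left
        elif out.corr_all is not None:
            cl = np.abs(out.corr_all[span, left - 1])
            cr = np.abs(out.corr_all[span, right - 1])
            # best single crossing: samples before the split go left
            gains = [cl[:s].sum() + cr[s:].sum() for s in range(span.size + 1)]
            split = int(np.argmax(gains))
            out.labels[span[:split]] = left
            out.labels[span[split:]] = right
        else:  # no cached correlations: split at the midpoint
            mid = span.size // 2
            out.labels[span[:mid]] = left
            out.labels[span[mid:]] = right
    if out.corr_all is not None:
        idx = np.flatnonzero(out.labels > 0)
        out.corr[idx] = out.corr_all[idx, out.labels[idx] - 1]
    return out


def smooth(
    seq: LabelSequence,
    templates: TemplateSet | np.ndarray | None = None,
    params: SmoothingParams | None = None,
) -> LabelSequence:
    """Dispatch to the smoother selected by ``params.mode``."""
    params = params or SmoothingParams()
    if params.mode == "none":
        return seq.copy()
    if params.mode == "windowed":
        return smooth_window(seq, templates, params)
    return reject_short_segments(seq, params.min_duration_ms)
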