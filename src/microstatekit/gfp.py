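"""Global field power (GFP) and extraction of GFP-peak topographies.

GFP at sample *n* is the spatial standard deviation of the average-referenced
map: ``GFP_n = sqrt(sum_i (v_in - vbar_n)^2 / C)``.  Local maxima of the GFP
curve mark instants of stable, high-SNR topography; the maps at those peaks
form the input bank for spatial clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_model import Recording, common_average_reference

logger = logging.getLogger(__name__)

__all__ = ["GfpSeries", "TopographyBank", "gfp_curve", "find_gfp_peaks",
           "extract_peak_maps"]


@dataclass
class GfpSeries:
    """Per-sample GFP values (microvolts) with their sampling rate."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("GFP series must be 1-D")
        if np.any(self.values < 0):
            raise ValidationError("GFP values cannot be negative")


@dataclass
class TopographyBank:
    """Average-referenced maps sampled at GFP peaks.

    ``maps`` is ``(M, C)``; ``source`` holds one ``(recording_id, sample)``
    pair per row; ``gfp_at_peak`` the GFP value at the peak sample.
    """

    maps: np.ndarray
    source: list[tuple[str, int]]
    gfp_at_peak: np.ndarray
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        self.gfp_at_peak = np.asarray(self.gfp_at_peak, dtype=float)
        if self.maps.shape[0] < 1:
            raise ValidationError("topography bank is empty")
        if len(self.source) != self.maps.shape[0] or (
            self.gfp_at_peak.shape[0] != self.maps.shape[0]
        ):
            raise ValidationError("bank rows, sources and GFPs must align")
        if np.max(np.abs(self.maps.mean(axis=1))) > 1e-8:
            raise ValidationError("bank maps must be average-referenced")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


def gfp_curve(rec: Recording) -> GfpSeries:
    """Compute the GFP curve of a recording.

    The recording is average-referenced internally, so the result is
    reference independent: ``values[n]`` is the population standard
    deviation across channels at sample ``n``.
    """
    if rec.n_channels < 2:
        raise ValidationError("GFP needs at least 2 channels")
    centered = common_average_reference(rec.data)
    values = np.sqrt(np.mean(centered**2, axis=0))
    return GfpSeries(values, rec.fs)


def find_gfp_peaks(g: GfpSeries, min_distance_samples: int = 0) -> np.ndarray:
    """Indices of strict interior local maxima of the GFP curve.

    A plateau counts as a single candidate at its first sample.  When
    ``min_distance_samples`` > 0, peaks are retained greedily by descending
    GFP so no two kept peaks are closer than the given distance.
    """
    v = g.values
    if v.size < 3:
        raise ValidationError("need at least 3 samples to find interior maxima")
    # Collapse runs of equal values, then test each run against its distinct
    # neighbours; the run's first sample represents a plateau peak.
    change = np.flatnonzero(np.diff(v) != 0)
    starts = np.concatenate(([0], change + 1))
    run_vals = v[starts]
    peaks = []
    for j in range(1, len(starts) - 1):
        if run_vals[j] > run_vals[j - 1] and run_vals[j] > run_vals[j + 1]:
            peaks.append(starts[j])
    peaks = np.asarray(peaks, dtype=int)
    if min_distance_samples > 0 and peaks.size:
        order = peaks[np.argsort(-v[peaks], kind="stable")]
        kept: list[int] = []
        for idx in order:
            if all(abs(idx - k) >= min_distance_samples for k in kept):
                kept.append(int(idx))
        peaks = np.sort(kept).astype(int)
    return peaks


def extract_peak_maps(
    recs: Recording | list[Recording],
    cap_per_recording: int | None = 1000,
    seed: int = 0,
    min_distance_samples: int = 0,
) -> TopographyBank:
    """Pool average-referenced GFP-peak maps across recordings.

    Group-level clustering operates on peaks pooled over subjects/trials.
    When a recording has more peaks than ``cap_per_recording``, a seeded
    uniform subsample of that size is kept (sorted, so source indices stay
    increasing within a recording).
    """
    if isinstance(recs, Recording):
        recs = [recs]
    if not recs:
        raise ValidationError("no recordings given")
    names0 = recs[0].channel_names
    rng = np.random.default_rng(seed)
    maps, sources, gfps = [], [], []
    for i, rec in enumerate(recs):
        if rec.channel_names != names0:
            raise ValidationError(
                f"recording {i} channel set differs from recording 0"
            )
        g = gfp_curve(rec)
        idx = find_gfp_peaks(g, min_distance_samples)
        if idx.size == 0:
            logger.warning("recording %d contributes no GFP peaks", i)
            continue
        if cap_per_recording is not None and idx.size > cap_per_recording:
            idx = np.sort(rng.choice(idx, size=cap_per_recording, replace=False))
        centered = common_average_reference(rec.data)
        rec_id = str(rec.meta.get("id", i))
        maps.append(centered[:, idx].T)
        sources.extend((rec_id, int(n)) for n in idx)
        gfps.append(g.values[idx])
    if not maps:
        raise ValidationError("no GFP peaks found in any recording")
    bank = TopographyBank(
        np.vstack(maps), sources, np.concatenate(gfps), list(names0)
    )
    logger.info("pooled %d peak maps from %d recordings", bank.n_maps, len(recs))
    return bank
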