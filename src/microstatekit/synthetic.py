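"""Ground-truthed synthetic EEG with planted microstate structure.

The generator embodies the microstate model itself: a small set of
quasi-stable, average-referenced template topographies that the scalp field
alternates between every ~100 ms.  Labels follow a first-order (semi-)
Markov chain with geometric segment durations by default (a truncated-
Gaussian option gives more realistic duration histograms); the signal is
the active template modulated by a rectified 10 Hz sinusoid (producing GFP
peaks twice per cycle, as alpha-band activity does) plus white sensor
noise.  Ground-truth labels and segments are returned so every pipeline
stage can be scored without external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .backfit import LabelSequence, SegmentList, segmentize
from .cluster import TemplateSet, _corr_matrix, gev
from .errors import ValidationError
from .io_model import Recording, common_average_reference

logger = logging.getLogger(__name__)

__all__ = ["SynthConfig", "make_templates", "simulate_recording"]


@dataclass
class SynthConfig:
    """Synthetic-recording parameters.

    ``mean_duration_ms`` defaults to 100 ms, the centre of the 80–120 ms
    range typical of EEG microstates.  ``snr`` is the amplitude ratio of
    the template-driven signal to the additive white noise.  ``transition``
    is a K x K row-stochastic matrix with zero diagonal or ``"uniform"``.
    """

    K_true: int = 4
    C: int = 32
    fs: float = 200.0
    duration_s: float = 120.0
    mean_duration_ms: float = 100.0
    duration_dist: str = "geometric"
    duration_sd_ms: float = 30.0
    transition: object = "uniform"
    snr: float = 4.0
    amplitude_uv: float = 10.0
    envelope_hz: float = 10.0
    seed: int = 0
    max_template_corr: float = 0.3

    def __post_init__(self) -> None:
        if self.K_true < 2:
            raise ValidationError("K_true must be >= 2")
        if self.C <= self.K_true:
            raise ValidationError("need more channels than templates")
        if not self.mean_duration_ms > 1000.0 / self.fs:
            raise ValidationError("mean duration must exceed one sample period")
        if not self.snr > 0:
            raise ValidationError("snr must be positive")
        if self.duration_dist not in ("geometric", "truncated_normal"):
            raise ValidationError(f"unknown duration_dist {self.duration_dist!r}")


def make_templates(
    K: int,
    C: int,
    seed: int = 0,
    max_corr: float = 0.3,
    orthogonal: bool = False,
    max_tries: int = 200,
) -> TemplateSet:
    """K zero-mean, unit-norm, mutually low-correlation smooth maps.

    Channels are placed on a ring; each map is a random mixture of the
    first few spatial harmonics, giving smooth profiles like real scalp
    topographies.  Maps are redrawn until all pairwise |corr| < ``max_corr``
    (error after ``max_tries``).  With ``orthogonal=True`` the maps are
    Gram-Schmidt orthogonalised instead (pairwise corr exactly 0).
    """
    if C <= K:
        raise ValidationError("need C > K")
    rng = np.random.default_rng(seed)
    theta = 2 * np.pi * np.arange(C) / C
    n_harmonics = min(max(3, K + 1), C // 2)
    basis = np.concatenate(
        [np.stack([np.cos(h * theta), np.sin(h * theta)]) for h in
         range(1, n_harmonics + 1)]
    )  # zero-mean rows by construction

    def draw() -> np.ndarray:
        m = rng.normal(size=basis.shape[0]) @ basis
        m -= m.mean()
        return m / np.linalg.norm(m)

    accepted: list[np.ndarray] = []
    while len(accepted) < K:
        for _ in range(max_tries):
            cand = draw()
            if orthogonal:
                for prev in accepted:
                    cand = cand - np.dot(cand, prev) * prev
                norm = np.linalg.norm(cand)
                if norm < 1e-8:
                    continue
                cand /= norm
                accepted.append(cand)
                break
            if all(abs(np.dot(cand, prev)) < max_corr for prev in accepted):
                accepted.append(cand)
                break
        else:
            raise ValidationError(
                f"could not draw map {len(accepted) + 1} of {K} with pairwise "
                f"|corr| < {max_corr} in {max_tries} tries"
            )
    maps = np.vstack(accepted)
    labels = np.arange(1, K + 1)
    total, per_class = gev(maps, np.ones(K), maps, labels)
    return TemplateSet(maps, labels, total, per_class)


def _draw_durations(cfg: SynthConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Segment durations in samples (>= 1)."""
    mean_samples = cfg.mean_duration_ms * cfg.fs / 1000.0
    if cfg.duration_dist == "geometric":
        return rng.geometric(p=min(1.0, 1.0 / mean_samples), size=n)
    sd = cfg.duration_sd_ms * cfg.fs / 1000.0
    draws = rng.normal(mean_samples, sd, size=n)
    return np.maximum(1, np.round(draws)).astype(int)


def _transition_matrix(cfg: SynthConfig) -> np.ndarray:
    K = cfg.K_true
    if isinstance(cfg.transition, str):
        if cfg.transition != "uniform":
            raise ValidationError(f"unknown transition spec {cfg.transition!r}")
        T = np.full((K, K), 1.0 / (K - 1))
        np.fill_diagonal(T, 0.0)
        return T
    T = np.asarray(cfg.transition, dtype=float)
    if T.shape != (K, K) or np.any(T < 0):
        raise ValidationError("transition must be a nonnegative K x K matrix")
    if np.max(np.abs(np.diag(T))) > 0:
        raise ValidationError("transition diagonal must be zero")
    if np.max(np.abs(T.sum(axis=1) - 1)) > 1e-9:
        raise ValidationError("transition rows must sum to 1")
    return T


def simulate_recording(
    cfg: SynthConfig | None = None,
    templates: TemplateSet | None = None,
) -> tuple[Recording, LabelSequence, SegmentList, TemplateSet]:
    """Simulate a recording; return it with its ground truth.

    The label sequence is a semi-Markov chain (durations drawn per segment,
    next state from the transition matrix); the multichannel signal is
    ``template[l_n] * envelope_n * amplitude + noise`` with the noise scaled
    so the overall signal/noise RMS ratio equals ``cfg.snr``, then average
    referenced.  Returns ``(recording, true_labels, true_segments,
    templates)``.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    if templates is None:
        templates = make_templates(
            cfg.K_true, cfg.C, seed=cfg.seed, max_corr=cfg.max_template_corr
        )
    if templates.K != cfg.K_true or templates.n_channels != cfg.C:
        raise ValidationError("templates do not match the config dimensions")
    n = int(round(cfg.duration_s * cfg.fs))
    T = _transition_matrix(cfg)

    labels = np.empty(n, dtype=int)
    pos = 0
    state = int(rng.integers(cfg.K_true)) + 1
    while pos < n:
        dur = int(_draw_durations(cfg, rng, 1)[0])
        labels[pos : pos + dur] = state
        pos += dur
        state = int(rng.choice(cfg.K_true, p=T[state - 1])) + 1

    t = np.arange(n) / cfg.fs
    phase = rng.uniform(0, np.pi)
    envelope = np.abs(np.sin(2 * np.pi * cfg.envelope_hz * t + phase))
    signal = templates.templates[labels - 1] * envelope[:, None] * cfg.amplitude_uv
    signal_rms = float(np.sqrt(np.mean(signal**2)))
    noise = rng.normal(0.0, signal_rms / cfg.snr, size=signal.shape)
    data = common_average_reference((signal + noise).T)
    rec = Recording(
        data,
        cfg.fs,
        [f"SYN{c:02d}" for c in range(1, cfg.C + 1)],
        {"synthetic": True, "seed": cfg.seed},
    )

    corr_all = _corr_matrix(common_average_reference(rec.data).T,
                            templates.templates)
    corr = corr_all[np.arange(n), labels - 1]
    gfp_vals = np.sqrt(np.mean(common_average_reference(rec.data) ** 2, axis=0))
    truth = LabelSequence(labels, corr, gfp_vals, cfg.fs, corr_all)
    logger.info(
        "simulated %g s, K=%d, C=%d, snr=%g (%d segments)",
        cfg.duration_s, cfg.K_true, cfg.C, cfg.snr, len(segmentize(truth)),
    )
    return rec, truth, segmentize(truth), templates
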