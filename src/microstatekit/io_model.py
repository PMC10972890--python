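"""Recording container, standard-format I/O and the preprocessing chain.

The central object is :class:`Recording`: a channels-by-samples matrix of
scalp potentials in microvolts together with the sampling rate and channel
names.  Readers exist for EDF and BrainVision (via :mod:`mne`), for a plain
delimited text matrix and for an HDF5 container; preprocessing covers the
standard EEG chain of band-pass filtering, notch filtering, common average
referencing (CAR) and anti-aliased resampling, applied in that order.

Filters are zero-phase forward-backward Butterworth (4th-order by default)
so that topography timing is not distorted; resampling is polyphase with an
anti-aliasing FIR.  ICA-based artifact removal is deliberately left to
upstream tooling: this module assumes cleaned data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np
from scipy import signal

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "PreprocessConfig",
    "load_recording",
    "write_recording",
    "preprocess",
    "common_average_reference",
]


@dataclass
class Recording:
    """Multichannel EEG segment.

    Parameters
    ----------
    data
        ``(C, N)`` float array, channels by samples, in microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        ``C`` unique channel labels.
    meta
        Free-form annotations (subject, trial, condition, ...).
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be a 2-D channels x samples array")
        c, n = self.data.shape
        if c < 2:
            raise ValidationError(f"need at least 2 channels, got {c}")
        if n < 1:
            raise ValidationError("recording has no samples")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        self.channel_names = [str(x) for x in self.channel_names]
        if len(self.channel_names) != c:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for {c} channels"
            )
        if not self.channel_names or len(set(self.channel_names)) != c:
            raise ValidationError("channel names must be unique and non-empty")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def copy(self) -> "Recording":
        return Recording(
            self.data.copy(), self.fs, list(self.channel_names), dict(self.meta)
        )


@dataclass
class PreprocessConfig:
    """Preprocessing chain parameters.

    ``bandpass``/``notch`` are ``(low, high)`` tuples in Hz or ``None``;
    ``car`` toggles common average referencing; ``target_fs`` requests
    resampling.  The defaults mirror common emotional-EEG practice: 1–45 Hz
    band-pass, 48–52 Hz power-line notch, CAR, down-sampling to 200 Hz.
    """

    bandpass: tuple[float, float] | None = (1.0, 45.0)
    notch: tuple[float, float] | None = (48.0, 52.0)
    car: bool = True
    target_fs: float | None = 200.0
    filter_order: int = 4

    def validate(self, fs: float) -> None:
        for name, band in (("bandpass", self.bandpass), ("notch", self.notch)):
            if band is None:
                continue
            low, high = band
            if not 0 < low < high:
                raise ValidationError(f"{name} band must satisfy 0 < low < high")
            if high >= fs / 2:
                raise ValidationError(
                    f"{name} upper edge {high} Hz is at or above Nyquist ({fs / 2} Hz)"
                )
        if self.target_fs is not None and self.target_fs > fs:
            raise ValidationError("target_fs cannot exceed the original rate")
        if self.filter_order < 1:
            raise ValidationError("filter_order must be >= 1")


def common_average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the across-channel mean at every time point."""
    return data - data.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MATRIX_SUFFIXES = {".tsv", ".csv", ".txt"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix == ".vhdr":
        return "brainvision"
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf"
    if suffix in _MATRIX_SUFFIXES:
        return "matrix"
    raise ValidationError(f"cannot infer format from suffix {suffix!r} ({path})")


def load_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from EDF, BrainVision, HDF5 or delimited text.

    Data are returned in microvolts.  ``format`` is one of ``edf``,
    ``brainvision``, ``matrix``, ``hdf``; when ``None`` it is inferred from
    the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt == "matrix":
        return _load_matrix(path)
    if fmt == "hdf":
        return _load_hdf(path)
    if fmt in ("edf", "brainvision"):
        return _load_mne(path, fmt)
    raise ValidationError(f"unknown format {fmt!r}")


def _load_mne(path: Path, fmt: str) -> Recording:
    import mne

    reader = {"edf": mne.io.read_raw_edf, "brainvision": mne.io.read_raw_brainvision}
    try:
        raw = reader[fmt](path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - surface the offending path
        raise IOError(f"failed to parse {path} as {fmt}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # mne works in volts
    return Recording(
        data_uv, float(raw.info["sfreq"]), list(raw.ch_names), {"source": str(path)}
    )


def _load_matrix(path: Path) -> Recording:
    """Delimited matrix: header ``fs=<Hz>  name1  name2 ...``, then one row
    per channel with samples as columns."""
    with open(path) as fh:
        header = fh.readline().strip()
    fields = header.split("\t") if "\t" in header else header.split(",")
    if not fields or not fields[0].startswith("fs="):
        raise IOError(f"{path}: first header field must be 'fs=<Hz>'")
    fs = float(fields[0][3:])
    names = fields[1:]
    delim = "\t" if "\t" in header else ","
    data = np.loadtxt(path, skiprows=1, delimiter=delim, ndmin=2)
    if data.shape[0] != len(names):
        raise IOError(
            f"{path}: {len(names)} channel names but {data.shape[0]} data rows"
        )
    return Recording(data, fs, names, {"source": str(path)})


def _load_hdf(path: Path) -> Recording:
    with h5py.File(path, "r") as fh:
        data = fh["/data"][()]
        fs = float(fh["/fs"][()])
        names = [
            x.decode() if isinstance(x, bytes) else str(x) for x in fh["/channels"][()]
        ]
        meta = json.loads(fh.attrs.get("meta", "{}"))
    return Recording(data, fs, names, meta)


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> None:
    """Write a recording as a delimited matrix or an HDF5 container.

    The HDF5 container uses datasets ``/data``, ``/fs``, ``/channels`` and a
    JSON ``meta`` attribute; round-trips are lossless.  The text matrix
    round-trips to its printed precision.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    try:
        if fmt == "matrix":
            header = "\t".join([f"fs={rec.fs:g}", *rec.channel_names])
            np.savetxt(path, rec.data, delimiter="\t", header=header, comments="",
                       fmt="%.10g")
        elif fmt == "hdf":
            with h5py.File(path, "w") as fh:
                fh.create_dataset("/data", data=rec.data)
                fh.create_dataset("/fs", data=rec.fs)
                fh.create_dataset(
                    "/channels", data=np.array(rec.channel_names, dtype="S")
                )
                fh.attrs["meta"] = json.dumps(rec.meta)
        else:
            raise ValidationError(f"unsupported output format {fmt!r}")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def preprocess(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Apply band-pass → notch → CAR → resample, returning a new Recording.

    Filtering is zero-phase (``sosfiltfilt`` on a Butterworth design);
    resampling is polyphase (``resample_poly``), so the output sample count
    is ``ceil(N * target_fs / fs)`` for rational rate ratios.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(rec.fs)
    data = rec.data
    fs = rec.fs
    if cfg.bandpass is not None:
        sos = signal.butter(
            cfg.filter_order, cfg.bandpass, btype="bandpass", fs=fs, output="sos"
        )
        data = signal.sosfiltfilt(sos, data, axis=1)
    if cfg.notch is not None:
        sos = signal.butter(
            cfg.filter_order, cfg.notch, btype="bandstop", fs=fs, output="sos"
        )
        data = signal.sosfiltfilt(sos, data, axis=1)
    if cfg.car:
        data = common_average_reference(data)
    if cfg.target_fs is not None and cfg.target_fs != fs:
        ratio = Fraction(cfg.target_fs / fs).limit_denominator(10_000)
        data = signal.resample_poly(data, ratio.numerator, ratio.denominator, axis=1)
        fs = cfg.target_fs
    logger.info(
        "preprocessed %d ch x %d samples -> fs=%g Hz", rec.n_channels,
        rec.n_samples, fs,
    )
    return Recording(data, fs, list(rec.channel_names), dict(rec.meta))
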