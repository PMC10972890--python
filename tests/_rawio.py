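"""Minimal EDF and BrainVision fixture writers for the test suite.

These produce small, standard-conforming files at test time so the readers
in :mod:`microstatekit.io_model` can be exercised against an independent
on-disk representation.  They are deliberately minimal writers for fixtures,
not general-purpose exporters.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_edf(path, data_uv: np.ndarray, fs: int, ch_names: list[str]) -> dict:
    """Write an EDF file (int16, one 1-second record per fs samples).

    Samples are quantised to the int16 grid over the data range; returns a
    manifest with the channel names, fs and the quantised physical values
    actually stored (for round-trip comparison).
    """
    data_uv = np.asarray(data_uv, dtype=float)
    c, n = data_uv.shape
    if n % fs != 0:
        raise ValueError("sample count must be a whole number of 1 s records")
    n_records = n // fs
    phys_min = float(np.floor(data_uv.min() - 1))
    phys_max = float(np.ceil(data_uv.max() + 1))
    dig_min, dig_max = -32768, 32767

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        assert len(b) <= width, text
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate 01-JAN-2020 X X X", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + c)), 8),
            pad("EDF", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(c), 4),
        ]
    )
    sig = b"".join(pad(name, 16) for name in ch_names)
    sig += b"".join(pad("AgAgCl electrode", 80) for _ in range(c))
    sig += b"".join(pad("uV", 8) for _ in range(c))
    sig += b"".join(pad(f"{phys_min:g}", 8) for _ in range(c))
    sig += b"".join(pad(f"{phys_max:g}", 8) for _ in range(c))
    sig += b"".join(pad(str(dig_min), 8) for _ in range(c))
    sig += b"".join(pad(str(dig_max), 8) for _ in range(c))
    sig += b"".join(pad("", 80) for _ in range(c))
    sig += b"".join(pad(str(fs), 8) for _ in range(c))
    sig += b"".join(pad("", 32) for _ in range(c))

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((data_uv - phys_min) / gain + dig_min).astype("<i2")
    quantised = (digital.astype(float) - dig_min) * gain + phys_min

    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_records):
            chunk = digital[:, r * fs : (r + 1) * fs]
            fh.write(chunk.tobytes())  # signal-major within each record
    return {"ch_names": list(ch_names), "fs": float(fs), "data_uv": quantised}


def write_brainvision(
    basepath, data_uv: np.ndarray, fs: float, ch_names: list[str]
) -> dict:
    """Write a BrainVision triplet (.vhdr/.vmrk/.eeg, IEEE float32, µV)."""
    base = Path(basepath)
    stem = base.name
    data_uv = np.asarray(data_uv, dtype=float)
    c, n = data_uv.shape
    interval_us = 1e6 / fs
    vhdr = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={c}",
        f"SamplingInterval={interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    vhdr += [f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(ch_names)]
    base.with_suffix(".vhdr").write_text("\n".join(vhdr) + "\n", encoding="utf-8")
    vmrk = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,20200101000000000000",
    ]
    base.with_suffix(".vmrk").write_text("\n".join(vmrk) + "\n", encoding="utf-8")
    data_uv.T.astype("<f4").tofile(base.with_suffix(".eeg"))
    stored = data_uv.astype(np.float32).astype(float)
    return {"ch_names": list(ch_names), "fs": float(fs), "data_uv": stored}
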