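"""Full-pipeline orchestration: config file, stage sequencing, manifest.

``run_pipeline`` executes preprocess → GFP-peak extraction → model-order
scan/selection → backfit/smooth → feature extraction (→ optional group
statistics) over a set of recordings and writes every artifact plus a JSON
manifest carrying the config hash and seed, so identical config + seed
reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .backfit import SmoothingParams, backfit, segmentize, smooth
from .cluster import ClusterConfig, TemplateSet, scan_and_select
from .errors import ValidationError
from .features import windowed_feature_table
from .gfp import TopographyBank, extract_peak_maps
from .io_model import PreprocessConfig, load_recording, preprocess

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "save_templates", "load_templates",
           "save_bank"]


def _from_dict(cls, data: dict):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValidationError(
            f"unknown keys for {cls.__name__}: {sorted(unknown)}"
        )
    kwargs = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run; YAML round-trippable."""

    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cap_per_recording: int | None = 1000
    k_min: int = 2
    k_max: int = 17
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    smoothing: SmoothingParams = field(default_factory=SmoothingParams)
    window_s: float = 15.0
    include_spatial: bool = True
    polarity: str = "absolute"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["preprocess"]["bandpass"] = (
            list(self.preprocess.bandpass) if self.preprocess.bandpass else None
        )
        d["preprocess"]["notch"] = (
            list(self.preprocess.notch) if self.preprocess.notch else None
        )
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key, sub in (
            ("preprocess", PreprocessConfig),
            ("cluster", ClusterConfig),
            ("smoothing", SmoothingParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = _from_dict(sub, kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Template / bank serialisation (HDF5 container)
# ---------------------------------------------------------------------------


def save_templates(tpl: TemplateSet, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("/templates", data=tpl.templates)
        fh.create_dataset("/labels_of_bank", data=tpl.labels_of_bank)
        fh.create_dataset("/gev_per_class", data=tpl.gev_per_class)
        fh.attrs["gev_total"] = tpl.gev_total
        if tpl.channel_names:
            fh.create_dataset("/channels", data=np.array(tpl.channel_names, dtype="S"))


def load_templates(path: str | Path) -> TemplateSet:
    with h5py.File(path, "r") as fh:
        names = None
        if "/channels" in fh:
            names = [x.decode() for x in fh["/channels"][()]]
        return TemplateSet(
            fh["/templates"][()],
            fh["/labels_of_bank"][()],
            float(fh.attrs["gev_total"]),
            fh["/gev_per_class"][()],
            names,
        )


def save_bank(bank: TopographyBank, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("/maps", data=bank.maps)
        fh.create_dataset(
            "/source",
            data=np.array([f"{r}:{s}" for r, s in bank.source], dtype="S"),
        )
        fh.create_dataset("/gfp", data=bank.gfp_at_peak)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_pipeline(
    cfg: PipelineConfig, inputs: list[str | Path], out_dir: str | Path
) -> dict:
    """Run the full pipeline over ``inputs`` and write artifacts to ``out_dir``.

    Returns the manifest (also written as ``manifest.json``): config digest,
    seed, selected K, and every artifact path.  Stage failures propagate
    with the stage name and offending input in the message.
    """
    if cfg.k_max - cfg.k_min < 4:
        raise ValidationError("scan range must span at least 5 values of K")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, object] = {}

    recs = []
    for p in inputs:
        try:
            rec = preprocess(load_recording(p), cfg.preprocess)
        except Exception as exc:
            raise RuntimeError(f"stage=preprocess input={p}: {exc}") from exc
        rec.meta.setdefault("id", Path(p).stem)
        recs.append(rec)

    try:
        bank = extract_peak_maps(recs, cfg.cap_per_recording, seed=cfg.seed)
    except Exception as exc:
        raise RuntimeError(f"stage=peaks: {exc}") from exc
    save_bank(bank, out / "bank.h5")
    artifacts["bank"] = "bank.h5"

    try:
        cluster_cfg = dataclasses.replace(cfg.cluster, seed=cfg.seed)
        scan, templates = scan_and_select(bank, cfg.k_min, cfg.k_max, cluster_cfg)
    except Exception as exc:
        raise RuntimeError(f"stage=cluster: {exc}") from exc
    scan.as_table().to_csv(out / "scan.tsv", sep="\t", index=False)
    save_templates(templates, out / "templates.h5")
    artifacts["scan"] = "scan.tsv"
    artifacts["templates"] = "templates.h5"

    feature_files, label_files = [], []
    for rec in recs:
        rid = rec.meta["id"]
        try:
            seq = smooth(backfit(rec, templates, cfg.polarity), templates,
                         cfg.smoothing)
            segs = segmentize(seq)
            table = windowed_feature_table(
                rec, templates, cfg.window_s, cfg.smoothing,
                cfg.include_spatial, cfg.polarity,
            )
        except Exception as exc:
            raise RuntimeError(f"stage=features input={rid}: {exc}") from exc
        lab_path = out / f"labels_{rid}.tsv"
        with open(lab_path, "w") as fh:
            fh.write("sample\tlabel\n")
            for n, lab in enumerate(seq.labels):
                fh.write(f"{n}\t{lab}\n")
        seg_path = out / f"segments_{rid}.tsv"
        with open(seg_path, "w") as fh:
            fh.write("label\tstart\tend\tduration_ms\n")
            for s in segs:
                fh.write(f"{s.label}\t{s.start}\t{s.end}\t{s.duration_ms:.6g}\n")
        feat_path = out / f"features_{rid}.tsv"
        table.to_csv(feat_path, sep="\t", index=False)
        label_files.append(lab_path.name)
        label_files.append(seg_path.name)
        feature_files.append(feat_path.name)
    artifacts["labels"] = label_files
    artifacts["features"] = feature_files

    manifest = {
        "config_digest": cfg.digest(),
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "k_optimal": int(scan.k_optimal),
        "gev_total": float(templates.gev_total),
        "inputs": [str(p) for p in inputs],
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: K=%d, %d recordings", scan.k_optimal, len(recs))
    return manifest
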