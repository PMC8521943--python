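"""Shared I/O: WAV audio, reports, run configuration and provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

__all__ = [
    "read_audio",
    "write_audio",
    "write_report",
    "read_report",
    "RunConfig",
    "write_provenance",
    "AudioFormatError",
]


class AudioFormatError(ValueError):
    """Raised when a WAV file cannot be decoded (corrupt or unsupported)."""


_PCM_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31, np.dtype(np.uint8): None}


def read_audio(path):
    """Read a RIFF/WAVE file -> (samples scaled to [-1, 1], sample_rate).

    Stereo files keep both channels (shape ``(n, 2)``); the sparse encoder
    downmixes later.  16/24/32-bit PCM and float WAVs are accepted.
    """
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:
        raise AudioFormatError(f"cannot read {path}: {exc}") from exc
    if data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.dtype(np.int16), np.dtype(np.int32)):
        x = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype in (np.dtype(np.float32), np.dtype(np.float64)):
        x = data.astype(np.float64)
    else:
        raise AudioFormatError(f"unsupported WAV encoding {data.dtype} in {path}")
    return x, float(rate)


def write_audio(path, samples, sample_rate: float) -> None:
    """Write mono or stereo float samples in [-1, 1] as 16-bit PCM WAV."""
    x = np.asarray(samples, dtype=np.float64)
    if np.max(np.abs(x), initial=0.0) > 1.0:
        raise ValueError("samples exceed full scale [-1, 1]")
    pcm = np.round(x * (2**15 - 1)).astype(np.int16)
    wavfile.write(str(path), int(sample_rate), pcm)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    return obj


def write_report(report, path, fmt: str = "json") -> None:
    """Serialise a report (dict / dataclass-like / DataFrame) losslessly."""
    path = Path(path)
    if fmt == "json":
        if isinstance(report, pd.DataFrame):
            doc = report.to_dict(orient="list")
        else:
            doc = _jsonable(report)
        path.write_text(json.dumps(doc, indent=1))
    elif fmt == "csv":
        if isinstance(report, pd.DataFrame):
            report.to_csv(path, index=False)
        elif isinstance(report, np.ndarray) and report.ndim == 2:
            pd.DataFrame(report).to_csv(path, index=False)
        else:
            pd.DataFrame(_jsonable(report)).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def read_report(path):
    path = Path(path)
    if path.suffix == ".csv":
        return pd.read_csv(path)
    return json.loads(path.read_text())


@dataclass
class RunConfig:
    """All pipeline defaults in one validated, YAML-loadable object."""

    seed: int = 0
    output_dir: str = "runs"
    verbosity: int = 1
    filterbank: dict = field(
        default_factory=lambda: {"M": 64, "fmin": 80.0, "fmax": None, "sample_rate": 16000}
    )
    encoder: dict = field(default_factory=lambda: {"K": 1024})
    raster: dict = field(default_factory=lambda: {"bin_ms": 25.0, "transform": "log1p"})
    synthesis: dict = field(
        default_factory=lambda: {"n_per_class": 60, "duration": 10.0, "sample_rate": 16000}
    )
    training: dict = field(
        default_factory=lambda: {
            "learning_rate": 1e-3,
            "batch_size": 24,
            "max_epochs": 250,
            "patience": 10,
            "train_fraction": 0.70,
            "n_repetitions": 10,
        }
    )
    audiometry: dict = field(
        default_factory=lambda: {
            "n_listeners": 18,
            "n_repetitions": 3,
            "latency_clinical": 0.0,
            "latency_remote": 0.0,
            "sweep_rate": 5.0,
        }
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        for key, value in doc.items():
            current = getattr(base, key)
            if isinstance(current, dict):
                extra = set(value) - set(current)
                if extra:
                    raise ValueError(f"unknown keys in config section {key!r}: {sorted(extra)}")
                current.update(value)
            else:
                setattr(base, key, value)
        return base

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def write_provenance(out_dir, config, seeds: dict) -> None:
    """Drop a provenance file (config hash, seeds, package version) in ``out_dir``."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = asdict(config) if hasattr(config, "__dataclass_fields__") else dict(config)
    blob = json.dumps(_jsonable(cfg), sort_keys=True).encode()
    doc = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": _jsonable(cfg),
        "seeds": _jsonable(seeds),
        "package_version": __version__,
    }
    (out_dir / "provenance.json").write_text(json.dumps(doc, indent=1))
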