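"""End-to-end pipeline helpers: corpus -> sparse codes -> spikegram features
-> classifier experiment.

``scene_learning_experiment`` is the package's scaled-down learning check: a
balanced synthetic corpus is encoded with matching pursuit, rasterized, and a
single train/test repetition of the scene CNN is run.  The default sizes
(2-s segments, K = 205 — the 10-s default K = 1024 scaled by duration — and a
25-ms raster over a 64-filter bank) keep one repetition tractable on a
laptop-class CPU while exercising every stage of the real pipeline.
"""

from __future__ import annotations

import logging

import numpy as np

from .classifier import CnnArchitecture, EvaluationReport, TrainingConfig, repeated_experiment
from .gammatone import GammatoneFilterbank, build_filterbank
from .sparse import matching_pursuit, rasterize_with_shape
from .synth import generate_corpus

log = logging.getLogger("hearkit")

__all__ = ["encode_records", "scene_learning_experiment"]


def encode_records(
    records,
    bank: GammatoneFilterbank,
    K: int,
    bin_width: int,
    transform: str = "log1p",
) -> np.ndarray:
    """Matching-pursuit encode + rasterize a list of SceneRecords -> (n, M, T)."""
    feats = []
    for i, rec in enumerate(records):
        code = matching_pursuit(rec.audio, bank, K)
        feat = rasterize_with_shape(code, bin_width, transform, n_filters=len(bank))
        feats.append(feat.grid)
        if (i + 1) % 50 == 0:
            log.info("encoded %d/%d segments", i + 1, len(records))
    return np.stack(feats)


def scene_learning_experiment(
    seed: int,
    n_per_class: int = 40,
    duration: float = 2.0,
    sample_rate: float = 16_000,
    K: int = 205,
    bin_ms: float = 25.0,
    M: int = 64,
    n_repetitions: int = 1,
    max_epochs: int = 25,
) -> EvaluationReport:
    """Generate, encode and classify a balanced synthetic scene corpus.

    Returns the :class:`EvaluationReport` of ``n_repetitions`` train/test
    runs at the scaled problem size.
    """
    records, _ = generate_corpus(
        n_per_class, seed=seed, duration=duration, sample_rate=sample_rate
    )
    labels_txt = [r.label for r in records]
    classes = sorted(set(labels_txt))
    y = np.array([classes.index(l) for l in labels_txt])
    bank = build_filterbank(M=M, sample_rate=sample_rate)
    bin_width = int(round(bin_ms / 1000.0 * sample_rate))
    log.info("encoding %d segments (K=%d, M=%d)", len(records), K, M)
    x = encode_records(records, bank, K=K, bin_width=bin_width)
    config = TrainingConfig(
        max_epochs=max_epochs,
        patience=min(10, max_epochs - 1),
        n_repetitions=n_repetitions,
        seed=seed,
    )
    arch = CnnArchitecture(n_classes=len(classes))
    log.info("training CNN on features %s", x.shape)
    return repeated_experiment(x, y, arch=arch, config=config, class_labels=classes)
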