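"""Gammatone filter dictionary.

The Gammatone filter is the standard linear model of basilar-membrane
frequency analysis: its impulse response is a gamma-distribution envelope
``t^(n-1) exp(-2 pi b t)`` modulating a tone at the centre frequency.  A bank
of such filters serves two roles here: as an auditory-periphery model and as
the dictionary for sparse matching-pursuit coding of audio.

Bandwidths follow the Glasberg & Moore equivalent-rectangular-bandwidth (ERB)
convention, ``ERB(f) = 24.7 (4.37 f / 1000 + 1)`` Hz, with the usual 4th-order
Gammatone scaling ``b = 1.019 ERB(f)``.  Centre frequencies are spaced
uniformly on the ERB-rate scale, the psychoacoustically natural frequency
axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GammatoneFilter",
    "GammatoneFilterbank",
    "build_filterbank",
    "atom_waveform",
    "erb_bandwidth",
    "hz_to_erb_rate",
    "erb_rate_to_hz",
    "erb_space",
    "save_filterbank",
    "load_filterbank",
]

DEFAULT_SAMPLE_RATE = 16_000
DEFAULT_FMIN = 80.0
GAMMATONE_ORDER = 4
#: truncate the impulse response where the gamma envelope has fallen this far
#: below its peak (amplitude dB); the discarded tail carries < 1e-6 of the
#: atom energy
TRUNCATION_DB = 60.0


def erb_bandwidth(frequency_hz):
    """Equivalent rectangular bandwidth (Hz) at ``frequency_hz`` (Glasberg & Moore)."""
    return 24.7 * (4.37 * np.asarray(frequency_hz) / 1000.0 + 1.0)


def hz_to_erb_rate(frequency_hz):
    """Map frequency in Hz to the ERB-rate (ERB-number) scale."""
    return 21.4 * np.log10(4.37 * np.asarray(frequency_hz) / 1000.0 + 1.0)


def erb_rate_to_hz(erb_rate):
    """Inverse of :func:`hz_to_erb_rate`."""
    return (10.0 ** (np.asarray(erb_rate) / 21.4) - 1.0) * 1000.0 / 4.37


def erb_space(fmin: float, fmax: float, n: int) -> np.ndarray:
    """``n`` frequencies from ``fmin`` to ``fmax`` uniform on the ERB-rate scale."""
    rates = np.linspace(hz_to_erb_rate(fmin), hz_to_erb_rate(fmax), n)
    hz = erb_rate_to_hz(rates)
    # pin the endpoints exactly despite round-trip rounding
    hz[0], hz[-1] = fmin, fmax
    return hz


@dataclass(frozen=True)
class GammatoneFilter:
    """One unit-norm Gammatone atom prototype.

    ``impulse_response`` is sampled at the bank's working rate and normalised
    to unit Euclidean norm so that inner products with it are amplitudes.
    """

    index: int
    center_frequency: float
    bandwidth: float
    impulse_response: np.ndarray = field(repr=False)

    def __post_init__(self):
        ir = np.asarray(self.impulse_response, dtype=np.float64)
        if ir.ndim != 1 or ir.size == 0 or not np.all(np.isfinite(ir)):
            raise ValueError("impulse response must be a non-empty finite 1-D array")
        object.__setattr__(self, "impulse_response", ir)

    def __len__(self) -> int:
        return self.impulse_response.size


@dataclass(frozen=True)
class GammatoneFilterbank:
    """Ordered bank of ``M`` Gammatone filters sharing one sample rate."""

    sample_rate: float
    filters: tuple
    fmin: float
    fmax: float

    def __post_init__(self):
        cfs = np.array([f.center_frequency for f in self.filters])
        if len(self.filters) < 2:
            raise ValueError("a filterbank needs at least 2 filters")
        if np.any(np.diff(cfs) <= 0):
            raise ValueError("center frequencies must be strictly increasing")
        lo = self.fmin * (1 - 1e-9)
        hi = self.fmax * (1 + 1e-9)
        if cfs[0] < lo or cfs[-1] > hi:
            raise ValueError("center frequencies must lie within [fmin, fmax]")

    @property
    def size(self) -> int:
        return len(self.filters)

    @property
    def center_frequencies(self) -> np.ndarray:
        return np.array([f.center_frequency for f in self.filters])

    @property
    def max_ir_length(self) -> int:
        return max(len(f) for f in self.filters)

    def __len__(self) -> int:
        return len(self.filters)

    def __getitem__(self, i: int) -> GammatoneFilter:
        return self.filters[i]


def _gammatone_ir(cf: float, bandwidth: float, sample_rate: float) -> np.ndarray:
    """Unit-norm 4th-order Gammatone impulse response, truncated at -60 dB envelope."""
    b = 1.019 * bandwidth
    decay = 2.0 * np.pi * b
    order = GAMMATONE_ORDER
    t_peak = (order - 1) / decay
    # generous upper bound: past the peak the envelope decays at least like
    # exp(-decay t) once the polynomial factor saturates
    t_max = t_peak + (TRUNCATION_DB / 20.0 * np.log(10.0) + 3.0 * np.log(4.0)) / decay
    n = np.arange(1, max(int(np.ceil(t_max * sample_rate)), 4) + 1)
    t = n / sample_rate
    env = t ** (order - 1) * np.exp(-decay * t)
    peak = env.max()
    keep = np.nonzero(env >= peak * 10.0 ** (-TRUNCATION_DB / 20.0))[0]
    t = t[: keep[-1] + 1]
    ir = t ** (order - 1) * np.exp(-decay * t) * np.cos(2.0 * np.pi * cf * t)
    nrm = np.linalg.norm(ir)
    if nrm == 0.0:
        raise ValueError(f"degenerate Gammatone filter at {cf} Hz")
    return ir / nrm


def build_filterbank(
    M: int = 64,
    fmin: float = DEFAULT_FMIN,
    fmax: float | None = None,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> GammatoneFilterbank:
    """Construct an ``M``-filter Gammatone dictionary.

    Centre frequencies are ERB-rate-uniform on ``[fmin, fmax]`` (default
    ``fmax = 0.45 * sample_rate``); every impulse response is unit-norm.
    """
    if fmax is None:
        fmax = 0.45 * sample_rate
    if not isinstance(M, (int, np.integer)) or M < 2:
        raise ValueError("M must be an integer >= 2")
    if not (0.0 < fmin < fmax < sample_rate / 2.0):
        raise ValueError("require 0 < fmin < fmax < sample_rate/2")
    cfs = erb_space(fmin, fmax, M)
    filters = tuple(
        GammatoneFilter(
            index=i,
            center_frequency=float(cf),
            bandwidth=float(erb_bandwidth(cf)),
            impulse_response=_gammatone_ir(float(cf), float(erb_bandwidth(cf)), sample_rate),
        )
        for i, cf in enumerate(cfs)
    )
    return GammatoneFilterbank(sample_rate=float(sample_rate), filters=filters, fmin=float(fmin), fmax=float(fmax))


def atom_waveform(
    bank: GammatoneFilterbank, filter_index: int, time_offset: int, length: int
) -> np.ndarray:
    """Materialise one dictionary atom as a waveform of ``length`` samples.

    The filter's impulse response is shifted to start at ``time_offset`` and
    truncated at the end of the buffer; no renormalisation is applied.
    """
    if not 0 <= filter_index < len(bank):
        raise IndexError(f"filter_index {filter_index} out of range [0, {len(bank)})")
    if time_offset < 0:
        raise ValueError("time_offset must be >= 0")
    out = np.zeros(int(length))
    ir = bank[filter_index].impulse_response
    n = min(len(ir), length - time_offset)
    if n > 0:
        out[time_offset : time_offset + n] = ir[:n]
    return out


def save_filterbank(bank: GammatoneFilterbank, path) -> None:
    """Write a JSON sidecar describing the bank (codes stay interpretable)."""
    doc = {
        "sample_rate": bank.sample_rate,
        "M": len(bank),
        "fmin": bank.fmin,
        "fmax": bank.fmax,
        "filters": [
            {
                "index": f.index,
                "center_frequency_hz": f.center_frequency,
                "bandwidth_hz": f.bandwidth,
            }
            for f in bank.filters
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_filterbank(path) -> GammatoneFilterbank:
    """Rebuild a bank from its JSON sidecar (impulse responses are re-derived)."""
    doc = json.loads(Path(path).read_text())
    fs = doc["sample_rate"]
    filters = tuple(
        GammatoneFilter(
            index=f["index"],
            center_frequency=f["center_frequency_hz"],
            bandwidth=f["bandwidth_hz"],
            impulse_response=_gammatone_ir(f["center_frequency_hz"], f["bandwidth_hz"], fs),
        )
        for f in doc["filters"]
    )
    return GammatoneFilterbank(
        sample_rate=fs, filters=filters, fmin=doc["fmin"], fmax=doc["fmax"]
    )
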