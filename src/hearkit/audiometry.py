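"""Remote-audiometry simulation and paradigm comparison.

Simulates pure-tone threshold measurement with a modified Hughson–Westlake
staircase (10 dB down after a response, 5 dB up after a miss; the threshold is
the lowest level with >= 2 responses out of up to 3 ascending presentations)
against listeners with a probabilistic (logistic) psychometric response.

Two measurement paradigms — a clinical button press and a smartphone
app — differ only in reaction latency.  The latency converts to a level bias
through the paradigm's level sweep rate: a listener reacts to the tone they
heard ``latency`` seconds ago, so a slower response records a threshold
``latency * sweep_rate`` dB higher.  The comparison reports per-frequency
clinical-minus-remote differences with median, quartiles, extremes and
1.5-IQR outliers, mirroring a box-plot analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SimulatedListener",
    "AudiogramResult",
    "ParadigmComparison",
    "measure_audiogram",
    "compare_paradigms",
    "DEFAULT_FREQUENCIES",
]

#: the five audiometric test frequencies (Hz)
DEFAULT_FREQUENCIES = (500, 1000, 2000, 4000, 6000)
STEP_UP = 5.0
STEP_DOWN = 10.0
GRID_DB = 5.0
START_LEVEL = 40.0
LEVEL_MIN = -10.0
LEVEL_MAX = 120.0
#: level increase per second of reaction latency (dB/s); the clinical and app
#: paradigms share the sweep but differ in latency
DEFAULT_SWEEP_RATE = 5.0


@dataclass(frozen=True)
class SimulatedListener:
    """Ground-truth hearing of one virtual test subject.

    ``psychometric_slope`` is the logistic spread (dB) of the detection
    probability around threshold; ``lapse_rate`` the chance of missing a
    clearly audible tone.
    """

    true_thresholds: dict
    psychometric_slope: float = 2.0
    lapse_rate: float = 0.01

    def __post_init__(self):
        if self.psychometric_slope <= 0:
            raise ValueError("psychometric_slope must be > 0")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must be in [0, 0.1]")
        if not all(np.isfinite(list(self.true_thresholds.values()))):
            raise ValueError("thresholds must be finite")

    def respond(self, frequency: float, perceived_level: float, rng: np.random.Generator) -> bool:
        theta = self.true_thresholds[frequency]
        if self.psychometric_slope < 1e-6:
            # step limit: detect exactly when the perceived level reaches threshold
            p = 1.0 if perceived_level >= theta else 0.0
        else:
            p = float(expit((perceived_level - theta) / self.psychometric_slope))
        p *= 1.0 - self.lapse_rate
        return bool(rng.random() < p)


@dataclass
class AudiogramResult:
    """Thresholds (dB, on the 5-dB grid) for one listener under one paradigm."""

    paradigm: str
    thresholds: dict
    repetition_index: int = 0
    unmeasurable: list = field(default_factory=list)


@dataclass
class ParadigmComparison:
    """Per-frequency clinical − remote difference samples and their summary."""

    differences: pd.DataFrame  # columns: listener, repetition, frequency_hz, difference_db
    summary: pd.DataFrame  # per-frequency median/quartiles/extremes/outlier count

    def median(self, frequency: float) -> float:
        row = self.summary[self.summary.frequency_hz == frequency]
        return float(row.median_db.iloc[0])


def _staircase(
    listener: SimulatedListener,
    frequency: float,
    latency_bias_db: float,
    rng: np.random.Generator,
    max_presentations: int = 200,
) -> float:
    """Modified Hughson–Westlake threshold search; returns nan if unmeasurable."""
    level = START_LEVEL
    heard_at: dict[float, int] = {}
    seen_at: dict[float, int] = {}
    ascending = False
    for _ in range(max_presentations):
        heard = listener.respond(frequency, level - latency_bias_db, rng)
        if ascending and heard:
            seen_at[level] = seen_at.get(level, 0) + 1
            heard_at[level] = heard_at.get(level, 0) + 1
            if heard_at[level] >= 2:
                return level
        elif ascending:
            seen_at[level] = seen_at.get(level, 0) + 1
        if heard:
            level -= STEP_DOWN
            ascending = False
        else:
            level += STEP_UP
            ascending = True
        if level < LEVEL_MIN:
            level = LEVEL_MIN
            ascending = True
        if level > LEVEL_MAX:
            return np.nan
        # a level refuted in 3 ascents cannot become threshold; drop its tally
        for lv, cnt in list(seen_at.items()):
            if cnt >= 3 and heard_at.get(lv, 0) < 2:
                seen_at.pop(lv)
                heard_at.pop(lv, None)
    return np.nan


def measure_audiogram(
    listener: SimulatedListener,
    paradigm: str,
    frequencies=DEFAULT_FREQUENCIES,
    seed: int = 0,
    response_latency: float = 0.0,
    sweep_rate: float = DEFAULT_SWEEP_RATE,
    repetition_index: int = 0,
) -> AudiogramResult:
    """Measure one audiogram under one paradigm.

    ``response_latency * sweep_rate`` is the dB bias the paradigm's reaction
    time induces; thresholds land on the 5-dB grid by construction of the
    staircase.
    """
    if len(frequencies) == 0:
        raise ValueError("frequencies must be non-empty")
    rng = np.random.default_rng(seed)
    bias = response_latency * sweep_rate
    thresholds, unmeasurable = {}, []
    for f in frequencies:
        thr = _staircase(listener, f, bias, rng)
        if np.isnan(thr):
            unmeasurable.append(f)
        else:
            thresholds[f] = float(GRID_DB * round(thr / GRID_DB))
    return AudiogramResult(
        paradigm=paradigm,
        thresholds=thresholds,
        repetition_index=repetition_index,
        unmeasurable=unmeasurable,
    )


def _draw_listener(rng: np.random.Generator, frequencies) -> SimulatedListener:
    """A normal-hearing listener: thresholds ~ N(5, 5) dB HL, clipped to [-10, 20]."""
    thr = {f: float(np.clip(rng.normal(5.0, 5.0), -10.0, 20.0)) for f in frequencies}
    return SimulatedListener(true_thresholds=thr)


def compare_paradigms(
    n_listeners: int,
    n_repetitions: int = 3,
    latency_clinical: float = 0.0,
    latency_remote: float = 0.0,
    seed: int = 0,
    frequencies=DEFAULT_FREQUENCIES,
    sweep_rate: float = DEFAULT_SWEEP_RATE,
    listeners: list | None = None,
) -> ParadigmComparison:
    """Simulate both paradigms on a cohort and compare them per frequency.

    Each listener is measured ``n_repetitions`` times under each paradigm;
    differences are clinical − remote, paired by repetition.  The summary
    gives median, 25/75 percentiles, min/max and the count of points beyond
    1.5 IQR from the quartiles.
    """
    if n_listeners < 1:
        raise ValueError("n_listeners must be >= 1")
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss)
    if listeners is None:
        listeners = [_draw_listener(master, frequencies) for _ in range(n_listeners)]
    rows = []
    for li, listener in enumerate(listeners):
        for rep in range(n_repetitions):
            s_clin, s_rem = master.integers(2**31, size=2)
            clin = measure_audiogram(
                listener, "clinical", frequencies, seed=int(s_clin),
                response_latency=latency_clinical, sweep_rate=sweep_rate, repetition_index=rep,
            )
            rem = measure_audiogram(
                listener, "remote_app", frequencies, seed=int(s_rem),
                response_latency=latency_remote, sweep_rate=sweep_rate, repetition_index=rep,
            )
            for f in frequencies:
                if f in clin.thresholds and f in rem.thresholds:
                    rows.append(
                        {
                            "listener": li,
                            "repetition": rep,
                            "frequency_hz": f,
                            "difference_db": clin.thresholds[f] - rem.thresholds[f],
                        }
                    )
    diffs = pd.DataFrame(rows)
    summaries = []
    for f in frequencies:
        d = diffs.loc[diffs.frequency_hz == f, "difference_db"].to_numpy()
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        iqr = q3 - q1
        outliers = int(np.sum((d < q1 - 1.5 * iqr) | (d > q3 + 1.5 * iqr)))
        summaries.append(
            {
                "frequency_hz": f,
                "n": d.size,
                "median_db": med,
                "q25_db": q1,
                "q75_db": q3,
                "min_db": d.min(),
                "max_db": d.max(),
                "n_outliers": outliers,
            }
        )
    return ParadigmComparison(differences=diffs, summary=pd.DataFrame(summaries))
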