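"""Synthetic multi-channel scan generator with ground-truth timelines.

The simulator emulates the statistical structure the analysis pipeline
assumes, in arbitrary sensor units (real acoustic amplitudes are
uncalibrated, so envelope SNR is the controlled quantity):

* three movement classes realized as Gaussian-windowed sinusoids (Gabor
  atoms) with all spectral mass well below 10 Hz — startles ~1 s, most
  vigorous, 3-8 Hz; general movements longer and of moderate amplitude,
  1-5 Hz; breathing quasi-periodic low-amplitude burst trains at 0.5-1.5 Hz;
* per-channel proximity attenuation: each event originates at a random 2-D
  source on the abdomen plane and reaches channel c scaled by
  ``(d0 / (dist_c + d0)) ** attenuation``, so the nearest sensor sees it
  strongest;
* maternal-motion artefacts: correlated low-frequency content on all
  acoustic channels together with a >= 0.1 g transient on the accelerometer
  (riding on a 1 g gravity baseline), so the IMU-based exclusion has
  something to find;
* additive white Gaussian background noise per channel;
* an annotation timeline lagging the true events by a uniform 0.5-3.5 s
  reaction delay, so the tolerance-window matching rule recovers them.

Event counts per class are homogeneous Poisson processes; default rates are
the study-scale averages (startle 0.87/min, general 1.5/min, breathing
5.8/min over ~20-minute scans).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .intervals import Interval
from .io_formats import (
    Annotation,
    AnnotationTimeline,
    DataRecord,
    MovementType,
    SensorRecording,
)

__all__ = [
    "BurstModel",
    "ScanScenario",
    "TrueEvent",
    "default_burst_models",
    "simulate_scan",
    "sample_burst",
    "simulate_cohort",
    "CohortResult",
    "cohort_summary",
]

GA_RANGE_WEEKS = (24 + 3 / 7, 34 + 6 / 7)  # study inclusion window


@dataclass(frozen=True)
class BurstModel:
    """Waveform model for one movement class."""

    mtype: MovementType
    amplitude_range: tuple[float, float]
    duration_range: tuple[float, float]
    center_freq_range: tuple[float, float]
    bandwidth_hz: float = 1.0
    periodic: bool = False  # breathing: train of small atoms
    period_range: tuple[float, float] = (0.8, 1.5)

    def __post_init__(self) -> None:
        for lo, hi in (
            self.amplitude_range,
            self.duration_range,
            self.center_freq_range,
            self.period_range,
        ):
            if not 0 < lo <= hi:
                raise ConfigurationError(f"invalid range ({lo}, {hi})")
        if self.center_freq_range[1] >= 10.0:
            raise ConfigurationError("burst spectral mass must stay below 10 Hz")


def default_burst_models() -> dict[MovementType, BurstModel]:
    """Startle > general > breathe amplitude ordering, all bursts < 10 Hz."""
    return {
        MovementType.STARTLE: BurstModel(
            mtype=MovementType.STARTLE,
            amplitude_range=(8.0, 12.0),
            duration_range=(0.5, 1.5),
            center_freq_range=(3.0, 8.0),
        ),
        MovementType.GENERAL: BurstModel(
            mtype=MovementType.GENERAL,
            amplitude_range=(3.0, 6.0),
            duration_range=(1.0, 4.0),
            center_freq_range=(1.0, 5.0),
        ),
        MovementType.BREATHE: BurstModel(
            mtype=MovementType.BREATHE,
            amplitude_range=(0.8, 1.5),
            duration_range=(1.5, 3.5),
            center_freq_range=(0.5, 1.5),
            periodic=True,
            period_range=(0.8, 1.5),
        ),
    }


def _default_positions(n: int) -> tuple[tuple[float, float], ...]:
    # grid arrangement on the unit abdomen plane (paper template analogue)
    cols = math.ceil(math.sqrt(n))
    rows = math.ceil(n / cols)
    pts = []
    for i in range(n):
        r, c = divmod(i, cols)
        x = (c + 0.5) / cols
        y = (r + 0.5) / max(rows, 1)
        pts.append((x, y))
    return tuple(pts)


@dataclass(frozen=True)
class ScanScenario:
    """Everything needed to synthesize one scan, fully seeded."""

    seed: int
    duration_s: float = 1200.0
    n_acoustic: int = 6
    fs: float = 128.0
    rates_per_min: dict = field(
        default_factory=lambda: {
            MovementType.BREATHE: 5.8,
            MovementType.GENERAL: 1.5,
            MovementType.STARTLE: 0.87,
        }
    )
    sensor_positions: Optional[tuple[tuple[float, float], ...]] = None
    source_attenuation: float = 1.5
    attenuation_floor: float = 0.1  # d0 regularizer in (d0/(d+d0))^alpha
    maternal_event_rate_per_min: float = 0.5
    maternal_amplitude_g: float = 0.3
    maternal_acoustic_amplitude: float = 2.0
    probe_move_rate_per_min: float = 0.05
    noise_sigma: float = 0.3
    reaction_delay_range_s: tuple[float, float] = (0.5, 3.5)
    burst_models: dict = field(default_factory=default_burst_models)
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        if not 1 <= self.n_acoustic <= 8:
            raise ConfigurationError("n_acoustic must be in 1..8")
        if any(r < 0 for r in self.rates_per_min.values()):
            raise ConfigurationError("event rates must be >= 0")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ConfigurationError("duration_s and fs must be > 0")
        if self.sensor_positions is None:
            object.__setattr__(
                self, "sensor_positions", _default_positions(self.n_acoustic)
            )
        if len(self.sensor_positions) != self.n_acoustic:
            raise ConfigurationError("one sensor position per acoustic channel")

    def expected_counts(self) -> dict[MovementType, float]:
        return {
            m: self.rates_per_min.get(m, 0.0) * self.duration_s / 60.0
            for m in MovementType
        }


@dataclass(frozen=True)
class TrueEvent:
    """Ground truth: where and when a movement actually happened."""

    t: float
    mtype: MovementType
    source: tuple[float, float]
    duration: float
    amplitude: float
    center_freq: float
    period: float = 0.0  # breathing inner period; 0 for single bursts

    @property
    def interval(self) -> Interval:
        return Interval(max(0.0, self.t), self.t + self.duration)


def _draw_events(scenario: ScanScenario, rng: np.random.Generator) -> list[TrueEvent]:
    """Poisson event draw; shared verbatim by scan synthesis and cohort tallies."""
    events: list[TrueEvent] = []
    for mtype in MovementType:  # fixed iteration order for determinism
        model = scenario.burst_models[mtype]
        lam = scenario.rates_per_min.get(mtype, 0.0) * scenario.duration_s / 60.0
        n = int(rng.poisson(lam)) if lam > 0 else 0
        max_dur = model.duration_range[1]
        if scenario.duration_s <= max_dur:
            raise ValidationError("scan shorter than the longest burst")
        for _ in range(n):
            dur = float(rng.uniform(*model.duration_range))
            t = float(rng.uniform(0.0, scenario.duration_s - dur))
            events.append(
                TrueEvent(
                    t=t,
                    mtype=mtype,
                    source=(float(rng.uniform()), float(rng.uniform())),
                    duration=dur,
                    amplitude=float(rng.uniform(*model.amplitude_range)),
                    center_freq=float(rng.uniform(*model.center_freq_range)),
                    period=float(rng.uniform(*model.period_range))
                    if model.periodic
                    else 0.0,
                )
            )
    # capacity check: no single class may be expected to fill the whole scan
    # (classes can overlap each other, so the bound is per type)
    for m in MovementType:
        busy = (
            scenario.rates_per_min.get(m, 0.0)
            * scenario.duration_s
            / 60.0
            * float(np.mean(scenario.burst_models[m].duration_range))
        )
        if busy > scenario.duration_s:
            raise ValidationError(
                f"expected {m.value} event time {busy:.0f} s exceeds scan "
                f"duration {scenario.duration_s:.0f} s"
            )
    return sorted(events, key=lambda e: e.t)


def sample_burst(
    model: BurstModel, fs: float, rng: np.random.Generator, noise_sigma: float = 0.3
) -> np.ndarray:
    """Draw one standalone burst waveform from a movement-class model.

    Duration, centre frequency, amplitude (and period, for periodic models)
    are sampled from the model's ranges; white noise at ``noise_sigma`` is
    added, as in a recorded channel.  Used to study class separability
    without synthesizing whole scans.
    """
    dur = float(rng.uniform(*model.duration_range))
    freq = float(rng.uniform(*model.center_freq_range))
    amp = float(rng.uniform(*model.amplitude_range))
    n = max(int(dur * fs), 8)
    t = np.arange(n) / fs
    if model.periodic:
        period = float(rng.uniform(*model.period_range))
        x = np.zeros(n)
        for j in range(max(1, int(dur / period))):
            c = (j + 0.5) * period
            x += _gabor(t, c, min(period, 1.0), freq, float(rng.uniform(0, 2 * np.pi)))
        x *= amp
    else:
        x = amp * _gabor(t, dur / 2, dur, freq, float(rng.uniform(0, 2 * np.pi)))
    if noise_sigma > 0:
        x = x + rng.normal(0.0, noise_sigma, size=n)
    return x


def _gabor(t: np.ndarray, t0: float, dur: float, freq: float, phase: float) -> np.ndarray:
    sigma = dur / 6.0  # +/-3 sigma spans the nominal duration
    return np.exp(-0.5 * ((t - t0) / sigma) ** 2) * np.sin(
        2 * np.pi * freq * (t - t0) + phase
    )


def _inject_event(
    acoustic: np.ndarray,
    times: np.ndarray,
    ev: TrueEvent,
    scenario: ScanScenario,
    rng: np.random.Generator,
) -> None:
    fs = scenario.fs
    i0 = max(0, int((ev.t - 1.0) * fs))
    i1 = min(times.size, int((ev.t + ev.duration + 1.0) * fs))
    tt = times[i0:i1]
    if ev.period > 0:  # breathing: train of small atoms, one per period
        wave = np.zeros_like(tt)
        n_atoms = max(1, int(ev.duration / ev.period))
        for j in range(n_atoms):
            c = ev.t + (j + 0.5) * ev.period
            wave += _gabor(tt, c, min(ev.period, 1.0), ev.center_freq,
                           float(rng.uniform(0, 2 * np.pi)))
    else:
        center = ev.t + ev.duration / 2.0
        wave = _gabor(tt, center, ev.duration, ev.center_freq,
                      float(rng.uniform(0, 2 * np.pi)))
    d0 = scenario.attenuation_floor
    for c, (px, py) in enumerate(scenario.sensor_positions):
        dist = math.hypot(ev.source[0] - px, ev.source[1] - py)
        scale = (d0 / (dist + d0)) ** scenario.source_attenuation
        acoustic[c, i0:i1] += ev.amplitude * scale * wave


def simulate_scan(
    scenario: ScanScenario,
) -> tuple[SensorRecording, AnnotationTimeline, list[TrueEvent]]:
    """Synthesize one scan: recording, lagged annotation timeline, ground truth."""
    rng = np.random.default_rng(scenario.seed)
    events = _draw_events(scenario, rng)
    n = int(round(scenario.duration_s * scenario.fs))
    times = np.arange(n) / scenario.fs
    acoustic = rng.normal(0.0, scenario.noise_sigma, size=(scenario.n_acoustic, n))
    accel = np.zeros((3, n))
    accel[2] = 1.0  # gravity baseline, g
    accel += rng.normal(0.0, 0.005, size=(3, n))

    for ev in events:
        _inject_event(acoustic, times, ev, scenario, rng)

    # maternal motion: correlated low-frequency content + accelerometer transient
    lam = scenario.maternal_event_rate_per_min * scenario.duration_s / 60.0
    n_maternal = int(rng.poisson(lam)) if lam > 0 else 0
    maternal_intervals = []
    for _ in range(n_maternal):
        dur = float(rng.uniform(1.0, 3.0))
        t0 = float(rng.uniform(0.0, scenario.duration_s - dur))
        i0, i1 = int(t0 * scenario.fs), int((t0 + dur) * scenario.fs)
        tt = times[i0:i1]
        env = np.sin(np.pi * (tt - t0) / dur) ** 2
        wobble = env * np.sin(2 * np.pi * 0.8 * (tt - t0) + rng.uniform(0, 2 * np.pi))
        acoustic[:, i0:i1] += scenario.maternal_acoustic_amplitude * wobble
        axis = int(rng.integers(0, 3))
        accel[axis, i0:i1] += scenario.maternal_amplitude_g * env
        maternal_intervals.append(Interval(t0, t0 + dur))

    # probe repositioning intervals (noted, not injected)
    lam_p = scenario.probe_move_rate_per_min * scenario.duration_s / 60.0
    probe_moves = []
    for _ in range(int(rng.poisson(lam_p)) if lam_p > 0 else 0):
        dur = float(rng.uniform(10.0, 30.0))
        t0 = float(rng.uniform(0.0, max(1e-6, scenario.duration_s - dur)))
        probe_moves.append(Interval(t0, t0 + dur))

    lo, hi = scenario.reaction_delay_range_s
    annotations = [
        Annotation(
            t=min(scenario.duration_s, ev.t + float(rng.uniform(lo, hi))),
            mtype=ev.mtype,
        )
        for ev in events
    ]
    recording = SensorRecording(
        subject_id=scenario.subject_id,
        acoustic=acoustic,
        accel=accel,
        fs=scenario.fs,
    )
    timeline = AnnotationTimeline(annotations=annotations, probe_moves=probe_moves)
    return recording, timeline, events


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortResult:
    record: DataRecord
    scenarios: list[ScanScenario]
    events: list[list[TrueEvent]]


def simulate_cohort(
    n_subjects: int,
    base_scenario: Optional[ScanScenario] = None,
    seed: int = 0,
    ga_breathing_effect: float = 0.15,
    subject_rate_sigma: float = 0.4,
) -> CohortResult:
    """Draw a cohort of subjects with per-subject scan scenarios.

    Gestational ages are uniform over the study inclusion window
    (24+3 to 34+6 weeks).  The breathing event rate increases log-linearly
    with gestational age (``ga_breathing_effect`` per week; 0 disables the
    dependence) on top of lognormal between-subject heterogeneity, so a
    Spearman analysis of breathing count vs gestational age has recoverable
    signal.  Counts in the returned table are tallies of each subject's
    ground-truth event draw; recordings can be synthesized on demand with
    :func:`simulate_scan` on the stored scenarios.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    if base_scenario is None:
        base_scenario = ScanScenario(seed=0)
    master = np.random.default_rng(seed)
    ga_mid = sum(GA_RANGE_WEEKS) / 2
    scenarios: list[ScanScenario] = []
    all_events: list[list[TrueEvent]] = []
    rows = []
    child_seeds = master.integers(0, 2**31 - 1, size=n_subjects)
    for i in range(n_subjects):
        sub_rng = np.random.default_rng(int(child_seeds[i]))
        ga = float(sub_rng.uniform(*GA_RANGE_WEEKS))
        rates = dict(base_scenario.rates_per_min)
        het = {
            m: float(np.exp(sub_rng.normal(0.0, subject_rate_sigma)))
            for m in MovementType
        }
        rates[MovementType.BREATHE] = (
            rates[MovementType.BREATHE]
            * math.exp(ga_breathing_effect * (ga - ga_mid))
            * het[MovementType.BREATHE]
        )
        for m in (MovementType.GENERAL, MovementType.STARTLE):
            rates[m] = rates[m] * het[m]
        # keep each class physically plausible: expected duty cycle <= 80%
        for m in MovementType:
            mean_dur = float(np.mean(base_scenario.burst_models[m].duration_range))
            rates[m] = min(rates[m], 0.8 * 60.0 / mean_dur)
        scenario = replace(
            base_scenario,
            seed=int(sub_rng.integers(0, 2**31 - 1)),
            rates_per_min=rates,
            subject_id=f"S{i + 1:03d}",
        )
        events = _draw_events(scenario, np.random.default_rng(scenario.seed))
        all_events.append(events)
        scenarios.append(scenario)
        counts = {m: sum(1 for e in events if e.mtype == m) for m in MovementType}
        rows.append(
            {
                "subject_id": scenario.subject_id,
                "gestational_age": ga,
                "n_breathe": counts[MovementType.BREATHE],
                "n_general": counts[MovementType.GENERAL],
                "n_startle": counts[MovementType.STARTLE],
                "scan_duration_min": scenario.duration_s / 60.0,
                "bmi": float(sub_rng.normal(26.0, 4.0)),
                "deepest_vertical_pool": float(sub_rng.normal(5.0, 1.5)),
                "estimated_fetal_weight": float(
                    np.exp(0.15 * ga) * 20.0 * sub_rng.lognormal(0.0, 0.1)
                ),
                "mca_pi": float(sub_rng.normal(2.0, 0.3)),
                "ua_pi": float(sub_rng.normal(1.0, 0.2)),
            }
        )
    record = DataRecord(table=pd.DataFrame(rows))
    return CohortResult(record=record, scenarios=scenarios, events=all_events)


def cohort_summary(
    record: DataRecord,
    factors: Optional[Sequence[str]] = None,
    seed: int = 0,
    n_perm: int = 999,
) -> dict:
    """Cohort summary: per-type totals/distributions and Spearman correlations.

    Each movement-type count is rank-correlated (average ranks on ties)
    against gestational age and every supplied factor column; p-values come
    from a seeded permutation test with ``n_perm`` shuffles.  All-constant
    factors yield an absent (None) correlation.
    """
    df = record.table
    if len(df) < 1:
        raise ValidationError("empty data record")
    if factors is None:
        factors = [c for c in ("bmi", "deepest_vertical_pool",
                               "estimated_fetal_weight", "mca_pi", "ua_pi")
                   if c in df.columns]
    rng = np.random.default_rng(seed)
    count_cols = ("n_breathe", "n_general", "n_startle")
    summary: dict = {
        "n_subjects": len(df),
        "totals": record.totals(),
        "per_subject": {
            c: {
                "mean": float(df[c].mean()),
                "median": float(df[c].median()),
                "min": int(df[c].min()),
                "max": int(df[c].max()),
            }
            for c in count_cols
        },
        "spearman": {},
    }
    factor_cols = ["gestational_age"] + [f for f in factors if f in df.columns]
    for c in count_cols:
        summary["spearman"][c] = {}
        for fac in factor_cols:
            x = df[c].to_numpy(dtype=float)
            y = df[fac].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            if x.size < 3 or np.all(y == y[0]) or np.all(x == x[0]):
                summary["spearman"][c][fac] = {"rho": None, "p_value": None}
                continue
            rho = float(stats.spearmanr(x, y).statistic)
            perm = np.empty(n_perm)
            for b in range(n_perm):
                perm[b] = stats.spearmanr(x, rng.permutation(y)).statistic
            p = float((np.sum(np.abs(perm) >= abs(rho) - 1e-12) + 1) / (n_perm + 1))
            summary["spearman"][c][fac] = {"rho": rho, "p_value": p}
    return summary
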