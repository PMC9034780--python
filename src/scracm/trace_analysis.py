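"""Per-spot response measurement from raw voltage-clamp sweeps.

The measurement pipeline follows the mapping experiment's conventions:
each spot's trace is baselined on a 40 ms window before its stimulus and
averaged across trials; peak and area (charge) of the evoked current are
measured in a 50 ms window after the stimulus; a response counts as
significant when its peak exceeds seven times the baseline standard
deviation of the averaged trace.  Inward currents (EPSCs at -70 mV) are
reported with positive peak and charge.

QC rules: cells with series resistance above 40 MΩ are discarded, and
cells showing a low-latency direct photocurrent (onset within 2 ms of the
stimulus, indicating opsin expression in the recorded cell itself) are
flagged for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .session import RecordingSession


@dataclass
class AnalysisConfig:
    """Detection and QC parameters (durations in ms, currents in pA)."""

    baseline_window_ms: float = 40.0
    response_window_ms: float = 50.0
    detect_sd_mult: float = 7.0
    onset_sd_mult: float = 3.0
    onset_sustain_ms: float = 0.5
    direct_latency_ms: float = 2.0
    max_series_res_mohm: float = 40.0
    inward_sign: int = -1

    def __post_init__(self) -> None:
        for name in ("baseline_window_ms", "response_window_ms",
                     "detect_sd_mult", "onset_sd_mult", "direct_latency_ms",
                     "max_series_res_mohm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.detect_sd_mult < 1:
            raise ValueError("detect_sd_mult must be >= 1")
        if self.inward_sign not in (-1, 1):
            raise ValueError("inward_sign must be -1 or +1")


@dataclass
class SpotResponse:
    """Measured response of one grid spot (averaged across trials)."""

    spot_index: int
    peak_pa: float
    charge_pc: float
    baseline_sd_pa: float
    significant: bool
    onset_latency_ms: float | None


@dataclass
class AveragedSegments:
    """Trial-averaged, baselined trace segments around each stimulus.

    ``segments[i]`` spans [-baseline_window, +response_window] around the
    stimulus of spot ``i``; index ``n_baseline`` is the stimulus sample.
    """

    segments: np.ndarray          # (n_spots, n_samples)
    full_field: np.ndarray | None  # (n_samples,) or None
    n_baseline: int
    sample_rate_hz: float

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate_hz


def _extract(sweep: np.ndarray, i0: int, n_b: int, n_r: int) -> np.ndarray:
    seg = sweep[i0 - n_b:i0 + n_r + 1]
    if len(seg) != n_b + n_r + 1:
        raise ValueError("stimulus too close to the sweep edge for the "
                         "baseline/response windows")
    return seg - seg[:n_b].mean()


def baseline_and_average(session: RecordingSession,
                         cfg: AnalysisConfig) -> AveragedSegments:
    """Baseline each spot's trace per trial and average across trials.

    Every spot must be present in every trial; a missing spot is reported
    with its spot and trial index.  The full-field events, when present,
    are averaged the same way.
    """
    fs = session.sample_rate_hz
    n_b = int(round(cfg.baseline_window_ms * fs / 1000.0))
    n_r = int(round(cfg.response_window_ms * fs / 1000.0))
    if n_b < 1 or n_r < 1:
        raise ValueError("baseline/response windows contain no samples")
    n_spots = session.n_spots
    acc = np.zeros((n_spots, n_b + n_r + 1))
    ff_acc = np.zeros(n_b + n_r + 1)
    n_ff = 0
    spots = session.schedule[~session.schedule["is_full_field"].astype(bool)]
    for trial in range(session.n_trials):
        sweep = np.asarray(session.sweeps[trial], dtype=float)
        grp = spots[spots["trial"] == trial]
        t_by_spot = dict(zip(grp["spot_index"], grp["t_ms"]))
        for s in range(n_spots):
            if s not in t_by_spot:
                raise ValueError(f"spot {s} missing from trial {trial}")
            i0 = int(round(t_by_spot[s] * fs / 1000.0))
            acc[s] += _extract(sweep, i0, n_b, n_r)
        ff = session.schedule[(session.schedule["trial"] == trial)
                              & session.schedule["is_full_field"].astype(bool)]
        for t in ff["t_ms"]:
            i0 = int(round(t * fs / 1000.0))
            ff_acc += _extract(sweep, i0, n_b, n_r)
            n_ff += 1
    acc /= session.n_trials
    full = ff_acc / n_ff if n_ff else None
    return AveragedSegments(acc, full, n_b, fs)


def measure_response(segment: np.ndarray, cfg: AnalysisConfig,
                     sample_rate_hz: float, n_baseline: int,
                     spot_index: int = -1) -> SpotResponse:
    """Measure peak, charge and significance of one averaged segment.

    Peak is the maximum of the inward-rectified trace over the response
    window; charge is its trapezoidal integral converted to pC; the
    response is significant when peak exceeds ``detect_sd_mult`` times the
    baseline SD.  Onset latency is the first crossing of
    ``onset_sd_mult`` x SD after the stimulus that stays above threshold
    for ``onset_sustain_ms`` (None if never crossed); the sustain
    requirement keeps single noise samples from faking sub-millisecond
    onsets.
    """
    segment = np.asarray(segment, dtype=float)
    if len(segment) <= n_baseline + 1:
        raise ValueError("segment has an empty response window")
    dt_ms = 1000.0 / sample_rate_hz
    resp = cfg.inward_sign * segment[n_baseline:]
    peak = float(resp.max())
    charge = float(np.trapezoid(resp, dx=dt_ms)) / 1000.0  # pA*ms -> pC
    sd = float(segment[:n_baseline].std())
    significant = peak > cfg.detect_sd_mult * sd
    threshold = cfg.onset_sd_mult * sd if sd > 0 else 0.0
    n_sustain = max(1, int(round(cfg.onset_sustain_ms * sample_rate_hz / 1000.0)))
    above = resp > threshold
    if len(above) >= n_sustain and n_sustain > 1:
        runs = np.convolve(above.astype(int), np.ones(n_sustain, dtype=int),
                           mode="valid") == n_sustain
        hits = np.nonzero(runs)[0]
    else:
        hits = np.nonzero(above)[0]
    onset = float(hits[0] * dt_ms) if len(hits) else None
    return SpotResponse(spot_index, peak, charge, sd, bool(significant), onset)


def measure_all(avg: AveragedSegments, cfg: AnalysisConfig) -> list[SpotResponse]:
    """Measure every spot of an averaged session."""
    return [measure_response(avg.segments[i], cfg, avg.sample_rate_hz,
                             avg.n_baseline, spot_index=i)
            for i in range(avg.segments.shape[0])]


def flag_direct_photocurrent(responses: list[SpotResponse],
                             cfg: AnalysisConfig) -> bool:
    """True when any significant spot responds faster than a synapse can.

    Direct (opsin-mediated) photocurrents follow the light pulse with
    sub-millisecond latency; a significant response with onset before
    ``direct_latency_ms`` marks the cell for exclusion.
    """
    return any(r.significant and r.onset_latency_ms is not None
               and r.onset_latency_ms < cfg.direct_latency_ms
               for r in responses)


def qc_filter(session: RecordingSession, cfg: AnalysisConfig) -> bool:
    """True (keep) unless series resistance exceeds the QC bound.

    The bound is strict: a cell at exactly the maximum is kept.
    """
    rs = session.series_resistance_mohm
    if rs is None or not np.isfinite(rs):
        raise ValueError("session has no series-resistance metadata")
    return rs <= cfg.max_series_res_mohm


def full_field_charge(session: RecordingSession, cfg: AnalysisConfig) -> float:
    """Trial-averaged, baselined charge (pC) of the full-field stimulus."""
    avg = baseline_and_average(session, cfg)
    if avg.full_field is None:
        raise ValueError("session contains no full-field events")
    r = measure_response(avg.full_field, cfg, avg.sample_rate_hz, avg.n_baseline)
    return r.charge_pc


@dataclass
class CorrelationReport:
    """Pearson correlation between input-peak depth and total charge."""

    r: float
    p: float
    n: int
    degenerate: bool = False


def detection_bias_check(cells: list[tuple[float, float]]) -> CorrelationReport:
    """Test for distance-dependent detection bias across cells.

    ``cells`` pairs each cell's largest-input-peak depth (µm) with its
    full-field charge (pC).  A significant correlation would indicate that
    weak total input biases maps toward the soma; zero variance in either
    variable makes r undefined and is flagged.
    """
    if len(cells) < 3:
        raise ValueError("need at least 3 cells for a correlation")
    depth = np.array([c[0] for c in cells], dtype=float)
    charge = np.array([c[1] for c in cells], dtype=float)
    if np.ptp(depth) == 0 or np.ptp(charge) == 0:
        return CorrelationReport(np.nan, np.nan, len(cells), degenerate=True)
    r, p = stats.pearsonr(depth, charge)
    return CorrelationReport(float(r), float(p), len(cells))
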