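"""End-to-end helpers chaining the analysis stages.

These are the paths the examples, the command-line interface and the
validation studies use: analyse one session from raw sweeps to an input
map, build the average morphology profile from a set of reconstructions,
and run whole simulated cohorts for parameter-recovery and false-positive
studies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .allocation import AllocationResult, allocate
from .map_builder import InputMap, Profile1D, build_map, vertical_profile
from .morphology import MorphProfile, Morphology, average_profiles, length_profile
from .session import RecordingSession
from .summary_report import CellResult
from .synthetic_data import SimSpec, generate_morphology, simulate_session
from .trace_analysis import (AnalysisConfig, SpotResponse, baseline_and_average,
                             flag_direct_photocurrent, full_field_charge,
                             measure_all, measure_response, qc_filter)


@dataclass
class CellAnalysis:
    """Raw-to-map analysis of one recorded cell."""

    responses: list[SpotResponse]
    input_map: InputMap
    total_pc: float
    qc_keep: bool
    direct_photocurrent: bool
    soma_depth_um: float

    def cell_result(self) -> CellResult:
        return CellResult(self.input_map, self.total_pc, self.soma_depth_um)


def analyze_session(session: RecordingSession,
                    cfg: AnalysisConfig | None = None) -> CellAnalysis:
    """Run the full per-cell analysis: baseline, detect, map, total charge."""
    cfg = cfg or AnalysisConfig()
    avg = baseline_and_average(session, cfg)
    responses = measure_all(avg, cfg)
    input_map = build_map(responses, session)
    if avg.full_field is not None:
        total = measure_response(avg.full_field, cfg, avg.sample_rate_hz,
                                 avg.n_baseline).charge_pc
    else:
        total = float("nan")
    return CellAnalysis(responses, input_map, total,
                        qc_filter(session, cfg),
                        flag_direct_photocurrent(responses, cfg),
                        session.soma_depth_um)


def average_morphology_profile(n: int = 11, seed: int = 0,
                               soma_depth_mean_um: float = 500.0,
                               soma_depth_sd_um: float = 30.0,
                               bin_um: float = 10.0) -> MorphProfile:
    """Average dendritic length profile over ``n`` generated morphologies.

    Soma depths are drawn around the cohort mean, profiles are pia-aligned,
    rescaled to the mean soma–pia distance and averaged — the synthetic
    analogue of an averaged set of reconstructed neurons.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    for k in range(n):
        depth = float(np.clip(rng.normal(soma_depth_mean_um, soma_depth_sd_um),
                              250.0, 750.0))
        morph = generate_morphology(depth, seed=int(rng.integers(2 ** 31)))
        profiles.append(length_profile(morph, bin_um=bin_um))
    return average_profiles(profiles, soma_depth_mean_um)


def simulate_cell(spec: SimSpec, seed: int,
                  soma_depth_um: float | None = None) -> tuple[RecordingSession, Morphology]:
    """Generate one cell's morphology and its simulated session."""
    rng = np.random.default_rng(seed)
    depth = soma_depth_um if soma_depth_um is not None else \
        float(np.clip(rng.normal(spec.soma_depth_um, 30.0), 250.0, 750.0))
    morph = generate_morphology(depth, seed=int(rng.integers(2 ** 31)))
    spec = replace(spec, soma_depth_um=depth)
    session, _ = simulate_session(spec, morph, seed=int(rng.integers(2 ** 31)))
    return session, morph


def recover_cell_targeting(spec: SimSpec, seed: int,
                           avg_morph: MorphProfile,
                           cfg: AnalysisConfig | None = None
                           ) -> tuple[tuple[float, float, float], CellAnalysis]:
    """Simulate one cell and recover its compartment split end to end.

    The session is analysed with the detection pipeline, the map's
    pia-aligned vertical profile is allocated against the average
    morphology rescaled to the cell's soma–pia distance.
    """
    session, morph = simulate_cell(spec, seed)
    analysis = analyze_session(session, cfg)
    vprof = vertical_profile(analysis.input_map, align="pia")
    alloc = allocate(vprof, avg_morph, soma_pia_um=session.soma_depth_um)
    return alloc.proportions, analysis


def targeting_recovery(spec: SimSpec, seeds: list[int],
                       avg_morph: MorphProfile | None = None
                       ) -> tuple[np.ndarray, float]:
    """Recover the targeting triple over several simulated cells.

    Returns the (n_seeds, 3) matrix of recovered proportions and the mean
    absolute error against the ground-truth targeting.
    """
    avg_morph = avg_morph if avg_morph is not None else average_morphology_profile()
    recovered = np.array([recover_cell_targeting(spec, s, avg_morph)[0]
                          for s in seeds])
    mae = float(np.mean(np.abs(recovered - np.asarray(spec.targeting))))
    return recovered, mae


def noise_false_positive_rate(seeds: list[int],
                              spec: SimSpec | None = None,
                              cfg: AnalysisConfig | None = None) -> float:
    """Fraction of spots called significant on sessions with no synapses."""
    spec = spec or SimSpec(total_charge_pc=0.0, n_trials=3)
    cfg = cfg or AnalysisConfig()
    n_sig = n_tot = 0
    for s in seeds:
        session, _ = simulate_cell(spec, s)
        analysis = analyze_session(session, cfg)
        n_sig += sum(r.significant for r in analysis.responses)
        n_tot += len(analysis.responses)
    return n_sig / n_tot
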