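"""Synthetic morphologies, axon profiles and simulated sCRACM sessions.

Every downstream stage of the pipeline is testable against known ground
truth: a stylised thick-tufted L5 morphology is generated, per-spot EPSC
charges are drawn from a chosen dendritic-targeting rule (charge at a grid
spot proportional to the dendritic length of the targeted compartments
inside that spot, times the compartment weight), and voltage-clamp sweeps
are synthesised with an EPSC-shaped kernel plus white Gaussian baseline
noise.  The per-spot charge matrix and the compartment split used are
returned as ground truth.

The stimulation protocol reproduces the mapping experiment: a 24 x 12 grid
of 41.7 µm spots (1000 µm along cortical depth x 500 µm horizontal), 1 ms
stimuli at 10 Hz in a pseudo-random order in which consecutive spots are
never grid neighbours, each trial ending with a full-field stimulus whose
noiseless charge equals the sum of all per-spot charges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry
from .morphology import Morphology, SWC_TYPE_SOMA
from .peters_rule import AxonProfile
from .session import RecordingSession

#: charge-measurement window after each stimulus (ms); the EPSC kernel is
#: confined to this window so that the windowed integral recovers the full
#: per-spot charge
RESPONSE_WINDOW_MS = 50.0

AXON_PATTERNS = ("FF", "FB_cortical", "FB_thalamic")


@dataclass
class SimSpec:
    """Parameters of one simulated mapping experiment.

    ``targeting`` is the ground-truth compartment weight triple
    (basal, oblique, tuft); it must be non-negative and sum to 1.
    """

    grid_depth_um: float = geometry.GRID_DEPTH_UM
    grid_width_um: float = geometry.GRID_WIDTH_UM
    n_rows: int = geometry.N_ROWS
    n_cols: int = geometry.N_COLS
    sample_rate_hz: float = 20_000.0
    stim_rate_hz: float = 10.0
    stim_dur_ms: float = 1.0
    n_trials: int = 8
    noise_sd_pa: float = 1.0
    epsc_rise_ms: float = 2.0
    epsc_decay_ms: float = 15.0
    synaptic_latency_ms: float = 3.0
    targeting: tuple[float, float, float] = (0.10, 0.15, 0.75)
    total_charge_pc: float = 8.0
    soma_depth_um: float = 500.0
    series_resistance_mohm: float = 15.0
    medial_sign: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("grid_depth_um", "grid_width_um", "sample_rate_hz",
                     "stim_rate_hz", "stim_dur_ms", "epsc_rise_ms", "epsc_decay_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_rows <= 0 or self.n_cols <= 0 or self.n_trials <= 0:
            raise ValueError("grid shape and n_trials must be positive")
        if not (0.0 <= self.synaptic_latency_ms < RESPONSE_WINDOW_MS):
            raise ValueError("synaptic_latency_ms must lie in [0, 50) ms")
        w = np.asarray(self.targeting, dtype=float)
        if w.shape != (3,) or np.any(w < 0):
            raise ValueError("targeting must be three non-negative weights")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"targeting weights must sum to 1, got {w.sum()!r}")
        if self.noise_sd_pa < 0 or self.total_charge_pc < 0:
            raise ValueError("noise_sd_pa and total_charge_pc must be non-negative")

    @property
    def spot_um(self) -> float:
        return self.grid_depth_um / self.n_rows

    @property
    def n_spots(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class GroundTruth:
    """What the simulator actually injected, for parameter-recovery tests."""

    per_spot_charge_pc: np.ndarray          # (n_rows, n_cols), native grid
    compartment_split: tuple[float, float, float]
    morphology_id: str

    @property
    def total_charge_pc(self) -> float:
        return float(self.per_spot_charge_pc.sum())

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"per_spot_charge_pc": self.per_spot_charge_pc.tolist(),
                       "compartment_split": list(self.compartment_split),
                       "morphology_id": self.morphology_id}, fh, indent=1)


# ---------------------------------------------------------------------------
# Morphology generator
# ---------------------------------------------------------------------------

class _TreeBuilder:
    def __init__(self) -> None:
        self.rows: list[tuple] = []
        self.labels: dict[int, str] = {}
        self._next = 1

    def add(self, swc_type: int, x: float, y: float, z: float, radius: float,
            parent: int, label: str) -> int:
        nid = self._next
        self._next += 1
        self.rows.append((nid, swc_type, x, y, z, radius, parent))
        self.labels[nid] = label
        return nid

    def path(self, swc_type: int, start_id: int, start_xy: tuple[float, float],
             steps: np.ndarray, label: str, radius: float = 0.6,
             y_min: float = 2.0, y_max: float = 1500.0) -> tuple[int, tuple[float, float]]:
        """Append a chain of nodes following per-step (dx, dy) displacements."""
        pid, (x, y) = start_id, start_xy
        for dx, dy in steps:
            x, y = x + dx, min(max(y + dy, y_min), y_max)
            pid = self.add(swc_type, x, y, 0.0, radius, pid, label)
        return pid, (x, y)


def generate_morphology(soma_depth_um: float, seed: int) -> Morphology:
    """Generate a stylised thick-tufted L5 pyramidal morphology.

    Basal dendrites radiate from the soma, the apical trunk ascends to a
    main bifurcation at roughly a third of the soma depth, obliques branch
    from the trunk, and the tuft fans out above the bifurcation towards the
    pia.  All tuft nodes lie strictly above the bifurcation by construction.
    Deterministic: the same (soma_depth_um, seed) yields a byte-identical
    SWC file.
    """
    if not (200.0 < soma_depth_um < 800.0):
        raise ValueError(
            f"soma_depth_um must lie in (200, 800) µm, got {soma_depth_um}")
    rng = np.random.default_rng(seed)
    d = float(soma_depth_um)
    bif = d * rng.uniform(0.32, 0.42)
    step = 10.0

    b = _TreeBuilder()
    soma = b.add(SWC_TYPE_SOMA, 0.0, d, 0.0, 8.0, -1, "soma")

    # apical trunk: soma -> bifurcation, slight lateral wobble
    ys = np.arange(d - step, bif, -step)
    ys = np.append(ys, bif)
    trunk_ids, trunk_y = [], []
    pid, x = soma, 0.0
    for y in ys:
        x += rng.normal(0.0, 1.2)
        x = float(np.clip(x, -25.0, 25.0))
        pid = b.add(4, x, float(y), 0.0, 1.5, pid, "oblique")
        trunk_ids.append(pid)
        trunk_y.append(float(y))
    bif_id, bif_xy = pid, (x, bif)

    # oblique branches off the trunk
    n_obl = int(rng.integers(3, 6))
    eligible = [i for i, y in enumerate(trunk_y) if bif + 40.0 < y < d - 30.0]
    for _ in range(n_obl):
        i = int(rng.choice(eligible))
        side = float(rng.choice([-1.0, 1.0]))
        theta = rng.uniform(-0.10, 0.30)          # >0 drifts towards the pia
        n_steps = int(rng.uniform(8, 15))
        steps = np.column_stack([np.full(n_steps, side * step * np.cos(theta)),
                                 np.full(n_steps, -step * np.sin(theta))])
        attach_xy = (float(b.rows[trunk_ids[i] - 1][2]), trunk_y[i])
        b.path(4, trunk_ids[i], attach_xy, steps, "oblique",
               y_min=bif + 5.0, y_max=d + 60.0)

    # tuft: two daughters at the bifurcation, each splitting once
    for side in (-1.0, 1.0):
        phi = rng.uniform(0.25, 0.50)             # angle from vertical
        n1 = int(rng.integers(6, 10))
        steps = np.column_stack([np.full(n1, side * step * np.sin(phi)),
                                 np.full(n1, -step * np.cos(phi))])
        mid_id, mid_xy = b.path(5, bif_id, bif_xy, steps, "tuft",
                                y_min=5.0, y_max=bif - 2.0)
        for dphi in (-rng.uniform(0.3, 0.6), rng.uniform(0.3, 0.6)):
            phi2 = phi + dphi
            n2 = int(rng.integers(8, 14))
            steps2 = np.column_stack([np.full(n2, side * step * np.sin(phi2)),
                                      np.full(n2, -step * abs(np.cos(phi2)))])
            b.path(5, mid_id, mid_xy, steps2, "tuft", y_min=5.0, y_max=bif - 2.0)

    # basal dendrites radiating down / sideways from the soma
    n_bas = int(rng.integers(4, 7))
    for _ in range(n_bas):
        a = rng.uniform(-0.2, np.pi + 0.2)        # mostly below the horizontal
        n_steps = int(rng.uniform(9, 16))
        steps = np.column_stack([np.full(n_steps, step * np.cos(a)),
                                 np.full(n_steps, step * abs(np.sin(a)) * 0.9
                                         if np.sin(a) >= 0 else step * np.sin(a) * 0.3)])
        b.path(3, soma, (0.0, d), steps, "basal", y_min=bif + 10.0, y_max=d + 250.0)

    nodes = pd.DataFrame(b.rows, columns=["id", "type", "x", "y", "z",
                                          "radius", "parent"])
    return Morphology(nodes, b.labels, d, bif, morphology_id=f"sim-{seed}")


# ---------------------------------------------------------------------------
# Axon profile generator
# ---------------------------------------------------------------------------

def _gauss(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sd) ** 2)


def generate_axon_profile(pattern: str, n_bins: int,
                          depth_extent_um: float = geometry.GRID_DEPTH_UM,
                          area: str | None = None) -> AxonProfile:
    """Generate a laminar axon-density profile of a canonical pathway class.

    ``FF`` peaks in middle and deep layers with almost no L1 density;
    ``FB_thalamic`` peaks in the outermost tenth of the cortex with a
    secondary mid-depth peak; ``FB_cortical`` pairs a superficial peak with
    diffuse deep density.  Profiles are peak-normalised to 1.
    """
    if pattern not in AXON_PATTERNS:
        raise ValueError(f"unknown axon pattern {pattern!r}; "
                         f"expected one of {AXON_PATTERNS}")
    if n_bins < 10:
        raise ValueError(f"n_bins must be >= 10, got {n_bins}")
    edges = np.linspace(0.0, depth_extent_um, n_bins + 1)
    u = (0.5 * (edges[:-1] + edges[1:])) / depth_extent_um
    if pattern == "FF":
        dens = _gauss(u, 0.32, 0.07) + 0.85 * _gauss(u, 0.65, 0.10)
    elif pattern == "FB_thalamic":
        dens = _gauss(u, 0.03, 0.03) + 0.55 * _gauss(u, 0.30, 0.07)
    else:  # FB_cortical
        dens = _gauss(u, 0.07, 0.04) + 0.35 * _gauss(u, 0.60, 0.25)
    dens = dens / dens.max()
    return AxonProfile(edges, dens, area or pattern)


# ---------------------------------------------------------------------------
# Stimulus schedule
# ---------------------------------------------------------------------------

def stimulus_sequence(n_rows: int, n_cols: int, rng: np.random.Generator,
                      max_restarts: int = 1000) -> np.ndarray:
    """Pseudo-random spot order with no grid-adjacent consecutive spots.

    Spots are drawn sequentially, uniformly among the remaining spots that
    are not 8-neighbours of the previous one; rare dead ends trigger a
    restart.  Spot indices are row-major over the native grid.
    """
    n = n_rows * n_cols
    rows = np.arange(n) // n_cols
    cols = np.arange(n) % n_cols
    for _ in range(max_restarts):
        remaining = list(rng.permutation(n))
        seq = [remaining.pop()]
        ok = True
        while remaining:
            r0, c0 = rows[seq[-1]], cols[seq[-1]]
            cand = [i for i, s in enumerate(remaining)
                    if max(abs(rows[s] - r0), abs(cols[s] - c0)) > 1]
            if not cand:
                ok = False
                break
            pick = cand[int(rng.integers(len(cand)))]
            seq.append(remaining.pop(pick))
        if ok:
            return np.asarray(seq)
    raise RuntimeError("could not build a non-adjacent stimulus sequence")


# ---------------------------------------------------------------------------
# EPSC kernel and sweep synthesis
# ---------------------------------------------------------------------------

def epsc_kernel(sample_rate_hz: float, rise_ms: float, decay_ms: float,
                window_ms: float = RESPONSE_WINDOW_MS) -> np.ndarray:
    """Difference-of-exponentials EPSC kernel, confined to the charge window.

    The kernel is sampled on ``[0, window_ms]`` and normalised so that its
    trapezoidal integral over that window is exactly 1 ms⁻¹; scaling by a
    charge (in pC, times 1000) yields a current in pA whose windowed
    trapezoidal integral recovers the charge exactly for noiseless data.
    """
    dt_ms = 1000.0 / sample_rate_hz
    t = np.arange(0.0, window_ms + dt_ms / 2, dt_ms)
    k = np.exp(-t / decay_ms) - np.exp(-t / rise_ms)
    return k / np.trapezoid(k, dx=dt_ms)


def epsc_kernel_integral_closed_form(rise_ms: float, decay_ms: float,
                                     window_ms: float = RESPONSE_WINDOW_MS) -> float:
    """Closed-form integral of the unnormalised kernel over the window (ms)."""
    return (decay_ms * (1.0 - np.exp(-window_ms / decay_ms))
            - rise_ms * (1.0 - np.exp(-window_ms / rise_ms)))


def compartment_length_grid(morph: Morphology, spec: SimSpec,
                            sample_um: float = 2.0) -> dict[str, np.ndarray]:
    """Dendritic length of each compartment inside each native grid spot.

    The grid is horizontally centred on the soma (x = 0) with its top row at
    the pia (depth 0).  Segments are subdivided at ``sample_um`` resolution
    and each piece assigned to the spot containing its midpoint; pieces
    outside the grid are dropped.
    """
    spot = spec.spot_um
    half_w = spec.grid_width_um / 2.0
    grids = {c: np.zeros((spec.n_rows, spec.n_cols)) for c in ("basal", "oblique", "tuft")}
    for seg in morph.segments().itertuples(index=False):
        if seg.label not in grids:
            continue
        n_sub = max(1, int(np.ceil(seg.length / sample_um)))
        f = (np.arange(n_sub) + 0.5) / n_sub
        xs = seg.x0 + f * (seg.x1 - seg.x0)
        ys = seg.y0 + f * (seg.y1 - seg.y0)
        cols = np.floor((xs + half_w) / spot).astype(int)
        rows = np.floor(ys / spot).astype(int)
        ok = (cols >= 0) & (cols < spec.n_cols) & (rows >= 0) & (rows < spec.n_rows)
        np.add.at(grids[seg.label], (rows[ok], cols[ok]), seg.length / n_sub)
    return grids


def ground_truth_charges(morph: Morphology, spec: SimSpec) -> GroundTruth:
    """Per-spot charges implied by the targeting rule.

    Charge from compartment *c* at a spot is proportional to the length of
    *c* inside the spot; each compartment's in-grid total is scaled so that
    compartment totals equal ``targeting * total_charge_pc`` exactly.
    """
    grids = compartment_length_grid(morph, spec)
    q = np.zeros((spec.n_rows, spec.n_cols))
    for w, comp in zip(spec.targeting, ("basal", "oblique", "tuft")):
        if w <= 0:
            continue
        total_len = grids[comp].sum()
        if total_len <= 0:
            raise ValueError(
                f"targeting weight for {comp!r} is {w} but the morphology has "
                f"no {comp} dendrite inside the stimulation grid")
        q += w * spec.total_charge_pc * grids[comp] / total_len
    return GroundTruth(q, tuple(spec.targeting), morph.morphology_id)


def simulate_session(spec: SimSpec, morph: Morphology,
                     seed: int | None = None) -> tuple[RecordingSession, GroundTruth]:
    """Synthesise a full mapping session for one cell.

    Each trial stimulates all spots once in a fresh pseudo-random order and
    ends with a full-field stimulus carrying the summed charge.  Sweeps are
    the noiseless EPSC trains plus white Gaussian noise of
    ``spec.noise_sd_pa``.  EPSCs follow each stimulus after the synaptic
    latency; the kernel is shortened so it still lies wholly inside the
    50 ms charge window, keeping noiseless charge recovery exact.
    """
    if not (0.0 < spec.soma_depth_um < spec.grid_depth_um):
        raise ValueError("soma depth must lie inside the grid's depth extent")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    gt = ground_truth_charges(morph, spec)
    q_flat = gt.per_spot_charge_pc.ravel()
    q_total = gt.total_charge_pc

    fs = spec.sample_rate_hz
    isi_ms = 1000.0 / spec.stim_rate_hz
    pre_ms = 100.0
    ff_ms = pre_ms + spec.n_spots * isi_ms
    n_samples = int(round((ff_ms + isi_ms + pre_ms) * fs / 1000.0))
    kernel = epsc_kernel(fs, spec.epsc_rise_ms, spec.epsc_decay_ms,
                         window_ms=RESPONSE_WINDOW_MS - spec.synaptic_latency_ms)
    nk = len(kernel)
    lat = int(round(spec.synaptic_latency_ms * fs / 1000.0))

    sweeps, rows = [], []
    for trial in range(spec.n_trials):
        seq = stimulus_sequence(spec.n_rows, spec.n_cols, rng)
        if spec.noise_sd_pa > 0:
            sweep = rng.normal(0.0, spec.noise_sd_pa, n_samples)
        else:
            sweep = np.zeros(n_samples)
        for k, spot in enumerate(seq):
            t_ms = pre_ms + k * isi_ms
            i0 = int(round(t_ms * fs / 1000.0)) + lat
            if q_flat[spot] > 0:
                sweep[i0:i0 + nk] -= 1000.0 * q_flat[spot] * kernel
            rows.append((trial, int(spot), t_ms, False))
        i0 = int(round(ff_ms * fs / 1000.0)) + lat
        if q_total > 0:
            sweep[i0:i0 + nk] -= 1000.0 * q_total * kernel
        rows.append((trial, -1, ff_ms, True))
        sweeps.append(sweep)

    schedule = pd.DataFrame(rows, columns=["trial", "spot_index", "t_ms",
                                           "is_full_field"])
    pixel = spec.spot_um / 2.0
    session = RecordingSession(
        sweeps, schedule, sample_rate_hz=fs,
        soma_row=int(np.clip(morph.soma_depth_um // pixel, 0, 2 * spec.n_rows - 1)),
        soma_col=spec.n_cols,  # soma centred horizontally
        soma_depth_um=morph.soma_depth_um,
        medial_sign=spec.medial_sign,
        series_resistance_mohm=spec.series_resistance_mohm,
        pia_row=0, n_rows=spec.n_rows, n_cols=spec.n_cols)
    return session, gt
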