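"""Build, normalise, align, average and project 2D synaptic charge maps.

Maps live on the quadrant-resolution grid (48 depth rows x 24 horizontal
columns at 20.833 µm pitch, i.e. the native 24 x 12 spot grid upsampled
2x with charge split equally among the four quadrants of each spot).
Vertical profiles are reported either from the pia (positive into the
tissue) or from the soma (positive toward the pia); horizontal profiles
are signed from the soma column, positive medial.  All reported peak
locations are integer multiples of the 20.833 µm pitch before rounding
to whole µm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import PIXEL_SIZE_UM
from .session import RecordingSession
from .trace_analysis import SpotResponse


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (62.5 -> 63)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


@dataclass
class InputMap:
    """A quadrant-resolution charge map with its anatomical anchors.

    ``grid[row, col]`` is charge in pC (or normalised units); row 0 is the
    shallowest row.  ``soma_anchor`` and ``pia_row`` are quadrant indices;
    ``medial_sign`` is +1 when increasing column index points medially.
    """

    grid: np.ndarray
    pitch_um: float = PIXEL_SIZE_UM
    soma_anchor: tuple[int, int] = (0, 0)
    pia_row: int = 0
    medial_sign: int = 1

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(self.grid < 0):
            raise ValueError("charge maps must be non-negative")

    @property
    def total(self) -> float:
        return float(self.grid.sum())


@dataclass
class Profile1D:
    """A 1D projection of a map with an explicit axis convention.

    ``positions_um[i]`` is the signed distance of bin ``i`` from the axis
    anchor: depth-from-pia (positive into the tissue), depth-from-soma
    (positive toward the pia) or horizontal-from-soma (positive medial).
    """

    values: np.ndarray
    positions_um: np.ndarray
    axis: str
    pitch_um: float = PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.values.shape != self.positions_um.shape:
            raise ValueError("values and positions must align")

    def normalized(self) -> "Profile1D":
        peak = self.values.max()
        vals = self.values / peak if peak > 0 else self.values
        return Profile1D(vals, self.positions_um, self.axis, self.pitch_um)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position_um": self.positions_um,
                             "value": self.values, "axis": self.axis})


def build_map(responses: list[SpotResponse],
              session: RecordingSession) -> InputMap:
    """Place measured charges on the grid and upsample to quadrant pixels.

    Non-significant spots contribute zero charge; each native spot's charge
    is split equally among its four quadrant pixels, conserving the total.
    """
    n_spots = session.n_spots
    if len(responses) != n_spots:
        raise ValueError(f"expected {n_spots} responses, got {len(responses)}")
    native = np.zeros((session.n_rows, session.n_cols))
    for r in responses:
        if r.significant:
            native[r.spot_index // session.n_cols,
                   r.spot_index % session.n_cols] = max(r.charge_pc, 0.0)
    grid = np.kron(native, np.ones((2, 2))) / 4.0
    return InputMap(grid, pitch_um=PIXEL_SIZE_UM,
                    soma_anchor=(session.soma_row, session.soma_col),
                    pia_row=session.pia_row, medial_sign=session.medial_sign)


def normalize_map(m: InputMap) -> InputMap:
    """Divide by the peak pixel; an all-zero map passes through with a warning."""
    peak = m.grid.max()
    if peak <= 0:
        warnings.warn("all-zero input map; normalisation is a no-op")
        return InputMap(m.grid.copy(), m.pitch_um, m.soma_anchor,
                        m.pia_row, m.medial_sign)
    return InputMap(m.grid / peak, m.pitch_um, m.soma_anchor,
                    m.pia_row, m.medial_sign)


def align_and_average(maps: list[InputMap],
                      mode: str = "pia") -> tuple[InputMap, np.ndarray]:
    """Align maps at quadrant resolution and average pixel-wise.

    Maps are shifted so that the chosen vertical anchor (``pia`` or
    ``soma``) and the soma column coincide; the averaging canvas is the
    union of shifted extents and each pixel is divided by the number of
    maps that cover it.  Returns the average map and the coverage counts.
    """
    if not maps:
        raise ValueError("need at least one map to average")
    if mode not in ("pia", "soma"):
        raise ValueError(f"mode must be 'pia' or 'soma', got {mode!r}")
    if len({m.pitch_um for m in maps}) != 1:
        raise ValueError("maps must share a pixel pitch")
    v_anchor = [m.pia_row if mode == "pia" else m.soma_anchor[0] for m in maps]
    h_anchor = [m.soma_anchor[1] for m in maps]
    v_ref, h_ref = max(v_anchor), max(h_anchor)
    shifts = [(v_ref - va, h_ref - ha) for va, ha in zip(v_anchor, h_anchor)]
    n_rows = max(sr + m.grid.shape[0] for (sr, _), m in zip(shifts, maps))
    n_cols = max(sc + m.grid.shape[1] for (_, sc), m in zip(shifts, maps))
    acc = np.zeros((n_rows, n_cols))
    counts = np.zeros((n_rows, n_cols))
    for (sr, sc), m in zip(shifts, maps):
        h, w = m.grid.shape
        acc[sr:sr + h, sc:sc + w] += m.grid
        counts[sr:sr + h, sc:sc + w] += 1
    avg = np.divide(acc, counts, out=np.zeros_like(acc), where=counts > 0)
    soma_rows = [sr + m.soma_anchor[0] for (sr, _), m in zip(shifts, maps)]
    pia_rows = [sr + m.pia_row for (sr, _), m in zip(shifts, maps)]
    soma_row = v_ref if mode == "soma" else round_half_up(float(np.mean(soma_rows)))
    pia_row = v_ref if mode == "pia" else round_half_up(float(np.mean(pia_rows)))
    out = InputMap(avg, maps[0].pitch_um, (soma_row, h_ref), pia_row,
                   maps[0].medial_sign)
    return out, counts


def vertical_profile(m: InputMap, align: str = "pia") -> Profile1D:
    """Project a map along the horizontal axis (sum per depth bin)."""
    values = m.grid.sum(axis=1)
    idx = np.arange(len(values))
    if align == "pia":
        pos = (idx - m.pia_row) * m.pitch_um
        axis = "depth-from-pia"
    elif align == "soma":
        pos = (m.soma_anchor[0] - idx) * m.pitch_um  # positive toward pia
        axis = "depth-from-soma"
    else:
        raise ValueError(f"align must be 'pia' or 'soma', got {align!r}")
    return Profile1D(values, pos, axis, m.pitch_um)


def horizontal_profile(m: InputMap, row_weights: np.ndarray | None = None) -> Profile1D:
    """Project a map along the depth axis (sum per horizontal bin).

    ``row_weights`` optionally weights rows before summing (used to project
    only the part of the map attributable to one dendritic compartment).
    Positions are signed from the soma column, positive medial.
    """
    grid = m.grid if row_weights is None else m.grid * np.asarray(row_weights)[:, None]
    values = grid.sum(axis=0)
    idx = np.arange(len(values))
    pos = (idx - m.soma_anchor[1]) * m.pitch_um * m.medial_sign
    return Profile1D(values, pos, "horizontal-from-soma", m.pitch_um)


@dataclass
class PeakLocation:
    """A profile peak as raw signed distance and rounded report value."""

    raw_um: float
    rounded_um: int
    found: bool = True


NO_PEAK = PeakLocation(np.nan, 0, found=False)


def peak_location(profile: Profile1D) -> PeakLocation:
    """Signed distance of the profile's maximum from its anchor.

    Exact ties are broken toward the anchor.  The raw distance is an
    integer multiple of the bin pitch; the reported value is rounded
    half-away-from-zero to whole µm.
    """
    if not np.any(profile.values > 0):
        return NO_PEAK
    mx = profile.values.max()
    tied = np.nonzero(profile.values == mx)[0]
    best = tied[np.argmin(np.abs(profile.positions_um[tied]))]
    raw = float(profile.positions_um[best])
    return PeakLocation(raw, round_half_up(raw))


def horizontal_bias(profile: Profile1D) -> PeakLocation:
    """Signed medio-lateral offset of the peak from the soma column.

    Positive is medial, negative lateral; identical to
    :func:`peak_location` applied to a horizontal profile.
    """
    if profile.axis != "horizontal-from-soma":
        raise ValueError("horizontal_bias expects a horizontal-from-soma profile")
    return peak_location(profile)
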