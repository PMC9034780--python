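"""Stimulation-grid geometry constants.

The photostimulation grid is a 1000 x 500 µm field split into 24 x 12 square
spots of light, with the long (24-spot) axis running along cortical depth,
aligned to the pia and to the apical dendrite of the recorded neuron.  Somas
are localised to one quadrant of a single spot, so maps are worked at twice
the native resolution ("quadrant" pixels).
"""

from __future__ import annotations

#: extent of the grid along cortical depth (µm); 24 spots
GRID_DEPTH_UM: float = 1000.0
#: horizontal extent of the grid (µm); 12 spots
GRID_WIDTH_UM: float = 500.0
#: native number of grid rows (depth axis)
N_ROWS: int = 24
#: native number of grid columns (horizontal axis)
N_COLS: int = 12
#: total number of stimulation spots per trial
N_SPOTS: int = N_ROWS * N_COLS

#: side of one square stimulation spot (µm)
SPOT_SIZE_UM: float = GRID_DEPTH_UM / N_ROWS
#: side of one quadrant pixel (µm); the working map resolution
PIXEL_SIZE_UM: float = GRID_DEPTH_UM / (2 * N_ROWS)


def spot_size_um(grid_extent_um: float = GRID_DEPTH_UM, n_spots: int = N_ROWS) -> float:
    """Side length of one stimulation spot (µm)."""
    return grid_extent_um / n_spots


def pixel_size_um(grid_extent_um: float = GRID_DEPTH_UM, n_spots: int = N_ROWS) -> float:
    """Side length of one quadrant pixel (µm), half a spot."""
    return grid_extent_um / (2 * n_spots)


def spot_irradiance_mw_mm2(power_uw: float = 300.0,
                           spot_um: float = SPOT_SIZE_UM) -> float:
    """Irradiance of one stimulation spot in mW/mm².

    Parameters
    ----------
    power_uw : measured laser power delivered to one spot, in µW.
    spot_um : side of the square spot, in µm.
    """
    power_mw = power_uw * 1e-3
    area_mm2 = (spot_um * 1e-3) ** 2
    return power_mw / area_mm2
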