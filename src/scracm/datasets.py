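"""Reference per-area input summary for mouse V2M ttL5 neurons.

The published mapping study of long-range input to thick-tufted layer-5
pyramidal neurons in medial secondary visual cortex (V2M) reports, for
seven input areas, the full-field total charge, the percentage of input
per dendritic compartment, the derived per-compartment charges, peak input
locations (tuft measured from the pia, basal and oblique from the soma),
horizontal biases (positive = medial) and the per-cell tuft-peak counts.
These printed values serve as inputs for arithmetic cross-checks of the
allocation stage (conservation, aggregation) — they are data, not
quantities this package re-measures.
"""

from __future__ import annotations

import pandas as pd

from .allocation import CompartmentSplit

#: order of areas as reported (feedforward, cortical feedback, thalamic)
AREAS = ("VISp", "V2M", "RSPg", "ACA", "ORB", "ATN", "LP")

_ROWS = [
    # area, n_animals, n_cells, soma_depth, soma_sem, total_pc, total_sem,
    # prop_pct (b, o, t), charge_pc (b, o, t), peak_um (b, o, t),
    # bias_um (b, o, t), tuft_peak_cells, tuft_peak_n
    ("VISp", 6, 9, 507, 22, 0.93, 0.11, (26, 33, 42), (0.24, 0.30, 0.39),
     (-63, 104, 188), (63, 42, -21), 5, 9),
    ("V2M", 4, 13, 498, 15, 11.24, 1.56, (24, 62, 14), (2.68, 6.96, 1.60),
     (-42, 83, 167), (21, 21, -21), 1, 13),
    ("RSPg", 9, 20, 503, 15, 3.40, 0.51, (30, 40, 30), (1.03, 1.36, 1.01),
     (-42, 42, 125), (21, 21, 0), 2, 20),
    ("ACA", 5, 23, 464, 9, 9.46, 1.32, (30, 45, 25), (2.83, 4.22, 2.41),
     (-42, 42, 83), (0, 0, -21), 1, 23),
    ("ORB", 3, 11, 521, 19, 7.16, 1.43, (35, 57, 9), (2.47, 4.05, 0.64),
     (-42, 21, None), (0, 21, 0), 0, 11),
    ("ATN", 3, 8, 435, 15, 2.48, 0.54, (8, 17, 75), (0.20, 0.42, 1.86),
     (-104, 104, 104), (21, 42, 21), 6, 8),
    ("LP", 4, 10, 500, 23, 0.97, 0.16, (10, 15, 75), (0.10, 0.14, 0.73),
     (-42, 21, 63), (-42, -21, -83), 9, 10),
]


def area_summary_table() -> pd.DataFrame:
    """The reference per-area summary as a tidy DataFrame (one row per area)."""
    recs = []
    for (area, n_animals, n_cells, depth, depth_sem, total, total_sem,
         props, charges, peaks, biases, tp, tpn) in _ROWS:
        recs.append({
            "area": area, "n_animals": n_animals, "n_cells": n_cells,
            "soma_depth_um": depth, "soma_depth_sem_um": depth_sem,
            "total_pc": total, "total_sem_pc": total_sem,
            "prop_basal_pct": props[0], "prop_oblique_pct": props[1],
            "prop_tuft_pct": props[2],
            "charge_basal_pc": charges[0], "charge_oblique_pc": charges[1],
            "charge_tuft_pc": charges[2],
            "peak_basal_um": peaks[0], "peak_oblique_um": peaks[1],
            "peak_tuft_um": peaks[2],
            "bias_basal_um": biases[0], "bias_oblique_um": biases[1],
            "bias_tuft_um": biases[2],
            "cells_with_peak_in_tuft": tp, "cells_with_peak_in_tuft_n": tpn,
        })
    return pd.DataFrame(recs)


def area_splits() -> list[CompartmentSplit]:
    """Per-area compartment splits built from the printed charges."""
    return [CompartmentSplit.from_charges(*row[8], area=row[0]) for row in _ROWS]
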