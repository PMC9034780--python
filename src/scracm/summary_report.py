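"""Per-area summaries, anatomy-vs-function comparisons and FDR control.

Assembles, for a cohort of analysed cells from one input area, the summary
record reported per area in mapping studies: mean ± SEM soma depth and
total charge, per-compartment peak locations (tuft from the pia, basal and
oblique from the soma), input proportions and proportional charges,
per-compartment horizontal biases, and the fraction of cells whose peak
input falls in the tuft.  Cross-area utilities compare rabies-traced input
cell counts with total synaptic charge (Spearman) and adjust p-values with
the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .allocation import (AllocationResult, CompartmentSplit, allocate,
                         morph_to_input_bins, proportional_charge)
from .map_builder import (InputMap, PeakLocation, Profile1D, align_and_average,
                          horizontal_bias, horizontal_profile, normalize_map,
                          peak_location, vertical_profile)
from .morphology import COMPARTMENTS, MorphProfile, rescale_profile, tuft_boundary_depth_um


@dataclass
class CellResult:
    """Everything derived from one cell needed for an area summary."""

    input_map: InputMap
    total_pc: float
    soma_depth_um: float


@dataclass
class AreaSummary:
    """One area's summary row: cohort stats, peaks, proportions, charges."""

    area: str
    n_cells: int
    n_animals: int | None
    soma_depth_um: float
    soma_depth_sem_um: float | None
    total_pc: float
    total_sem_pc: float | None
    peak_um: dict[str, PeakLocation]
    proportions: tuple[float, float, float]
    charges_pc: tuple[float, float, float]
    bias_um: dict[str, PeakLocation]
    cells_with_peak_in_tuft: int

    def split(self) -> CompartmentSplit:
        return CompartmentSplit(self.proportions, self.charges_pc,
                                float(np.sum(self.charges_pc)), self.area)

    def to_row(self) -> dict:
        row = {"area": self.area, "n_cells": self.n_cells,
               "n_animals": self.n_animals,
               "soma_depth_um": self.soma_depth_um,
               "soma_depth_sem_um": self.soma_depth_sem_um,
               "total_pc": self.total_pc, "total_sem_pc": self.total_sem_pc,
               "cells_with_peak_in_tuft": self.cells_with_peak_in_tuft}
        for c in COMPARTMENTS:
            row[f"prop_{c}_pct"] = 100.0 * self.proportions[COMPARTMENTS.index(c)]
            row[f"charge_{c}_pc"] = self.charges_pc[COMPARTMENTS.index(c)]
            row[f"peak_{c}_um"] = (self.peak_um[c].rounded_um
                                   if self.peak_um[c].found else None)
            row[f"bias_{c}_um"] = (self.bias_um[c].rounded_um
                                   if self.bias_um[c].found else None)
        return row


def _sem(x: np.ndarray) -> float | None:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else None


def _compartment_peaks(avg_map: InputMap,
                       alloc: AllocationResult) -> dict[str, PeakLocation]:
    """Per-compartment peak locations from the allocated average profile.

    Tuft peaks are reported as depth from the pia; basal and oblique peaks
    as signed distance from the soma's quadrant row, positive toward the
    pia.  Using the quadrant row (not the continuous soma depth) keeps all
    reported distances on the 20.833 µm pixel lattice.
    """
    soma_depth_q = (avg_map.soma_anchor[0] - avg_map.pia_row) * avg_map.pitch_um
    peaks: dict[str, PeakLocation] = {}
    for i, c in enumerate(COMPARTMENTS):
        vals = alloc.per_bin[i]
        pos = alloc.positions_um if c == "tuft" else soma_depth_q - alloc.positions_um
        prof = Profile1D(vals, pos, "depth-from-pia" if c == "tuft"
                         else "depth-from-soma", avg_map.pitch_um)
        peaks[c] = peak_location(prof)
    return peaks


def summarize_area(area: str, cells: list[CellResult], morph: MorphProfile,
                   n_animals: int | None = None) -> AreaSummary:
    """Build an area summary from analysed cells and the average morphology.

    Normalised maps are pia-aligned and averaged; the average map's
    vertical profile is allocated to compartments with the average
    morphology rescaled to the cohort's mean soma depth; proportional
    charges use the mean full-field total.  A cell counts as peaking in
    the tuft when the argmax of its own vertical profile is shallower than
    the main bifurcation of the morphology rescaled to that cell.
    """
    if not cells:
        raise ValueError(f"area {area!r}: no cells survived QC")
    totals = np.array([c.total_pc for c in cells])
    depths = np.array([c.soma_depth_um for c in cells])
    mean_depth = float(depths.mean())

    avg_map, _ = align_and_average([normalize_map(c.input_map) for c in cells],
                                   mode="pia")
    vprof = vertical_profile(avg_map, align="pia")
    alloc = allocate(vprof, morph, soma_pia_um=mean_depth)
    split = proportional_charge(alloc.proportions, float(totals.mean()), area)
    peaks = _compartment_peaks(avg_map, alloc)

    # per-compartment horizontal biases: weight rows by the compartment's
    # share of dendritic length at that depth before projecting
    L = morph_to_input_bins(morph, vprof, soma_pia_um=mean_depth)
    biases: dict[str, PeakLocation] = {}
    for i, c in enumerate(COMPARTMENTS):
        w = np.divide(L[i], L.sum(axis=0), out=np.zeros_like(L[i]),
                      where=L.sum(axis=0) > 0)
        biases[c] = horizontal_bias(horizontal_profile(avg_map, row_weights=w))

    n_tuft = 0
    for c in cells:
        prof = vertical_profile(c.input_map, align="pia")
        pk = peak_location(prof)
        if not pk.found:
            continue
        boundary = tuft_boundary_depth_um(rescale_profile(morph, c.soma_depth_um))
        if np.isfinite(boundary) and pk.raw_um < boundary:
            n_tuft += 1

    return AreaSummary(area, len(cells), n_animals, mean_depth, _sem(depths),
                       float(totals.mean()), _sem(totals), peaks,
                       split.proportions, split.charges_pc, biases, n_tuft)


def summaries_to_table(summaries: list[AreaSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])


# ---------------------------------------------------------------------------
# Rabies counts vs functional input
# ---------------------------------------------------------------------------

def load_rabies_counts(path) -> pd.DataFrame:
    """Load a rabies input-cell count table (area, experiment, count, ...)."""
    df = pd.read_csv(path)
    if "area" not in df.columns or "count" not in df.columns:
        raise ValueError("rabies count table needs 'area' and 'count' columns")
    if (df["count"] < 0).any():
        raise ValueError("rabies counts must be non-negative")
    return df


@dataclass
class SpearmanReport:
    r: float
    p: float
    n: int
    degenerate: bool = False


def anatomy_vs_function(counts: pd.DataFrame,
                        summaries: list[AreaSummary]) -> SpearmanReport:
    """Spearman correlation of mean input-cell counts vs total charge.

    Pairs areas present in both tables; requires at least 3 paired areas.
    A ties-only input (zero rank variance) is flagged as degenerate.
    """
    mean_counts = counts.groupby("area")["count"].mean()
    pairs = [(mean_counts[s.area], s.total_pc) for s in summaries
             if s.area in mean_counts.index]
    if len(pairs) < 3:
        raise ValueError("need at least 3 paired areas")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanReport(np.nan, np.nan, len(pairs), degenerate=True)
    r, p = stats.spearmanr(x, y)
    return SpearmanReport(float(r), float(p), len(pairs))


def bh_adjust(p_values, alpha: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns (adjusted p-values, reject flags at the given FDR).  Adjusted
    values are monotone non-decreasing after sorting the raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adjusted, reject
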