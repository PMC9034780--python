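"""Axo-dendritic overlap ("Peters' rule") input predictions.

Peters' rule posits that synapse counts are proportional to the spatial
overlap of axonal and dendritic arbors.  Here both the laminar axon-density
profile of an input pathway and the (pia-aligned, averaged) dendritic length
profile are peak-normalised and multiplied bin-wise; large products mark
depths where both axons and dendrites are present, i.e. where the rule
predicts input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import PIXEL_SIZE_UM
from .morphology import MorphProfile, rebin_conserving


@dataclass
class AxonProfile:
    """Normalised axon density versus cortical depth for one input area."""

    depth_edges_um: np.ndarray
    density: np.ndarray
    area: str = ""

    def __post_init__(self) -> None:
        self.depth_edges_um = np.asarray(self.depth_edges_um, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValueError("axon density must be non-negative")
        if not np.any(self.density > 0):
            raise ValueError("axon profile must have at least one positive bin")

    @property
    def depth_centers_um(self) -> np.ndarray:
        return 0.5 * (self.depth_edges_um[:-1] + self.depth_edges_um[1:])

    @classmethod
    def from_csv(cls, path, area: str = "") -> "AxonProfile":
        """Load a (depth_um, density) table; depth_um are bin centers."""
        df = pd.read_csv(path)
        centers = df["depth_um"].to_numpy(dtype=float)
        step = np.median(np.diff(centers))
        edges = np.concatenate([centers - step / 2, [centers[-1] + step / 2]])
        return cls(edges, df["density"].to_numpy(dtype=float), area)

    def to_csv(self, path) -> None:
        pd.DataFrame({"depth_um": self.depth_centers_um,
                      "density": self.density}).to_csv(path, index=False)


@dataclass
class PredictedInput:
    """Peak-normalised axon x dendrite product profile for one input area."""

    depth_edges_um: np.ndarray
    product: np.ndarray
    area: str = ""

    @property
    def depth_centers_um(self) -> np.ndarray:
        return 0.5 * (self.depth_edges_um[:-1] + self.depth_edges_um[1:])

    def to_csv(self, path) -> None:
        pd.DataFrame({"depth_um": self.depth_centers_um,
                      "predicted": self.product}).to_csv(path, index=False)


def _resample_density(edges: np.ndarray, values: np.ndarray,
                      new_edges: np.ndarray) -> np.ndarray:
    """Rebin a density (per-bin amount = density * width) onto new edges."""
    widths = np.diff(edges)
    amount = values * widths
    new_amount = rebin_conserving(edges, amount, new_edges)
    return new_amount / np.diff(new_edges)


def predict_input(axon: AxonProfile, dendrite: MorphProfile,
                  bin_um: float = PIXEL_SIZE_UM) -> PredictedInput:
    """Predict an input profile from axo-dendritic overlap.

    Both factors are resampled onto a common depth grid from the pia,
    peak-normalised to 1, and multiplied bin-wise.  The prediction is
    invariant to positive rescaling of either factor.
    """
    dend_total = dendrite.total()
    max_depth = max(axon.depth_edges_um[-1], dendrite.bin_edges_um[-1])
    n_bins = int(np.ceil(max_depth / bin_um))
    edges = np.arange(n_bins + 1) * bin_um
    ax = _resample_density(axon.depth_edges_um, axon.density, edges)
    de = _resample_density(dendrite.bin_edges_um, dend_total, edges)
    if ax.max() > 0:
        ax = ax / ax.max()
    if de.max() > 0:
        de = de / de.max()
    product = ax * de
    if not np.any(product > 0):
        warnings.warn("axon and dendrite depth supports are disjoint; "
                      "prediction is all-zero")
    return PredictedInput(edges, product, axon.area)


@dataclass
class ProfileSimilarity:
    """Similarity between a predicted and a measured depth profile."""

    cosine: float
    pearson_r: float
    pearson_p: float
    difference: np.ndarray
    defined: bool = True


def compare_profiles(predicted: np.ndarray, measured: np.ndarray) -> ProfileSimilarity:
    """Cosine similarity and Pearson r between two profiles on a common grid.

    Both inputs should be peak-normalised non-negative profiles of equal
    length.  All-zero inputs yield an undefined (flagged) similarity.
    """
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.shape != m.shape:
        raise ValueError(f"profiles must share a grid, got {p.shape} vs {m.shape}")
    diff = p - m
    np_, nm = np.linalg.norm(p), np.linalg.norm(m)
    if np_ == 0 or nm == 0:
        return ProfileSimilarity(np.nan, np.nan, np.nan, diff, defined=False)
    cosine = float(np.dot(p, m) / (np_ * nm))
    if np.ptp(p) == 0 or np.ptp(m) == 0:
        r, pv = np.nan, np.nan
    else:
        r, pv = stats.pearsonr(p, m)
    return ProfileSimilarity(cosine, float(r), float(pv), diff)
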