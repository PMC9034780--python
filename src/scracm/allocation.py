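"""Allocate measured synaptic input to dendritic compartments.

A cell's vertical input profile is "deconvolved" with the average dendritic
morphology: within each depth bin the measured charge is apportioned to
basal, oblique and tuft in proportion to each compartment's share of the
dendritic length in that bin (all three compartments carry similar spine
densities, so length is the natural weight).  Bins holding charge but no
dendrite inherit the shares of the nearest dendrite-bearing bin, so charge
is conserved.  Proportions times the full-field total give absolute
compartment charges in pC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .map_builder import Profile1D
from .morphology import COMPARTMENTS, MorphProfile, rebin_conserving, rescale_profile


@dataclass
class CompartmentSplit:
    """Input proportions and absolute charges per dendritic compartment."""

    proportions: tuple[float, float, float]   # (basal, oblique, tuft), sum 1
    charges_pc: tuple[float, float, float]
    total_pc: float
    area: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        c = np.asarray(self.charges_pc, dtype=float)
        if np.any(p < 0) or np.any(c < 0):
            raise ValueError("proportions and charges must be non-negative")
        if self.total_pc < 0:
            raise ValueError("total charge must be non-negative")
        if self.total_pc > 0 and abs(c.sum() - self.total_pc) > 1e-9 * max(1.0, self.total_pc):
            raise ValueError("compartment charges must sum to the total")

    @classmethod
    def from_charges(cls, basal: float, oblique: float, tuft: float,
                     area: str = "") -> "CompartmentSplit":
        total = basal + oblique + tuft
        props = tuple(np.array([basal, oblique, tuft]) / total) if total > 0 \
            else (0.0, 0.0, 0.0)
        return cls(props, (basal, oblique, tuft), total, area)

    def as_dict(self) -> dict:
        return {"area": self.area, "total_pc": self.total_pc,
                **{f"prop_{c}": p for c, p in zip(COMPARTMENTS, self.proportions)},
                **{f"charge_{c}_pc": q for c, q in zip(COMPARTMENTS, self.charges_pc)}}


@dataclass
class AllocationResult:
    """Bin-level apportionment of a vertical input profile."""

    proportions: tuple[float, float, float]
    per_bin: np.ndarray         # (3, n_bins), compartment order basal/oblique/tuft
    positions_um: np.ndarray    # depth from pia of each bin
    defined: bool = True        # False when the input profile carries no charge


def morph_to_input_bins(morph: MorphProfile, profile: Profile1D,
                        soma_pia_um: float | None = None) -> np.ndarray:
    """Resample a morphology profile onto a pia-aligned input profile's bins.

    Optionally rescales the morphology to the cell's own soma–pia distance
    first.  Returns a (3, n_bins) length matrix in compartment order.
    """
    if profile.axis != "depth-from-pia":
        raise ValueError("allocation requires a pia-aligned vertical profile")
    if soma_pia_um is not None:
        morph = rescale_profile(morph, soma_pia_um)
    pitch = profile.pitch_um
    edges = np.concatenate([profile.positions_um, [profile.positions_um[-1] + pitch]])
    return np.vstack([rebin_conserving(morph.bin_edges_um, morph.lengths[c], edges)
                      for c in COMPARTMENTS])


def allocate(profile: Profile1D, morph: MorphProfile,
             soma_pia_um: float | None = None) -> AllocationResult:
    """Split a vertical input profile among dendritic compartments.

    The result is invariant to positive rescaling of the input profile,
    and the per-bin apportionment conserves charge bin by bin.
    """
    lengths = morph_to_input_bins(morph, profile, soma_pia_um)
    bin_total = lengths.sum(axis=0)
    if not np.any(bin_total > 0):
        raise ValueError("morphology profile has no dendritic length on the input grid")
    values = np.clip(profile.values, 0.0, None)
    n_bins = len(values)
    shares = np.zeros_like(lengths)
    have = np.nonzero(bin_total > 0)[0]
    for i in range(n_bins):
        j = i if bin_total[i] > 0 else have[np.argmin(np.abs(have - i))]
        shares[:, i] = lengths[:, j] / bin_total[j]
    per_bin = shares * values[None, :]
    comp = per_bin.sum(axis=1)
    total = comp.sum()
    if total <= 0:
        return AllocationResult((0.0, 0.0, 0.0), per_bin,
                                profile.positions_um, defined=False)
    return AllocationResult(tuple(comp / total), per_bin, profile.positions_um)


def proportional_charge(proportions: tuple[float, float, float],
                        full_field_total_pc: float,
                        area: str = "") -> CompartmentSplit:
    """Convert input proportions into absolute compartment charges.

    Proportions may carry rounding error (printed percentages often sum to
    99–101%); a sum within 0.02 of 1 is accepted and used as-is.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 0.02:
        raise ValueError(f"proportions must sum to ~1, got {p.sum():.4f}")
    if full_field_total_pc < 0:
        raise ValueError("total charge must be non-negative")
    charges = p * full_field_total_pc
    return CompartmentSplit(tuple(p), tuple(charges),
                            float(charges.sum()), area)


def aggregate_splits(splits: list[CompartmentSplit]) -> CompartmentSplit:
    """Combine per-area splits into a grand total and overall proportions.

    The grand total is the sum of area totals; each overall compartment
    proportion is the summed compartment charge divided by the grand total.
    """
    if not splits:
        raise ValueError("need at least one area split to aggregate")
    charges = np.sum([s.charges_pc for s in splits], axis=0)
    total = float(np.sum([s.total_pc for s in splits]))
    props = tuple(charges / total) if total > 0 else (0.0, 0.0, 0.0)
    return CompartmentSplit(props, tuple(charges), total, area="all")
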