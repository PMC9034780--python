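"""Compartment-labelled neuron morphologies and depth-binned length profiles.

Thick-tufted layer-5 pyramidal dendrites are split into three compartments:

* **basal** — dendrites originating at the soma (other than the apical trunk);
* **oblique** — dendrites originating from the apical trunk proximal to the
  main bifurcation, *including the trunk itself*;
* **tuft** — everything distal to the main bifurcation.

Coordinates follow a slice convention: ``y`` is depth below the pia in µm
(pia at ``y = 0``, increasing into the tissue), ``x`` is the medio-lateral
axis with the soma at ``x = 0``.  SWC files store the compartment in the
type column: 1 = soma, 3 = basal, 4 = apical trunk + oblique, 5 = tuft
(a custom use of type 5, documented in the README).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SWC_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]

#: SWC type codes for compartments (type 5 is a custom tuft label)
SWC_TYPE_SOMA = 1
SWC_TYPE_BASAL = 3
SWC_TYPE_APICAL = 4
SWC_TYPE_TUFT = 5

COMPARTMENTS = ("basal", "oblique", "tuft")

_TYPE_TO_LABEL = {SWC_TYPE_BASAL: "basal", SWC_TYPE_APICAL: "oblique",
                  SWC_TYPE_TUFT: "tuft", SWC_TYPE_SOMA: "soma"}
_LABEL_TO_TYPE = {"basal": SWC_TYPE_BASAL, "oblique": SWC_TYPE_APICAL,
                  "tuft": SWC_TYPE_TUFT, "soma": SWC_TYPE_SOMA}


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path) -> pd.DataFrame:
    """Read an SWC file into a node table with columns id,type,x,y,z,radius,parent."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, names=SWC_COLUMNS)
    df[["id", "type", "parent"]] = df[["id", "type", "parent"]].astype(int)
    return df


def write_swc(nodes: pd.DataFrame, path) -> None:
    """Write a node table as SWC with fixed 6-decimal formatting (byte-stable)."""
    buf = io.StringIO()
    for row in nodes.itertuples(index=False):
        buf.write(f"{int(row.id)} {int(row.type)} {row.x:.6f} {row.y:.6f} "
                  f"{row.z:.6f} {row.radius:.6f} {int(row.parent)}\n")
    with open(path, "w", newline="\n") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Morphology container
# ---------------------------------------------------------------------------

@dataclass
class Morphology:
    """A single connected neuron tree with per-node compartment labels.

    ``nodes`` is an SWC-style table; ``labels`` maps each node id to one of
    soma/basal/oblique/tuft.  ``bifurcation_depth_um`` is the depth (from
    pia) of the main apical bifurcation, or None for trees without one.
    """

    nodes: pd.DataFrame
    labels: dict[int, str]
    soma_depth_um: float
    bifurcation_depth_um: float | None = None
    morphology_id: str = "morph"

    def segments(self) -> pd.DataFrame:
        """Parent->child segments with length, depth span, x span and label."""
        idx = self.nodes.set_index("id")
        child = self.nodes[self.nodes["parent"] >= 0]
        parent = idx.loc[child["parent"].to_numpy()]
        d = np.sqrt((child["x"].to_numpy() - parent["x"].to_numpy()) ** 2
                    + (child["y"].to_numpy() - parent["y"].to_numpy()) ** 2
                    + (child["z"].to_numpy() - parent["z"].to_numpy()) ** 2)
        lab = np.array([self.labels[i] for i in child["id"]])
        return pd.DataFrame({
            "length": d,
            "y0": parent["y"].to_numpy(), "y1": child["y"].to_numpy(),
            "x0": parent["x"].to_numpy(), "x1": child["x"].to_numpy(),
            "label": lab,
        })

    def total_length(self, compartment: str | None = None) -> float:
        seg = self.segments()
        if compartment is not None:
            seg = seg[seg["label"] == compartment]
        return float(seg["length"].sum())

    def to_swc(self, path) -> None:
        """Write SWC with compartment labels encoded in the type column."""
        out = self.nodes.copy()
        out["type"] = [_LABEL_TO_TYPE[self.labels[i]] for i in out["id"]]
        write_swc(out, path)

    @classmethod
    def from_swc(cls, path, morphology_id: str = "morph") -> "Morphology":
        """Load an SWC file.

        If the type column already distinguishes tuft (type 5) the labels are
        taken verbatim; otherwise the main bifurcation is located and
        compartments are derived with :func:`label_compartments`.
        """
        nodes = read_swc(path)
        if (nodes["type"] == SWC_TYPE_TUFT).any():
            labels = {int(i): _TYPE_TO_LABEL[int(t)]
                      for i, t in zip(nodes["id"], nodes["type"])}
            soma_y = float(nodes.loc[nodes["type"] == SWC_TYPE_SOMA, "y"].iloc[0])
            tuft_y = nodes.loc[nodes["type"] == SWC_TYPE_TUFT, "y"]
            bif = float(tuft_y.max()) if len(tuft_y) else None
            return cls(nodes, labels, soma_y, bif, morphology_id)
        return label_compartments(nodes, morphology_id=morphology_id)


# ---------------------------------------------------------------------------
# Compartment labelling
# ---------------------------------------------------------------------------

def _children_map(nodes: pd.DataFrame) -> dict[int, list[int]]:
    ch: dict[int, list[int]] = {}
    for nid, par in zip(nodes["id"], nodes["parent"]):
        ch.setdefault(int(par), []).append(int(nid))
    return ch


def _subtree_nodes(root: int, children: dict[int, list[int]]) -> list[int]:
    out, stack = [], [root]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(children.get(n, ()))
    return out


def label_compartments(nodes: pd.DataFrame, min_daughter_frac: float = 0.25,
                       min_remaining_frac: float = 0.25,
                       morphology_id: str = "morph") -> Morphology:
    """Label every dendritic node as basal, oblique or tuft.

    The apical trunk is followed from the soma along the dominant (largest
    remaining length) child.  A branch point qualifies as a bifurcation
    when at least two daughter subtrees each carry at least
    ``min_daughter_frac`` of the apical length distal to that point.  The
    **main bifurcation** is the most distal qualifying node that still has
    at least ``min_remaining_frac`` of the whole apical length distal to it
    (the floor stops near-symmetric branch points inside the tuft from
    being picked; if no qualifying node clears the floor, the most distal
    qualifying node is used, so a bare trunk ending in a single terminal
    split is still bifurcated there).  Everything distal to the main
    bifurcation is tuft; the trunk and pre-bifurcation branches are
    oblique; remaining soma-rooted subtrees are basal.

    Trees without a qualifying bifurcation are labelled all-oblique on the
    apical side, with an empty tuft and a warning.
    """
    nodes = nodes.reset_index(drop=True)
    children = _children_map(nodes)
    idx = nodes.set_index("id")
    roots = nodes.loc[nodes["parent"] < 0, "id"].astype(int).tolist()
    soma_ids = set(nodes.loc[nodes["type"] == SWC_TYPE_SOMA, "id"].astype(int))
    if not soma_ids or not roots:
        raise ValueError("morphology must contain a soma root node (type 1)")
    root = roots[0]
    if root not in soma_ids:
        raise ValueError("root node must be part of the soma")
    soma_y = float(idx.loc[root, "y"])

    coords = {int(i): np.array([idx.loc[i, "x"], idx.loc[i, "y"], idx.loc[i, "z"]])
              for i in nodes["id"].astype(int)}

    def seg_len(a: int, b: int) -> float:
        return float(np.linalg.norm(coords[a] - coords[b]))

    # subtree length below each node (length of edges within the subtree)
    sub_len: dict[int, float] = {}

    def fill_sub_len(n: int) -> float:
        total = 0.0
        for c in children.get(n, ()):
            total += seg_len(n, c) + fill_sub_len(c)
        sub_len[n] = total
        return total

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, len(nodes) * 2 + 100))
    try:
        fill_sub_len(root)
    finally:
        sys.setrecursionlimit(old)

    soma_children = [c for c in children.get(root, ()) if c not in soma_ids]
    apical_roots = [c for c in soma_children
                    if int(idx.loc[c, "type"]) in (SWC_TYPE_APICAL, SWC_TYPE_TUFT)]
    if not apical_roots:
        raise ValueError("no apical trunk: no soma child carries apical SWC type 4")
    apical_root = max(apical_roots, key=lambda c: sub_len[c])

    # walk the dominant path, recording qualifying bifurcations
    apical_total = sub_len[apical_root]
    candidates: list[tuple[int, float]] = []  # (node, apical length distal to it)
    n = apical_root
    while True:
        kids = children.get(n, [])
        if not kids:
            break
        masses = sorted((sub_len[c] + seg_len(n, c) for c in kids), reverse=True)
        remaining = sum(masses)
        if len(kids) >= 2 and remaining > 0 and masses[1] >= min_daughter_frac * remaining:
            candidates.append((n, remaining))
        n = max(kids, key=lambda c: sub_len[c] + seg_len(n, c))
    bif_node: int | None = None
    if candidates:
        cleared = [c for c, rem in candidates
                   if rem >= min_remaining_frac * apical_total]
        bif_node = cleared[-1] if cleared else candidates[-1][0]

    labels: dict[int, str] = {int(i): "soma" for i in soma_ids}
    apical_nodes = _subtree_nodes(apical_root, children)
    if bif_node is None:
        warnings.warn("no main bifurcation found; apical tree labelled oblique, tuft empty")
        tuft_nodes: set[int] = set()
        bif_depth = None
    else:
        tuft_nodes = set()
        for c in children.get(bif_node, ()):
            tuft_nodes.update(_subtree_nodes(c, children))
        bif_depth = float(idx.loc[bif_node, "y"])
    for nid in apical_nodes:
        labels[nid] = "tuft" if nid in tuft_nodes else "oblique"
    for c in soma_children:
        if c == apical_root:
            continue
        for nid in _subtree_nodes(c, children):
            labels[nid] = "basal"

    return Morphology(nodes, labels, soma_y, bif_depth, morphology_id)


# ---------------------------------------------------------------------------
# Depth-binned length profiles
# ---------------------------------------------------------------------------

@dataclass
class MorphProfile:
    """Per-compartment dendritic length per depth bin along the apical axis.

    Bins are measured from the pia (``bin_edges_um[0]`` is the shallowest
    edge, normally 0).  ``soma_depth_um`` anchors soma-relative conventions;
    after rescaling to a common soma–pia distance, pia- and soma-aligned
    averages coincide.
    """

    bin_edges_um: np.ndarray
    lengths: dict[str, np.ndarray] = field(default_factory=dict)
    soma_depth_um: float = np.nan
    align: str = "pia"
    bifurcation_depth_um: float | None = None

    @property
    def bin_um(self) -> float:
        return float(self.bin_edges_um[1] - self.bin_edges_um[0])

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])

    def total(self) -> np.ndarray:
        """Summed dendritic length over compartments, per bin."""
        return np.sum([self.lengths[c] for c in COMPARTMENTS], axis=0)

    def compartment_total(self, compartment: str) -> float:
        return float(self.lengths[compartment].sum())

    def centroid_depth_um(self, compartment: str) -> float:
        """Length-weighted mean depth of a compartment (from pia)."""
        w = self.lengths[compartment]
        if w.sum() <= 0:
            return np.nan
        return float(np.average(self.bin_centers_um, weights=w))

    def to_frame(self) -> pd.DataFrame:
        out = {"depth_um": self.bin_centers_um}
        out.update({c: self.lengths[c] for c in COMPARTMENTS})
        return pd.DataFrame(out)


def rebin_conserving(edges_old: np.ndarray, values: np.ndarray,
                     edges_new: np.ndarray) -> np.ndarray:
    """Rebin a per-bin amount onto new edges, conserving the total.

    Assumes the amount is uniformly distributed within each old bin
    (piecewise-constant density); implemented by interpolating the
    cumulative amount at the new edges.
    """
    cum = np.concatenate([[0.0], np.cumsum(values)])
    cum_new = np.interp(edges_new, edges_old, cum, left=0.0, right=cum[-1])
    return np.diff(cum_new)


def length_profile(morph: Morphology, bin_um: float = 10.0,
                   align: str = "pia") -> MorphProfile:
    """Bin dendritic length per compartment in ``bin_um`` depth bins.

    Each segment's length is apportioned to bins by the linear overlap of
    its depth span; segments at a single depth contribute wholly to the bin
    containing that depth.
    """
    if bin_um <= 0:
        raise ValueError(f"bin_um must be positive, got {bin_um}")
    seg = morph.segments()
    seg = seg[seg["label"].isin(COMPARTMENTS)]
    ymax = float(max(seg[["y0", "y1"]].to_numpy().max(), morph.soma_depth_um))
    n_bins = int(np.ceil(ymax / bin_um)) + 1
    edges = np.arange(n_bins + 1) * bin_um
    lengths = {c: np.zeros(n_bins) for c in COMPARTMENTS}
    for row in seg.itertuples(index=False):
        lo, hi = sorted((row.y0, row.y1))
        lo, hi = max(lo, 0.0), min(hi, edges[-1])
        if hi < lo:
            continue
        arr = lengths[row.label]
        if hi - lo < 1e-12:
            b = min(int(lo // bin_um), n_bins - 1)
            arr[b] += row.length
            continue
        b0, b1 = int(lo // bin_um), min(int(hi // bin_um), n_bins - 1)
        for b in range(b0, b1 + 1):
            o = max(0.0, min(hi, edges[b + 1]) - max(lo, edges[b]))
            arr[b] += row.length * o / (hi - lo)
    return MorphProfile(edges, lengths, morph.soma_depth_um, align,
                        morph.bifurcation_depth_um)


def rescale_profile(profile: MorphProfile, target_soma_pia_um: float) -> MorphProfile:
    """Linearly rescale the depth axis so the soma maps to ``target_soma_pia_um``.

    Length per bin is conserved (density scales inversely with the stretch).
    The result is resampled back onto the profile's original bin width.
    """
    if not np.isfinite(profile.soma_depth_um) or profile.soma_depth_um <= 0:
        raise ValueError("profile has no positive soma-pia distance to rescale from")
    s = target_soma_pia_um / profile.soma_depth_um
    edges_scaled = profile.bin_edges_um * s
    bin_um = profile.bin_um
    n_bins = int(np.ceil(edges_scaled[-1] / bin_um))
    edges_new = np.arange(n_bins + 1) * bin_um
    lengths = {c: rebin_conserving(edges_scaled, profile.lengths[c], edges_new)
               for c in COMPARTMENTS}
    bif = (profile.bifurcation_depth_um * s
           if profile.bifurcation_depth_um is not None else None)
    return MorphProfile(edges_new, lengths, target_soma_pia_um, profile.align, bif)


def average_profiles(profiles: list[MorphProfile], target_soma_pia_um: float,
                     align: str = "pia") -> MorphProfile:
    """Rescale each profile to a common soma–pia distance and average.

    All profiles are stretched from the pia so their somas coincide at the
    target depth, resampled onto common bins, then averaged bin-wise.
    """
    if not profiles:
        raise ValueError("need at least one profile to average")
    rescaled = [rescale_profile(p, target_soma_pia_um) for p in profiles]
    bin_um = rescaled[0].bin_um
    n_bins = max(len(p.bin_edges_um) - 1 for p in rescaled)
    edges = np.arange(n_bins + 1) * bin_um
    lengths = {c: np.zeros(n_bins) for c in COMPARTMENTS}
    for p in rescaled:
        for c in COMPARTMENTS:
            v = p.lengths[c]
            lengths[c][:len(v)] += v
    for c in COMPARTMENTS:
        lengths[c] /= len(rescaled)
    bifs = [p.bifurcation_depth_um for p in rescaled
            if p.bifurcation_depth_um is not None]
    bif = float(np.mean(bifs)) if bifs else None
    return MorphProfile(edges, lengths, target_soma_pia_um, align, bif)


def tuft_boundary_depth_um(profile: MorphProfile, frac: float = 0.05) -> float:
    """Depth of the tuft/oblique boundary estimated from a profile.

    If the profile carries an explicit main-bifurcation depth it is used;
    otherwise the deepest bin where tuft length is at least ``frac`` of the
    tuft peak serves as the boundary.
    """
    if profile.bifurcation_depth_um is not None:
        return float(profile.bifurcation_depth_um)
    tuft = profile.lengths["tuft"]
    if tuft.max() <= 0:
        return np.nan
    good = np.nonzero(tuft >= frac * tuft.max())[0]
    return float(profile.bin_edges_um[good[-1] + 1])
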