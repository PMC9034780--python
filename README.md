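# scracm

Analysis pipeline for **subcellular channelrhodopsin-assisted circuit
mapping (sCRACM)**: from grid-stimulation voltage-clamp sweeps to per-cell
and per-area dendritic input maps, compartment-level input allocation, and
Peters'-rule axo-dendritic overlap predictions — plus a synthetic-data
generator that produces ground-truth-known recordings so every stage is
testable without wet-lab data.

## The problem

sCRACM maps *where on a neuron's dendritic tree* a long-range pathway makes
functional synapses.  Axons expressing a channelrhodopsin are stimulated
spot by spot on a grid laid over a brain slice (here 24 × 12 spots of
41.7 µm covering 1000 × 500 µm, the long axis along cortical depth), under
TTX/4-AP so only directly illuminated terminals release.  The somatic
voltage-clamp current (−70 mV, 20 kHz) evoked at each spot is baselined in
a 40 ms pre-stimulus window, averaged across trials, and its **charge**
(time-integral over a 50 ms post-stimulus window, in pC) is taken as the
input strength at that location; a spot counts as input when its peak
exceeds 7× the baseline standard deviation.  Charge maps are normalised to
their peak, aligned by pia or soma at quadrant-pixel resolution
(20.8 µm), and averaged across cells.

For thick-tufted layer-5 (ttL5) pyramidal neurons the vertical input
profile is split among three dendritic compartments — **basal** (soma-
originating), **oblique** (apical trunk and its pre-bifurcation branches)
and **tuft** (distal to the main bifurcation) — by apportioning each depth
bin's charge according to the compartments' dendritic-length shares in an
average reconstructed morphology (lengths from SWC reconstructions, binned
in 10 µm along the apical axis and rescaled to each cell's soma–pia
distance).  Multiplying peak-normalised laminar axon density with the
peak-normalised dendritic profile gives the input predicted by **Peters'
rule** (synapses ∝ axo-dendritic overlap), which can be compared with the
measured profile.

The package is a library first (`import scracm`), with narrative scripts
under `examples/` and a thin CLI (`scracm simulate | analyze | run`).

## Worked example

```sh
python examples/03_compartment_allocation.py
```

simulates one ttL5 cell with ground-truth targeting 10 % basal / 15 %
oblique / 75 % tuft and 8 pC total input, runs detection, builds the map
and allocates it against an 11-morphology average profile:

```
basal      9.4 %    0.76 pC
oblique   12.9 %    1.03 pC
tuft      77.6 %    6.21 pC
total    100.0 %    8.00 pC
```

The recovered proportions track the generator's targeting within a few
percentage points, and the absolute charges are the proportions times the
measured full-field total.  `examples/05_area_summary.py` additionally
pushes the published seven-area reference table through the aggregation
arithmetic and prints the 35.64 pC grand total with its 27/49/24 %
basal/oblique/tuft split.

## File formats

**Session HDF5** — `/sweeps/trial{n}`: float32 current (pA) per trial;
`/schedule`: table of (`trial` i4, `spot_index` i4 with −1 = full-field,
`t_ms` f8, `is_full_field` i1); `/meta` attributes: `sample_rate_hz`,
`soma_row`, `soma_col` (quadrant indices), `soma_depth_um`, `medial_sign`,
`series_resistance_mohm`, `holding_mv`, `pia_row`, `n_rows`, `n_cols`.

**SWC** — standard 7-column table; compartments are encoded in the type
column: 1 = soma, 3 = basal, 4 = apical trunk + oblique, 5 = tuft (a
custom use of type 5).  Files written by the package are byte-stable for
a given generator seed.  Axon profiles and map projections are plain CSV.
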