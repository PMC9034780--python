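# Methods

## Measurement model

Each recorded cell yields per-trial current sweeps at 20 kHz, one
stimulus per grid spot per trial plus one full-field stimulus.  For every
spot the trace segment spanning [−40, +50] ms around its stimulus is
baselined on its own 40 ms pre-window and averaged across trials.  On the
averaged segment:

* **peak** = max of the inward-rectified trace over the 50 ms response
  window (pA);
* **charge** = trapezoidal integral of the inward-rectified trace over the
  same window, in pC (1 pA·ms = 1 fC).  Inward currents are reported as
  positive charge;
* **significance**: peak > 7 × SD of the averaged trace's baseline window
  (strictly greater; the threshold is applied to the cell average, not per
  trial);
* **onset latency** = first crossing of 3 × baseline SD that stays above
  threshold for 0.5 ms.  The sustain requirement exists because a single
  super-threshold noise sample would otherwise fake a sub-millisecond
  onset; with it, a cell is flagged as carrying a direct (opsin-mediated)
  photocurrent only when a genuinely sustained current begins within 2 ms
  of the stimulus.

QC: cells with series resistance > 40 MΩ (strict) are discarded; flagged
direct-photocurrent cells are excluded from averaging.  Charge is
preferred over peak throughout because the integral is less attenuated by
dendritic filtering; non-significant spots carry zero charge into maps, so
every map statistic is conditional on the 7×SD detection rule.

## Maps and reported distances

Native 24 × 12 spot grids (rows along cortical depth) are upsampled 2× to
20.833 µm quadrant pixels with each spot's charge split equally among its
four quadrants (charge-conserving; the soma is only localisable to a
quadrant, so all alignment happens on this lattice).  Maps are normalised
to their peak pixel, aligned horizontally on the soma column and
vertically on either the pia or the soma row, and averaged over the union
canvas with per-pixel divisors equal to the number of contributing cells.
Projections are sums (not means) so they conserve total charge exactly.

Peak locations and horizontal biases are the argmax bin's signed offset
from the anchor, ties broken toward the anchor, reported on the
20.833 µm lattice and rounded half-away-from-zero to integer µm (hence
the 21/42/63/83/104 … report values).  Tuft peaks are measured from the
pia, basal and oblique peaks from the soma's quadrant row (positive
toward the pia), horizontal biases from the soma column (positive
medial).

## Compartment allocation

The average morphology profile (per-compartment dendritic length per
10 µm depth bin, averaged over 11 reconstructions after rescaling each to
a common soma–pia distance) is rescaled to the analysed cell's soma–pia
distance and conservatively rebinned onto the map's 20.833 µm depth grid.
Within each depth bin, measured charge is apportioned to basal / oblique /
tuft in proportion to their length shares in that bin; "deconvolution"
here means this bin-wise weighting, not a sliding convolution — it is the
only reading that yields compartment proportions.  Bins with charge but no
dendritic length inherit the shares of the nearest dendrite-bearing bin
(nearest-bin assignment conserves charge; a drop-the-bin variant would
not).  A single pia-aligned depth grid is used for all three compartments:
after rescaling to the cell's own soma–pia distance, pia- and soma-aligned
grids coincide, so a dual-alignment mode would change nothing but the
bookkeeping.  Compartment proportions × the full-field total give absolute
charges; area aggregates sum charges before re-deriving proportions.

Length (not membrane area or spine count) is the weight because the three
compartments carry similar spine densities; the allocation is invariant to
scaling the input profile and conserves charge at every stage.

Known bias: in depth bins where compartments overlap, allocation by raw
length shares ignores the fact that a strongly targeted compartment
contributes more charge per micron there.  With well-separated
compartments this contributes ≲2–3 percentage points of error (measured by
the recovery study below); it is inherent to the method, not to this
implementation.

## Morphology handling

SWC trees are labelled basal / oblique / tuft from the soma out.  The
apical trunk is walked along the dominant-length child; a branch point
qualifies as a bifurcation when ≥2 daughters each hold ≥25 % of the
apical length distal to it, and the **main** bifurcation is the most
distal qualifying node that still has ≥25 % of the whole apical length
distal to it.  The floor is needed because distal tuft branch points are
often near-symmetric and would otherwise qualify; the fallback (no node
clears the floor → most distal qualifying node) keeps degenerate trees
such as a bare trunk ending in one terminal split working.  Both
fractions are configurable.  Trees with no qualifying bifurcation are
labelled all-oblique with an empty tuft and a warning.

Length profiles apportion each segment's length to 10 µm depth bins by
linear overlap of its depth span.  Rescaling to a target soma–pia
distance stretches the depth axis linearly from the pia and conserves
per-compartment length (density scales inversely); profiles are averaged
bin-wise after rescaling.  Depth binning collapses the horizontal axes;
horizontal structure enters only through the 2D maps.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study conditions: 24 × 12 grids of 41.7 µm
spots (1000 µm along depth × 500 µm horizontal), 1 ms stimuli at 10 Hz in
a pseudo-random order in which consecutive spots are never 8-neighbours,
one full-field stimulus per trial, 20 kHz sweeps.  Defaults (chosen once
as realistic study conditions): 8 trials, baseline noise SD 1 pA per
sweep, total input 8 pC (the strong-input end of the observed 0.9–11 pC
full-field range, i.e. comfortable SNR for recovery studies), targeting
(0.10, 0.15, 0.75), soma depth 500 µm.

* **Morphologies** are stylised ttL5 trees: basal dendrites radiating from
  the soma, a trunk ascending to a main bifurcation at ~32–42 % of soma
  depth, obliques off the trunk, a tuft fanning to the pia.  They are
  deterministic per seed (byte-identical SWC) and carry ground-truth
  labels.
* **Per-spot charges** follow the targeting rule: charge from compartment
  *c* at a spot ∝ length of *c* inside the spot × weight *c*, normalised
  so compartment totals equal weight × total charge exactly.
* **EPSC kernel**: difference of exponentials (rise 2 ms, decay 15 ms),
  beginning one synaptic latency (default 3 ms) after the stimulus and
  truncated to the remainder of the 50 ms charge window, normalised by its
  sampled trapezoidal integral.  Truncation-plus-numeric-normalisation
  makes noiseless charge recovery exact to machine precision (the
  closed-form integral of the untruncated kernel is kept as an independent
  oracle in the tests; with a 15 ms decay only ~96 % of the kernel's mass
  lies inside 50 ms, so windowing is what guarantees exactness).  The
  latency matters: with zero latency every strong EPSC would trip the
  2 ms direct-photocurrent rule.
* **Stimulus order** is drawn sequentially, uniformly among remaining
  non-adjacent spots, restarting on the rare dead end — equivalent in its
  guaranteed property (no consecutive 8-neighbours) to rejection-sampling
  whole permutations, but without the ~e⁻⁸ acceptance rate.
* **Noise** is white Gaussian only.  Real recordings add 1/f noise,
  synaptic background and slow drift; the detection criterion only uses
  the baseline SD, so white noise exercises it fully, but passing tests
  say nothing about robustness to non-stationary baselines.  Cable
  attenuation, opsin kinetics, light scattering (the ~60 µm effective
  optical resolution) and slice-angle artifacts are deliberately not
  modelled: simulated recovery quantifies the analysis chain, not those
  physical confounds.

## Peters'-rule prediction

Axon density (any depth-binned CSV) and the pia-aligned average dendritic
profile are conservatively rebinned to a common 20.833 µm depth grid,
each peak-normalised, and multiplied bin-wise.  The prediction is
invariant to positive rescaling of either factor; disjoint supports give
an all-zero prediction with a warning.  Since the printed comparisons are
overlays without a statistic, the package reports cosine similarity
(primary) and Pearson r (secondary) between predicted and measured
profiles on the common grid.

## Area summaries and statistics

Per-area proportions and peaks are computed from the pia-aligned average
of the cohort's normalised maps, allocated with the average morphology
rescaled to the cohort's mean soma depth; totals are means of per-cell
full-field charges (SEM with n−1; reported as unavailable for n = 1).  A
cell "peaks in the tuft" when the argmax of its own vertical profile is
shallower than the main-bifurcation depth of the average morphology
rescaled to that cell.  Per-compartment horizontal biases project the
average map after weighting each depth row by the compartment's length
share at that depth.

Anatomy-vs-function comparisons use Spearman rank correlation between
mean rabies input-cell counts and total charges.  Benjamini–Hochberg
adjustment is the standard step-up procedure (statsmodels backend,
cross-checked against a brute-force oracle in the tests), default FDR
0.1.

## Validation problem sizes

The recovery study uses 10 simulated cells at default conditions with an
11-morphology average profile (mean absolute proportion error ~1–2
percentage points, bound ≤5); the false-positive study uses 10
synapse-free sessions of 3 trials (2880 spot decisions); the overlap
consistency check uses targeting proportional to in-grid compartment
length with a flat axon profile at three noise levels.  These sizes keep
the full validation in the tens of seconds while leaving the statistical
margins wide.

## Known limitations

Allocation inherits the average-morphology assumption: cells whose
dendritic layout deviates from the average are mis-apportioned in overlap
bins.  The 7×SD criterion censors small inputs, so proportions are
conditional on detectability (the detection-bias check — Pearson
correlation between peak-input depth and full-field charge — is the
built-in control).  Horizontal biases are quantised at 20.8 µm and should
be read as lattice offsets, not micron-accurate displacements.
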