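# Methods

## Measurement model

A spread interphase nucleus is treated as a 2D intensity raster in which
fluorescence is proportional to local DNA amount. After background
subtraction, per-nucleus parameters are:

| parameter        | definition                                             | units |
|------------------|--------------------------------------------------------|-------|
| size             | pixel count of the nucleus mask                        | px, µm² |
| DNA content      | Σ (I − background) over the nucleus mask               | a.u. |
| DNA density      | content / area, also per CC and per euchromatin        | a.u./µm² |
| heterogeneity    | sd/mean of background-subtracted nucleus intensities   | — |
| RHF              | CC content / nucleus content                           | — |
| n_CC             | number of labelled chromocenters                       | — |

Contents partition exactly — nucleus = chromocenters + euchromatin over the
same pixels with the same background — so RHF is bounded in [0, 1] and
content conservation holds to machine precision. The nucleolus gets no
dedicated mask; its pixels count as euchromatin. All intensity sums are
background-subtracted (the camera/slide offset is removed); whether raw or
subtracted sums are used only rescales contents jointly, and every derived
quantity used downstream (RHF, heterogeneity, C-values) is invariant under
a common intensity scale.

An alternative heterogeneity mode (`deviating_fraction`: share of pixels
departing >10% from the mean) is provided because legacy image-analysis
packages define the quantity that way; the coefficient of variation is the
default.

## Segmentation

The text-book pipeline for this kind of image is deliberately simple and
parameter-light:

- **Nucleus**: Otsu's threshold on the full image histogram, 8-connected
  components, smallest accepted object 50 px, largest component kept
  (`segment_all_nuclei` returns all of them for multi-nucleus fields),
  holes filled so a dim nucleolus cannot punch a hole in the mask.
- **Background**: mean intensity outside a 5-px dilation of the whole
  foreground, avoiding halo contamination.
- **Chromocenters**: pixels whose background-subtracted intensity exceeds
  μ + k·σ of the background-subtracted nucleus pixels, k = 2.0 by default;
  8-connected components below `min_cc_area` = 4 px are discarded; labels
  are ordered by decreasing integrated intensity (ties: centroid row, then
  column). Zero chromocenters is a valid outcome. Chromocenters closer than
  the labelling connectivity merge into one object — mirroring the frequent
  association of chromocenters in real nuclei — and no watershed splitting
  is attempted.

Both thresholds are defined relative to image statistics, so masks are
invariant under intensity rescaling. Coordinates are 0-based row-major;
areas are reported in pixels and in µm² (pixels × pixel_size²). Legacy RGB
TIFFs are accepted only with an explicit channel choice — DAPI lives in one
plane and a silent luminance conversion would corrupt quantitation.

## Ploidy calibration

Guard-cell nuclei are assumed diploid (2C) and non-endoreduplicated; every
nucleus then gets `c_value = 2 × content / mean(guard-cell content)`.
This is a relative calibration: it needs at least one guard-cell record and
inherits the guard-cell mean's sampling error. A diploid G2 nucleus is
indistinguishable from a tetraploid G1 nucleus by content alone; no attempt
is made to resolve that.

## Cell-type classification

Deterministic, ordered rule on shape descriptors (area, circularity
4πA/P² with Crofton perimeter, best-fit-ellipse aspect ratio):
VC if aspect ≥ 3.0; else GC if area ≤ 30 µm² and circularity ≥ 0.85; else
EC if area ≥ 120 µm²; else PC. Elongation is tested first so large
elongated vascular nuclei are never labelled endopolyploid. The cutoffs are
package defaults chosen to separate the presets' populations — the sorting
this emulates is done qualitatively by eye at the microscope — and all four
are configurable. Small round parenchyma nuclei will be mislabelled GC by
any such rule; the generator's populations keep that rate ≤ a few percent.

## TE partition model

`te_in_cc = (RHF·G − T) / (f·G)` with defaults T = 16.3 Mb
(8.76 Mb centromeric 180-bp satellite + 7.5 Mb 45S NOR arrays) and
f = 0.10. The 19.3-Mb tandem-repeat figure that circulates for the same
arrays is reachable via `GenomeModel(tandem_total=19.3)`; 16.3 is the
default because it is the sum of the two component estimates used here.
5S rDNA (~0.5 Mb) is excluded: it frequently resides outside chromocenters.
45S copy-number variation between accessions (<1% of genome size) is
ignored. The partition is affine in RHF with slope 1/f, its complement is
exact by construction, and its physical edges are
`rhf_bounds = (T/G, (T + f·G)/G)`; at G = 211 Mb these are 0.0773 and
0.1773, i.e. 0.077 at 3 d.p. and 0.18 at 2 d.p. (the lower bound is
reported unrounded/3 d.p. — conventional rounding would print 0.08, and
this module does not second-guess coarser roundings). Report columns round
TE fractions to 2 d.p. and percentages to whole percent; raw values are
always retained.

## Synthetic-nucleus generator

What it emulates: DAPI-stained spread nuclei as an ellipse of uniform
euchromatin intensity `eu`; `cc_count` non-overlapping bright discs of
intensity `f_cc·eu` (peripherally biased placement: radial fraction sampled
in [0.5, 1] of the inset ellipse, matching the peripheral location of
chromocenters); an optional central nucleolus at `0.3·eu` (present for
PC/VC/EC-type presets, absent for GC); a 2% extranuclear background (so
background subtraction is actually exercised); additive Gaussian noise with
sd = 0.05·eu clipped to the bit range (8/16 bit; 16 by default — at 8 bit
quantization is visibly coarser).

Ground truth is computed from the noiseless float raster before noise and
quantization. A chromocenter pixel's **full** signal above background
(baseline + excess) counts as heterochromatin, exactly as the measurement
sums it, keeping generator and measurer commensurable; hence
`true_rhf = f·C / (A − (1−q)·N − C + f·C)` for CC area C, nucleus area A,
nucleolus area N and nucleolus factor q.

Preset sampling inverts that expression: each nucleus draws a target RHF
(normal, sd 0.008 around the preset target), a DNA content (lognormal,
CV 0.12 around the preset's C-value ratio), an area (normal, CV 0.08) and
an aspect ratio, then solves the required total chromocenter area and the
euchromatin intensity in closed form. Chromocenter radii get ±10% jitter
around the solved mean radius. Sub-pixel jitter of the nucleus center makes
rasterized areas unbiased across a population, so population mean RHF
converges on the preset target (within ±0.005 at n = 200).

Preset targets (population means): RHF — GC 0.19, PC/Col/Ler 0.13, VC 0.12,
C24 0.12, Ws 0.10, EC 0.09, Cvi 0.08; DNA content ratios — GC 1.0 (2C
anchor), PC 2.0, VC 2.5, EC 3.35, with C24/Ws at 2.3 reflecting their
larger, more 4C-shifted parenchyma nuclei; nuclear areas — GC 18.4 µm²
(disc of diameter 4.84 µm), PC 46, VC 55 (aspect 3.3–4.5), EC 140 µm²;
chromocenter counts — GC 5–6, accessions/PC/VC 7–8, EC 8–10. Ws and EC RHF
targets are back-solved from their reported TE-in-euchromatin shares (77%
and 87% at a 211-Mb genome); VC satisfies ">40% of TEs in CCs" at 211 Mb.
The GC preset uses a chromocenter contrast factor of 4 (3 elsewhere),
encoding the sharper CC/euchromatin boundary and higher heterogeneity of
guard-cell nuclei.

Determinism: per-nucleus seeds derive from the master seed via
`SeedSequence(master, spawn_key=(index,))`; geometry and noise use separate
substreams, so identical (preset, n, seed) triples are byte-identical and
the noiseless geometry can be replayed independently of the noise.

What it does **not** emulate — and what passing recovery tests therefore do
not demonstrate about real data: optics (no PSF blur, so chromocenter edges
are a single pixel wide and segmentation is easier than in reality), uneven
illumination, dye-specific binding biases, chromocenter shape variation
(discs only), diffuse heterochromatin, touching nuclei in crowded fields,
and 3D structure (a flat 2D section stands in for a spread nucleus).
Recovery rates measured here are upper bounds on real-world performance;
the value of the synthetic route is exactness of the ground truth, not
realism of the noise.

## Profiling

Pearson correlations with two-sided t-distributed p-values are computed per
group over the nuclear + chromocenter parameter set (euchromatin parameters
are omitted — euchromatin dominates every nucleus, >80% of content, and
adds little contrast). Zero-variance parameters yield undefined (NaN)
entries, never 0. Significance tiers: *, **, *** at 0.05/0.01/0.001, raw
p-values by default; Benjamini–Hochberg adjustment is available
(`bh_adjust=True`) but off, matching common practice for these descriptive
matrices. PCA z-scores each parameter over all records, drops constant
parameters with a warning, and pins component signs (largest-magnitude
loading positive) for determinism. Group comparisons: pairwise Welch
t-tests (unequal variances, two-sided) plus one-way ANOVA; with equal
variances and sizes Welch coincides with Student's t. Letter-based compact
significance displays are not produced; the pairwise p-value table carries
the same information.

## Problem sizes and numerical choices

Default test and acceptance populations use 50 nuclei per group at
0.1 µm/px — comfortably inside the 30–100 nuclei per sample customary for
this kind of profiling, and the pipeline processes them in seconds.
Tolerances: ground-truth self-consistency and vectorized-vs-pixel-loop
agreement at 1e-9 (relative); partition complementarity at machine
precision; stochastic recovery bands as stated per test. Degenerate inputs
fail loudly: uniform images, empty masks, zero-mean intensities, missing
ploidy anchors and undersized groups each raise a specific exception rather
than returning silently wrong numbers.

## Pipeline and reproducibility

Stages exchange plain CSV/TIFF/JSON artifacts in a working directory; every
CSV starts with a `# nucleomorph v… config=<sha256-prefix>` comment, writes
are atomic (tmp + rename), and a rerun with an identical config reproduces
byte-identical tables. Configs are flat key/value documents (JSON, or YAML
when available); CLI flags override file values. There is no hidden global
randomness: every stochastic step takes its seed from the run config.
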