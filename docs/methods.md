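# Methods

## The distortion model and its inversion

A raster-scanned field of view suffers a radial distortion whose
strength is summarized by a single angle A (degrees): the distorted
radius of a point at normalized undistorted radius `r_u` is
`r_d = (360/Aπ)·arctan(2 r_u tan(Aπ/720))`, a one-parameter family that
reduces to the identity as A → 0 (the arctan linearizes). The centre of
distortion need not be the frame centre; it is parameterized by two
offsets X_off, Y_off through `c1 = 0.5·C·(1 + |X_off|/S_x)` (and
analogously c2), with the scale constants S_x = S_y = 60 fixed
throughout. Because this form can only push the centre toward larger
coordinates, a negative offset is interpreted as a flip of the image
along that axis before remapping (undone afterwards), which reaches all
four quadrants. Compensation samples the acquired frame at
`M = c·(1 + r·f)` with bilinear interpolation, `f = r_u/r_d` for
pincushion and `r_d/r_u` for barrel, `f ≡ 1` at the removable
singularity `r_u = 0`. Samples falling outside the acquired frame are
zero-filled, and the sampling-validity mask is kept alongside (see
below).

The simulator needs the *forward* distortion. The pincushion↔barrel
mode swap is only a first-order inverse of the compensation remap: at
A = 51° it leaves a ≈0.5 % radial residual at the frame edge — several
pixels on a 1000-px tile, enough to displace the parameter-estimation
optimum. `induce` therefore applies the exact functional inverse: the
radial sampling function of `compensate` is strictly monotone, so it is
tabulated on a dense radius grid (8193 nodes) and inverted by linear
interpolation. `compensate(induce(img))` then round-trips to bilinear
interpolation error (MAE < 0.5 levels on smooth images over the central
80 %).

## Parameter estimation

Two adjacent tiles acquired with the same optics carry the same
distortion but different content; after a *correct* compensation their
shared region agrees, after a wrong one it does not. Each candidate
triple (A, X_off, Y_off — signed, covering the four flip variants) is
scored by `d_k`, the mean absolute difference of the two compensated
tiles over the shared region R12, and the argmin wins. Two numerical
choices matter:

* **Border masking.** Near the tile border the compensation map samples
  outside the acquired frame; those zero-filled samples carry no
  information about the parameters, yet summed over all of R12 they
  dominate `d_k` (measured floor ≈ 23 intensity levels vs ≈ 1 when
  masked) and bias the argmin by several units. `d_k` is therefore
  averaged over the pixels whose remap samples inside *both* frames.
* **Search schedule.** The grid defaults to A ∈ [5°, 60°] and offset
  magnitudes [0, 60], unit steps, all four flip variants — it brackets
  both parameter sets the model is known to produce. The exhaustive
  unit-step scan (~820 k candidates) is the reference; the default
  coarse→fine schedule scans step 5 on copies block-mean downsampled
  2× (the parameters are scale-free), then refines at full resolution
  with step-2 and step-1 passes within one coarse step of the running
  argmin. 2× was chosen over 4× because the shallower (A, X_off) valley
  can alias at 4×.

Preprocessing for scoring follows the opening (5×5 square) + Otsu
binarization recipe, which makes the score robust to high-frequency
noise. On noiseless synthetic targets this binarization quantizes away
the sub-pixel gradients that unit-step recovery depends on, so the
random-triple recovery test scores raw intensities; the headline
(51°, −49, −47) recovery runs with the default preprocessing.

Identifiability caveat: from a single vertical strip, X_off moves the
sampled positions by only ~0.4 px per unit at the strip, and A and
X_off trade off along a shallow valley. A calibration pair should share
a generous overlap (20–30 % of the tile is used here); at a 9 %
acquisition overlap the triple is not reliably identifiable to ±1.

## Resonant-scan resampling

The resonant mirror sweeps with position `x(θ) = (1 − cos θ)/2` while
samples arrive uniformly in phase over the central β fraction of
[0, π] (default β = 0.9; the turnaround extremes are discarded in
hardware). `correct_resonant` inverts this per row by 1-D linear
interpolation at `θ = arccos(1 − 2x)`; `apply_resonant` is the exact
forward model, so the pair round-trips to interpolation error. Point
resampling preserves constants exactly but does *not* conserve row
integrals in general — the Jacobian reweights content — so the
approximate row-sum conservation holds only for rows whose variation is
small against their mean (≈1 % there, up to ~8 % on high-contrast
rows).

## Tile alignment and compositing

Placement starts from the stage estimate (displacement in µm divided by
the pixel pitch) relative to the already-placed left (else top)
neighbour. A candidate offset is scored per neighbour by extracting
both overlap patches, 2× block-mean downsampling (noise suppression),
taking the per-pixel |difference| and its population standard
deviation; `σ_k` sums the available neighbour terms. The coarse scan
steps 10 px over ±30 px (the window must exceed stage repeatability
error; the simulator's ±8 px jitter is comfortably inside); if
`σ_max − σ_min ≥ 1.5` levels the 2-px fine scan within ±12 px of the
coarse argmin decides (one coarse step plus one fine step, so a score
valley straddling the midpoint between coarse nodes is still covered),
otherwise the stage estimate is kept and
flagged — a featureless overlap cannot be aligned by content, and a
fabricated offset would be worse than the stage's own accuracy. Ties
break toward the smallest displacement from the stage estimate, then
row-major.

Two guards keep the score meaningful: candidates whose overlap with any
placed neighbour shrinks below 16 px on an axis are invalid (the
standard deviation of a sliver is spuriously small and otherwise wins),
and the σ computation masks pixels that are zero-filled compensation
border bands on either side (those bands are identical in every tile
and otherwise act as a strong false alignment cue). Compositing
likewise never lets an invalid band overwrite neighbour content.
Default blending is overwrite (newest tile wins); feather blending
(edge-distance-weighted averaging across the overlap width) is
available by flag.

## Virtual H&E rendering

The two lookup tables follow Beer–Lambert absorption toward the target
stain colors: `LUT_c(i) = 255·exp(−(255 − c)·i·k/255)` per 8-bit color
component c, stored as 8-bit entries so the final per-pixel product
`HE = H_remap · E_remap / 255` stays on the 8-bit scale (the product is
computed in floating point and rounded once). Defaults: hematoxylin
(B,G,R) = (180, 0, 90), eosin (210, 165, 250), k = 2.5. Zero signal in
both channels renders white — unstained area looks like bright-field
background — and each output component is monotone non-increasing in
each input intensity.

The contrast-enhancement step (`dce`) is this package's own
background-suppression-then-gain operator exposing the single control
`α_max`: background = grayscale opening with a disk (default radius
31 px, larger than any nucleus), foreground = clipped residual, gain
`g = min(α_max, 255/p99(residual))`. Defaults α_max = 8.0 (THG) and
5.0 (TPEF). It is deliberately pluggable behind one function. Optional
gamma (default 1.0 = off) and bilateral smoothing (off) sit between
enhancement and remapping.

## The bitmap container

`.rfpb` is a frozen little-endian layout: a 4096-byte header (magic
`RFPB`, version 1, dimensions, channels, bit depth, tile-grid shape,
pixel pitch, preview dimensions, section offsets, zero-padded),
followed by a 10× block-mean preview (ceiling-divided dimensions,
partial edge blocks averaged over their actual extent), followed by the
payload row-major with pixels interleaved B, G, R. No compression: the
byte count is exactly `4096 + 3·⌈W/10⌉·⌈H/10⌉ + 3·W·H`, ROI reads are
row-wise seeks, and a 1-gigapixel mosaic computes to ≈2.8 binary GB.
BigTIFF export streams 512-row bands into 512×512 tiles so memory stays
bounded at gigascale.

## The scan simulator

`make_tissue_scene` emulates the morphology contrast the two channels
carry in stained tissue: channel 1 holds anti-aliased elliptical
nuclei (default 1500 mm⁻² at 167 nm pitch, radii 6–14 px with mild
eccentricity, non-overlapping by rejection sampling) over a low haze;
channel 2 holds smooth vessel ribbons plus band-limited Gaussian
texture. The morphological scales are compressed relative to real
tissue at this pitch (real nuclei would span 30–60 px) so that
desk-scale test scenes stay feature-dense; consequences: alignment and
enhancement are exercised on realistic *statistics* (texture, sparse
blobs, haze) but not realistic *absolute scales*, and nothing here
validates color fidelity against real stained tissue — the LUT
arithmetic is exact, but its visual quality on real data is outside
what these tests can show.

`simulate_scan` cuts tiles at planned positions plus integer jitter
uniform in [−8, 8] px per axis (stage repeatability error; the first
tile is unjittered and anchors the frame), applies the forward
distortion, then the cosinusoidal resampling, then Gaussian noise
(default σ = 5, clipped; Poisson optional). The stage log records only
the nominal positions — the jitter is precisely what the stitcher must
recover. All randomness flows from one seeded generator.

## Problem sizes in the test suite

The suite runs on 300–900 px scenes and 300–400 px calibration tiles
(2×2 scan grids), where every stated property is already expressed:
the model parameters are scale-free, and the alignment search only sees
the overlap strips. The acceptance script uses 1000-px calibration
tiles. These sizes are the package's chosen desk-scale defaults;
`plan_mosaic` arithmetic covers the full gigapixel geometry exactly.

## Known limitations

* The contrast-enhancement operator matches the published parameter
  surface (α_max) but not the published algorithm's internals.
* `estimate_params` assumes both tiles share one distortion; drifting
  optics between tiles are not modelled.
* The stitcher chains placements through one neighbour; there is no
  global adjustment, so placement error can accumulate across very long
  rows (invisible at test scale, by design identical to sequential
  real-time operation).
* Color output is defined by the LUT arithmetic alone; no colorimetric
  calibration against scanned brightfield slides is attempted.
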