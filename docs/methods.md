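# Methods

## Scope and design

`ktrscope` is organised as a pipeline of small, composable stages rather
than a monolithic workflow: every stage consumes and produces plain
containers (`FrameStack`, `LabelMask`, `CellTrack`, `TraceSet`,
`DoseMatrix`, pandas tables), so each can be validated in isolation
against ground truth from the synthetic generator. The dose–response fit
is the one place where a statistical model is estimated from data, and it
follows the model/results idiom (`HillCurveModel(...).fit()` returns a
results object with estimates, standard errors, RSS and a `summary()`).

## Synthetic movies

The generator emulates widefield live-cell imaging of adherent cells at a
12-minute cadence (0.2 h frame interval, default 48 h, i.e. 240 frames).

**Geometry and motion.** Nuclei are disks of radius 8 µm (default),
Gaussian-blurred (σ = 0.7 px) to emulate the PSF, moving as a reflected
Gaussian random walk (default σ = 1 µm/frame). A hard-core pairwise
repulsion keeps centre separations above 2.1 nuclear radii: nuclei are
solid, and without excluded volume random walkers would overlap and merge
into single blobs — a failure mode of the generator, not of a detector.
Each cell carries a cytoplasm annulus of uniform intensity extending
10 µm beyond the nucleus, i.e. exactly the span of the downstream 2–10 µm
quantification ring. A wider annulus would overlay neighbouring cells'
rings with signal the contested-pixel exclusion cannot attribute, and a
narrower one (e.g. 6 µm) would leave the outer ring on background so that
the ring *median* no longer reflects cytoplasmic signal. Cytoplasm is
never rendered on top of any nucleus (confluent monolayers tile; nuclei
are not covered by neighbours' cytoplasm), which keeps nuclear medians
clean where cells touch.

**Channels.** Four channels are rendered: H2B (nuclear marker, per-cell
intensity factor halving at division), CDK4/6 and CDK2 KTR sensors
(nucleus at a fixed level `N0 = 1000` a.u., cytoplasm at `N0 × activity`,
so the background-subtracted C/N ratio of rendered pixels equals the true
activity), and a degron channel (nuclear intensity `N0 × degron`). A
constant background of `0.05 × N0` provides signal for background
estimation.

**Activity trajectories.** Piecewise-smooth:

- *untreated*: CDK4/6 ≈ 0.9 with a slow oscillation; CDK2 rises with cell
  age from 0.45 toward 1.55 (saturating exponential, τ = 6 h) and resets
  at division; a geminin-type degron accumulates after ~8 h of age.
- *cdk46i*: CDK4/6 decays to a 0.2 plateau (τ = 3 h); all cells arrest at
  CDK2 ≈ 0.5. A configurable fraction are persisters: a logistic rise
  (τ = 1.2 h) from 0.5 to 1.6 whose 1.0-crossing is placed uniformly in a
  24–36 h window (the crossing-time distribution is a parameter — no
  specific distribution is asserted). A Cdt1-type degron drops ~3 h after
  the CDK2 rise (S entry).
- *cdk46i_plus_cdk7i*: as cdk46i with a smaller persister fraction.

Default persister fractions are 0.48 (CDK4/6i) and 0.10 (combination),
emulating reported persister proportions under mono-therapy and a strong
combination effect; both are overridable per config. Ground-truth
persister labels are always the sliding-window rule applied to the true
CDK2 trajectory, so construction and definition cannot drift apart.

**Noise and illumination.** Poisson shot noise scaled so a nuclear-level
signal has the configured SNR (default 10), plus a small Gaussian read
noise (0.5% of `N0`); `snr=None` renders noiseless frames. Illumination
bias is a smooth multiplicative quadratic field equal to 1 at the centre
and `1 − amplitude` at the corners. Divisions (untreated scenario only)
are a per-frame hazard (`division_rate_per_h`, default 0.04/h, with a
10 h refractory age) placing daughters one nucleus radius to either side
of the parent, each with ~half the parent's H2B intensity. Treated
scenarios arrest and do not divide.

All outputs are pure functions of the configuration including the seed
(single `numpy` Generator, fixed call order): identical configs give
bit-identical stacks.

What the generator does **not** emulate: nuclear texture, photobleaching,
focus drift, apoptosis, cell shape change, 3-D structure, and reporter
saturation. Passing tests therefore demonstrate algorithmic correctness
under the stated imaging model, not performance on arbitrary real data.

## Segmentation

*Fixed-cell*: Otsu threshold on log intensity (robust for bimodal
DNA-stain histograms; overridable), hole filling, 4-connected components,
area filter 30–800 µm² (mammalian nucleus scale), watershed on the
distance transform for components above the area ceiling.

*Live-cell*: the image is centred and scaled by median/MAD so the LoG
detection threshold is expressed in robust-SNR units — detections are then
invariant to multiplying the image by any positive constant. Eight
log-spaced LoG scales span `radius_range/√2` (default radii 5–12 µm);
maxima within one minimum radius merge to the brighter seed; peaks within
the minimum blob scale of the border are discarded (LoG boundary
artefacts). Masks grow from seeds by a per-seed local Otsu threshold in a
(4·r_max)² window, limited to 2·r_max from the seed; contested pixels go
to the nearer seed, ties to the lower label; each label keeps the
connected component containing its seed.

*Flat-field*: background pixels (below Otsu on the log of the temporal
median image) are fitted with a full quadratic 2-D polynomial; images are
divided by the mean-normalised surface. With the generator's quadratic
bias this is exact up to noise.

## Tracking

Per frame pair, a globally optimal one-to-one assignment minimising
summed centroid displacement (Hungarian algorithm), gated at
`max_step_um` (default 40 µm per 12-min frame). Global assignment is what
makes the linker robust to "deflection": a newborn daughter cannot steal
a continuing track's detection if a cheaper total assignment exists.
Unmatched track ends bridge over up to 2 missing frames onto unmatched
starts within `max_step × (gap+1)`. Intensity is deliberately not part of
the linking cost — it is reserved for the mitosis test.

Mitosis detection recognises two geometries at a division frame *t+1*:
(i) a track ends at *t* and two unlinked tracks are born at *t+1* within
25 µm; (ii) the common case under distance-only linking — the parent
track continues into one daughter while the other appears as a newborn;
the continuing track is then split at the division. In both cases the
call requires combined daughter nuclear intensity within 30% of the
parent's; competing candidates resolve by intensity mismatch, then
distance. The numeric thresholds (25 µm, 0.3) are package defaults —
"closely adjacent" and "comparable" are not quantified in the underlying
assay description — and are configurable.

## Reporter quantification

The cytoplasm of label L is the set of pixels whose Euclidean distance to
L's mask lies in [2, 10] µm, excluding pixels claimed by another label's
ring and pixels inside or within 2 µm of any other mask (per-pixel
exclusion: contested pixels are dropped from both rings rather than
dropping whole cells, which keeps data while honouring the overlap rule).
Distances are measured from the mask boundary (exact Euclidean distance
transform). Both compartments are summarised by the **median**; the
nuclear statistic mirrors the cytoplasmic one for symmetry and outlier
robustness. A scalar background (estimated as the median of pixels
farther than the ring outer radius from every mask, or supplied) is
subtracted before the ratio; ratios are therefore invariant to positive
rescaling of the channel. Labels with fewer than 30 usable ring pixels
are flagged invalid rather than reported.

Traces are assembled on the frame grid per track, indexed by time since
treatment; interior gaps of at most 2 frames (bridged detections or
invalid rings) are linearly interpolated and flagged; longer runs remain
invalid — dynamics are never fabricated. Traces shorter than 18 h are
excluded from persister analysis.

Degron phase calling: Cdt1 mode detects a sustained (≥ 3 frames) drop
below 0.5 × running maximum (G1/S at the steepest drop) and a subsequent
sustained recovery above 0.7 × the pre-drop level (S/G2); geminin mode
detects a sustained rise above baseline + 3 MAD (S entry). All fractions
and the sustain length are configurable; a constant or noise-only trace
yields no transitions, not an error.

## Persister classification

A cell is a persister when its longest **contiguous** run of frames with
CDK2 C/N > 1.0, clipped to the 30–48 h window (closed at both edges),
strictly exceeds 4 h. Run length is the time spanned,
`(n_frames − 1) × 0.2 h`, so a run of exactly 4.0 h does not qualify. A
cumulative-time variant is available behind a flag but is not the
default. Cells with less than 80% valid coverage of the window are
excluded from numerator and denominator with a reason code. The
implementation is verified exactly against a brute-force window
enumeration on random traces.

## Dose–response, synergy, volume

The 4PL curve is fitted by bounded least squares on log dose with
multi-start initialisation (quartiles of the positive log-dose range ×
Hill slopes {0.5, 1, 2, 4}); standard errors come from the Jacobian at
the optimum. A fit whose span |top − bottom| is below 5% of the response
scale is flagged non-converged with NaN IC50 (a flat curve has no
identifiable IC50). The recovery study (`ic50_recovery_study`) perturbs a
unit-window 4PL on a two-fold dilution series centred on the true IC50
with constant-CV multiplicative noise — the standard error model for
plate-reader and image-intensity assays.

Bliss synergy is the plain independence model: after re-referencing the
replicate-mean checkerboard to its measured vehicle cell and clamping to
[0, 1] (so the zero-dose margins carry exactly zero excess by
construction), excess = observed − (ya + yb − ya·yb) with ya, yb taken
from the margins; the summary score is 100 × mean excess over the grid,
with a seeded cell-wise bootstrap over replicates for the 95% CI. No
smoothing or outlier correction is applied — the score is the formula,
not a reimplementation of any particular web tool.

Tumor volume is the caliper formula `width² × length / 2` with the
shorter measurement taken as width regardless of argument order.

## Morphometry

Tumor segmentation: Otsu threshold, morphological closing (50 µm
radius), largest connected component, hole filling. The margin-distance
field is the exact Euclidean distance transform of the mask in µm
(outside pixels carry a −1 sentinel). CD8⁺ cells are LoG spots at
lymphocyte scale (radii 3–6 µm) within a 50 µm-dilated mask
neighbourhood. The periphery is the in-mask band with margin distance up
to 500 µm and the core everything deeper; a cell exactly at 500 µm counts
as periphery (the core is strictly "> 500 µm"; the tie set has measure
zero in practice). Periphery + core counts equal the in-mask total by
construction; a tumor too thin to have a core reports NaN core density
with a flag.

## Problem sizes and numerical choices

Benchmarks run at desk scale chosen to exercise every code path: 20–25
cells × 240 frames (noiseless end-to-end recovery), 25 cells × 120 frames
at SNR 10 with divisions (tracking/mitosis), 50-nucleus fields
(detection), 4 × 4 mm sections at 2 µm/px with 400–1000 cells
(morphometry), 100-curve fitting studies. Ties in mask growth and
mitosis pairing are broken deterministically (nearer seed, lower label;
smaller mismatch, then distance), and every stochastic routine takes an
explicit seed, so all results are reproducible bit-for-bit.

## Known limitations

- The LoG grower assumes roughly convex, blob-like nuclei; elongated or
  lobed nuclei will be under-segmented.
- Linking cost is centroid distance only; extremely dense fields with
  steps comparable to cell spacing will swap identities.
- The C/N readout assumes the 2–10 µm ring samples cytoplasm; in highly
  confluent real images much of a ring can be excluded, and the invalid
  flag (not interpolation) is the only mitigation.
- Bliss scoring assumes the response is an inhibition probability in
  [0, 1]; viability readouts must be converted (`y = 1 − normalized
  response`) first.
- The synthetic generator's simplifications (listed above) mean
  quantitative benchmarks bound algorithmic error, not biological or
  optical error on real microscopes.
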