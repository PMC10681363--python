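# Methods

`bait2dtm` implements baited reconstruction: locating particles in 2D
cryo-EM-style images by whitened 2D template matching (2DTM) against a
high-resolution 3D template, reconstructing the located targets in 3D, and
quantifying how much of the resulting map is template bias rather than
evidence, using omit templates and the Ω metric.  This note records the
models, the numerical choices, and what the synthetic studies do and do not
demonstrate.

## Density simulation

Templates are rendered from atomic models with an isotropic Gaussian atom
model: atom *i* of atomic number *Z<sub>i</sub>* contributes a 3D Gaussian of
integrated weight *Z<sub>i</sub>* and variance σ² = (B<sub>i</sub> +
B<sub>extra</sub>)/(8π²) (the Debye–Waller relation, B in Å²).  Each
Gaussian is integrated exactly over voxel cells (erf differences per axis),
so the voxel sum equals ΣZ<sub>i</sub> for in-box atoms regardless of σ, and
integer-voxel shifts are exact.  A width floor of 0.5 voxels guards the
B → 0 limit, where a point mass on a grid would alias; below the floor the
grid, not the B-factor, sets the band limit.  This simulator deliberately
replaces a
physical electron-scattering calculation: absolute density scale is
irrelevant downstream because matching normalizes the template and Ω is a
ratio.

Defaults used by the validation studies: 1 Å pixels, B<sub>extra</sub> =
20 Å² on top of per-atom B-factors of 10–30 Å².  The resulting band limit
(~2.5 Å) relative to sampling matches the regime of real 2DTM templates
(B ≈ 30–50 Å² at ~1 Å sampling), which matters for the false-positive
statistics discussed below.

## Projection, CTF, micrograph synthesis

Projections are central Fourier slices: the volume is 2× zero-padded, its
centered FFT is sampled on the plane perpendicular to the rotated beam axis
with trilinear interpolation, and sub-pixel shifts are applied as phase
ramps.  Euler angles are intrinsic ZYZ (φ, θ, ψ) in degrees, rotating the
object before projection along z.  Against a real-space rotation oracle
(cubic-spline `affine_transform`), rotated projections agree to ~4% RMS;
without the 2× padding the error is ~14%, which is why the padding is not
optional.

The CTF follows the standard weak-phase convention, underfocus positive:
CTF(k) = −[w·cos χ + √(1−w²)·sin χ], χ = πλΔf·k² − (π/2)C<sub>s</sub>λ³k⁴,
with relativistic λ(V).  Defaults: 300 kV, C<sub>s</sub> 2.7 mm, amplitude
contrast 0.07, and a single defocus plane of 12 000 Å for the desk-scale
studies (the in-vitro benchmark in the field also searched no defocus
range).

Synthetic micrographs plant CTF-filtered projections at uniform random
orientations (cos θ uniform) and uniform positions with a half-box margin
and non-overlapping boxes, in white Gaussian noise.  The particle amplitude
for a desired matched-filter peak SNR is a·‖P‖/σ solved for a, with ‖P‖
averaged over random projections.  The optional backgrounds ("gradient",
"blobs") add a smooth field *and* modulate the local noise amplitude by
±40% of the same field — emulating variable specimen thickness, which
raises background and noise power together.  A purely additive smooth field
would be almost entirely removed by spectral whitening and would *not*
violate the Gaussian threshold model; the noise-power modulation is what
produces the excess false positives observed for structured backgrounds.
All randomness flows from one integer seed; identical seeds reproduce
micrographs bit for bit.

What the generator does not model: solvent, dose and radiation damage,
detector MTF, movie frames, astigmatism variation, molecular crowding, or
conformational heterogeneity.  Conclusions from these studies therefore
address the correctness of the pipeline's statistics and geometry, not its
behaviour on real cellular data.

## Whitening and score calibration

The matched-filter score ("2DTM SNR") is calibrated so pure-noise locations
are standard normal: the image is whitened (FT divided by the square root
of its radially averaged power spectrum, DC removed) and rescaled to unit
variance; each template projection is CTF-modulated, filtered by the same
whitening profile, made zero-mean and unit-norm; circular FFT
cross-correlation then yields N(0, 1) noise scores directly.

One estimator detail is load-bearing.  Whitening with the *raw* per-shell
power of the same image couples the filter to the very fluctuations the
matched filter scores: a coherent fluctuation inflates its own shell
estimate and suppresses its own response, deflating the far tail of the
score distribution (measured tail ratio 0.96 at 3.5σ, worse further out).
`match_template_2d` therefore whitens internally with the radial spectrum
smoothed by a 1.5-shell Gaussian in the log domain, which restores tails
indistinguishable from an oracle (data-independent) filter.  The public
`whiten` operation defaults to exact flattening (its contract is a flat
output spectrum); the smoothing width is exposed as `psd_smoothing`.

## False-positive model and its limits

Noise-only detections are governed by the Gaussian tail: the probability
that a noise location exceeds threshold t is r<sub>f</sub>(t) =
½·erfc(t/√2); multiplied by the number of search locations (pixels ×
orientations × defocus planes) it gives the expected false-positive count,
and inversion (via erfcinv, exact) gives the threshold for a chosen count —
by convention one per micrograph.  At the published search sizes this
reproduces the working thresholds 7.30 (6.88 × 10¹² locations) and 7.85
(4.88 × 10¹⁴).

The location-count model predicts the *mean* number of exceedance locations
exactly (verified against an oracle-whitened reference), but the score
field is correlated over the template footprint, so exceedances arrive in
clusters: at the one-per-image threshold a ~6σ extreme — expected
somewhere in every ~10⁹ locations — covers 15–30 correlated cells at once.
Consequences: merged peak counts under-count the model by the mean cluster
size (~2.5×), and exceedance-location counts have variance ~6–8× Poisson.
The noise-calibration study therefore counts exceedance locations (the
model's own quantity, unbiased) and any Poisson-width acceptance band on
such counts must be read with this over-dispersion in mind.  This is
intrinsic to matched filtering with band-limited templates at ~1 Å
sampling, not an implementation artifact.

## Peak extraction and refinement

Targets are greedy maxima of the SNR map above threshold, each suppressing
a disc of the exclusion radius (default half the template box); border
peaks are flagged, not dropped (correlation is circular).  Local refinement
re-scores a target over a fine angular/defocus grid with integer-pixel
shifts and parabolic sub-pixel interpolation, using the same whitened
scoring (the whitening profile resampled onto the template box); if no
candidate beats the input score the input is returned unchanged, so
refined SNR never decreases.

A physical limitation worth stating: at peak SNR ≈ 10 with a 48-px
template, orientations within ~8–10° of the truth change the score by less
than one noise standard deviation.  Inside this basin the argmax is
noise-driven, so refinement cannot localize orientation better than a few
degrees, and refined poses can legitimately move *away* from the truth for
individual particles.  This pose-noise basin shrinks with particle SNR and
with template size, and it is the mechanism behind both the reconstruction
resolution ceiling at low SNR and the alignment component of template bias.

## Reconstruction and FSC

Each boxed particle's FT (residual shift removed by a phase ramp, CTF
multiplied) is spread into a 2×-oversampled 3D Fourier accumulator at its
Euler orientation with trilinear interpolation; CTF² accumulates into a
weight volume; per-voxel Wiener normalization divides by (ΣCTF² + ε) with
ε = 1% of the mean populated weight.  Half-maps split particles by index
parity (deterministic; no seed bookkeeping).  700 noiseless projections
of a 48³ phantom reconstruct with FSC > 0.99 to 0.8 Nyquist.  FSC uses
1-voxel shells; the resolution estimate linearly interpolates the first
crossing below 0.143.

## Template bias: Ω

The difference between a full and an omit template defines test regions;
with ρ<sub>full</sub> and ρ<sub>omit</sub> the masked density sums of the
two reconstructions, Ω = (ρ<sub>full</sub> − ρ<sub>omit</sub>)/ρ<sub>full</sub>.
Ω is reported unclamped with a range flag, per-region for each connected
component, and is invariant under joint rescaling of both maps.

Two estimator choices matter in the noisy, desk-scale regime:

- **Mask tolerance.**  A voxel enters the mask when |full − omit| exceeds
  `rel_tol` × the maximum difference.  With `rel_tol` near zero the mask
  includes the omitted residues' full Gaussian tails, where the *retained*
  neighbouring residues still contribute most of the density (omit/full
  in-mask ratio 0.74 for a period-10 omit of the synthetic polymer): Ω is
  then diluted toward zero even for a maximally biased reconstruction.  The
  sweep study uses `rel_tol` = 0.2, restricting the test regions to the
  residue cores where the templates differ materially.

- **Density scaling.**  The two reconstructions must be identically scaled.
  An ordinary least-squares fit of one noisy map onto another is biased
  toward zero by the noise power in the denominator (measured scale 0.3 for
  maps at this particle count, inflating Ω from 0.07 to 0.7).  When both
  maps come from the same pipeline on the same micrographs, the symmetric
  norm-ratio estimator s = √(Σref²/Σmov²) is exact in expectation;
  `scale_match(method="norm")` implements it and the sweep uses it.  The
  least-squares fit remains the default for maps of different provenance.

## The threshold sweep study

The sweep study plants particles in noise, searches every micrograph with
the full and the omit template, and measures Ω as a function of the
detection threshold.  Desk-scale parameters and their reasons:

- 12 micrographs of 256², 4 particles each, at peak SNR 20 — the
  large-target regime (the field's in-cell sweep used its ~1.6 MDa large
  ribosomal subunit).  At SNR 20 the 30° search grid assigns poses by pure
  quantization, identically for both templates; at SNR 10 the noise-driven
  pose basin interacts with the omitted regions and the resulting
  *differential* alignment overfitting alone produces Ω ≈ 0.3–0.5 in the
  residue cores, swamping the false-positive effect the sweep is meant to
  trace.  (That overfitting is real template bias — the mechanism behind
  the few-percent floor reported on real data — but at desk scale it must
  be suppressed to see the threshold dependence.)
- Periodic omit, period 10 (10% of mass): scattered omits probe bias
  throughout the model; larger omitted fractions measurably drag the
  omit-search poses.
- Peak exclusion radius 16 px (a third of the box): half-box exclusion
  caps the number of noise targets per image so severely that true
  particles dominate the low-threshold reconstructions and Ω cannot
  approach 1; 16 px admits dense false positives while remaining above the
  self-sidelobe radius at SNR 20.

With these choices the sweep at seed 1 gives Ω = [1.00, 0.93, 0.42, 0.16,
0.14] over thresholds [2.5, 3.5, 4.5, 5.4, 6.9] — the expected shape: an
Einstein-from-noise plateau far below the noise floor, a steep fall near
threshold ≈ 4.5, and a low floor at and above the one-false-positive
threshold.  (The 1.00 carries the out-of-range flag: the scaled omit-map
sum in the mask fluctuates around zero when the target lists are almost
pure noise.)  The floor's exact value is stochastic and
condition-dependent; the study asserts the shape, not a number.

## Study sizes

All validation studies use a 2-chain × 20-residue random-walk polymer
(160 atoms; 4 heavy atoms per residue, 3.8 Å backbone steps confined to a
compact sphere) and 256² micrographs.  The noise calibration and the bias
sweep render it at 1 Å into a 48³ template; the calibration searches 100
noise-only micrographs with a 72-orientation grid.  The end-to-end
recovery study plants 300 particles at peak SNR 10 over 30 micrographs,
searches a 15°/15° grid, and applies three-stage local refinement; it
samples at 1.5 Å into a 32³ box — the usual pixel ≈ resolution/3 rule,
since the pose accuracy attainable at SNR 10 supports ~4.5 Å (the
half-map FSC estimate of the study itself), and finer sampling would only
move the FSC targets outside the recoverable band.  These sizes keep each
study in the minutes range on one CPU while exercising every pipeline
stage; they are stated here once and used consistently by the test suite
and the acceptance script.

## Known limitations

- Pose accuracy at SNR ≈ 10 is bounded by the noise basin (above), which
  caps reconstruction resolution from detected-pose particles well below
  what the same images would support with true poses.
- The erfc threshold model counts locations; detection counts after peak
  merging run ~2–3× lower, and location counts are over-dispersed.  Real
  workflows inherit both effects.
- D2 symmetry handling covers omit-site replication and search-grid
  restriction; map symmetrization is not implemented.
- The Ω measurement assumes the two reconstructions differ only by the
  template used for detection; comparing maps from different pipelines
  requires external density scaling.
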