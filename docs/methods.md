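# Methods

This note records the models behind each analysis stage, the conventions
and parameter choices that are decisions rather than measurements, what the
synthetic generators do and do not emulate, and the numerical details a
maintainer would need.

## Coordinates and angles

Images are indexed `[row, col]`, origin at the top-left pixel centre, x
rightward along columns, y downward along rows. All angles are measured
from the +x axis, **counterclockwise-positive as displayed on screen**,
i.e. `atan2(-d_row, d_col)`. Texture orientations are axial quantities on
[0°, 180°); all circular statistics on them use the angle-doubling
transform (map θ → 2θ, summarize on the circle, halve back). Bias angles
and ellipse orientations are reported in (−90°, 90°], positive =
counterclockwise. Vector fields (displacement, traction) store components
in the same screen frame: `v`/`ty` positive points up-screen. A single
stated frame avoids the classic failure mode of chirality analyses —
silently flipping CW and CCW.

Physical units are µm, s and Pa throughout the library; conversion happens
only at I/O. The default image calibration is 0.645 µm/px and the default
live-imaging interval 3 s.

## Chirality

The texture orientation field is the Gaussian-derivative gradient rotated
by 90° (σ = 2 px default). The ROI (annulus or band rasterized from the
pattern geometry) is tiled into grid subregions (default 32 px ≈ 20 µm;
the tests use 24 px against the generator's 16-px texture blocks so each
subregion spans a few independent orientation patches). Within a
subregion, pixels below the 25th-percentile gradient magnitude (quantile
taken over the whole ROI) are discarded; each surviving pixel deposits a
von Mises kernel (κ = 8) on a 1°-binned accumulator over doubled angles,
weighted by gradient magnitude; the dominant direction is the accumulator
argmax refined by parabolic interpolation; the resultant length of the
weighted circular resultant flags unreliable (crossed or isotropic)
subregions. Accumulator bin width, κ, the magnitude quantile and the grid
size are free parameters of the method — none is measurable from data —
and all are exposed as arguments.

Bias = signed axial difference between the dominant direction and the
circumferential tangent through the subregion centroid (ring) or the
pattern axis (line). Summaries use the circular mean and SD on doubled
biases and the Rayleigh test (pingouin); classification is CCW/CW only
when the Rayleigh p < α (default 0.05, two-sided convention) and the mean
bias is positive/negative, otherwise "none".

Subregions need ≥ 50% of their pixels inside the ROI and ≥ 30 surviving
pixels. The null/control condition in the tests is isotropic texture
(κ = 0, uniform axial orientations): with zero bias but finite κ the
subregion biases genuinely concentrate at 0° and a Rayleigh test correctly
rejects uniformity, so an isotropic texture — not a zero-bias anisotropic
one — is the faithful analog of an unpatterned control.

## Synthetic texture generator

`gen_ring_texture` tiles the pattern mask into 16-px blocks; each block
draws one orientation = reference direction at the block centre + bias +
axial von Mises noise (sampled on doubled angles so κ concentrates the
*orientation*; κ = ∞ means no dispersion, κ = 0 isotropic), and renders
sinusoidal stripes (period 8 px, amplitude 0.4 over a 0.5 background,
Gaussian pixel noise σ = 0.05 by default). Sampled angles and block
centres are returned with the truth. The generator does not emulate phase
contrast halos, uneven illumination, or cell-scale segmentation structure;
passing recovery tests therefore demonstrate correctness of the
orientation statistics, not robustness to microscope artefacts.

## Junctions

Skeletonization: Gaussian smooth (σ = 1 px), Otsu threshold (fixed
threshold available), `skimage.morphology.skeletonize`, then iterative
pruning of terminal spurs shorter than 2 µm. Tracing collapses touching
node pixels (degree ≠ 2) into node clusters and emits each degree-2 run
between clusters as one path; pure cycles are emitted closed, split at
their lexicographically smallest pixel. Loops are scored by splitting at
the two farthest-apart points and scoring each half (the chord of a closed
curve is otherwise undefined). Tortuosity = polyline arc length / endpoint
distance; it is scale-invariant and ≥ 1 by the triangle inequality.

The network generator builds a Voronoi diagram of uniform seeds (finite
*and* clipped semi-infinite ridges, so every junction vertex keeps its full
degree inside the frame), perturbs each edge with a sine of amplitude
2 px / 3 periods by default, rasterizes at ~2 px width, and integrates the
true arc length on a 4096-point polyline. An optional shear (x → x + s·y)
of the vertices produces networks with a known chirality sign for the
boundary-angle test. Pixel-chain path lengths overestimate smooth curves
by up to ~8% (staircase effect), so measured skeleton tortuosities are
compared against truth loosely; the tortuosity *operation* itself is
validated on the generator's exact polylines (2% tolerance, dominated by
the 32× subsampling of the stored truth).

Ellipse fits use second central moments of the mask; axis lengths are
4√λ (the moment-equivalent ellipse); polarization < 1.02 is flagged
degenerate and θ reported as 0 (orientation of a near-disc is noise).

## Traction force microscopy

PIV: mean-subtracted windows (default 32 px, 50% overlap, 2 passes),
FFT cross-correlation zero-padded to twice the window, correlation divided
by the triangular overlap envelope (without this the tilted pedestal locks
the subpixel fit toward zero lag), integer peak restricted to half the
window, 3-point Gaussian subpixel fit per axis, peak-to-second-peak ratio
as SNR (threshold 1.3), invalid or low-SNR nodes replaced by the local
median and flagged. Later passes re-extract the deformed window at the
integer-rounded previous displacement. Residual subpixel bias of the
3-point estimator on Gaussian beads is ≈ 0.1 px near half-pixel shifts;
the acceptance bound (RMSE < 0.2 px at density 0.02 beads/px²) includes
it. Recovery tests evaluate interior nodes: windows that straddle the
image edge or a wrap seam see inconsistent texture by construction.

Forward model and inversion use the Boussinesq elastic half-space surface
Green tensor in Fourier space,

    G(k) = 2(1+ν)/(E k³) · [[(1−ν)k² + ν k_y², −ν k_x k_y],
                            [−ν k_x k_y, (1−ν)k² + ν k_x²]],

the standard FTTC kernel for flat polyacrylamide gels (half-space, free
surface; finite gel thickness is out of scope). The forward model pads the
traction grid 4× to approximate the free-space convolution and is
validated against an independent direct-space quadrature of the real-space
Green function on a 16×16 grid (2% agreement away from boundaries; the
oracle samples the analytic traction on a 10× offset-refined subgrid, so
the singular self-term is integrated rather than skipped). Inversion is
per-wavenumber Tikhonov, `T = (GᵀG + λ²I)⁻¹GᵀU`, zero-frequency component
removed (rigid drift); λ is either explicit or chosen at the L-curve
corner (maximum discrete curvature of log residual vs log solution norm
over 25 log-spaced values). Because the measured field is periodic in the
FFT while the physics is not, reconstruction artifacts concentrate in a
~1-window rim at the image boundary; recovery metrics are computed on the
interior. Exact linearity in E holds at λ = 0.

Ring decomposition projects node tractions onto radial/tangential unit
vectors about the ring centre; net moment Σ r⃗ × T⃗ dA (CCW positive),
contractile moment −Σ (T⃗·r̂)|r| dA, and the force-balance residual
|Σ T⃗ dA| / Σ |T⃗| dA over the annulus.

The bead-pair generator renders Gaussian spots (σ = 1.5 px) at uniform
positions and shifts each by the bilinearly interpolated forward
displacement; it does not model photobleaching, z-drift or bead detachment
— the analysis contract being tested is displacement recovery. Synthetic
test scenes use displacement amplitudes of ~0.3–1.4 px, matching the range
where the PIV defaults are appropriate.

## Calcium

Traces are per-frame ROI means. Baseline F₀ and noise SD come from the
frames whose 15-frame running mean lies in the lowest quartile (robust to
spark contamination), then are refined on all frames below F₀ + 2.5 SD —
the quartile selection alone biases F₀ low by ~σ/2, which would inflate
every amplitude by several percent. Detection marks runs of ≥ 2 frames
with F > F₀ + 3.8·SD (the SparkMaster convention; the criterion is a free
parameter), merges runs separated by < 2 frames, and sets onset to the
last sub-threshold frame. Shallow decay tails can re-cross the threshold
and produce small duplicate events at low SNR; callers that want one event
per burst filter on amplitude (the analysis drivers keep events with
ΔF/F₀ ≥ 0.5).

Parameters per event: amplitude (F_peak − F₀)/F₀ with the raw peak frame;
time to peak (peak − onset); FDHM as the time above half amplitude,
measured as the interpolated first-rise-to-last-fall span minus interior
sub-half dips — this counting form is symmetric under noise, so
seed-averaged FDHM is unbiased, and it reduces to the exact interpolated
crossings for noise-free monotone pulses (triangular pulse of base B gives
exactly B/2); full duration to the return below F₀ + SD; decay τ by
nonlinear least squares of A·exp(−t/τ) from the peak to the 10%-amplitude
crossing, seeded by a log-linear fit. Events cut by the trace end are
flagged partial. Amplitudes are ΔF/F₀ (the raw-vs-normalized choice is
undocumented in typical reports; normalized is adopted and stated).
Spatial FWHM is only defined when a line-scan/2D crop is supplied.

Calibration `[Ca²⁺]ᵢ = K_d (F − F_b)/(F_max − F)` uses K_d = 345 nM
(fluo-4); it is strictly increasing on [F_b, F_max) and errors outside
that range rather than extrapolating. No photobleaching correction is
applied by default.

The synthetic spark shape is a linear rise over the time-to-peak followed
by a single-exponential decay — adequate for testing detection and
parametrization, but real astrocyte transients have finite upstroke
curvature and occasionally compound release; the generator enforces ≥ 3τ
separation and refuses overlapping events. Recovery tests run at the
3-s imaging cadence with slow kinetics (rise 9 s, τ 30 s) and SNR 10
(peak ΔF = 10× noise SD); at this setting seed-averaged parameters recover
within 5% and timing within one frame. At SNR ≈ 3 detection still finds
events but single-event kinetics degrade gracefully (amplitude scatter
~30%); that regime is not asserted in tests.

## Barrier

TEER = (R − R_m)·A exactly; negative values (measurement below blank) are
returned and flagged, not clipped. The default insert area is 4.5 cm²
(6-well transwell). An optional normalization by the micropatterned area
fraction (mask area / insert area) is exposed as a separate helper since
the exact seeding-density normalization in such experiments is a lab
convention, not a formula.

Permeability uses the standard two-compartment sink-condition analysis:
P_app = slope(receiver amount vs time)/(A·C₀) by least squares, endothelial
Pe via series subtraction 1/Pe = 1/P_app − 1/Pe_blank. Receiver
concentration needs the receiver volume to become an amount; the volume is
an explicit argument (default 1 mL) because no units close without it. The
blank-insert Pe is a required input, not a constant. The synthetic series
uses constant-CV (5%) assay noise over 13 samples in one hour — sparser or
noisier designs push single-run errors above 10%.

Group contrasts use the classical equal-variance Student's two-tailed
t-test (Welch behind a flag) and fold change of means.

## Pipeline and determinism

`run_pipeline` merges the user config over documented defaults, fans the
global seed out to per-stage seeds by fixed offsets (chirality +101,
junctions +202, tfm +303, calcium +404, barrier +505), and writes a
`summary.json` with sorted keys and no timestamps, so identical
config + seed reproduce byte-identical output. Default stage sizes (three
288-px rings per scenario, one 256-px network, two 192-px bead scenes, a
400-frame trace, 8 records/group) keep a full run under ~10 s on one core;
they are deliberately small demonstration sizes, and every free parameter
is in the config. The acceptance-grade problem sizes (50 rings, 200 null
seeds, 100 spark seeds, 50 PIV seeds) live in the test suite and were
chosen as the smallest sizes at which the estimators' seed-to-seed scatter
is clearly inside the stated tolerances.

## Known limitations

- The PIV subpixel estimator retains ~0.1 px peak-locking bias near
  half-integer displacements; window-deformation or optical-flow refinement
  would reduce it but is out of scope.
- FTTC assumes an infinitely thick substrate and a relaxed reference image;
  absolute tractions from live pairs without a cell-free reference are
  relative.
- Skeleton-based arc lengths carry pixel-quantization error (~up to 8% on
  smooth curves); tortuosity comparisons against sub-pixel truth should use
  the generator polylines.
- The junction tracer can merge two true edges when rendering fuses nearly
  parallel curves; path-count agreement is asserted in aggregate (±5%), not
  per network.
- Classification of chirality is binary-with-null; no effect-size model or
  mixed-effects structure across rings is attempted (none is needed for the
  synthetic conditions).
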