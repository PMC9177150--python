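# Methods

This note documents the models, conventions, parameters and numerical
choices behind `stereomer`, and what the synthetic validation does and does
not establish about real operating-room data.

## Coordinate conventions

All world coordinates are millimetres in RAS orientation; NIfTI volumes are
reoriented to RAS on read and voxel centers sit at `affine · index`
(0-based).  Distance to target (dtt) is signed along the planned
trajectory: positive above the planned target (toward the entry point),
negative below, matching the clinical drive range of +10 mm to −4 mm around
the target.

**Frame registration.** The image→frame map is a least-squares *rigid*
(6-DOF) transform fit to the AC, PC and midsagittal fiducial pairs by SVD
(Kabsch).  Scaling is deliberately excluded: a stereotactic frame is a
rigid body, and a similarity fit would silently absorb planning errors into
a scale factor.  The RMS fiducial registration error is reported alongside.
Collinear fiducials leave a rotation unconstrained and raise a degeneracy
error.

**Ring/arc angles.** Frame vendors do not share one trigonometric
convention.  The package default (`angle_convention="ras"`) maps ring α and
arc β to the unit direction `(cos β, sin β·cos α, sin β·sin α)` so that
ring = arc = 90° is vertical; mounting tokens apply documented sign flips
(`lateral-left` negates the lateral component).  The convention is explicit
and unit-tested rather than inferred; exports from a specific planning
system may need a different convention, which is why the parameter exists.

**Ben-Gun layout.** Channel offsets are built from the unit projection of
frame +Y onto the plane perpendicular to the trajectory ("anterior"
reference), with medial/lateral resolved per hemisphere (medial points
toward the midline).  Non-central offsets have norm 2 mm; the rotated
configuration turns the cross 45° about the trajectory (right-hand rule).
A trajectory parallel to +Y has no anterior reference and is rejected.
Because the layout requires an external reference axis, offset
equivariance holds for global rotations that fix +Y, not arbitrary ones.

## MER feature extraction

**Stable part.** Electrode settling and transient artifacts contaminate
segment edges.  Short-time RMS (0.25 s windows, 0.125 s hop) is screened by
a robust z-score: windows deviating from the median by more than
3 × 1.4826·MAD are flagged, isolated single-window flags are forgiven
(real artifacts span many windows), and the longest contiguous stable run
is kept.  Segments shorter than 4 s, or whose stable run is shorter than
4 s, are rejected with a machine-readable reason.  The 1.4826 factor
normalizes the MAD to the Gaussian SD so the 3-sigma rule flags ~0.3% of
stationary windows; with the raw MAD the same rule would flag ~4% and
fragment stationary data.

**NRMS.** Per-depth RMS divided by the median RMS of the first five stable
steps (the dorsal-most recordings, outside the nucleus).  With fewer than
five stable steps the available ones are used and a warning flag is set; a
zero baseline is an error, not a NaN.

**Spike detection.** The built-in detector band-passes 300–3000 Hz
(4th-order Butterworth, forward–backward, hence zero phase), estimates the
noise level as σn = median(|x|)/0.6745, and takes downward crossings of
−4σn with 1 ms dead time; waveforms are cut −0.5/+1.5 ms around the trough
following each crossing.  All events form one candidate cluster by design:
the pipeline assumes single-unit activity and retains at most one cluster
per segment.  Externally sorted clusters can be fed to the QC stage
directly; when several pass, the highest-SNR representative is kept.

**Residual SNR.** Peak-to-peak of the mean waveform divided by twice the
standard deviation of the residuals (waveforms minus mean).  The factor 2
converts a ±SD noise band to a peak-to-peak-comparable denominator; the
value is capped at 100 when the residual spread is numerically zero.

**Quality rules.** A cluster is rejected when it has fewer than 100 spikes,
when the fraction of inter-spike intervals below 3 ms exceeds 0.10
(strictly — a cluster at exactly 10% passes), or when SNR < 1.5.  Reasons
are reported with precedence count → ISI → SNR.

## Mapping and the brain-shift estimator

Depth profiles are linearly resampled onto a 0.1 mm dtt grid with no
extrapolation (grid points outside the measured range stay missing).
Nucleus boundaries along a trajectory are found by sampling the line at
0.01 mm and testing containment; entry is the largest dtt inside, exit the
smallest.  Containment uses nearest-voxel lookup for label volumes and a
generalized winding number for meshes; distances use a KD-tree over
boundary-voxel centers (half-voxel accuracy) or dense surface samples for
meshes.  Boundaries are necessarily clamped to the sampled drive range.

For the shift estimate, both depth signals are arctan-transformed — NRMS,
and the *negated* distance to the nucleus (proximity), so that agreement
produces a positive correlation peak; the transform compresses heavy tails
and makes the two distributions comparable.  At each candidate lag on the
0.1 mm grid (default range ±5 mm, a plausible brain-shift magnitude) the
Pearson correlation is computed over the overlapping non-missing bins;
z-scoring over the overlap makes the estimate invariant to positive affine
rescaling of either signal.  At least 20 overlapping bins are required at
every lag.  Ties break toward the smaller absolute lag, and a positive lag
means the physiological pattern sits dorsal to the imaging-defined one.
The estimator is exactly shift-equivariant for on-grid shifts.

**Group statistics.** Trajectories are sorted by maximum cross-correlation
and the better half retained; within it, the high-lag group holds lags
above mean + 1 SD (sample SD), and the low-lag group is the equally sized
set with the smallest lags.  Lags enter the split signed, not absolute.
The imaging-based shift is compared between groups with the unpaired
Mann–Whitney rank-sum test by default; a signed-rank variant (pairing by
lag order) is available for compatibility, but two independent groups call
for an unpaired test.  The lag–imaging correlation defaults to Pearson with
Spearman available.  The depth-band comparison tests nucleus-near (top 20%
by trajectory–nucleus distance) against nucleus-far (bottom 20%) NRMS at
every 0.1 mm bin with at least 5 values per group, then applies
Benjamini–Hochberg across bins at q = 0.01 and reports the contiguous
significant band and the near group's median entry/exit.

## Cluster density and overlap

Accepted clusters and all recording sites are pooled in the left hemisphere
(x > 0 mirrored through the midsagittal plane; a nonlinear flip field can
be supplied).  On a 0.22 mm isotropic grid, each voxel's density is the
number of clusters divided by the number of recordings within a closed
1 mm Euclidean ball of its center; voxels with no recordings are undefined
and excluded from the overlap on both sides.  The overlap at threshold τ is
100·|S ∩ nucleus|/|S| with S = {defined voxels with density ≥ τ}; the
threshold is interpreted on the ratio scale (0.5 = half the local
recordings yielded a cluster), not percent-of-maximum.

A known resolution limit follows from the construction: at a nucleus
boundary the 1 mm ball mixes inside and outside recordings, so voxels up to
~0.3 mm outside the surface can sit near density 0.5, and with 0.5 mm drive
steps the discrete sampling pushes roughly half of that thin shell to ≥0.5.
On synthetic no-shift cohorts (where spiking is uniform inside the nucleus
by construction) this caps the τ = 0.5 overlap at about 82–89% rather than
the mid-90s seen with real recordings, where boundary units have attenuated
amplitudes and are detected less often — the synthetic condition is
deliberately adversarial for this metric.

## Stimulation module

The activated volume is a sphere centered on the stimulation site.  The
default radius model is `r = sqrt(I_mA · (pw/90 µs) / k2)` — zero at zero
amplitude, strictly increasing in amplitude and pulse width, strictly
decreasing in the tissue constant k2 (denominator), with k2 = 0.8 by
default and the conventional exploration range 0.5–1.0 (values outside are
allowed but logged).  The model is a pluggable callable: the sphere
heuristic is a placeholder for titration against clinical observations,
and nothing downstream depends on its exact form beyond the contract.
Streamline filtering is segment-exact: a polyline is kept when any segment
(not merely a vertex) passes within the radius, so sparse polylines whose
chord crosses the sphere between vertices are not missed.

## Synthetic cohorts: what they emulate

The generator mimics the retrospective acquisition: plans scattered
laterally around an ellipsoidal nucleus (semi-axes 3 × 5 × 2 mm), descended
by Ben-Gun bundles of three parallel lines 2 mm apart, recording every
0.5 mm from +10 to −4 mm at 24 kHz in 10 s segments.  The planned target
sits in the ventral portion of the nucleus (entry ≈ +3 mm, exit ≈ −1 mm
along the trajectory), matching the asymmetric drive range; plan scatter of
1.5 mm makes ~80% of lines traverse the nucleus, as in the study cohort's
distance spread.  Inside the (shifted) physiological nucleus the noise RMS
is doubled and refractory-Poisson spiking at 30 Hz injects biphasic,
negative-leading templates at 8× the noise level; a lognormal gain drift
(SD 0.1) models slow nonstationarity.  Brain shift is a pure
along-trajectory translation of the physiological nucleus, shared within a
bundle — the estimator only measures along-trajectory lag, so richer
deformation is out of scope.  The imaging-based shift column is the true
shift plus 0.2 mm Gaussian noise.

Two signal modes exist.  `"full"` generates raw traces and drives the
entire feature pipeline; `"rms"` draws per-depth RMS directly from the
generating model (the RMS of a 10 s Gaussian segment concentrates to ~0.2%
of its σ, so only the gain drift matters) and is used for many-seed
estimator sweeps where waveform synthesis adds nothing to what is being
measured.  Recovery metrics are evaluated on the best-correlating half of
each cohort — the same retention rule the group analysis itself uses —
and aggregated as medians over seeds; individual seeds where few lines
traverse the nucleus have honestly heavier error tails.

What passing these tests does *not* show: robustness to cardioballistic
and movement artifacts, anesthesia effects, non-stationary firing,
multi-unit activity, amplitude attenuation near nucleus boundaries, or
errors in nonlinear normalization — none of which the generator models.

## Problem sizes

The validation suite uses 100 cohorts of 20 lines (rms mode) for shift
recovery, one full-waveform 20-line cohort for the end-to-end pipeline and
density map, 2000 replicates for the rank-test type-I error and the
FDR-control simulation, 1000 random clusters for the QC rule oracle, and
10-line batches for geometric oracles — sizes at which every Monte-Carlo
bound in the tests is stable across seeds while the whole suite runs in a
few minutes on one CPU.
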