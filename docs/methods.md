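# Methods

This note documents the models, the numerical choices behind them, and
what the synthetic study conditions do and do not establish.

## Composite scattering model and the two-stage fit

The intensity model is a sum of a power law (large-scale gel-like
fractal network), a Lorentzian (correlated domains of size η), and, at
the second stage, an exponential cut-off on the power law plus a
Gaussian correlation peak centred at q₀ with width σ. η and m are shared
between the cut-off and the Lorentzian; there is no hidden second
correlation length. The derived spacing d* = 2π/q₀ is attached to every
stage-two result and satisfies d*·q₀ = 2π to machine precision.

**Loss.** Unweighted squared residuals of log₁₀ I over points with
I > 0. The log transform balances the three decades of intensity between
the low-q power law and the high-q background; without it the low-q
points dominate the fit entirely. Points with non-positive or non-finite
intensity are flagged at read time and excluded here (the reduction
artefacts stay visible in the data containers). An uncertainty-weighted
loss (dI propagated into log space) is available behind `weighted=True`.

**Parameterisation and bounds.** Amplitude-like parameters (a, c, d, b,
η, σ) are optimised in log₁₀; exponents, q₀ and the packed linear terms
stay native. Default boxes: n, m ∈ [0, 6] (covers the observed range —
n near 4 early, both exponents settling near 2.5), η ∈ [1, 10³] Å,
q₀ ∈ [0.012, 0.028] Å⁻¹, σ ∈ [5×10⁻⁴, 0.02] Å⁻¹. The q₀ box is wider
than the 0.013–0.025 Å⁻¹ peak-*search* window because observed
inter-domain spacings reach ≈233 Å (q₀ ≈ 0.027) at Maturation: the
search window identifies the emerging peak, while the fit must keep
tracking it as it drifts out. Solver: scipy `least_squares` (trust
region reflective), ftol/xtol/gtol 10⁻¹⁰, 500 iterations per start.

**Sequential seeding and multi-start.** Stage one is initialised from
the data (log–log slope of the low-q decade → n, a; high-q tail median →
b; mid-q excess → c). Stage two is seeded from the stage-one parameters
with q₀ started at the detected q⁺ plus the window edges and two σ
starts (0.002, 0.006) — the Gaussian term creates local minima, so a
single start is fragile. Starts are tried in a deterministic order, and
a later start displaces the incumbent only when its residual is lower by
more than 2% (relative): ties keep the earliest.

**Temporal continuity refinement.** At low peak amplitude the model has
a continuous, noise-degenerate valley: a broadened Gaussian can partly
stand in for the Lorentzian, and (c, η, m) trade off against each other.
At 2% intensity noise the valley bottom moves with the noise, so
independent per-frame maximum-likelihood fits scatter in exactly the
parameters the phase map needs. Because the structural evolution is
smooth on the 5-minute acquisition cadence, `fit_series` follows the
forward warm-started sweep with alternating backward/forward refinement
passes: each frame is refit with a weak quadratic penalty anchoring the
packed parameters to the neighbouring frame's solution (weight 0.02 per
characteristic step scale — roughly "five noise points per step-scale of
movement"), and the anchored solution is adopted when its *data*
residual is within 10% of the incumbent's. Data-determined directions
are untouched (the 120-point data term dominates the 9 penalty terms);
only flat directions are pulled onto a continuous branch. A cold-start
mode (`warm_start=False, refine_passes=0`) exists for independence
checks. Failed frames are recorded and skipped; the series continues.

## Model-free metrics

The apparent invariant integrates I·q² by the trapezoid rule over the
measured grid only — no Porod/Guinier extrapolation, hence "apparent":
its absolute value depends on the q-window and shows apparent temporal
evolution. The correlation peak is the most prominent strict local
maximum inside the mid-q window; on a steep underlying slope the
apex of the *sum* sits slightly below the Gaussian centre, a bias shared
with any peak-picking on measured curves. `find_correlation_peak`
defaults to raw intensity and zero prominence threshold; the
series-level `metric_traces` instead smooths over 3 points and demands
prominence ≥ 2% of the local intensity, because with multiplicative
noise an unfiltered strict local maximum fires in essentially every
frame. For frames without a detectable peak, the mid-q trace reads the
intensity at the series' reference position (median detected q⁺), so
the two-regime intensity trace is defined through the whole run; the
landmarks derive from that merged trace. t(q⁺) is the earliest time
attaining the trace maximum; t(q_on) is the first time after the
post-maximum minimum at which the trace exceeds that minimum by 10% of
the total range (the onset of the second rise has no published formula;
the fraction is configurable).

## Phase clustering

Z-scoring uses the population convention per sample over the eight
parameters (a, n, c, η, m, d, q₀, σ); the background is excluded.
Zero-variance columns become zeros with a warning rather than NaNs.
DBSCAN uses a closed ball (distance ≤ eps) with the point itself counted
toward min_samples — conventions differ between implementations, so the
test suite pins this one against a brute-force oracle. Clusters take the
four canonical phase names in order of median member time; extra
clusters beyond four are demoted (smallest first) to noise with a
warning, and fewer than four are reported as-is, never padded. Hull
volumes are computed in the Z-scored (n, m, d) subspace where the phase
envelopes are visualised — an eight-dimensional option exists but on
~60 frames an 8-D hull is noise-dominated — with phases of fewer than
four points or degenerate geometry assigned volume 0. Per-phase η and
d* statistics use the population standard deviation, so single-member
phases report ± 0.

## Kinetics

The logistic form is forced by the onset definition: only for
baseline + A/(1+e^{−(t−t_m)/τ}) does "two time constants before the
midpoint" land exactly at a fraction 1/(1+e²) = 0.11920 of A. Initial
values come from data quantiles (5%/95% for baseline and amplitude, the
first mid-crossing for t_m), making the fit deterministic. A fit that
fails to beat a flat model by at least 1% of variance is flagged — the
logistic family contains near-flat members, so a strict comparison would
never trigger. The plateau time has no published definition; the default
rule takes the first time the 3-point-smoothed trace enters and stays
within 2% (of the trace range) of its final median, and `plateau_rule=
"fit"` provides t_m + 2τ instead. On noisy traces the "last exit from
the band" construction is conservative (late) — the band is of the same
order as the smoothed noise.

Spectral channels read the mean within ±2 nm of 450 nm (turbidity proxy:
the attenuation of the excitation line at 90°) and 485 nm (ThT
emission). FTIR preprocessing subtracts the buffer 1:1 (a scalar-scaled
subtraction is available), isolates 1590–1720 cm⁻¹, removes the linear
baseline through the window endpoints (which anchors them to zero) and
normalises to unit trapezoidal area; band kinetics read ±2 cm⁻¹ around
1620 and 1695 cm⁻¹ and are min–max normalised per band.

## Joint MCR-ALS

The two probes are concatenated column-wise over the shared frame-time
rows; every fluorescence channel is linearly resampled onto the SANS
frame times and the series are truncated to their temporal overlap. Each
block is scaled to unit maximum and the fluorescence block rescaled so
both carry equal total variance — otherwise the ~120-column SANS block
out-votes the emission block. Alternating NNLS (one exact
non-negativity-constrained solve per row of C, then per column of S)
makes the lack of fit, 100·√(SSE/total SS), non-increasing by
construction; it is asserted at every iteration. Convergence: relative
lack-of-fit change < 10⁻⁸ or 500 iterations. Scale indeterminacy is
fixed by unit-maximum signatures with the compensating scale moved into
C; the reconstruction is invariant under this renormalisation.
Initialisation is purest-row selection (successive rows of maximal
residual after projecting out the span of those chosen); seeded random
non-negative starts are the fallback and drive the restart envelopes:
restarts within 5% (relative) of the best lack of fit are
component-matched to the best solution by profile correlation and the
pointwise min/max over the matched profiles forms the uncertainty band.
Only non-negativity constraints are applied — no closure (the components
are not an exhaustive mass balance) and no unimodality. The default
component count is 3; `select_rank` (smallest rank explaining ≥ 99.5% of
variance, with the full scree) is always reported so the choice is
auditable. Correlation maps min–max normalise each signal, resample it
onto the component time grid, truncate to the common overlap and report
Pearson r; constant signals give NaN.

## Synthetic study conditions

The generators reproduce the acquisition design: frames every 5 min from
t = 5 min on q ∈ 0.002–0.5 Å⁻¹ (120 log-spaced points), pH decaying
exponentially 7.5 → 3.6 with rate proportional to the GdL load (0.042
min⁻¹ per % w/v, placing pH ≈ 4.5 at 35 min for 1%), a ThT logistic with
midpoint 128 min and τ = 20.5 min (onset 87 min), a slower turbidity
rise, and amide-I spectra whose 1695 cm⁻¹ band saturates fast while the
1620 cm⁻¹ band follows a lagged sigmoid.

Parameter truth trajectories are sums of logistic steps between
per-phase anchors (boundaries 35, 180, 300 min) plus smooth seeded
drift. Anchors follow the observed evolution: η 100 → 50 → 70 → 62 Å,
d* 365 → 380 → 295 → 235 Å, Gaussian amplitude peaking near 0.35 early
in Pre-assembly then declining gradually (its own step times, 35 and
95 min), n peaking near 4, m near 2.7 then 2.5. The power-law amplitude
is derived from a scripted low-q intensity (tens of cm⁻¹) because
scripting `a` directly lets the n evolution swing I(q_min) over decades.
Intensity noise is multiplicative (default 2%, the mid-q relative-error
regime of reduced data) plus an additive floor of background × noise;
at zero noise the series is an exact inverse crime and the fits recover
the truth to optimizer tolerance. The within-phase drift uses a
Gaussian-smoothed noise process with a correlation length of a few
frames and phase-dependent amplitude, largest during Pre-assembly: slow
drift yields a large total spread (the structural plasticity that makes
the Pre-assembly hull dominate the phase map) while keeping
consecutive-frame steps small enough for DBSCAN's chain connectivity —
fast uncorrelated scatter of the same amplitude fragments the cluster.
FTIR noise is multiplicative, and the random-coil band loses exactly the
area the β bands gain (redistribution conserving the amide-I oscillator
strength), so the area normalisation does not distort the band
waveforms.

What passing on these conditions shows — and what it does not: the
pipeline provably inverts its own forward model under realistic noise,
cadence and parameter evolution, with correct oracle-checked building
blocks. Real reduced data add effects the generator omits: instrument
resolution smearing, q-dependent (not purely multiplicative) error
structure, background drifts, frames lost to beam interruptions, and
model misspecification (real gels are not exactly
power-law + Lorentzian + Gaussian). Recovery rates measured here are
therefore upper bounds on real-data performance, and the phase-map
behaviour is demonstrated on the packaged fixed-seed reference series;
under reseeded drift realisations the four-cluster recovery holds for
most but not all seeds at eps = 1.0.

## Orchestration

`run_full` executes metrics → fits → phases → kinetics → MCR →
correlations from a single config, skipping stages whose inputs are
absent (SANS-only runs are valid; the methanol mode stops at stage-one
fits and skips phases/MCR since no correlation peak exists). Outputs are
fixed-name CSVs plus a JSON report with stage status, landmark times, a
phase summary table, the MCR lack of fit and SHA-256 checksums of every
file written. All randomness flows from the config seed; re-running a
config reproduces the outputs byte-for-byte (writers print floats with
`%.17g`, and readers parse with round-trip precision).

## Known limitations

* Landmark t(q_on) and the ThT plateau time are heuristic definitions
  (documented above); both expose their thresholds as parameters.
* The continuity-refined fits trade a small bias in weakly identified
  parameters for a large variance reduction; cold-start mode quantifies
  the trade on any series.
* MCR rotational ambiguity is reduced, not eliminated, by the joint
  blocks and non-negativity; the restart envelopes make the remaining
  ambiguity visible rather than removing it.
* The eight-dimensional hull option is provided but defaults off; hull
  volumes on few dozen points are estimator-noisy in high dimension.
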