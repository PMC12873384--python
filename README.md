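# silkgel

Multimodal analysis of regenerated silk fibroin (RSF) gelation for
scattering and biophysics groups following protein self-assembly in real
time: time-resolved small-angle neutron scattering (SANS) acquired
simultaneously with ThT fluorescence and a turbidity proxy, plus off-line
pH and FTIR amide-I series. The package turns those raw time series into
the quantities that describe the gelation pathway — structural parameter
trajectories, a phase map, resolved components and kinetic landmarks —
and ships seeded generators that emulate the beamline study conditions so
every stage is testable without instrument data.

## The models

**Hierarchical scattering model.** Each reduced 1-D frame I(q) on
q ∈ 0.002–0.5 Å⁻¹ is fitted sequentially with two composite models.
Stage one captures the gel network and correlated domains:

    I(q) = a/qⁿ + c / (1 + (ηq)ᵐ) + b

with power-law amplitude a and gel fractal exponent n (large-scale
network), Lorentzian amplitude c and correlation length η (Å) with
internal exponent m (domain structure), and incoherent background b.
Stage two, seeded from stage one, adds an exponential cut-off on the
power law and a Gaussian correlation peak:

    I(q) = (a/qⁿ)·e^{−(ηq)ᵐ} + c/(1 + (ηq)ᵐ) + d·e^{−(q−q₀)²/(2σ²)} + b

η and m are shared between the cut-off and the Lorentzian. The
inter-domain spacing d* = 2π/q₀ (Å) is derived, never fitted. Fits
minimise squared residuals of log₁₀ I over points with I > 0. The
methanol-induced pathway (rapid aggregation, no correlation peak) uses
stage one only.

**Model-free metrics.** Per frame: the apparent invariant
Q* = ∫ I(q)·q² dq over the measured range, the mid-q correlation peak q⁺
(most prominent local maximum in 0.013–0.025 Å⁻¹) with its intensity,
and the mean low-q intensity — plus the landmark times t(q⁺) (peak
intensity maximum) and t(q_on) (onset of the second intensity rise).

**Phase map.** The eight fitted parameters (a, n, c, η, m, d, q₀, σ) are
Z-scored and clustered with DBSCAN (eps = 1.0, min_samples = 5);
clusters ordered by median time become the four gelation phases
Initiation → Pre-assembly → Network Assembly → Maturation, summarised by
convex-hull volume shares in the (n, m, d) subspace and per-phase
η / d* statistics.

**Joint component resolution.** SANS and fluorescence blocks sharing the
frame-time rows are concatenated and factorised by multivariate curve
resolution – alternating least squares (MCR-ALS, non-negativity on
concentrations and both signature blocks), giving three components with
concentration profiles C1–C3, scattering and emission signatures,
restart-based uncertainty envelopes, and a Pearson bubble matrix against
the model parameters, ThT and turbidity.

**Kinetics.** ThT traces are fitted with a four-parameter logistic
baseline + A/(1 + e^{−(t−t_m)/τ}); the onset ThT_on = t_m − 2τ sits at
1/(1+e²) ≈ 11.9% ("approximately 12%") of the amplitude. FTIR amide-I
spectra are buffer-subtracted, baseline-corrected and area-normalised
before the 1620 cm⁻¹ (crystalline β-sheet) and 1695 cm⁻¹ (antiparallel
β-contact) band kinetics are extracted.

## Worked example

```python
import silkgel as sg
from silkgel import synthetic as syn
from silkgel.kinetics import fit_sigmoid, landmarks
from silkgel.metrics import metric_traces

data = syn.reference_dataset(seed=1)          # one complete synthetic sample
mt = metric_traces(data["sans"])              # model-free per-frame metrics
traj = sg.fit_series(data["sans"])            # sequential two-stage fits
phases = sg.cluster_phases(traj)              # DBSCAN phase map
fit = fit_sigmoid(data["tht"])                # logistic ThT kinetics
lm = landmarks(fit, data["tht"])

print(f"t(q+) = {mt.t_q_plus:.0f} min, t(q_on) = {mt.t_q_on:.0f} min")
print(f"ThT onset {lm.tht_on:.0f} min, midpoint {lm.tht_m:.0f} min, "
      f"plateau {lm.tht_p:.0f} min")
print(phases.summary().round(1).to_string(index=False))
```

prints

```
t(q+) = 70 min, t(q_on) = 210 min
ThT onset 87 min, midpoint 128 min, plateau 369 min
           phase  volume_pct  n_frames  eta_mean  eta_sd  dstar_mean  dstar_sd
      Initiation         0.0         6     100.9     1.4       367.2       1.0
    Pre-assembly        95.1        27      51.1     4.7       386.2      10.2
Network Assembly         4.5        23      71.3     2.7       300.4      11.1
      Maturation         0.3        24      60.2     3.9       234.0       2.5
```

The correlation-peak maximum precedes the ThT onset, which precedes the
ThT midpoint — β-sheet formation follows nanoscale clustering. The
Pre-assembly phase occupies nearly all of the parameter-space hull
volume (high structural plasticity), with correlation lengths shrinking
from ≈100 Å at Initiation to ≈60 Å at Maturation and the inter-domain
spacing tightening from ≈370 Å to ≈235 Å.

The same pipeline runs from the shell:

```sh
silkgel simulate -o sample --seed 1        # write a synthetic sample dir
silkgel metrics sample/manifest.yaml       # q*, q+, low-q traces
silkgel fit sample/manifest.yaml           # two-stage fit table
silkgel run -c config.yaml                 # full orchestrated analysis
```

Deposited experimental CSVs can be analysed the same way by pointing a
manifest at the per-frame files (the reader accepts a column-name
dialect map).

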