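# Methods

This note records the models behind each dibkit module, the defaults and
why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that affect results.

## Osmotic transport model

The two-droplet system is closed: solute amounts n₁, n₂ are fixed
(water is the only permeant; aspirin and buffer are treated as
impermeable on the measurement time scale), and total volume is
conserved. The flux law is the standard osmotic volume flow

    dV₁/dt = P_f · V_w · A · (c₁ − c₂),  c_i = n_i / V_i,

with V_w = 18.05 cm³/mol (molar volume of water in the 25–30 °C working
range, exposed as `osmotic.V_W_CM3_PER_MOL`). Osmolality (mOsm/kg) maps
to concentration (mol/m³) one-to-one under the dilute convention (water
density 1 kg/L); ideal osmotic behaviour is assumed, so osmotic
coefficients are folded into the measured osmolalities. Internally
lengths are μm, volumes μm³, time s; V_w·c is dimensionless so
P_f·A·(V_w·Δc) is directly μm³/s.

Only V₁ is integrated (V₂ follows by conservation, which therefore holds
to machine precision); the solver is adaptive RK45 at rtol 1e−10 with a
terminal event guarding against a droplet volume reaching zero (possible
when one droplet carries no solute). The requested `dt` is a sampling
interval, not a solver step. The bilayer contact area is held at its
initial value during simulation: over the shrinkage windows analysed the
area change is second-order, and the contact radius is emitted as a
constant column.

Radii are reconstructed from volumes in either `sphere` mode (default:
full-sphere volume; cap corrections are second-order at contact angles of
25–37°) or `truncated` mode (sphere minus the contact-plane cap, inverted
numerically by bracketed root-finding); forward and inverse paths always
use the same mode.

### P_f estimators

- *Initial slope*: a line through the first `window` volume samples gives
  (dV₁/dt)|₀, and P_f = slope / (V_w·A₀·Δc₀). Exact in the noiseless
  small-time limit; biased low as the window grows because the driving
  force decays (this monotone bias is asserted in the tests).
- *Trajectory fit*: bounded scalar least squares of both droplets' radii
  against the forward model, minimised over P_f; the standard error comes
  from the local curvature of the objective, se = √(2σ²/SSR″). When no
  initial state is supplied it is reconstructed from the first sample —
  note that with noisy data this reconstruction, not the fit itself,
  dominates the estimator variance, so recovery studies pass the known
  initial state.

Both raise a cannot-estimate error when Δc = 0 (P_f is unidentifiable
without a driving force). The relative-change statistic
100·(P_f − P_f°)/P_f° is rounded to a whole percent, the reporting
convention for this quantity.

## Interfacial energetics

The contact angle of two adherent spherical droplets is the mean
half-angle θ = ½[arcsin(r/R₁) + arcsin(r/R₂)] — symmetric in the two
radii and reducing to arcsin(r/R) for equal droplets. Angles are stored
in degrees and converted only inside the trigonometry. The derived
quantities γ_B = 2γ_m cos θ, ΔF = 2γ_m(cos θ − 1) and π = γ_m(1 − cos θ)
satisfy two identities used as machine-precision invariants:
γ_B + |ΔF| = 2γ_m and |ΔF| = 2π. ΔF is kept signed (≤ 0, adhesion is
spontaneous) with |ΔF| exposed for report output, which rounds γ_B to 2
decimals and |ΔF| to 3.

## DSC analysis

Excess heat capacity is Cp(T) = Φ/(β·n) with Φ the endothermic-up heat
flow (mW → kcal/s via 4184 J/kcal) and β the scan rate (°C/min → °C/s);
endothermic-down inputs are flipped at read time. The baseline is the
straight line through the mean points of two flanking windows — linear
because the analysed transition region is narrow; sigmoidal baselines are
out of scope. A prominent maximum lying inside a flanking window aborts
the correction (prominence judged against a robust MAD scatter estimate,
so a peak inside a window cannot mask itself).

Tm is the apex of the parabola through the maximum sample and its two
neighbours, decoupling Tm precision from the temperature grid (error
≤ grid/10 for symmetric peaks). ΔH is the trapezoidal integral over the
peak support: the contiguous region where the corrected curve exceeds
max(noise floor, 1% of apex), extended outward to the baseline
crossings. The noise floor is z·σ with z = max(3, √(2 ln n) + 1): the
threshold must grow with record length because the expected extreme of n
noise samples is ~√(2 ln n)·σ, and a flat 3σ cutoff reads pure noise as
a transition on scans of hundreds of points. σ is estimated from the
first/last deciles by MAD unless supplied. When no sample clears the
floor the result is the explicit no-transition record (ΔH = 0, Tm
undefined) — the physically expected outcome for the 1:1
lipid:cholesterol composition. Temperature shifts are reported to one
decimal and enthalpy changes as whole percents.

## Raman analysis

Band intensity is the windowed maximum (±10 cm⁻¹), robust and
parameter-free; fitted band amplitudes could be added without changing
the interface. Normalisation scales the 2849 cm⁻¹ band to 1 and is
idempotent and scale-invariant. Aspirin subtraction resamples the
reference to the mixture grid (linear interpolation), scales it by
k = I_mix(1606)/I_ref(1606) — the single-anchor rule is preferred over
full-spectrum least squares, whose scale would be biased by the lipid
bands — and clips negative residuals at zero. Over-subtraction is flagged
when the clipped intensity *mass* exceeds 5% of the total: counting
negative samples would misfire, since baseline noise dips below zero in
half of all baseline channels regardless of k. No smoothing is applied by
default. The order ratios require coverage of 2800–3000 cm⁻¹ and error
out naming any band that sits below the noise floor; cholesterol-rich
compositions (4:1, 1:1), whose C–H region is confounded by overlapping
sterol bands, are outside the scope of ratio analysis.

## Synthetic data

Generators are pure functions of (config, seed); each modality draws from
an independent stream derived from the master seed, so one modality can
be regenerated alone, and fixture trees are byte-identical for a fixed
seed. Every fixture carries its truth record.

- *Response tables.* The default P_f table holds the reported condition
  values per (lipid, cholesterol ratio, pH) at χ_ASA = 0 and 0.5, with
  linear interpolation in between; the DSC table holds the reported
  (Tm, ΔH) pairs with invented Gaussian widths of 0.8–1.6 °C that broaden
  with drug content. These defaults make closed-loop recovery tests
  double as consistency checks against the reported values.
- *Shrinkage.* Two 100 μm droplets, 40 μm contact radius, 300 vs
  100 mOsm/kg, 60 samples at 5 s — a gradient and duration that identify
  P_f in the 30–120 μm/s range. Noise is multiplicative Gaussian on the
  radii (1% default), emulating image-analysis error that scales with
  droplet size. Not emulated: droplet drift, segmentation outliers,
  evaporation, area relaxation.
- *DSC.* Cp = ΔH·N(T; Tm, σ) on a −40…0 °C grid at 0.05 °C, plus a
  mildly sloped linear baseline, additive noise (0.002 kcal·mol⁻¹·°C⁻¹
  default, ~0.04% of the main-peak apex — instrument-class thermograms at
  ~16 mg/mL lipid are very clean), mapped to heat flow through the exact
  inverse of the molar normalisation (5 °C/min, 3×10⁻⁷ mol defaults).
  Not emulated: thermal lag, multi-component transitions, hysteresis.
- *Raman.* Lipid and aspirin band tables (Gaussians) over
  1200–3100 cm⁻¹ at 1 cm⁻¹. A disorder parameter d ∈ [0,1] shifts the
  2848 band upward and reweights/broadens the asymmetric band, so both
  order ratios rise monotonically with d; d is linear in χ_ASA with a
  steeper slope at pH 3 (uncharged drug partitions into the chain region)
  and attenuated by cholesterol. The pure-lipid truth spectrum carries no
  1606 cm⁻¹ intensity (only a far tail of the 1650 cm⁻¹ C=C band), so
  anchor-scaled subtraction is exact up to noise. Not emulated:
  fluorescence background, cosmic rays, cholesterol band overlap.

Because the generators share the analytic forms the analysers assume
(Gaussian peaks, exact flux law), passing closed-loop tests demonstrates
correctness of the computational chain — unit handling, baseline algebra,
estimator consistency, subtraction scaling — not robustness to the model
mismatch real instruments produce.

## Problem sizes

Default analyses are desk-scale: shrinkage series of 60–120 samples,
801-point thermograms, 1901-point spectra; the Monte-Carlo recovery
study uses 30 replicate seeds per permeability value. All were chosen as
representative of the corresponding instrument outputs.

## Known limitations

- The contact-angle formula assumes two spherical caps meeting at a flat
  contact disc; strongly unequal droplet pressures that bow the bilayer
  are not modelled.
- The permeability model treats solutes as ideal and impermeable; slow
  drug permeation would bias long-window fits.
- The linear two-window DSC baseline substitutes for the (unspecified)
  instrument-software baseline; it is validated only on synthetic data.
- The anchor-scaled Raman subtraction assumes the mixture's aspirin
  spectrum is a scalar multiple of the pure reference; matrix effects
  that reshape bands would leave residuals.
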