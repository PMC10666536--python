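# dibkit

Analysis toolkit for droplet-interface-bilayer (DIB) studies of
drug–membrane interaction: osmotic water permeability from droplet
shrinkage, interfacial energetics from droplet contact geometry, DSC
phase-transition thermodynamics, and Raman acyl-chain order ratios —
plus seeded synthetic-data generators that emulate all four measurement
modalities, so every stage of the pipeline is testable without any
instrument data.

The scientific setting: a DIB is the lipid bilayer that forms at the
contact zone of two lipid-monolayer-coated aqueous droplets held in oil.
It is a convenient model membrane for asking how an amphipathic drug
(here aspirin, whose charge state switches around its pKa ≈ 3.5) perturbs
phosphatidylcholine bilayers with varying cholesterol content. dibkit
implements the complete computational chain of such a study for users who
have digitized droplet radius time series, heat-flow thermograms and
Raman spectra.

## The quantities computed

**Osmotic water permeability.** Two droplets with solute amounts n₁, n₂
and bilayer contact area A exchange water by the osmotic volume-flow law

    dV₁/dt = P_f · V_w · A · (c₁ − c₂),  c_i = n_i/V_i,  dV₂/dt = −dV₁/dt

with V_w = 18.05 cm³/mol the molar volume of water. `dibkit.osmotic`
forward-simulates this closed system and inverts observed radius series
to P_f (μm/s) by either an initial-slope estimator or full-trajectory
least squares, and reports the whole-percent change P_f/P_f° relative to
the drug-free bilayer.

**Interfacial energetics.** From the monolayer tension γ_m of the
oil–lipid–water interface and the droplet contact angle θ
(θ = ½[arcsin(r/R₁) + arcsin(r/R₂)] from the contacting-sphere geometry):

    γ_B = 2 γ_m cos θ        bilayer tension
    ΔF  = 2 γ_m (cos θ − 1)  Young–Dupré free energy of bilayer formation
    π   = γ_m (1 − cos θ)    lateral pressure ( = |ΔF| / 2 )

**DSC.** `dibkit.dsc` converts heat flow (mW) at a known scan rate and
lipid amount into molar excess heat capacity, removes a linear baseline
anchored in two flanking windows, and reads the main transition: Tm as
the parabolic-interpolated apex, ΔH as the integrated peak area
(kcal/mol), plus the FWHM.

**Raman order ratios.** `dibkit.raman` normalises spectra to the
2849 cm⁻¹ phospholipid band, removes aspirin-originating bands by
subtracting the pure-aspirin reference scaled at its 1606 cm⁻¹ aromatic
anchor, and reports the acyl-chain order ratios I(2848)/I(2890) and
I(2930)/I(2890), whose increase signals chain decoupling and disorder.

## Worked example

Derive bilayer energetics from measured (γ_m, θ) pairs — here the
drug-free DOPC bilayer and the same bilayer at aspirin mole fraction 0.5:

```sh
$ cat tension_demo.csv
label,gamma_m_mN_m,theta_deg
1:0,1.12,36.7
1:1,0.92,25.9
$ dibkit tension tension_demo.csv
label  gamma_m_mN_m  theta_deg  gamma_B_mN_m  abs_delta_F_mJ_m2  lateral_pressure_mN_m
  1:0          1.12       36.7          1.80              0.444               0.222011
  1:1          0.92       25.9          1.66              0.185               0.092407
```

The drug lowers the bilayer tension from 1.80 to 1.66 mN/m and more than
halves the adhesion free energy (0.444 → 0.185 mJ/m²) — a looser, more
weakly adherent bilayer.

Simulate a noisy shrinkage measurement and invert it back to P_f:

```sh
$ dibkit simulate --pf 70 --t-end 600 --dt 5 --noise-sd 0.005 --seed 7 \
    -o demo_series.csv
wrote 121 samples to demo_series.csv
$ dibkit fit-pf demo_series.csv
method: trajectory-fit
pf_um_s: 66.4465
se_um_s: 0.7428
residual_norm: 0.45994
n_points: 121
```

A single noisy run lands within a few μm/s of the generating 70 μm/s;
like the instrument studies this emulates, per-condition values should be
means over many runs (`dibkit synth` + `dibkit report` automate that for
a whole synthetic study; see `dibkit --help` for the `dsc` and `raman`
subcommands).

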