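# Methods

## The landmark-extraction algorithm

A transient is a time series F(t) in detector units with t = 0 at saturation
pulse (SP) onset; PAM-style recordings carry a 10 ms pre-pulse baseline
(negative times), PEA-style recordings start at the pulse.

1. **Initial level.** F_O (dark-acclimated) or F_S (light-acclimated) is the
   arithmetic mean of the baseline when one exists; otherwise the intercept at
   t = 0 of a least-squares line through the first five pulse samples. The
   two estimators correspond to the two instrument families; neither smooths
   beyond what it needs.
2. **Maximum.** F_M (or F_M′) and its timing t_P are the raw argmax over the
   pulse, earliest sample winning ties. An optional centered moving median
   (`fp_median_width`) is available for noisy uniformly sampled traces and is
   off by default.
3. **Rise fit.** The 0.5–5 ms segment is fitted with a ninth-degree
   polynomial by least squares. The basis is the numpy `Polynomial` domain
   mapping of the fit window onto [−1, 1]; a raw power basis at degree 9 over
   a millisecond axis would be numerically ill-conditioned. The fit is in
   linear time — the window spans a single decade, where a conditioned
   linear-time basis is stable.
4. **Inflections.** Candidate J timings are the real roots of the fitted
   polynomial's exact second derivative (companion-matrix eigenvalues, so
   closely spaced roots are not missed; imaginary parts below 1e-9 after
   back-mapping count as real) at which the third derivative is strictly
   positive. These are local minima of the slope — the momentary plateau that
   defines the J step.
5. **Selection.** Among qualifying inflections inside the acceptance window,
   the one nearest the 2 ms anchor is t_J, ties breaking earlier. The default
   acceptance window equals the fit window; a wide preset (0.6–25 ms) suits
   noisy grid data. When the acceptance window exceeds the fit window, the
   polynomial is fitted over the hull of both so that F_J is always evaluated
   inside the fitted domain. Within a treatment series the J timing
   identified on the control can be pinned with `fixed_tj_ms`, the convention
   used when curves in a series are compared at one timing.
6. **Proxy.** F_J is the fitted polynomial at t_J and
   V_J(′) = (F_J − F_0) / (F_M − F_0). Where the fitted F_J overshoots the
   observed F_M (or undershoots F_0) by at most 0.1 % of the dynamic range —
   a polynomial wiggling on a plateau — it is clamped to the boundary;
   larger violations exclude the trace rather than report V_J outside [0, 1].

### Quality control

A trace is excluded (V_J unset, reason recorded) when:

- **saturation** — any pulse sample reaches `detector_max − tol_adu`
  (`tol_adu` defaults to 0; real ADCs may clip a few counts early). Judged on
  the pulse segment of raw, non-SP-normalized traces only.
- **low_snr** — the relative fit residual ρ = RMS / (F_M − F_0) exceeds 0.02,
  or (dark mode only) the variable fraction F_V/F_M = 1 − F_0/F_M falls below
  0.5. The first catches noise that defeats reliable F_J identification; the
  second catches pulses too weak to approach PSII closure, for which F_M —
  and hence V_J — is undefined. The F_V/F_M rule is disabled in light mode,
  where an elevated F_S legitimately compresses the rise; it also assumes
  background-corrected signals, as instruments provide. Neither threshold is
  claimed from measurement; both are this package's operational choices.
- **no_inflection_in_window** — no qualifying inflection inside the
  acceptance window, the classic signature of a weak SP that produces no
  clear J step.

## The kinetic model

Five mean-field states per PSII: a (fraction of centers with Q_A reduced),
e_B (mean electrons on the two-electron Q_B gate, 0–2), p (reduced fraction of
the photoactive PQ pool, n_PQ quinones), d (oxidized fraction of the
inter-system acceptor pool — plastocyanin, P700, ferredoxin, NADP⁺ — n_D
electrons), and s (FNR/CBB sink activity). Fluxes in electrons s⁻¹ PSII⁻¹:

    J_L   = k_L_ref (PFD / 2000) (1 − a)
    J_AB  = k_AB [a (1 − e_B/2) − γ_AB (1 − a) e_B/2]
    J_ex  = k_ex [(e_B/2)(1 − p) − γ_ex (1 − e_B/2) p]
    J_b6f = k_b6f p d / (d + K_acc)
    J_FNR = k_FNR (1 − d) s

    da/dt   = J_L − (1 − x_DCMU) J_AB − k_rec a
    de_B/dt = (1 − x_DCMU) J_AB − 2 J_ex
    dp/dt   = (2 J_ex − J_b6f − k_TO p + k_NDH (1 − p)) / (2 n_PQ)
    dd/dt   = (J_FNR − J_b6f) / n_D
    ds/dt   = (s_target − s) / τ,   τ = tau_FNR in light, tau_relax in dark

Fluorescence follows the closed-center fraction through PSII excitonic
connectivity: F = F0_rel + (FM_rel·quench_mult − F0_rel)·C(a) with
C(a) = a(1 − p_conn)/(1 − p_conn·a). The donor side is assumed
non-limiting; there is no S-state cycling and no PSI photochemistry as such.

Three structural choices deserve comment:

- **The saturating b6f flux** d/(d + K_acc) encodes that the fast
  plastocyanin/PSI shuttle keeps cytochrome b6f supplied with oxidized
  acceptors at full rate until the downstream pool is nearly exhausted. This
  is what separates the I and P features: with a flux merely proportional to
  d, the acceptor pool drains smoothly from the start and the fluorescence
  peaks as soon as the pool-fill balance is reached — no distinct I step
  exists (verified numerically).
- **Weak reverse transfer** (γ_AB, γ_ex = 0.05) lets a partly reduced PQ pool
  back electrons up onto Q_B and Q_A in darkness. This produces the elevated
  dark F_O of cyanobacteria, whose respiratory complexes (NDH-1/SDH, k_NDH)
  keep the pool partly reduced at night; a fully irreversible chain pins dark
  a at 0 regardless of pool redox.
- **Q_A⁻ recombination** (k_rec = 2 s⁻¹) is a slow loss channel that keeps
  sustained-light steady states away from complete closure; without it, any
  treatment that removes all pool-oxidation routes drives F_S to F_M′ exactly
  and V_J′ becomes 0/0.

### Treatments

DCMU blocks Q_A⁻ → Q_B transfer by the bound fraction x = C/(C + K_D)
(single-site binding; K_D = 0.001 µM puts the block near 1 at 0.1 µM).
Glycolaldehyde sets the sink target to zero. KCN zeroes the terminal-oxidase
rate k_TO. Methyl viologen keeps the sink active from the start
(s(0) = s_max, dark target s_max). Actinic pre-illumination integrates the
system under `al_pfd` for `al_duration` before the pulse. NPQ and state
transitions are represented only by the scalar `quench_mult` on FM_rel.

### Default parameters and calibration

The five rate constants (k_L_ref, k_AB, k_ex, k_b6f, tau_FNR) were tuned by
`calibrate_defaults` — a coarse multiplicative grid search followed by
Nelder–Mead on the log-rates — to place the landmarks of the simulated
dark-acclimated control at their canonical timings: the J inflection at 2 ms
and the I inflection at 30 ms (both measured through the same
polynomial-derivative pipeline the package ships, the I step on a 5–100 ms
window anchored at 30 ms), and the P maximum inside 200–300 ms. The shipped
defaults achieve t_J = 2.00 ms, t_I = 30.00 ms, t_P = 259 ms at an SP of
2000 µmol photons m⁻² s⁻¹. Pool sizes (n_PQ = 4 quinones, n_D = 95
electrons), the b6f half-saturation K_acc = 0.25, connectivity p_conn = 0.5,
and the sink bounds were fixed by hand to values in the physiological range
before the rate search. The cyanobacterial preset (k_NDH = 25, k_TO = 20 s⁻¹)
leaves ~23 % of the pool reduced after dark acclimation, matching the
reported 10–25 % range for dark-adapted cyanobacteria.

### Instrument emulation

Excitation is attenuated by the path-averaged Beer–Lambert factor
g(c) = (1 − 10^(−εc))/(εc ln 10) (ε = 0.08 per mg Chl a L⁻¹); the detected
amplitude scales as c·10^(−βc) (β = 0.11), which rises to a maximum near
4 mg Chl a L⁻¹ and falls beyond — the observed rise-then-fall of absolute
signal with culture density. Profiles: "pam-like" samples uniformly every
10 µs from 10 µs through 639.97 ms (the nominal 630 ms pulse plus the
trailing partial interval), i.e. exactly 63 997 pulse-window samples, with a
10 ms baseline; "pea-coarse"/"pea-fine" draw 63/827 log-spaced samples with
no baseline and no measuring light, so their amplitude scales with SP
intensity and traces must be SP-normalized before comparison. Noise is
additive zero-mean Gaussian with scale `noise_sigma_rel · (F_M − F_0)` from a
seeded generator (`numpy` `default_rng`; dataset seeds derive from
`SeedSequence([seed, row, col])`), followed by clipping at the detector
ceiling. Grid generation emulates the gain-setting step of a density series:
the detector scale is reduced so the largest amplitude in the series stays
below 80 % of the detector range.

## Numerical choices

- Stiff-capable integration with `scipy.integrate.solve_ivp` (LSODA,
  rtol 1e-8, atol 1e-10, dense output); state accessors clip to the physical
  bounds, and the raw solver output stays within them to ≤1e-6.
- Dark steady states are obtained by relaxing the analytic irreversible-chain
  guess for 500 s of simulated darkness (the reverse-transfer coupling has no
  closed form).
- The ideal-curve maximum is located on a dense mixed linear/log grid of
  ~20 000 points over the pulse.
- Degenerate inputs: traces shorter than degree + 1 points inside the fit
  window, windows outside the data range, F_M ≤ F_0, and empty pulse segments
  raise errors at the operation level; `extract_features` converts QC-type
  failures into excluded features and propagates only structural errors.

## What the synthetic data do and do not show

The generator reproduces the features the extraction pipeline depends on —
O-J-I-P timing and ordering, treatment limits (DCMU → V_J = 1; full pool
reduction → V_J′ = 1), the monotone dependence of V_J on SP intensity and
culture density with QC-excluded cells at the weak-excitation corner, dark
respiratory pool reduction, high-light compression of the V_J′ dynamic range,
seeded instrument noise and clipping. Passing tests on it therefore show the
pipeline is correct and well-behaved under those conditions; they do not show
that real instruments' undocumented sampling layouts, detector nonlinearity,
species differences, or biology outside the model are handled.

Known limitations:

- Slow (30 s–minutes) V_J′ dynamics are compressed: FNR/CBB activation is a
  single first-order variable with a ~1.3 s light time constant, so
  glycolaldehyde drives the pool fully reduced within seconds rather than
  ~2 minutes, dark-to-light transients lack the minutes-scale CBB activation
  peak, and methyl viologen and control time courses converge at 30 s
  resolution instead of separating as they do in vivo.
- Under moderate actinic light the activated sink capacity far exceeds the
  light input, so KCN (terminal-oxidase removal) barely shifts the simulated
  V_J′, unlike the strong response of real cyanobacteria where CO₂-limited
  carbon fixation leaves the oxidases carrying a substantial share of the
  flux.
- The degree-9 polynomial fit carries a small systematic bias on curves with
  sharp early curvature inside the 0.5–5 ms window (~0.06 ms on the
  simulator's own control curve relative to a finite-difference oracle);
  on smooth test functions the detector agrees with the oracle to
  within 0.05 ms.
- Density optics are a path-averaged Beer–Lambert/reabsorption caricature,
  qualitatively right, not radiometrically exact; log-spaced "PEA" sampling
  emulates vendor schemes that are not publicly specified.
- I-step detection is exposed only as a calibration landmark, not a reported
  feature; the transient dip between F_J′ and F_P′ seen under some treatments
  is not detected.
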