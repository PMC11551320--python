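# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the known limitations of the package, in the spirit of a
methods section a user can audit.

## Exchange model and forward calculations

An `ExchangeModel` is an N-state continuous-time Markov scheme with
directed first-order rate constants `k_ij` (s⁻¹), stationary populations
`p_i`, and per-state chemical-shift positions (ppm relative to the
acquisition carrier) and relaxation rates R1, R2.  Construction enforces
population normalization (1e-9), non-negative rates, and detailed balance
`p_i k_ij = p_j k_ji` (1e-8) on every edge; the rate matrix `K` with
`K[j,i] = k_i→j` then has zero column sums and the populations span its
null space.

**CEST.**  During the saturation period the 3N-vector (Mx, My, Mz per
state) evolves under `dM/dt = A M` with `A = K⊗I₃` plus per-state blocks
for R1/R2 decay, off-resonance precession `Ω_i = (δ_i − offset)·2π·ν₀`,
and B1 nutation `ω₁ = 2π B₁`.  The initial condition is equilibrium
z-magnetization (populations), consistent with a long recycle delay.
Longitudinal relaxation is homogeneous (decay toward zero, not toward
equilibrium); the no-saturation reference is propagated identically, so the
normalized profile is R1-baseline-free and tends to 1 far off resonance.
ppm↔Hz conversion happens in exactly one place
(`exchange_core.GAMMA_FRACTION`): the observed-nucleus frequency is the
¹H field times 0.101329 (¹⁵N) or 0.251450 (¹³C); gyromagnetic-ratio signs
are dropped since only offset differences enter.

**CPMG.**  Transverse magnetization (complex M⁺ per state) evolves under
exchange, R2 and precession for a constant time `T_CT`, interrupted by
`n_cyc` cycles of τ–180°–2τ–180°–τ with ideal instantaneous pulses
(complex conjugation); `ν_cpmg = n_cyc/T_CT`.
`R2,eff = −ln(I/I0)/T_CT` with I the observed state's in-phase signal.
R1 leakage and off-resonance pulse effects are neglected, the standard
idealization for constant-time relaxation-compensated experiments.

**Propagation.**  Both observables need `exp(A t)` for ~100 matrices that
differ only in their diagonal (one per offset).  The implementation uses
batched eigendecomposition (`numpy.linalg.eig` over the offset axis), which
is ~20× faster than looping scipy's scaling-and-squaring `expm`; a residual
check on the worst-conditioned matrix falls back to `expm` when the
eigenbasis is ill-conditioned.  Equivalence with an independent
explicit-Euler integrator (dt = 1 µs) is property-tested to 1e-3 in
normalized intensity.  The Euler oracle is only valid near resonance: far
off-resonance its amplitude error grows on oscillatory modes while the
profile is trivially ~1, so the comparison is made across the dip region.

**Closed forms.**  The fast-exchange limit `Rex = p_A p_B Δω²/k_ex`
(optionally with the usually negligible ΔR2² subtracted inside the
numerator, default off), the slow-exchange limit (Rex equals the rate of
leaving the observed state), and the Carver–Richards two-state dispersion
are provided as oracles and initializers.  Carver–Richards is itself an
approximation (dominant-eigenmode decay): pointwise it deviates from the
exact propagation by up to several percent of Rex at slow exchange and
intermediate pulse rates, while the dispersion *amplitude*
`R2,eff(ν_min) − R2,eff(ν_max)` agrees to better than 2% across regimes —
the cross-validation tests therefore compare amplitudes.

## Synthetic data: what it emulates and what it does not

Fixtures encode the reference experimental conditions: a two-state temperature-jump series
(rates 0.09/0.36 h⁻¹, and 0.24/0.98 h⁻¹ with the prolyl isomerase at a
1.25× intensity scale; 45 Ground + 37 FS assigned peaks), three-state
Enigma↔Ground↔PD ¹⁵N CEST at 20 °C (populations 8/89/3%, k_G→E = 12 s⁻¹,
k_G→PD = 2 s⁻¹; 5 residues) and 4 °C (2/23/75%, k_G→E = 6 s⁻¹,
k_G→PD = 2 s⁻¹; 11 residues, Ground and PD traces both observed),
two-state methyl ¹³C CEST (k_ex = 173 s⁻¹, p_b = 7%), a slow two-state
process for residues 39–42 (k_ex = 6.4 s⁻¹, p = 5%, recorded at both B1
fields), a two-temperature CPMG pair with k_leave ≈ 12 and ≈ 2 s⁻¹ groups
doubling from 25 to 35 °C, and a PD-dominant volume table
(15/10/75%).  Acquisition parameters follow the reference experiments: ¹⁵N CEST offsets
104–135 ppm in 25 Hz steps at an 800 MHz ¹H field with B1 = 10 Hz /
T_relax = 500 ms or 20 Hz / 400 ms; methyl CEST 8–25 ppm in 40 Hz steps,
20 Hz, 400 ms; ¹⁵N CPMG at 600 MHz with T_CT = 60 ms, n_cyc 0–60, and
duplicate planes at n_cyc 0, 30, 60.

Design choices not fixed by the reference conditions:

* **Time grid** for real-time series: first point at 0.12 h (~7 min dead
  time), 0.33 h spacing, 16 h horizon (49 spectra).
* **Starting populations** after the jump: p_G = 0.6 (equilibrated warm),
  relaxing to the equilibrium 0.8 — only the direction of the jump matters
  for rate recovery.
* **Response factors**: per peak/residue, log-normal (sd 0.3), clipped to
  [0.8, 2.5] for assigned real-time peaks (so every assigned switching peak
  sits decisively above the 4×10⁵ amplitude filter at the simulated noise),
  [0.4, 3.0] for CEST responses, [0.7, 2.0] for CPMG.  Weak *unassigned*
  peaks with tiny responses are included in the real-time tables and are
  removed by the assignment clause of the filter.
* **Noise**: Gaussian spectral noise with sd 2% of the tallest peak in the
  table — except the CPMG fixtures, which use 0.5% because that experiment
  is the high-sensitivity acquisition of the set (32 scans per FID against 4
  for the HSQC series, plus duplicates); at 2% the two-temperature
  significance test could not resolve even 10 s⁻¹ Rex increases, which
  would contradict the precision the reference classification implies.
* **Methyl probe set**: 12 methyls, six with Δω < 0.7 ppm and six in the
  larger group up to 4.1 ppm, matching the reported composition of the
  methyl data.  With only small-Δω probes the maximum-likelihood k_ex
  itself scatters ±15% across noise realizations, inconsistent with the
  printed ±8 s⁻¹.
* **Seeds**: each fixture carries a structural seed fixing the "sample"
  (responses, positions, relaxation rates); the simulation seed controls
  only the noise, so changing it never changes the noiseless signal.

What the generator does **not** emulate: 2D lineshapes, peak overlap and
integration artifacts beyond a response factor, B1 inhomogeneity, scalar
couplings, temperature-dependent chemical shifts, and cross-correlated
relaxation.  Passing tests therefore demonstrate correct inference under
idealized integration, not robustness to peak-overlap pathologies.

## Fitting

**Real-time global fit.**  For fixed k the per-peak (a_i, b_i) are linear
and solved exactly (one `lstsq` per shared time grid), so the shared rate
is found by a 1-D profile search (60-point log grid on [0.05, 12] h⁻¹ plus
Brent refinement, xatol 1e-10).  The bounded window matters: outside it the
[1, e^(−kt)] design degenerates on a ~20-min/16-h series and the amplitude
of a noise-only trace is unbounded.  The directional split uses the median
over matched residues of `a_FS/(a_G + a_FS)`; the per-residue response
ratio has unit median, so the median estimate is unbiased.  The bootstrap
(default 1000 replicates, explicit seed required) re-draws every point from
its stated sd and resamples peaks with replacement within each state.

**CEST global fit.**  Weighted least squares (scipy `trf` with a
finite-difference Jacobian exploiting the block sparsity: global kinetics
dense, per-residue parameters block-diagonal).  Rates are fit in log space
and populations in logit space; positions in ppm.  The per-profile
reference intensity I0 is a conditionally linear nuisance with a Gaussian
constraint at the measured reference plane's relative noise, projected out
in closed form — without it, the correlated normalization error of noisy
reference planes biases k_ex by ~10%.  The objective is multi-modal in the
minor-state positions, so the fit uses (i) dip-derived candidate positions
(local minima below max(0.05, 3×noise) of the smoothed trace), (ii) a
chi²-prescreen over many cheap starts with class diversity (assignment-
anchored, minor-permutation, warm), (iii) a two-state prefit cascading into
three-state fits, (iv) a bounded per-residue "polish" that re-optimizes
misfitting residues from mirrored (±Δω), swapped, and dip-based restarts,
and (v) for the symmetric linear chain, canonical orientation of the two
minor states before the final refinement — the minor whose positions sit
nearest the random-coil region (121.5 ppm anchor for backbone ¹⁵N) is PD,
the same deduction an assignment-based analysis makes.  Tolerances
ftol = xtol = 1e-8 (well below the noise floor of any fixture); reduced
χ² = χ²/(n_points − n_params).

**Model comparison.**  Topologies are ranked by reduced χ²; pairs within a
10% band (configurable) are reported indistinguishable, and edges whose
fitted exchange rate collapses below 1e-3 s⁻¹ are flagged underdetermined.
Warm starts map a nested fit into a superset topology twice — once with new
edges at a negligible rate (so adding an edge can never fit worse) and once
at a moderate rate (so a genuinely present process is found).

**CPMG estimator and test.**  Rex is the R2,eff at the point nearest the
low-frequency anchor (50 Hz backbone, 25 Hz methyl) minus the mean of the
two largest-frequency points; duplicate planes are averaged and the larger
of the noise-based and duplicate-based sd is carried.  The reference analysis does not
name its nonparametric test; this package draws Monte-Carlo replicates of
each temperature's Rex from its propagated sd and reports the two-sided
sign-reversal tail probability, Bonferroni-corrected by the number of
residues measured at both temperatures.  No dispersion-curve model is ever
fit to experimental-style data — in the slow-to-intermediate regime the
two-state closed form cannot separate populations from rates at one field,
so Carver–Richards exists only as a simulation oracle.

**Landscape.**  The reference state is Ground at each temperature.  Free
energies are Boltzmann inversions (R = 1.98720425e-3 kcal/(mol·K));
barriers use the Eyring equation with κ = 1, k_B = 1.380649e-23 J/K,
h = 6.62607015e-34 J·s, and round-trip to machine precision.  Merging
multiplies the CEST populations by the real-time Ground-ensemble mass
(scale = p_G,realtime / Σ p_CEST), which keeps the merged set normalized;
transitions measured in one direction only are drawn as a single effective
barrier from the measured side.  The cold-landscape offset defaults to
2 kcal/mol; if that still leaves the shared rate-limiting barrier below its
warm-temperature height, a warning reports the minimal compliant offset.

## Known limitations

* **k_ex/p degeneracy at very slow exchange.**  For the residue 39–42
  process (k_ex = 6.4 s⁻¹, p = 5%) both B1 fields are far above k_ex, so
  the CEST data determine only the product k_G→alt = k_ex·p: the dip depth.
  Separating k_ex from p would require resolving ~1 Hz linewidth
  differences on a 25 Hz offset grid.  The package recovers the product to
  a few percent; the individual parameters wander a factor ~2 along the
  likelihood ridge at the simulated noise.
* **Enigma rate at 4 °C.**  With the Enigma state at 2%, k_G→E is weakly
  identified (a truth-started fit moves ~25% at the default noise); the
  4 °C fit is relied on for populations and the Ground–PD kinetics, the
  20 °C fit (Enigma at 8%) for the Ground–Enigma kinetics — mirroring how
  the two temperatures complement each other in the experimental design.
* **Minor-minor exchange is underdetermined**: the fully connected
  three-state fit redistributes flux between the direct Ground–PD edge and
  the path through Enigma at nearly constant χ²; populations remain pinned
  by dip depths.  The comparison report flags collapsed edges but makes no
  identifiability claim beyond the χ² band.
* Problem sizes (residue counts, offsets, replicate counts) are the
  fixtures' own study-scale values; the bootstrap default of 1000 replicates
  is reduced to 200 in the test suite, which leaves percentile intervals
  stable to well within the tolerances tested.
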