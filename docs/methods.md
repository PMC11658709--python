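# Methods

## Model

### Condensed (7-field) model

Seven line densities (1/μm) live on a periodic 1D membrane of perimeter
`L`: cytoplasmic inactive Rac1 `ρ_r`, membrane active Rac1 `ρ_R`,
cytoplasmic GAP `ρ_g`, membrane Rac1–GAP complex `ρ_RG`, cytoplasmic
DGAP1 `ρ_d`, membrane DGAP1 `ρ_D`, and membrane Rac1–DGAP1 complex
`ρ_RD`. Cytoplasmic pools diffuse (`D_r`, `D_g`, `D_d`); membrane pools
do not. The reactions are

- saturating (auto)catalytic Rac1 membrane binding + activation:
  `ρ_r (1 − ρ_R/ρ_Rmax)(k1 + k11 ρ_R + k12 ρ_RG)`;
- GAP complex formation `k2 ρ_R ρ_g` and dissociation `k3a ρ_RG`, which
  hydrolyzes Rac1 and returns both partners to the cytoplasm;
- saturating DGAP1 membrane binding
  `ρ_d (1 − ρ_D/ρ_Dmax)(k4 + k41 ρ_R + k42 ρ_RG)`;
- Rac1–DGAP1 complex formation `k5 ρ_R ρ_D` and its two dissociation
  channels `k6a ρ_RD` (Rac1 stays active on the membrane) and
  `k6b ρ_RD` (Rac1 returns to the cytoplasm inactive).

Each of the three species totals (`N_Rac1`, `N_GAP`, `N_DGAP1`,
homogeneous line densities `N/L`) is conserved exactly by construction;
the reaction terms sum to zero within each conservation group, which the
test suite asserts both symbolically (column sums of the analytic
Jacobian) and numerically on every integration.

Saturation factors are clamped at zero so that a transient numerical
overshoot beyond `ρ_Rmax`/`ρ_Dmax` cannot reverse the binding flux.
Construction of a parameter set does **not** reject totals exceeding the
saturation capacity (`N/L > ρ_max`): the saturation bounds only the
membrane-bound pool, not the species total, and some published parameter
sets are only meaningful under this reading. Physical-range violations
are instead detected dynamically.

### Extensive (8-field) model

The extensive model splits membrane binding from nucleotide exchange by
adding a membrane-bound *inactive* pool `ρ_m`: binding feeds `ρ_m`, which
either activates (`k_act`) or detaches (`k_minus1`). It further adds an
alternative complex dissociation `k3b` (Rac1 remains active on the
membrane), spontaneous DGAP1 detachment `k_minus4`, and two extra
Rac1–DGAP1 dissociation channels `k6c`, `k6d` that leave DGAP1 on the
membrane. With the extra channels set to zero and `ρ_m = 0`, the
extensive reaction terms reduce to the condensed ones exactly (the
binding flux is routed through the `ρ_m` equation); this degeneration is
a unit test.

### Parameters

`ModelParameters()` carries the baseline values (rates in 1/s or
μm/s-equivalents, diffusivities in μm²/s, `L = 40 μm`, `N_Rac1 = 5200`,
`N_GAP = 1200`, `N_DGAP1 = 1600`, `ρ_Rmax = 200/μm`, `ρ_Dmax = 40/μm`).
Named variant sets used by specific analyses are bundled as YAML under
`racwaves/data/overrides/` and loadable with
`ModelParameters.defaults(name)` / `load_parameters(name)`.

Saturation-density rescaling (`with_rho_Rmax`, `with_rho_Dmax`) holds the
intrinsic binding constants `k/ρ_max` fixed, which is the convention under
which the saturation-density sensitivity coefficient is defined.

## Linear stability analysis

The homogeneous steady state solves four independent balance equations
plus the three conservation constraints, via deterministic multi-start
trust-region least squares with non-negativity bounds (residual tolerance
1e−10; a warm start supports continuation along parameter scans). The
dispersion relation evaluates the eigenvalues of `J − q²𝔇` at the
discrete wavenumbers `q_n = 2πn/L`, with `J` the analytic reaction
Jacobian and `𝔇 = diag(D_r, 0, D_g, 0, D_d, 0, 0)`. The three
conservation-induced zero eigenvalues at `q = 0` are classified as
neutral, not unstable. Per-mode labels (stationary/oscillatory by
`Im σ`) are combined into an overall classification: stable, Turing,
Hopf, or Turing–Hopf.

The marginal wavenumber `q_m` is the last sign change of the leading
real part on a 400-point scan to `q = 3 μm⁻¹`, refined by Brent's
method; the traveling-wave speed is `v = |Im σ(q_m)|/q_m` with the
marginal eigenvalue found by branch tracking from `0.9 q_m`. Normalized
sensitivities use a relative forward step of 1% (default; halving the
step changes the reported coefficients by < 0.02). The minimum perimeter
at which mode `n` destabilizes is `L_n_min = 2πn/q_m`, holding the linear
total densities `N/L` fixed as `L` varies.

Caveat: at a stationary (Turing) instability the eigenvalue *at the
marginal wavenumber* can still be complex (the real unstable branch
merges with a conjugate pair before its real part crosses zero), so
`wave_speed` should only be interpreted for oscillatory regimes.

## Simulation

### 1D ring

Method of lines: periodic second-order 3-point Laplacian, stiff BDF
integration (`scipy.integrate.solve_ivp`, rtol 1e−8, atol 1e−10) with the
exact Jacobian sparsity pattern, output on a uniform 1 s (configurable)
cadence. Initial conditions are the homogeneous steady state with white
Gaussian noise at a configurable SNR (30 dB default) — after noise is
added, negatives are clipped and each field rescaled so all copy numbers
are conserved *exactly* — or a seeded single-Fourier-mode pattern
(zero-sum, hence also conservative). Noise is applied on top of a seeded
pattern as well, because a noise-free seeded standing wave lies on an
invariant symmetric manifold and would never undergo the
standing-to-rotating transition.

Conserved totals are checked on the output (abort beyond relative 1e−4;
measured drift is below 1e−6 over 8000 s runs). Densities may undershoot
zero by at most the solver-tolerance-scale floor 1e−6 (then clipped);
larger undershoots abort the run. The floor is deliberately larger than
the solver's absolute tolerance, since the integrator cannot guarantee
positivity tighter than its own error control.

### Pattern classification

A kymograph is classified from its space–time autocorrelogram
`A(ΔΦ, Δt)`:

1. relative angular contrast < 1e−3 → homogeneous;
2. temporal period `T` = first local maximum of `A(0, Δt)`; recurrences
   shorter than 8 frames are treated as noise artifacts (no period);
3. no period: persistent zero-lag correlation (mean `A(0, Δt>0)` ≥ 0.2)
   → stationary, otherwise homogeneous (uncorrelated noise);
4. with a period (record must cover ≥ 3 periods): ridge slope ≥ 50% of
   the single-ridge reference speed `2π/(nT)` → traveling; else
   half-period anticorrelation `A(0, T/2) < −0.2` → standing; else
   stationary/homogeneous by the persistence rule.

The ridge slope is estimated from the dominant angular harmonic
`B_n(Δt) = ⟨A(ΔΦ, Δt) e^{−inΔΦ}⟩`: per-lag phase increments
`angle(B(Δt+δ) B*(Δt))` are averaged with weights `|B(Δt+δ) B(Δt)|`.
For a standing wave `B_n` is real and flips sign at the nodes; the
weights vanish exactly there, so the ambiguous ±π phase jumps carry no
weight and the estimator returns ~0 instead of a spurious drift (a naive
argmax ridge track misreads the π jump at `T/4` as motion). Windowed
classification (`transition_run`) applies this per overlapping window to
detect standing→rotating transitions and direction reversals; windows
must cover at least three periods.

### 2D disk

Polar finite-volume grid (`n` rings × `m` angular segments,
`r_i = (2i−1)h/2`) with a conservative flux-form Laplacian: interior
radial fluxes telescope exactly and the outer radial flux is replaced by
the membrane reaction flux, so the scheme conserves both species to
solver precision. The membrane carries active Rac1 and Rac1–GAP line
densities coupled to the boundary ring through primed (2D) rate
constants; `convert_rates` maps 1D constants onto them via the ratio of
the homogeneous reference densities. Integration is BDF (rtol 1e−7,
atol 1e−9) with the full coupled sparsity pattern; a 20×60 grid resolves
the published disk scenarios.

## Kymograph analytics

- **Autocorrelogram**: per-frame angular mean removal, FFT circular
  spatial correlation, truncated temporal averaging; assembled over
  signed lags using the point symmetry `A(−ΔΦ, −Δt) = A(ΔΦ, Δt)` (the
  −π column is its own mirror on an even angular grid). The estimate is
  invariant under affine intensity transforms. Truncated averaging
  biases standing-wave values at large lags by up to ~0.07 when the
  window is not an integer number of periods.
- **Correlation**: Pearson correlation over all matrix elements of two
  co-registered channels (default window: first 120 s), and a sliding
  variant with one-frame stride for tracking phase flips.
- **PCA phase alignment**: the two channels are stacked into a
  `2n_t × m` matrix, rows standardized, and the `m` angular positions
  projected onto the first two principal components
  (scikit-learn PCA). The polar angle of each column gives its
  oscillation phase; the common period comes from the first principal
  axis (zero-crossing spacing, spectral-peak fallback); columns are
  circularly shifted by `−Tφ/2π` and averaged into aligned per-channel
  profiles. A warning is raised when the first two components carry
  < 20% of the variance.
- **Phase portraits**: shoelace signed area of the closed
  (channel-1, channel-2) trajectory; positive = counterclockwise; a
  warning flags trajectories whose endpoints do not close within 10% of
  the trajectory diameter.
- **Spatial noise PSD**: square-root variance stabilization, 4th-order
  zero-phase high-pass Butterworth along the angular axis (cutoff 0.15
  cycles/sample by default), single-sided `2/N |FFT|²` averaged over
  frames, reported per sample and optionally per μm.
- **Irregular sampling**: per-frame periodic linear interpolation onto a
  uniform angular grid; duplicate angles are rejected.

## Synthetic data

`SyntheticSpec` generates deterministic two-channel kymograph pairs with
ground truth: traveling/standing harmonic waves (mode order, period,
direction), stationary raised-cosine domains, homogeneous and pure-noise
records; Gaussian or mean-scaled ("poisson_like") noise calibrated by
SNR in dB against the clean signal variance; optional angular sampling
jitter. Channel 2 carries a configurable phase offset (π by default,
giving noise-free Pearson correlation −1). Scope: these are *pattern
phantoms* for validating the analysis pipeline, not simulations of
microscopy physics — no optics, bleaching, or segmentation artifacts are
modeled. `from_simulation` maps simulation fields (default: membrane
active Rac1 and total membrane DGAP1) onto intensity channels with the
same noise models.

The end-to-end recovery battery (20 specs spanning patterns, modes,
directions and SNRs of 10–20 dB) is recovered at ≥ 19/20 by the
classifier, with autocorrelogram- and PCA-based period estimates within
5%.

## Known discrepancies and limitations

Two published behaviors are **not** reproduced; the corresponding
acceptance tests fail deliberately and are not weakened:

1. **Condensed/extensive equivalence.** At the printed equivalence copy
   numbers (N_Rac1 = 9200, N_GAP = 880, N_DGAP1 = 1500, k11 = 5e−3) the
   extensive model here is *marginally linearly stable* (leading mode-1
   growth rate ≈ −1.5e−3 1/s) and perturbations decay to homogeneity,
   while the condensed baseline travels. All eight on/off combinations
   of the extra channels (`k6c/k6d`, `k3b`, `k_minus4`) are also stable
   at that point, and no subcritical attractor was found from large
   perturbations. The instability boundary sits at N_Rac1 ≈ 9150 and
   nearby unstable copy numbers (e.g. N_Rac1 = 8400) do travel, but with
   a period 12.7% away from the condensed baseline — outside the stated
   10%. The implementation was verified against the printed extensive
   equations term by term; the discrepancy is parametric (the printed
   set sits just on the stable side here), not structural.
2. **2D disk copy numbers.** At the printed disk parameters the
   homogeneous disk state is linearly stable in this implementation:
   N_Rac1 = 7600 (and 6900) decay, while values inside the unstable
   window (e.g. N_Rac1 = 9000) produce membrane patterns of the expected
   kinds on the same 20×60 grid. As in (1), the qualitative scenario
   reproduces but the printed operating point lies outside the unstable
   window here.

One further published scenario (a rotating monopole variant set) is
marginally stable in this implementation (leading growth rate −0.004)
and decays; the traveling-wave demonstrations in the tests therefore use
the baseline set, which robustly rotates.

Other limitations: the 1D model treats the cytoplasm as a
one-dimensional shell (no radial cytoplasmic gradients); the 2D disk
model carries only the Rac1/GAP subsystem on the membrane; linear
stability predictions are local (the nonlinear wave settles ~2% slower
than the marginal-mode speed); and classification thresholds (contrast
1e−3, slope fraction 0.5, anticorrelation −0.2, persistence 0.2) are
heuristics validated on the synthetic battery, not fitted to data.
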