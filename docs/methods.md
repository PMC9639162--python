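# Methods

## Physical model

Energy transfer between a membrane-embedded donor and acceptor is treated in
the Förster (weak-coupling, point-dipole) regime: chromophores far enough
apart that wave-function overlap is negligible, close enough that emission and
reabsorption do not occur. The coupling is the screened dipole–dipole
interaction

    V_DA = κ |μ_D||μ_A| / (4π ε₀ η² r³)

and the transfer rate the golden-rule expression k = (2π/ħ)|V_DA|²·J/(hc),
with the spectral overlap J of the unit-area donor emission and acceptor
absorption line shapes carried on the wavenumber axis (so J has units of cm
and hc is taken in J·cm). The screening enters as η² in the denominator of V
(η⁴ in |V|²); the default η = 1.478 is the experimentally measured refractive
index of DPPC monolayers. Competing channels (fluorescence, Dexter transfer,
charge transfer) are out of scope: at the ≥21 Å separations relevant here they
are either absent or not rate-determining for the transfer itself.

All internal arithmetic is SI (constants from scipy's CODATA tables at full
precision); eV, cm⁻¹, Debye, atomic units and Å are converted only at module
boundaries. Unit round trips are tested to 1 part in 10¹⁰ because every
downstream number is sensitive to these factors.

A note on one conversion: a donor dipole strength of 23.8 au² corresponds to
√23.8 × 2.5417 D/au = 12.40 D, while the companion reference value in the
literature for this system is printed as 12.3 D. The ~0.1 D difference is
plausibly ⟨|μ|⟩ vs √⟨μ²⟩ ensemble averaging and is left as-is: the package
performs the exact conversion, and the 12.3 D figure is used verbatim where it
serves as a printed input.

## Two-step protocol

Assumption: absorption/emission spectra and TDMs computed in implicit solvent
transfer unchanged into the membrane, while the membrane controls only
position and orientation.

1. **Ensemble photophysics.** Conformer properties are Boltzmann-weighted,
   w_i ∝ exp(−E_i/k_B T), evaluated with the max-shift (softmax) trick.
   Temperature defaults to 298.15 K (room-temperature spectroscopy);
   whether the supplied energies are electronic or free energies is the
   caller's choice — they are used as given. Degenerate minima share weight
   automatically.
2. **TDM mapping.** Because TDMs are invisible to classical force fields,
   each TDM is proxied by a reference vector built as a signed linear
   combination of atomic positions (`ReferenceVectorSpec`). For a rigid
   planar donor the N–N difference vector tracks the emissive TDM to ~1°.
   For the tris-bipyridine acceptor the shipped defaults build one vector
   along and one perpendicular to the C₂ axis from the six nitrogen
   positions; the exact published coefficients are not recoverable, so the
   combination is fully user-configurable and the defaults are a documented
   reconstruction.
3. **Near-degenerate states.** Two states that swap electronic character
   across conformers (here S₇/S₈) are declared a degenerate group: they share
   the averaged dipole strength and spectral overlap but keep their distinct
   orientations. The ∥/⊥ orientation assignment follows the most stable
   conformers, which dominate the Boltzmann weight; numerically, the
   published coupling ratio |V|²(S₇)/|V|²(S₈) = 0.733 matches the closed-form
   ⟨κ²⟩ ratio 0.737 only under the assignment S₅,S₇ → ∥ (tilt 49.6°) and
   S₆,S₈ → ⊥ (29.6°), which is what the defaults encode.
4. **Membrane frame.** TDMs are placed in the xz-plane at their trajectory-
   mean tilt; the donor azimuth is held fixed and the acceptor is rotated
   about the normal in 1° steps (360 points), averaging |V|² over the grid.
   Because κ(φ) is a first-order trigonometric polynomial, the full-period
   grid average equals the analytic ⟨κ²⟩ = ½cos²ϕ_D cos²ϕ_A +
   4 sin²ϕ_D sin²ϕ_A to machine precision, and results are insensitive to the
   step below 5°. Averaging only the acceptor azimuth is equivalent to
   averaging both (only the azimuth difference enters); tilt signs are
   irrelevant to the average. The separation is r = d_D + d_A along the
   normal — chromophores assumed directly opposite; lateral displacement is a
   known, acknowledged neglect.
5. Per-state rates from the supplied overlaps; total by summation
   (k_total = Σ k_i, τ = 1/k_total exactly).

Averaging the distance before taking r⁻⁶ systematically underestimates the
rate relative to per-frame pairing (Jensen's inequality, r⁻⁶ convexity); the
one-step protocol and a dedicated test quantify this.

## One-step protocol

Per-snapshot TDMs, vertical energies and membrane depths (e.g. from QM/MM)
are paired over the **full Cartesian product** of donor × acceptor snapshots,
not index-matched. For each pair: r_ij = d_i + d_j along the normal; the
acceptor's QM-derived TDM vectors are rotated about the normal on the azimuth
grid (donor fixed, implemented as the exact per-pair grid accumulation); the
per-state overlap is the closed-form overlap of two unit-area Gaussians
centered at the two vertical energies,

    J = exp(−Δν̃²/(2(σ_D²+σ_A²))) / √(2π(σ_D²+σ_A²)),

with fwhm defaults 0.05 eV (donor) and 0.2 eV (acceptor); and the pair rate
sums the per-state rates (donor: its single emissive transition; acceptor: the
10 lowest states by default). The reported rate is the arithmetic mean of the
pair rates; per-state diagnostics are means of the per-pair |V|², J and k —
never the rate recomposed from averaged factors, which would lose the
correlation between close approach, orientation and overlap. No spectral
shift is applied in this mode by default.

## Spectra and overlaps

Stick spectra are convoluted with unit-area Gaussians (σ = fwhm/(2√(2 ln 2)));
fwhm values given in eV are converted to cm⁻¹ before evaluation. The default
grid is 1 cm⁻¹ spanning all sticks ± 5 fwhm; a user grid that truncates a
stick raises an error naming it. Halving the grid step changes overlap values
by < 10⁻⁴ relative. Rigid spectral shifts (to match experimental band maxima)
are explicit, logged parameters applied to stick energies before convolution —
never inferred from data. Numeric overlaps require both inputs normalized and
resample onto the common window at the finer step; whether the integrand is
evaluated on an eV or cm⁻¹ axis is an internal convention — the cm⁻¹ axis is
used throughout so J carries the printed unit cm.

## Trajectory reduction

Pose observables per frame: depth = |z_COM(chromophore) − z_COM(membrane
center reference)| and tilt = arcsin(|v_z|/|v|) of the reference vector,
folded into [0°, 90°] since the membrane normal has no preferred sign. The
membrane is assumed assembled in the xy-plane; other frames must be
pre-rotated. The membrane-center selection (e.g. terminal lipid tail atoms)
is exposed; all matched atoms are mass-averaged. Detachment screening
excludes a trajectory whose depth exceeds 40 Å for more than 25% of frames —
the threshold must sit above the ~30 Å outer binding mode, and both knobs are
configurable and logged. Pooled means run over all frames of retained
trajectories. XYZ trajectories are read via MDAnalysis (masses guessed from
element names); precomputed (time, depth, tilt) tables bypass coordinates.

## Synthetic data

The generators emulate the statistical structure of the study system, not its
physics: no lipid dynamics, no electronic structure, no correlation between
orientation and depth unless configured. Defaults encode the study
conditions: a 92-member conformer ensemble whose energy ladder has ~5 kJ/mol
(≈2 kT) gaps with ±30% uniform jitter — chosen so the three most stable
conformers always carry ≥95% of the Boltzmann weight, mirroring the weight
concentration of the real acceptor ensemble; 100-snapshot donor/acceptor sets
with donor emission uniform on 2.0–2.4 eV, pose means 13.3 Å / 11.7° (donor)
and 20.1 Å (acceptor), reference tilts 49.6°/29.6°; 10 acceptor states with
"aligned" (two orthogonal reference directions + small noise → step/sigmoid
alignment profiles) or "isotropic" (uniform random → near-linear sorted cos²θ
curves) orientation modes. Angular noise is an exact rotation by the drawn
angle about a random axis perpendicular to the base vector. Pose series are
exact-discretization Ornstein–Uhlenbeck processes (correlation time 2 ns,
frame spacing 0.2 ns), optionally with Markov switching between two depth
modes (17/30 Å). All randomness flows from a mandatory seed through numpy's
PCG64 generator, so output is platform-reproducible.

Consequently, passing tests demonstrate the correctness of the rate algebra,
the averaging protocols and the statistical recovery machinery — not the
accuracy of any force field or electronic-structure method, which are
upstream of this package.

## Numerical choices and diagnostics

* Dominance counts (∥ vs ⊥): dominant = larger cos²θ; ties break toward ∥ and
  are logged (no published tie rule exists).
* The linearity score of a sorted cos²θ curve is the R² of its best straight
  line; an isotropic ensemble scores ≈0.94, a 50/50 aligned/orthogonal
  mixture ≈0.75, and a constant (perfectly aligned) curve is defined as 0.
* The orthogonality defect |cos²θ_∥ + cos²θ_⊥ − 1| flags conformers (default
  threshold 0.1) where geometric distortion breaks the planar two-reference
  picture.
* κ² maximization runs over (θ_D, θ_A, Δφ) — the full two-orientation grid
  reduced by rotational symmetry about r̂ — at 1° resolution.
* Zero-magnitude TDMs couple to zero rather than erroring; zero vectors are
  rejected wherever a direction is required.

## Problem sizes

Default test and reproduction workloads are desk-scale: 360-point azimuth
grids, snapshot products up to ~30×30×10 states, Monte-Carlo isotropy checks
at 10⁶ samples, pose series of 10³–10⁴ frames. The per-pair one-step kernel
is vectorized over the snapshot product and accumulates the azimuth grid in
(n_D × n_A × n_states) blocks, so 100×100×10 (the realistic scale) remains
tractable in memory.

## Known limitations

* Point-dipole coupling only; no transition-density or TrESP corrections, so
  accuracy degrades toward the short-distance end (~21 Å closest approach).
* Lateral chromophore displacement along the membrane plane is ignored; r is
  the sum of depths along the normal.
* The two-step protocol inherits the TDM→reference-vector mapping, which is
  reliable for rigid chromophores (donor-like, ≤1° deviation) and of limited
  validity for floppy ones whose TDM orientations are disordered.
* Spectral overlaps depend on user-supplied line widths and shifts; the
  one-step Gaussian-pair overlap has no vibronic structure.
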