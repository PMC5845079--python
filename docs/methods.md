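# Methods

## Model overview and assumptions

The simulator is a two-dimensional, off-lattice, center-based model.
Cells are hemispheres whose substrate projection is a circle of fixed
radius (R = 2.5 μm for epithelial/cancer cells, R_t = 2 μm for
T-lymphocytes); they are viable or removed, with no intermediate
states and no cell-cycle phases. Substrate mechanics are not resolved:
the elastic response enters only through the closed-form strain-energy
kernel `M0·exp(−λ d/R)` and the contact energy
`(4/15√2)(E_c/π)(h/R)^{5/2}`. The chemokine is quasi-static (its
diffusion is fast relative to cell motion), reduced to the steady-state
logarithmic Green's-function superposition over live cancer-cell
positions; secretion stops instantly at engulfment. Collagen in the
stromal annulus is uniform in density and perfectly aligned with the
islet circumference; its only effect is the exponential radial
attenuation encoded in the orientation tensor. There is no nutrient
field, no angiogenesis, no collagen remodeling and no telomere-style
division-rate decay.

## Parameters

All quantities are in the kg–μm–min system.

| symbol | meaning | default | notes |
|---|---|---|---|
| R, R_t | cell / T-cell radius | 2.5, 2.0 μm | fixed per phenotype |
| E_s, E_c | substrate / cell modulus | 5e-5, 0.5e-5 kg/(μm·min²) | λ = E_s/E_c = 10 |
| F | traction force | 3.163e-2 kg·μm/min² | calibrated, see below |
| β, μ | mobility, friction | 1 min⁻¹, 0.2 | α = βR³/(μF) ≈ 2470 |
| D | cell diffusivity | 0.005 μm²/min | variance rate of the random walk |
| D_c, γ | chemokine diffusivity, secretion | 0.001 μm²/min, 10 min⁻¹ | kernel strength γ/(2πD_c) ≈ 1592 |
| gates | divide/mutate/die | 0.03 (0.04 cancer) / 0.05 / 0.1 | compared against ‖M̂‖ |
| τ_d, τ_m, τ_a | growth times | 5, 10, 10 min | clocks reset at birth/division/mutation |
| event rate | all stochastic events | 10 min⁻¹ | P ≈ 0.632 per 0.1-min step |
| kill rules | weak / strong | 2.5 μm, 10 min / 3.5 μm, 5 min | contact clocks per T–cancer pair |
| N_w | T cells, weak immunity | 10 | strong fields N_s = 2N_w |
| tcell_death_prob | death risk per engulfment | 0.2 | no established value; exposed in config |

**Traction-force calibration.** Literature-tabulated values for F span
(10–25)·10² kg·μm/min², while figure-level analyses use F = 10; neither
is consistent with the quoted detection threshold ε ≈ 1.99×10⁻⁵⁴ at the
30-μm sensing range, nor with the ~0.03 two-cell equilibrium stimulus,
under the tabulated modulus and radius. The package therefore defaults
to the calibrated F* = √(ε·e^{120}·2π²E_sR⁴) ≈ 3.163×10⁻², the unique
value that makes the model's own worked numbers mutually consistent
(M0 ≈ 2.596×10⁻², equilibrium stimulus ≈ 0.026 ≈ the quoted 0.03,
equilibrium overlap ≈ 2.0 μm against the quoted ≈ 2.35). The other two
conventions remain selectable overrides. D and D_c are treated as
variance rates (μm²/min) for dimensional consistency of √(2D dt).

## Motion composition

The literal combination "drift of magnitude max(M_remote − ΣM_ij, 0)
along ẑ plus a separate per-pair repulsive displacement α·M_ij" cannot
be stationary at the two-cell balance point M_remote = M_ij, yet that
balance is the model's defining equilibrium. The engine therefore
composes attraction `α·M_remote·ẑ` (ẑ the normalised stimulus-weighted
direction toward neighbours) with per-pair repulsion `α·M_ij` away from
each contacting partner. On the two-cell axis this equals the signed
net energy α(M_remote − M_ij) toward the partner and vanishes exactly
at the solved equilibrium; for symmetric neighbourhoods (regular
hexagon) both terms cancel. The elementary operations (positive-part
drift, per-pair contact displacement) remain exposed unchanged for
analysis use.

**Shape of the two-cell balance.** With the calibrated defaults the
residual attraction−repulsion has two roots in h: a shallow one near
h ≈ 0.09 μm and the quoted "maximum equilibrium overlap" near
h ≈ 2.03 μm. `equilibrium_overlap` returns the larger root, the one
the two-cell analysis quotes. Because the attraction is exponential in h
while the contact energy is a 5/2 power, that upper root moves *up*
when the contact energy is scaled up — the intuitive "stronger
repulsion, smaller overlap" monotonicity holds only for the shallow
root — and daughters placed at birth distance R (h = R) sit slightly
inside the attractive basin. At those separations the deterministic
drift is O(10⁻³ μm/min), far below the random-walk scale, so in
practice daughter separation is diffusion-dominated and the
minimum-separation clamp (0.1 μm) prevents coincidence.

## Numerics

* **Integration.** Explicit Euler–Maruyama only; nonlinear terms
  (stimuli, contacts, gradients, tensors) are evaluated at the previous
  step. The contact energy is only C⁰ at h = 0, so higher-order schemes
  would not raise the convergence order.
* **Time step.** dt = min(0.1, R/(2·max‖v‖)) over the deterministic
  epithelial/cancer speeds, floored at dt_min = 0.02 min. Two
  deliberate deviations from the literal all-cell rule: (i) T-cell
  chemotactic speeds scale with the number of cancer sources
  (≈1592/d per source), so including them would collapse dt toward zero
  as the tumor grows; (ii) transiently squeezed cell pairs can hold
  max‖v‖ high indefinitely. In both cases the hard per-step
  displacement caps (R/2 for large cells, R_t/2 for T cells) enforce
  the non-overtaking guarantee the step rule exists for, so the caps,
  not dt, are the stability mechanism.
* **Cutoffs.** The detection threshold defaults to ε = 0; a
  neighbour cutoff at the sensing range d̂ = 30 μm is applied as a pure
  optimisation (signals beyond it are ~1.99×10⁻⁵⁴, below double
  rounding relative to M0).
* **Degenerate inputs.** Distances are clamped at 0.1 μm
  centre-to-centre (one symmetric projection pass per step); the
  chemokine kernel clamps distances below r_min = R_t; the orientation
  tensor is undefined at the islet centre (the engine substitutes the
  identity there); the reflecting boundary is a circle 10 μm outside
  the stroma.
* **Randomness.** One `numpy` PCG64 generator per replicate, consumed
  in a fixed order (monolayer noise, T-cell noise, event draws in
  cell-id order, placement draws, immune draws), making every replicate
  bit-reproducible from its seed. Sweeps derive per-run generators from
  (base seed, k index, replicate).
* **Event ordering.** Within a step: mutation → anoikis → division,
  drawn independently; a cell that mutates or dies cannot also divide
  that step. Dead and engulfed cells are removed immediately.

## Emergent population dynamics, and what the tests show

Under the calibrated constants, a relaxed monolayer cell senses
‖M̂‖ ≈ M0 = 0.026 < 0.03: the division gate is open in any
non-crowded configuration, so the epithelial population grows roughly
exponentially (doubling ≈ τ_d = 5 min) until local crowding — remote
stimulus from neighbours within ~1 μm — closes the gate. Mutation
(≥ 0.05) and anoikis (≥ 0.1) likewise fire only in tightly packed
clusters. This is a direct consequence of the gate values and the
calibrated amplitude; it means the monolayer is not a steady state, and
simulated horizons are chosen so that population sizes stay in the
hundreds-to-low-thousands.

The scenario tests and examples therefore run a deliberately small
study: islet radius 6 μm (~7 initial cells, a few hundred by t = 40),
stroma thickness 15 μm, horizon 40 min, N_w = 5, four replicates per
arm, and the deterministic seed-one-cancer-cell-at-t = 10-min switch so
that every replicate contains a tumor at a known time (mutations also
arise endogenously in dense clusters, but later and more erratically).
The full-scale defaults (35-μm islet, 400-min horizon, endogenous
mutation) remain the package defaults for users with more patience.

At that scale the suite verifies, over seeded ensembles: strong
immunity clears the tumor in the majority of replicates while weak
immunity rarely does and ends with a higher cancer fraction; and both
the mean immune response time and the mean maximum cancer fraction are
non-decreasing in k over {0, 0.3, 0.6}. These are the qualitative
fingerprints of the model — synthetic-data checks of the implementation,
not evidence about real islets: the generator emulates the model's own
idealisations (homogeneous substrate, point-source chemokine, uniform
aligned collagen), none of the biological heterogeneity of real tissue.

## Known limitations

* The division gates make unbounded epithelial proliferation intrinsic
  (see above); there is no homeostatic turnover.
* The two-cell "maximum equilibrium overlap" is a balance point, not an
  attractor: configurations compressed past it drift together until the
  separation clamp holds them, which makes dense clusters clump rather
  than relax to a lattice.
* The engulfment reading of the proximity rules treats the
  distance/time thresholds as governing the kill interaction (with a
  configurable T-cell death risk), since a death-only reading would
  give the strong immune system faster T-cell loss and no kill
  mechanism at all.
* 2-D only; no finite-element mechanics; chemokine decay, collagen
  degradation, angiogenesis and telomere-dependent rates are out of
  scope.
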