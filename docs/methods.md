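# Methods

`cellsolute` models the coupled fate of oxygen, glucose, VEGF and viable
neural stem cells in a plastic-compressed collagen gel cultured under medium
in a 96-well plate for 24 h, and provides the two analysis stages used to
parameterize such a model: Morris elementary-effects screening and a
two-step particle-swarm calibration against four experimental observation
blocks (replayed here as synthetic pseudo-experiments).

## Governing equations

All species live on a 1D axial column (gel below, medium above). In the gel:

    dc/dt = D_cg ∇²c − M_c n c/(c + c̄)
    ds/dt = D_sg ∇²s − M_s n s/(s + s̄) · (1 + A c̄/(c + c̄))
    dv/dt = D_vg ∇²v − K v + n (α c + β e^{−c/c_τ}) / (1 + n/n_τ)
    dn/dt = −n (δ₀ + δ_c c̄/(c + c̄) + δ_s s̄/(s + s̄))

In the medium the same transport holds with medium diffusivities, no cells,
and VEGF decay only. The VEGF source term deserves a note: the typeset form
of this expression is ambiguous in its fraction placement; the reading
implemented here — per-cell output `α c + β e^{−c/c_τ}` divided by the
crowding saturation `1 + n/n_τ` — is the only one under which `n_τ` acts as a
crowding factor (per-cell secretion halves at `n = n_τ`) and under which α
and β carry their published units. This choice is flagged rather than silent.

Cells neither proliferate (the cell line is conditionally immortalized and
cultured without 4-OHT) nor migrate on this timescale, so the density
equation is death-only; `n_max` is carried as metadata but enters no
equation.

**Parameter count.** The free constants are exactly 19: three gel and three
medium diffusivities, two maximal consumption rates, two half-saturations,
the anaerobic factor A, the VEGF turnover K and five secretion constants
(α, β, c_τ, n_τ — four — plus D_vg already counted), and three death rates.

## Units and oxygen solubility

Internal units are SI mass concentrations (kg/m³, cell/m³, m, s); assay
units (%O₂, mmHg, mol/mL, mM, pg/mL, cells/mL) exist only at the I/O
boundary. Oxygen conversions go through two module constants: 7.6 mmHg per
%O₂ (probe convention) and a solubility of 1.33e-8 mol/mL per %O₂
(equivalently 4.256e-4 kg/m³ per %, O₂ at 32 g/mol). The solubility is fixed
to reproduce the dual listing of the oxygen half-saturation constant
(1.65e-8 mol/mL ↔ 1.24 % O₂); the published kg/m³ value of the same constant
(5.13e-4, implying ~1.21 %) is then inconsistent by ~3 %. The kg/m³
(modeling-unit) column is treated as authoritative and the mismatch is
accepted at the I/O boundary rather than absorbed by a per-quantity fudge.
The same applies to α, whose printed practical-unit and modeling-unit values
are not exactly interconvertible by any single solubility constant.

## Parameter values and bounds

The packaged fixture (`data/final_params.yaml`) reproduces the published
final calibrated values verbatim. Four of them fall outside the literature
search intervals used for screening (converted to modeling units):

| parameter | fixture | literature interval |
|---|---|---|
| D_c_gel | 4.98e-10 m²/s | [1e-10, 4e-10] |
| D_s_gel | 2.67e-10 m²/s | [2.3e-11, 1.51e-10] |
| D_s_med | 9e-11 m²/s | [5.65e-10, 1.09e-9] |
| M_s | 1.75e-18 kg/cell/s | [9.0e-18, 3.96e-17] |

`D_s_med` below the gel value is likely a typo in the source table, and the
`M_s` entry is internally inconsistent with the accompanying narrative
(which calls it ~10× *higher* than literature); both are preserved verbatim
and reported by `check_bounds` rather than corrected. Because of these
violations, calibration uses `calibration_bounds()`: each literature
interval widened, where needed, to the union with [nominal/3, nominal·3],
so the nominal (or synthetic ground-truth) vector is always representable.

Three parameters have no literature interval (A, α, β); the packaged choices
(A ∈ [0.5, 10]; α ∈ [1e-22, 1e-19]; β ∈ [1e-23, 1e-20]) bracket the final
values by roughly an order of magnitude either side. Parameters whose
interval spans ≥ 2 decades are sampled and searched in log₁₀ space —
uniform linear exploration of, e.g., [3.2e-20, 2.5e-17] would essentially
never visit the lower decades.

## Geometry

The well radius is 3.175 mm (96-well). 240 µL of cellular collagen is cast
and plastic compression removes interstitial fluid ~40-fold (seeding
densities 0.5/0.78/1.5 ×10⁶ cells/mL become 20/31/60 ×10⁶), leaving a 6 µL,
~0.19 mm gel. The culture medium above is taken as 200 µL (~6.3 mm), the
handling volume used throughout the assay protocol; the source does not
state the culture volume explicitly. Radial gradients are neglected (the
well wall slope argument makes them <0.2 % of axial ones).

## Discretization and time integration

A two-part finite-volume mesh puts 20 % of the cells in the gel and 80 % in
the medium (default N=100), uniform within each domain, with the gel–medium
interface exactly on a cell face; interfacial flux uses the harmonic-mean
face diffusivity, which enforces continuity of concentration and flux.
Boundary conditions: oxygen Dirichlet (ambient set-point) at the medium–air
interface and no-flux at the base; glucose and VEGF no-flux everywhere
outside. Initial conditions: gel oxygen at 12 % equivalent (preconditioned
medium), medium at ambient; glucose 25 mM medium / 1.25 mM gel; VEGF zero;
cells uniform in the gel.

Time stepping is backward Euler for diffusion with the Michaelis–Menten
sinks linearised about the current state and folded into the implicit
diagonal (unconditionally stable and positivity-preserving for any Δt —
an explicit treatment of diffusion would be unstable at Δt = 100 s on ~10 µm
gel cells); the VEGF source is evaluated at the current state and the cell
ODE is integrated exactly over each step with frozen rates, which keeps `n`
strictly positive and monotone nonincreasing. Default Δt = 100 s. Values in
[−1e-12, 0) after a solve are clipped to zero; anything lower aborts with a
diagnostic. At the reference resolution, doubling both resolutions changes
the 24-h gel-average oxygen by ~0.04 % (the published convergence criterion
was ~1 %).

The probe observable ("centre of the construct") is read at the axial
midpoint of the gel; the gel average (volume-weighted mean over gel cells)
is the principal scalar observable for screening and calibration.

## Morris screening

Trajectories are built on a four-level grid with the standard jump
Δ = p/(2(p−1)) = 2/3: a random admissible base point, then each coordinate
flipped once by ±Δ in random order. From a 500-trajectory candidate pool the
r = 40 most mutually spread are kept by greedy maximin on pairwise
trajectory distance (sum of point-to-point Euclidean distances). Statistics
per parameter and output: μ* = mean |EE| and σ = EE standard deviation with
1/r normalisation (the population form of the source formula). The screened
outputs are the four 24-h gel averages under a reference condition (ambient
1 %, 60e6 cells/mL); the condition is configurable since the original
screening condition is not stated. Model failures exclude a whole trajectory
with a warning rather than aborting the screen.

## Calibration

Cost: per species, mean absolute difference between nondimensionalised
predictions and observations, summed over species. Normalisations: oxygen by
the condition's ambient partial pressure, glucose by the initial 25 mM,
viability is already a fraction, VEGF (initially zero, so the published
"initial concentration" rule is undefined) by the block's maximum observed
value. One cost evaluation runs the solver once per unique condition — the
12 (ambient × density) pairs cover all four blocks.

The swarm is a standard global-best PSO with inertia, bound clipping with
velocity zeroing on clipped coordinates, and a velocity clamp at half the
search range. "1250 samples" is read as 1250 iterations of 20 particles
(the only reading consistent with the stated 25,000 simulations); an
optional plateau stop (relative improvement < 1e-6 over 50 iterations)
substitutes for the convergence criterion the source cites but does not
specify. Step 1 fits {δ₀, δ_c, δ_s, D_cg, c̄, M_c, D_sg, s̄, M_s, A} to the
oxygen/glucose/viability blocks with the published coefficients c1=2,
c2=0.2, w=0.6; step 2 fits {D_vg, K, c_τ, n_τ, α, β} to VEGF with w=0.7,
holding step 1 fixed. A dataset lacking the step-1 blocks skips step 1 with
an explicit warning. `calibration_spread` repeats the whole procedure across
seeds and tabulates per-parameter spread — the multi-start check that
optimizer variability is not what limits the fit.

The published acceleration coefficients (c2 = 0.2, nearly asocial) are tuned
for the full 25,000-evaluation budget; at strongly reduced budgets they
demonstrably under-converge (a 4-D sphere stalls at ~1e-2 after 4,000
evaluations). `SwarmConfig` therefore defaults to the canonical fully-social
setting c1 = c2 = 2, w = 0.7, and the scaled-down recovery study passes
those defaults explicitly while keeping the published coefficients as the
defaults of the full two-step procedure.

## Synthetic data

The generator replays the study's condition matrix through the forward
solver: centre-probe oxygen every 0.5 h for 24 h at 1/3/7 % ambient for the
highest density (144 observations, mmHg), and 24-h medium glucose (mM), gel
viable fraction, and medium VEGF (pg/mL) over 4 ambients × 3 densities
(12 each). "Normoxia" is labelled 19 % following the simulation run matrix
(the assay table says 21 %). Noise is multiplicative Gaussian truncated at
zero, CV 5 % for oxygen/glucose and 8 % for viability/VEGF — conservative
stand-ins for error bars that are plotted but not numerically reported.
Provenance (true parameters, design, noise, solver settings) is recorded so
any dataset regenerates bit-identically from its manifest.

What the generator does *not* emulate: the nested replicate structure of the
experiments (n = 4 independent repeats × 3 samples is flattened to i.i.d.
noise), assay chemistry, imaging artifacts, probe insertion transients, or
model discrepancy of any kind — synthetic recovery tests therefore
demonstrate that the pipeline can invert its own model under measurement
noise, not that the model is correct for real constructs. Note also that the
source calibrated the oxygen block against the *gel-average* trace, while
the synthetic dataset defaults to the *centre-probe* trace to mirror what
was actually measured; the choice is a `StudyDesign` switch and the cost
always compares like with like.

## Problem sizes used by the test suite

Full-budget runs (20 × 1250, r = 40 over 500 candidates, N = 100) are the
package defaults. The test suite exercises the same code paths at reduced
sizes chosen to keep the suite comfortably interactive: forward runs for
calibration tests use N = 50 / Δt = 600 s (endpoint observables differ from
the reference resolution by ≲0.6 %), the ground-truth recovery study uses
10 particles × 150 iterations on 5 %-noise data, and screening sanity checks
use r ≤ 8 with small candidate pools. The recovery study checks the three
parameters the data constrain best (M_c, c̄, δ₀); the remaining step-1
parameters are only weakly identifiable from 24-h endpoints at this noise
level and budget.

## Known limitations

- 1D axial transport only; no advection, swelling, temperature dependence,
  or medium refreshment over the 24 h.
- VEGF has no feedback on viability, no isoform speciation and no
  collagen-binding kinetics.
- The death law is phenomenological; its three rates are partially
  degenerate given endpoint-only viability data.
- Published parameter-table anomalies (see above) are preserved, not fixed.
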