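# Methods

`spherochip` simulates perfusion and drug delivery to multicellular tumour
spheroids (MCTS) cultured in microwell arrays on a microfluidic chip, and
screens the device design space full-factorially. This note records the
model, its numerical treatment, the parameter defaults and the design
choices that were genuinely open.

## Physical model

**Geometry.** The simulated domain is one *unit cell* of a microwell row:
a segment of each supply channel (x-direction), the rectangular connector
duct(s) joining channel and well (y-direction), the cylindrical microwell
(axis along chip height z) and a porous spheroid of diameter 100 µm at the
well centre. Devices with the left connector at the closed sentinel level
(0.1 µm) have no left channel at all (SSC topology); all others are DSC.
A row of many wells is this cell repeated along x; because the flow is
linear (Stokes), channel pressure drops chain additively and a single cell
suffices.

Fixed dimensions (all config-overridable): channel cross-section
200 × 100 µm, connector length 100 µm, well depth = chip height = 100 µm,
unit-cell pitch 400 µm. These are explicit assumptions consistent with
droplet-array spheroid chips of this class; the design factors (connector
width/height 20–60 µm, chamber radius 80–160 µm, porosity 0.2–0.9, flow
rates 0.01–0.02 ml/h) ride on top of them.

**Flow.** Steady incompressible creeping flow with a Brinkman drag in the
spheroid:

    0 = −∇p + µ∇²u − (µ/κ) χ_sph u,     ∇·u = 0

At these rates and scales Re ≈ 10⁻², so the inertial terms of the full
momentum equation are negligible; dropping them makes the operator linear,
a property the tests exploit (field-wise linearity in the inlet rates).
The spheroid permeability follows Kozeny–Carman,
κ = d² ε³ / (180 (1−ε)²), with grain (cell) diameter d = 15 µm — a typical
epithelial cell. κ(0.5) = 6.25 × 10⁻¹³ m². No body force; no internal mass
source.

**Transport.** Time-dependent advection–diffusion with zero reaction:

    ∂c/∂t + ∇·(−D∇c) + v·∇c = 0

Drug enters solely through the inlet Dirichlet value c_in from t = 0⁺.
Inside the spheroid the diffusivity carries a Bruggeman tortuosity
correction D_eff = ε^1.5 D; the advecting velocity is the Darcy seepage
field from the flow solve. Defaults model a 10 µM doxorubicin perfusate:
D = 1.6 × 10⁻¹⁰ m²/s (aqueous small-molecule value),
c_in = 10⁻² mol/m³.

## Discretization and solvers

Both solvers share an isotropic voxel grid (default 10 µm; 5 µm for the
duct oracle, 20 µm for qualitative sweeps). Cells are labelled by region
membership of their centres; walls are *not* penalized but enforced
exactly: the flow unknowns live on a staggered (MAC) arrangement, normal
velocities on fluid–solid faces are zero and tangential stencils use a
ghost value reflected across the wall (second-order no-slip). Inlet faces
carry the rectangular-duct Fourier-series profile renormalized so the
discrete flux equals the prescribed rate exactly; channel outlets sit at
the reference pressure with zero-gradient velocity.

The velocity/pressure saddle point is solved by eliminating velocity: the
velocity block (three decoupled SPD component Laplacians plus drag) is
factorized sparsely once, and the pressure Schur complement is solved by
conjugate gradients preconditioned with a SIMPLE-style sparse
approximation (D diag(A)⁻¹ G, factorized). The verified relative residual
is ~10⁻¹⁰, far below the 10⁻⁴ (four orders of magnitude) convergence
requirement, and the discrete divergence vanishes to solver precision in
every fluid cell.

Transport uses conservative backward-Euler finite volumes: first-order
upwind advective face fluxes (monotone, so the discrete maximum principle
0 ≤ c ≤ c_in holds), harmonic-mean face diffusivities across the spheroid
interface, advective outflow at outlets, zero wall flux. The implicit
operator is factorized once and reused every step (dt default 1–2 s;
accuracy is checked by halving). The conservative form closes the global
mass balance to round-off; `mass_balance_report` audits it per run.

Oracles: the duct profile matches the series solution to 0.4 % at 5 µm
voxels with exact flow-rate recovery; a porous slab reproduces Darcy's
pressure drop µLU/κ to < 5 %; diffusion into a surface-bathed sphere
tracks the classical series solution.

## Design metrics and clustering

Each run is reduced to five spheroid-averaged metrics: concentration,
velocity magnitude, shear rate (√(2 D:D) of the strain-rate tensor),
advective-flux magnitude |u c| and diffusive-flux magnitude |D∇c|.

*Evaluation time.* Flow metrics are steady. For the concentration and flux
metrics the package defaults to the **perfusion-window average**: the
solver accumulates ∫c dt every step, and metrics are evaluated on the mean
field c̄ = (1/T)∫c dt (exact window averages for concentration and
advective flux; the diffusive entry is the flux of the mean field). A
single-instant evaluation (`evaluation=<seconds>`) is also supported but
is degenerate at long horizons: with zero reaction the domain saturates at
c_in well before 120 min for every porosity level (spheroid diffusion time
a²/D_eff ≤ ~3 min), so instantaneous gradients — and with them the
diffusive flux — decay to zero and flux ratios become 0/0. The window
average is the package's deliberate design choice for this reason.

A transport mode is *dominant* when one volume-averaged flux is ≥ 10× the
other (boundary inclusive); otherwise the scenario is mixed. Metrics are
min-max normalized per column (a constant column maps to all zeros — a
declared convention), and designs are clustered agglomeratively with
Euclidean distance and complete (farthest-point) linkage; heatmap rows
follow the dendrogram leaf order. SciPy's linkage is used and is verified
against a brute-force O(n³) agglomeration oracle in the tests.

## Sweep orchestration

Every (geometry, flow-scenario) pair is an independent deterministic job;
parallelism is process-based with no shared state, so results are
bit-identical for any worker count (asserted in the tests). Records
persist per design under the output root with a manifest for resuming;
failures are recorded, not fatal. The pipeline contains no random number
generation; `seed` is a reserved, unused config key. A full 19,200-design
sweep at 10 µm fidelity is a cluster-scale job; the shipped tests and the
reproduction script use coarse subsets (2–8 designs at 10–20 µm voxels,
dt 2–10 s), which keeps every configuration on a desk-scale budget.

## What the model does and does not capture

The unit cell reproduces duct hydraulics, porous-media seepage and
advective–diffusive drug uptake quantitatively (see the oracle suite). Two
structural simplifications matter when comparing with measurements on real
chips:

- **Dead-end wells.** In this topology the microwell couples to the supply
  channel(s) only through the connector ducts. With equal co-current inlet
  rates there is no net pressure difference across the well, so well flow
  is purely shear-driven and decays exponentially along the connector;
  computed well speeds are orders of magnitude below the supply-channel
  speed. Devices whose wells sit directly in the channel flow path will
  show far higher well velocities and advective drug fluxes than this
  model predicts. Unequal supply rates (Q1 = 2 Q2) do create a cross-well
  pressure difference and genuine through-flow, and the model resolves the
  resulting advection enhancement.
- **No uptake kinetics.** Reaction, binding and metabolism are zero, so
  the long-time state is uniform saturation at c_in; sub-saturation
  plateaus seen in cell-laden experiments are outside the model.

Also not modelled: inertial/transient flow, spheroid growth or
deformation, multi-species transport, and unstructured meshing (the voxel
size is the single resolution knob; refinement studies back the reported
tolerances).
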