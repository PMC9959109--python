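# Methods

`emuflux` estimates intracellular carbon fluxes in *E. coli* central
metabolism from steady-state isotope-labeling data: fragment mass-isotopomer
distributions (MIDs) measured by GC-MS after growth on a positionally
13C-labeled substrate, together with measured external rates (growth rate,
glucose uptake, acetate secretion) and the cell's macromolecular composition.
This note records the models, conventions and numerical choices, and what the
synthetic validation does and does not demonstrate.

## Network model

The packaged model (`data/ecoli_core_13c.tsv`) covers glucose metabolism of
aerobically grown *E. coli*: the Embden–Meyerhof–Parnas pathway, the pentose
phosphate pathway, the Entner–Doudoroff route, the TCA cycle with the
glyoxylate shunt, anaplerosis (PEP carboxylase, PEP carboxykinase as OAA
decarboxylation, malic enzyme), the FBPase and PEP-synthetase futile-cycle
partners, both acetate routes (reversible Pta-AckA from acetyl-CoA and
irreversible PoxB from pyruvate), explicit biosynthesis of the measured amino
acids, the serine and threonine routes to glycine with an irreversible
glycine-cleavage system, serine deaminase, the aspartate→fumarate carbon
transfer of nucleotide amination, a biomass drain, and CO2 exchange with the
environment as an explicit reversible reaction (the environmental pool is
unlabeled, as for a culture sparged with air).

Atom transitions are written as letter strings per reaction, 1-based and
lowercase (no pool exceeds 9 carbons). Transketolase and transaldolase follow
the ping-pong mechanism: metabolite-specific reversible half-reactions that
produce/consume enzyme-bound C2 (TKC2) and C3 (TAC3) fragments, so any
donor/acceptor pairing is representable. Molecular symmetry of succinate and
fumarate is encoded as two equally weighted atom-map variants on the
reactions that produce or consume them (0.5/0.5), which scrambles labeling
without touching mass balances. The rotational symmetry of the phenyl ring in
Phe/Tyr is *not* modeled; the packaged fragments are dominated by side-chain
carbons, and the approximation is shared between generator and fitter.

Reversible reactions are a forward/reverse pair, `F = max(net,0) + exch`,
`R = max(-net,0) + exch`; exchange affects labeling only. For fitting,
exchange is parameterized as `exch = u * x/(1-x)` with `x ∈ [0, 0.95]` and
`u` the measured uptake, so the feasible space of one exchange coordinate is
a box.

The steady-state space is parameterized by a named free-flux basis obtained
from a row-reduction of the stoichiometric matrix with a preferred column
order (pathway entry points and slack fluxes are chosen as free parameters
where linear independence allows). Any parameter assignment satisfies
`S·v = 0` by construction.

## Biomass equation

Protein and RNA mass fractions are strain measurements; DNA is fixed at
3.1 % of dry weight; the remaining dry weight is split among phospholipids,
LPS, peptidoglycan and glycogen at the fixed mass ratio 9.1 : 3.4 : 2.5 :
2.5. Each class is expanded into precursor drains through monomer tables
(amino-acid and nucleotide compositions, average monomer recipes for the
lipid/murein/glycogen classes) shipped as an editable YAML fixture. The drain
coefficient of building block *i* in class *P* is
`massfrac_P × 1000 / meanMW_P × molfrac_i` (mmol/gDW), mapped onto network
pools by per-monomer recipes; the biomass reaction then carries flux equal to
the specific growth rate. Recipes are pure drains: small carbon releases
along a route (e.g. the orotate decarboxylation) are neglected — the audit
test checks total drained carbon stays within 10 % of the canonical
~0.48 gC/gDW. Energy cofactors do not enter carbon balancing and are not
carried. K_DW/OD enters only through the measured composition; a sensitivity
test verifies that rebuilding the biomass equation with a different K_DW/OD
leaves the fitted normalized TCA flux essentially unchanged on noise-free
data.

## EMU simulation

Measured fragments are mapped to EMUs (metabolite, carbon subset) and the
network is decomposed backwards through the atom maps. All EMUs of one size
depend linearly on same-size EMUs and on convolutions of strictly smaller
ones, so the default solver assembles one dense linear system per size level
(`A(v)X = B(v)Y`), with flux-dependent coefficients precompiled into
coordinate arrays; a full-model simulation of all 34 packaged fragments takes
well under a millisecond. Strongly-connected-component blocks within each
size are computed and exposed, and a per-SCC solving mode is kept as the
structural baseline; both modes agree to machine precision and are tested
against each other. Pools that receive no flux in a given state (e.g. the
glyoxylate pool when the shunt is off) are assigned an all-zero MID, which
downstream terms weight by zero flux — this keeps the cascade defined on the
boundary of the flux space during optimization. Dense LU is used throughout;
the largest merged system in the packaged problem is well below 10^2
unknowns, so sparse representations are unnecessary.

An independent brute-force oracle solves the full 2^n positional-isotopomer
balances by damped fixed-point iteration (tolerance 1e-14) and marginalizes
to MIDs. It shares no solver code with the cascade and verifies it to 1e-10
on linear, branched/condensing and cyclic-reversible toy networks. The
fixed-point contraction slows as exchange fluxes dominate net fluxes, so the
oracle is a verification tool for small networks, not a production solver.

## Substrate labeling and natural abundance

The tracer is 100 % [1,2-13C]glucose: positions 1 and 2 carry fraction 1.0 of
13C; unlabeled positions default to natural abundance 0.0107 (toggleable),
since nominally fully enriched preparations still carry natural 13C at the
remaining positions. Raw GC-MS fragment MIDs can be corrected for the
isotope patterns of non-backbone atoms (derivatization carbons, H, N, O, S,
Si) by the standard correction-matrix method: the combined isotope pattern of
all non-backbone atoms forms a lower-triangular Toeplitz system that is
inverted in the least-squares sense, with clipping and renormalization.
Fragment carbon subsets and ion formulas ship as an editable fixture; the
sugar-fragment assignments are declared assumptions.

## Flux fitting

The objective is the variance-weighted sum of squared residuals between
measured and simulated quantities. Measured MIDs are normalized to sum to 1,
which makes one channel per fragment redundant and correlates the channel
noise; consistently with the degree-of-freedom convention (every channel
except one per fragment, plus the three external rates, minus the free
parameters), the residual vector excludes each fragment's dominant measured
channel. Without this, the renormalization-induced correlation inflates the
SSR on fragments with concentrated MIDs and mis-calibrates the chi-square
gate. External rates enter as weighted residuals, not constraints. Default
per-channel MID standard deviation is 0.003 mol fraction (typical GC-MS
precision), overridable per measurement.

Optimization is bounded trust-region-reflective nonlinear least squares
(finite-difference Jacobian, tolerances 1e-9) over the free net fluxes and
exchange coordinates. Dependent irreversible nets can go slightly negative
inside the optimizer; a steep linear penalty residual (weight 1e3 per unit of
violation) restores feasibility, and is inactive at any interior optimum.
Multi-start sampling (default 300 points) draws free nets uniformly (uptake
and growth near their measured values) and rejects infeasible draws; the
minimal-SSR optimum that passes the chi-square test at α = 0.05 is reported,
with ties broken by start order. If no start passes, the best optimum is
returned flagged as failing — never silently accepted.

Four structural non-identifiabilities exist in this network/measurement
combination, all invisible to both labeling and external rates: the
PoxB-vs-Pta-AckA acetate split (both routes release pyruvate C1 as CO2 and
export pyruvate C2–C3), serine deaminase (serine inherits 3-phosphoglycerate
carbons unchanged), the FBPase and PEP-synthetase futile cycles, the
aspartate→fumarate amination transfer at its default coupling, and the
malic-enzyme round trip (with malate unmeasured, a shift of pyruvate supply
from pyruvate kinase to malic enzyme can be exactly compensated by the
reversible MDH/fumarase exchanges). These six fluxes are anchored at zero by
default — a reporting convention, overridable via `anchors=`. The acetate
ambiguity is surfaced where it matters: the pyruvate-dehydrogenase flux is
reported as an interval whose lower bound routes all secreted acetate through
pyruvate oxidase (PDH supplies only the acetyl-CoA sinks) and whose upper
bound adds the acetate efflux routed through Pta-AckA.

## Bootstrap confidence intervals

Parametric-bootstrap percentile intervals: replicate datasets are drawn from
the fitted model's predicted means plus Gaussian noise at the measurement
SDs, refit warm-started from the optimum (optionally with random restarts),
and replicates failing the chi-square test are discarded. Percentile bounds
use linear interpolation between order statistics (`h = (n-1)q`), pinned for
reproducibility. Batches (default 100 replicates, max 1000) repeat until
every tracked CI border moves less than 0.5 normalized-flux percentage
points between batches; fewer than 20 retained replicates flags the interval
unconverged. Two fitted fluxes are called different across strains when their
95 % intervals do not overlap — a declared convention, since non-overlap at
the same level is stricter than a two-sample test.

## Synthetic data generator

The generator defines three scenario presets. Ground-truth flux vectors are
the deterministic solution of a quadratic program over the model's nullspace:
hard equality targets (glucose uptake, citrate-synthase flux, growth rate,
acetate efflux, and the six anchored slack fluxes at zero), soft wishes for
the remaining pathway splits, and irreversibility constraints.

* `wild_type`: uptake 8 mmol/gDW/h, growth 0.65 1/h, citrate synthase 65 % of
  uptake, acetate overflow 20 %, oxidative PP ~22 %, composition 55 %
  protein / 20 % RNA, K_DW/OD 0.51.
* `hppa`: identical fluxome to wild type (the co-expression strain is
  phenotypically indistinguishable).
* `hppa_dppa`: uptake 6, growth 0.375 (biomass yield 23 % below wild type),
  citrate synthase exactly 0.64× the wild-type normalized value, acetate
  overflow 69 % (carbon balance then forces the oxidative PP flux slightly
  below wild type), composition 50 % protein / 16 % RNA, K_DW/OD 0.66.

These are design conditions chosen to be qualitatively realistic for glucose
batch growth, not literature values; the acetate overflow of the replacement
strain is what closes the carbon balance at the reduced TCA flux and yield.
Noise is independent Gaussian per MID channel (default sd 0.003) followed by
row renormalization — deliberately without clipping, so the noise model is
exactly linear-Gaussian; external rates get Gaussian noise truncated at zero.
Exchange fluxes of the ground truth are fixed plausible values scaled to
uptake.

What the synthetic validation shows: the estimator recovers its own
generator's ground truth (round trip), its chi-square gate is calibrated
under the assumed noise model, and bootstrap intervals approximately attain
nominal coverage. What it does not show: robustness to real-data features
absent from the generator — correlated channel noise, derivatization
artifacts and imperfect natural-abundance correction, metabolic channeling,
inaccurate atom maps, or composition measurement error.

## Problem sizes used in the validation suite

Round-trip recovery uses 50 multi-starts per preset; the strain-comparison
experiment uses 20 starts per strain and bootstrap batches of 25 capped at 50
replicates; chi-square calibration uses 50 seeds with truth-warm-started
refits; bootstrap coverage uses 200 runs × 30 replicates on a three-carbon
toy network. These sizes give stable statistics while keeping the whole
suite comfortably fast on a single CPU.
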