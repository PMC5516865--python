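# Methods

## The signaling model

`erbbqsp` simulates ligand-driven activation of Akt through the ErbB
receptor family in cells expressing EGFR, HER2 and ErbB3 (ErbB4 is
excluded; its expression in the cell systems of interest is negligible).
The model is written entirely in mass-action kinetics:

* **Ligand capture.** Heregulin (HRG) binds ErbB3; betacellulin (BTC)
  binds EGFR. Both are reversible bimolecular steps.
* **Dimerization.** Ligand-bound receptors heterodimerize with free
  partners (HRG:ErbB3 with EGFR or HER2; BTC:EGFR with ErbB3). In the
  default topology BTC-bound EGFR pairs *only* with ErbB3 — this routing
  is the model's explanation for BTC-induced ErbB3 phosphorylation, and
  BTC:EGFR homodimerization / BTC:EGFR–HER2 pairing exist behind build
  flags, off by default. Ligand-free receptors also pair weakly
  (constitutive dimerization), producing the basal phospho-signal.
  ErbB3:ErbB3 homodimers are excluded: with two kinase-dead partners the
  pair cannot trans-phosphorylate.
* **Phosphorylation cycle.** Every dimer containing a kinase-active
  partner (EGFR or HER2) converts to its phospho-form at `kphos` and
  back at `kdephos`. ErbB3 is phosphorylated only in trans, by its
  partner.
* **Trafficking.** Phospho-dimers internalize (`kint`); the endosomal
  pool either recycles its receptors to the membrane (`krec`, ligand
  lost) or is degraded (`kdeg`). With `kdeg = 0` total receptor mass is
  conserved exactly, which the test suite checks to 1e-6.
* **PI3K/Akt.** Phospho-ErbB3 carries six PI3K docking sites, lumped
  into one binding reaction whose on-rate is scaled by the multiplicity
  (`kon_pi3k x pi3k_sites`). Akt activation is an explicit enzymatic
  cycle — complex + Akt ⇌ complex:Akt → complex + pAkt — rather than a
  single bilinear rate. This matters: with a bare bilinear law, steady
  p-Akt is *exactly* proportional to total Akt, pinning the Akt
  amount-sensitivity at 1.0 and making it impossible for any receptor to
  rank above Akt in a sensitivity analysis. The enzymatic form is still
  pure mass action and reduces to the bilinear law far from saturation.
  Adaptor binding does not shield a dimer from the phosphatase or from
  internalization (both paths eject the bound PI3K/Akt); without those
  channels the PI3K-bound states are absorbing, basal signal can never
  be cleared by a drug, and PI3K acquires a large spurious sensitivity
  through pure shielding.

The default cell line expresses 1e5 EGFR, 2e5 HER2 and 2e4 ErbB3
receptors per cell, with 1e5 PI3K and 1e6 Akt molecules. ErbB3 scarcity
is deliberate and biologically grounded: ErbB3 is the low-abundance,
rate-limiting node of the network, which is exactly why the sensitivity
analysis finds it to be the best intervention point.

## Units and numerics

Extracellular species are specified in nmol/l, everything else in
molecules/cell. Internally every amount is converted to molecules/cell
using an extracellular (medium) volume of 1e-9 l/cell, so conservation
is exact by construction; bimolecular fluxes in concentration terms are
invariant to this volume choice, which only sets the *reservoir* size —
i.e. how much bound ligand depletes the medium. (A pericellular-shell
volume of 1e-12 l/cell would make a 1 nmol/l ligand dose ~600
molecules/cell, fully consumed by 2e4 receptors, contradicting the
ligand-in-excess design of the experiments being emulated; the
pericellular volume is retained as the documented unit bridge in
`receptors_to_concentration`.)

Integration uses LSODA with an analytic Jacobian assembled from the
reaction stoichiometry (relative tolerance 1e-6, absolute 1e-8).
Protocol events — timed ligand or drug additions after a 30-min
equilibration phase — are applied by stop-and-restart, never
interpolated through. Determinism is bit-exact for identical inputs.
`steady_state` integrates in chunks until max |dy/dt|/(|y|+1e-9) falls
below the tolerance and *flags* non-convergence: note that with
degradation active and no synthesis the only fixed point is the empty
state (every pool decays exponentially, with constant relative
derivative), so long-horizon comparisons are made against the
degradation-balanced network.

## Default rate constants

No numeric rate table exists for this model family in print, so the
defaults are order-of-magnitude literature values for receptor tyrosine
kinase systems — ligand kon ~1e6 /M/s, ligand Kd 1–2 nmol/l, minutes-
scale dimerization, `kphos/kdephos` = 5/1 per minute, trafficking on the
10–20 min scale — refined once, by coarse scan, so that the default model
operates in the documented qualitative regime: ErbB3-limiting, strongly
forward-driven ligand dimerization (`kon_dim_lig` 4e-6 per molecule per
min), weak constitutive pairing (`kon_dim_const` 1e-8, enough that high
HER2 measurably sequesters ErbB3), PI3K-saturated phospho-ErbB3 and
near-saturated Akt turnover. Every value is overridable per cell line
through `parameter_overrides`, and each entry in the default
`ParameterSet` carries a provenance note.

## Drug mechanisms

All three mechanisms are purely additive network extensions, so zero
dose reproduces the unextended trajectories exactly.

* **ErbB3 blocker** (seribantumab-class): monovalent-equivalent
  reversible binding to free ErbB3 with sub-nanomolar Kd (default
  0.2 nmol/l). Antibody-bound ErbB3 can neither bind HRG nor enter any
  dimerization route (this single occupancy rule silences HRG-driven,
  BTC-routed and constitutive signal alike), and it internalizes at
  `internalization_multiplier x kint` (default 2x) with the internalized
  pool degraded by default (fraction 1, configurable) — producing the
  observed total-ErbB3 downregulation.
* **HER2/ErbB3 bispecific** (MM-111-class): strict two-step binding.
  The drug docks onto HER2 with solution kinetics, then the tethered
  ErbB3 arm (deliberately weak in solution, default Kd 50 nmol/l)
  crosslinks ErbB3 with its per-molecule on-rate boosted
  `crosslink_factor`-fold (default 1e3 — numerically the ratio of the
  extracellular to the pericellular volume, i.e. the concentration gain
  of membrane confinement). No HER2 anchor, no ErbB3 engagement.
* **EGFR TKI** (erlotinib-class, modeled like lapatinib): reversible
  binding to every unphosphorylated EGFR-containing species with equal
  affinity (default ki 50 nmol/l). TKI-bound dimers do not
  trans-phosphorylate; TKI-bound monomers do not dimerize. A saturating
  dose therefore leaves HRG-driven HER2:ErbB3 signal intact — the
  mechanistic basis of the blocker+TKI combination. Note that even a
  large TKI excess leaves a small phospho-signal: the free-dimer
  fraction ki/(ki+dose) is amplified by `kphos/kdephos`, so "saturating"
  in the tests means ≥400x ki.

The HER2 potency scan reproduces the crossover logic: the blocker's IC50
rises with HER2 (constitutive HER2:ErbB3 pairing sequesters ErbB3 away
from the antibody), the bispecific's falls (more anchors, more avidity),
and with defaults the curves cross once, near 1e5 HER2 receptors/cell.

## Sensitivity analysis

Local, species-amount sensitivity by central finite differences
(default ±1%): the initial pool (or event-added amount, for ligands) is
scaled by 1±h, and

S = (1/T) ∫₀ᵀ [O⁺(t) − O⁻(t)] / [2 h O₀(t) + ε] dt,  T = 2 h,

by trapezoidal quadrature on the output grid (ε = 1e-12; points where
the nominal output is exactly zero are 0/0 limits and are excluded).
Normalizing by the time-varying nominal trace makes S a time-averaged
d ln O / d ln X — dimensionless and invariant to rescaling of either
axis, so it is comparable across species and outputs. Signed values are
reported; ranking uses |S|, displayed in HRG-condition order. Parameter
(rate-constant) sensitivities and global methods are out of scope.

## Calibration

Dose–time phospho matrices are normalized per readout to the largest
signal under either stimulus (joint-max rule), the same rule is applied
to the simulations, and the objective is unweighted SSE over the full
grid. Optimization is an elitist GA in log-parameter space (log-uniform
initialization, tournament of 3, uniform crossover 0.7, per-gene
Gaussian mutation 0.2 at σ=0.15 log10, elite of 1 — making the
best-so-far trace provably monotone), fully reproducible from its seed.

Which parameters are worth freeing is an identifiability question. Under
joint-max normalization the absolute signal scales cancel, and the
strong-dimerization regime kinetically traps ligand: the ligand
*off*-rates become flat directions, and kphos/kdephos/PI3K-on are
mutually compensatory. The worked recovery example therefore frees the
three kinetically distinct constants — `kon_hrg` (rise time vs dose),
`kint` (post-peak decline) and `kdeact_akt` (p-Akt relaxation) — which a
3-dose x 6-time grid pins down within 2-fold at 5% noise (typically
within 1.5-fold). The broader default bounds table remains available
and configurable.

## Pharmacokinetics

One-compartment model with first-order absorption from an i.p. depot
(bioavailability 1) and Michaelis–Menten elimination, in µg / ml / h:

dA/dt = −ka·A,  dC/dt = ka·A/V − (Vmax/V)·C/(Km+C).

Saturable elimination is the standard reading of a terminal half-life
that lengthens with dose. Defaults are mouse-scale: ka 0.3 /h, V 2 ml,
Vmax 10 µg/h, Km 50 µg/ml — Km deliberately at the concentration where
clearance visibly accelerates. These defaults give strictly
dose-ordered terminal half-lives over a 150/300/600 µg single-dose
series sampled at 1–168 h, and a 600 µg q3d schedule that holds the
steady-state trough above the 100 µg/ml (667 nmol/l at 150 kDa) goal.
Fitting is joint least-squares in log-concentration across dose groups
with a seeded log-space multistart; a single dose group cannot separate
Vmax from Km and is flagged `weakly_identified` rather than rejected.
Trough computation requires a uniform repeating schedule of ≥5 cycles
and flags non-stationarity (e.g. accumulation without elimination).

## Tumor growth and synergy

Caliper volume is width²×length×0.52. Exponential growth is fitted on
log-volume (volumes floored at 1 mm³ with a warning) by a linear mixed
model with group-specific fixed slopes and per-mouse random intercepts
(REML; random slopes behind a flag; statsmodels `MixedLM`). A singular
fit falls back to the per-mouse OLS slope average with a warning.
%TGI = (k_ctrl − k_i)/k_ctrl × 100, passed to the Bliss expectation
f_AB = f_A + f_B − f_A·f_B unclamped — regressions give TGI > 100%, and
the expectation is then flagged as non-probabilistic via a warning
rather than silently truncated. The synergy call uses a ±5 percentage
point tolerance around the expectation (no printed margin exists; five
points is well inside the Monte-Carlo spread of the rate estimates at
the default noise).

## Ligand screen and viability

Screen plates: replicate-median per ligand, subtract the median HSA
(vehicle) signal, divide by the largest background-subtracted signal in
the cell line. The top ligand scores exactly 1 (ties all map to 1),
below-background ligands go negative and are retained, and a plate with
nothing above background raises rather than emitting noise. Viability
dose–response curves are compared by trapezoidal AUC over log10-dose
(the dose axis is logarithmic by design of such titrations); the AUC
fold-change is invariant to common rescaling.

## Synthetic data: what it does and does not show

Every generator is a pure function of its arguments including the seed.
Signaling and PK noise is multiplicative (assay CVs are relative;
Gaussian-relative or lognormal), tumor noise is additive on the log
scale (matching the log-linear model), and PK censoring is left-
censoring at a configurable quantification limit with censored records
dropped, not imputed. Caliper widths/lengths are back-derived from the
simulated volumes through the 0.52 formula at a fixed aspect ratio.

The generators reproduce the *statistical structure the estimators
assume* — which is the point: they make every stage testable as a
closed loop (generate at known truth → analyze → recover the truth).
Passing those loops demonstrates correctness of the estimators under
their own assumptions; it does not demonstrate robustness to what real
data add — model misspecification (non-exponential growth,
non-Michaelis elimination), correlated or heteroscedastic assay noise,
batch effects, or dropout that is informative rather than purely
assay-limited.

## Problem sizes

The shipped checks use desk-scale sizes chosen to exercise every code
path: 3-dose × 4–6-time signaling grids, 7-point HER2 scans with
11-dose titrations, 20-replicate Monte-Carlo loops for PK and growth
recovery, 8 mice per group, and a GA of 24×25 for the recovery example.
All are parameters, not constants.

## Known limitations

* No receptor synthesis: the model describes acute (hours-scale)
  experiments; without synthesis, degradation makes the empty state the
  only true steady state.
* ErbB4, EGF and the Erk/MAPK arm are out of scope by design.
* TKI-bound dimers neither dissociate nor internalize (they only
  release the TKI); this truncation is invisible at the readouts used
  but is not literal biochemistry.
* The bispecific has no direct solution-phase ErbB3 arm engagement
  (anchor-first binding); a monovalent ErbB3 interaction would add a
  weak HER2-independent effect at high dose.
* PK is a lumped MM-elimination model — target-mediated disposition,
  tissue compartments and allometric scaling are not modeled.
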