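# Methods

`spatialqsp` couples a whole-patient compartmental ODE model of tumor–immune
dynamics under PD-1 checkpoint blockade to 3D on-lattice agent-based tumor
volumes with a finite-volume cytokine layer, and layers virtual-clinical-trial
and biomarker-selection machinery on top. This note records the model forms,
the parameter choices that matter, the numerical decisions, and what the
synthetic test conditions do and do not establish.

## Whole-patient ODE module

Compartments: tumor, tumor-draining lymph node (LN), central (blood), and
peripheral. Species: cancer cells `C1`; tumor effector/regulatory/exhausted
T cells; central Teff/Treg; a dimensionless antigen pool; pMHC-loaded APCs
and primed LN pools; antibody concentration in central, peripheral and tumor
compartments.

Reaction forms (all rates per day):

- **Growth** — logistic, `r·C1·(1 − C1/(w·K))`. `K` is a whole-tumor
  carrying capacity; when the module tracks only a fraction `w` of the tumor
  its capacity share scales accordingly, which is what makes whole-tumor
  behavior independent of the ODE/ABM split (see *Coupling*).
- **Killing** — `k_C_death_by_T · Teff/(C1 + T_all) · (1 − H) · C1`, where
  `T_all = Teff + Treg + Texh` and `H` is the checkpoint modifier below.
- **Exhaustion** — two routes:
  `k_Teff_death_by_C · C1/(C1 + T_all) · H₁ · Teff` (PD-L1 contact, Hill
  exponent 1) and `k_Teff_inhibBy_Treg · Treg/(C1 + T_all) · (1 + H) · Teff`
  (Treg suppression, amplified by checkpoint engagement).
- **Transmigration** — proportional to the product of adhesion sites
  (`S_adhesion_tot · vol_tum_max · C1/K`) and T cells on tumor vasculature
  (`Cent.T · vol_tum_max · f_vol_BV · C1/K / vol_cent`), i.e. quadratic in
  tumor burden.
- **LN priming chain** — cancer-cell death feeds the antigen pool
  (`antigen_per_death · antigen_strength` per death, first-order clearance);
  antigen loads APCs; priming of the naive pool and clonal expansion of the
  primed pools are saturating (Michaelis) in loaded APCs, with expansion
  limited by a LN carrying capacity (`ln_capacity`, default 5e8 cells) so
  the positive feedback between tumor killing and T-cell supply ignites but
  saturates at a physiological central pool (~5e9 effector cells). Primed
  cells egress to blood at `k_ln_out`; the Treg output is a fixed fraction
  of the Teff output. Tumor mutational burden (`n_clones`) scales the
  priming gain linearly, normalized to the default of 100 clones. These
  forms are this package's own closure: the qualitative loop (more death →
  more neoantigen → more priming) is the modeled biology; the specific
  saturating forms and constants are documented defaults, not fitted.
- **Antibody PK** — two-compartment (central/peripheral) with linear
  clearance; the tumor concentration equilibrates toward
  `gamma_nivo_tum ×` plasma as a sampling compartment whose mass feedback
  on plasma is neglected (tumor volume ≪ central volume). A 3 mg/kg bolus
  raises the central concentration by `dose·mass/(MW·V_cent)` ≈ 2.9e-7 M.

The default parameterization was chosen once so that an untreated virtual
patient progresses (growth to carrying capacity, immune pool decays) while
checkpoint blockade can flip the priming feedback and produce regression —
the bistable respond/progress phenotype that makes cohort endpoints
informative. It is deliberately responder-rich relative to clinical response
rates; no clinical dataset was fitted.

**Integration.** LSODA via `scipy.integrate.solve_ivp`, rtol 1e-6, atol 1e-9
(configurable). Species are clipped to zero after each step within a small
tolerance; deeper negative excursions raise a stepping error carrying the
time and state. The checkpoint modifier inside the RHS is memoized on the
antibody concentration rounded to four significant digits (well below the
Hill sensitivity scale).

## Immune-synapse equilibrium

Within a T-cell/target synapse, total synaptic PD-1 is
`T1 = Teff_PD1_tot · A_syn/A_T`; total synaptic PD-L1 is
`T2 = C1_PDL1_tot · A_syn/A_C · f(IFNγ)` with
`f = base + (1 − base)·Hill(c; EC50, n)` — PD-L1 is IFNγ-inducible with a
5% basal floor. A bivalent anti-PD-1 antibody binds with one arm
(constant `k2 = 2·f_vol_tum/kd_nivo`, two equivalent arms) and cross-links a
second PD-1 with efficiency `chi` (constant
`k3 = chi/(kd_nivo·Na·A_syn·d_syn·1e-15)`). The PD-1:PD-L1 2D association
uses the same synaptic-volume conversion,
`k1 = 1/(kd_PD1_PDL1·Na·A_syn·d_syn·1e-15)`; with the default geometry
`k1·T2 ≈ 2`, i.e. moderate occupancy rather than saturation, which is what
gives the antibody a realistic competitive window.

At equilibrium the bound fraction `x = bonds/T2` satisfies a monic cubic
whose coefficients are

```
a2 = −[2 + 1/(k1·T2) + T1/T2 + Nivo·k2/(k1·T2)·(1 − 2·k3/k1)]
a1 =   1 + 1/(k1·T2) + 2·T1/T2 + Nivo·k2/(k1·T2)
a0 = −T1/T2
```

derived by eliminating the free species from the equilibrium and
conservation relations. The cubic has exactly one root in the open interval
(0, 1); without antibody it factors as `(x − 1)·quadratic` and the physical
root is the smaller quadratic root, evaluated in closed form with the
numerically stable `2·ratio/(b + √disc)` expression. With antibody the root
is found by bracketed Brent iteration on (0, 1) (tolerance 1e-12), with the
bracket retreated from x = 1 when the cubic grazes zero there. A mass-action
kinetic relaxation of the same network (Radau, long horizon, steady-state
residual check) serves as an independent oracle in the tests; agreement is
at the 1e-11 relative level.

The bond count feeds `H = (X/K)^n / (1 + (X/K)^n)` (default K = 300 bonds,
n = 2); killing is scaled by `(1 − H)`, PD-L1 exhaustion by `H` at exponent
1, Treg exhaustion by `(1 + H)`.

## Voxel lattice and agent rules

Cubic voxels of 20 µm; one cancer cell per voxel; up to 8 T cells in a
cancer-free voxel, 1 if a cancer cell is present. Movement uses von Neumann
(6-voxel) neighborhoods, interaction scanning uses Moore (26-voxel)
neighborhoods, both truncated at no-flux boundaries. Neighbor tables are
memoized per grid. Agent update order is a fresh uniform permutation each
step to avoid directional artifacts.

**Cancer lineage.** Cancer stem-like cells (CSC) divide at rate
`r_s = r/(1 − k)`; a fraction `k` of divisions is asymmetric (one CSC + one
progenitor). Progenitors divide at `r_p` up to `d_max` rounds, after which
daughters are senescent; senescent cells die at `mu`. Rates convert to
per-step probabilities via `P = 1 − exp(−rate·dt)`. Division requires a free
von Neumann voxel; a crowded cell's attempt is logged and skipped. Each CSC
carries a unique lineage label inherited by its progenitor descendants. The
mean-field of these rules is a linear ODE chain whose asymptotic
composition is closed-form:

```
p  = k·r_s/((1−k)·r_s + r_p)      P1 : CSC ratio
l1 = 2·r_p/((1−k)·r_s + r_p)     Pi : Pi−1 ratio
l2 = 2·r_p/((1−k)·r_s + mu)      Sn : P_dmax ratio
q  = 1 + p·(l1^dmax − 1)/(l1 − 1) + p·l1^(dmax−1)·l2
```

with fractions `(1/q, p·l1^(i−1)/q, p·l1^(dmax−1)·l2/q)`; the `l1 → 1`
degenerate geometric sum (`q = 1 + p·d_max + p·l2`) is taken when
`|l1 − 1| < 1e-9`. These fractions seed newly populated voxels so that
filling never perturbs the composition. Note the asymptotic growth rate `r`
is *net of* senescent death; this matters when matching the ODE tumor (see
*Coupling*).

**T cells.** Effector CD8s and Tregs are recruited at vascular entry points
(Poisson-placed, density per mm³, configurable per region and z-stratum)
with per-point Bernoulli probability `n = Cent.T · Tum.C1 · k_rec`,
`k_rec = n_r·k_Teff_transmig·vol_tum_max·f_vol_BV/(K·vol_cent)`; the
normalization `n_r` (default 10) keeps the maximum `n` below 1 along default
trajectories, and a warning is logged if it is exceeded. Effectors in Moore
contact with a cancer cell become cytotoxic; cytotoxic cells emit IL-2 and
IFNγ, accumulate local IL-2 exposure, and once the cumulative exposure
crosses `il2_threshold` may divide (up to `il2_max_divisions` per cell;
daughters start as effectors). Killing is evaluated once per cancer cell
per step with a single aggregated draw:
`P_kill = 1 − exp(−dt·k_C_death_by_T·(1−H)·q_teff)` where `q_teff` is the
fraction of cytotoxic CD8s among all Moore-neighborhood cells of the
target — matching the compartmental reaction form rather than independent
per-attacker draws. Exhaustion draws use
`P = 1 − exp(−dt·k_Teff_death_by_C·H)` (every cell expresses PD-L1, so the
neighborhood PD-L1 fraction is 1) and
`P = 1 − exp(−dt·k_Teff_inhibBy_Treg·(1+H)·q_treg)`. Exhausted cells stop
killing but persist, occupy space and die at the natural lifespan. The
synapse is solved per target from its local IFNγ and the tumor antibody
concentration, memoized within a step on the quantized concentration.

**Invasive front window.** Front-type volumes populate only the lower-z
half and record the cancer center of mass at initialization. When the
center of mass drifts ≥ 1 voxel, all contents — agents, occupancy, entry
points, cytokine rasters — translate by the negated integer drift; voxels
opened on the tumor side (low z) are repopulated from the lineage fractions
at the volume's fill probability, voxels opened on the stromal side stay
empty; anything shifted off-grid is removed and counted. Shifts are
restricted to the z axis (the front normal).

## Cytokine fields

Each cytokine obeys `∂c/∂t = D∇²c − γc + s − u·c` on the agent lattice with
no-flux boundaries. One step applies an implicit locally-one-dimensional
splitting — three tridiagonal Thomas solves (banded LU), one per axis —
followed by a pointwise implicit reaction update
`c ← (c + dt·s)/(1 + dt·(γ + u))`. The sweep matrices have unit column
sums, so with no decay or uptake total mass is conserved to round-off
(measured drift ~1e-14 relative over 1000 steps); the implicit treatment is
unconditionally stable and keeps concentrations nonnegative. Sources sit at
voxel centers and are rebuilt from agent positions every step, so a source
follows its cell exactly. Fields advance with `n_pde_substeps` (default 10)
substeps per ABM step. Accuracy benchmark: a centered point source run to
steady state on a refined grid (10 µm voxels, 71³, decay length 100 µm)
reproduces the analytic screened profile `s·e^(−r√(γ/D))/(4πDr)` with
shell-averaged error ≈ 1% for r between 60 and 200 µm; errors grow near the
singular source voxel and within ~2 decay lengths of the boundary, which
bounds the comparison window. Halving the voxel and time step reduces the
error, consistent with the scheme's order.

Numeric values of D, γ and per-cell secretion/uptake rates are documented
defaults of this package (diffusivity 8.6e4 µm²/day ≈ 1e-6 cm²/s, decay
12–24/day), not asserted against any measurement.

## ODE/ABM coupling

A fraction `w_qsp` of the tumor-compartment cell species is tracked by the
ODE module; one or more ABM volumes stand for the rest, with region-type
weights `k_i`. Raw volume counts scale by
`s_i = k_i·(1 − w)/w · C_qsp/ΣC_i` (recomputed each step). Per
synchronization interval `dt`: the volumes advance first against frozen ODE
inputs (central Teff/Treg, tumor antibody); then the ODE integrates; then
scaled ABM recruitment is deducted from the central pools (clamped at zero
with a warning) and scaled ABM cancer deaths are added to the antigen pool.
The one-`dt` feedback lag is accepted and documented. Initial conditions
carry the weight: the ODE starts at `w × ` the whole-tumor burden, and both
its logistic capacity and its quadratic recruitment flux are rescaled by
`w` so each side represents exactly its share.

The invariance contract — whole-tumor trajectories unchanged under the
split weight — is exercised in a configuration where the two tumor
representations are genuinely equivalent: immune killing off, and the ODE's
net growth `r` split into gross growth `r + δ` and innate death `δ`, where
`δ = mu × (senescent steady fraction)` is the lineage's per-capita
senescent turnover (the lineage `r` already nets this out). Under those
conditions whole-tumor cancer counts agree to ~1e-5 % between w = 0.9 and
w = 0.5, and the central effector pool — which flows through the stochastic
ABM death → antigen → priming chain, with ABM noise amplified ninefold at
w = 0.5 — agrees within a few percent. With the full rule set (IL-2
divisions, spatial crowding, contact-limited killing) the two
representations are intentionally *not* identical; those mechanisms are the
spatial module's scientific content.

## Virtual trials and statistics

**Cohorts.** Selected parameters are sampled by Latin hypercube: per
dimension, one draw per equal-probability stratum, independently permuted,
mapped through log-normal quantiles with median equal to the baseline value
and per-parameter log-σ (default band 0.3–0.5; the spread is a modeling
choice). Each patient runs several stochastic replicates; endpoints are
computed per replicate and summarized by the median (minima are taken per
replicate first). Pretreatment biomarkers (initial diameter, total cancer
count, regional cancer densities, blood and tumor T-cell counts, mutational
burden) are read at the last pre-dose record.

**Endpoints.** Tumor diameter pools cancer and T cells:
`d = (6·Σnᵢ·Vᵢ/(π(1 − f_vol_tum)))^(1/3)` with 20 µm cancer cells, 10 µm
lymphocytes and void fraction 0.5. Relative change is against the diameter
at the first-infusion time. Best response is the minimum relative change
from 8 weeks after the first dose. Categories: CR if the whole-tumor cancer
count falls below a detection floor (default 1e5 cells), PR at ≤ −30%, PD
at > +20%, SD otherwise; responders are CR/PR. Time to progression is the
first output-grid point (default daily) exceeding +20%, censored at the
horizon; no interpolation.

**PRCC.** Ranks on both sides; for each parameter the linear effect of all
other ranked parameters is removed from both its ranks and the outcome
ranks and the residuals are correlated; p-values use the t transform with
`n − p` degrees of freedom (the conventional `n − p − 2` differs
negligibly at the cohort sizes used). Significance stars at 1e-3 / 1e-6 /
1e-9. PRCC is exactly invariant under monotone transforms of the outcome.

**Selection.** Forward stepwise from the intercept-only model, adding the
candidate with the smallest likelihood-ratio p-value while p < α (default
0.05, per-step, no multiplicity correction — under an all-null table with m
candidates the model stays empty at roughly `(1 − α)^m`); backward
elimination drops the largest-p candidate while p > α. Families: OLS
(continuous), logistic (responder), Cox proportional hazards (TTP, Efron
ties, horizon-censored records carry event = 0). The null Cox partial
log-likelihood is evaluated in closed form at β = 0 with Efron tie handling
so nested LRTs are consistent with the fitted models. Robustness: 100
resamples *with replacement* of size 0.9 n — a deliberately literal,
slightly unconventional bootstrap variant — with forward selection per
resample and per-candidate selection percentages reported; note that on a
fixed dataset a chance-correlated decoy can recur across (dependent)
resamples, so frequencies are interpreted relative to the planted signals.
Subgroups: median dichotomization (ties to the lower group), subgroup means
with t-based 95% CIs, response rates with Wilson score intervals (flagged
unbounded at 0 or n events), and the log hazard ratio of high vs low from a
single-covariate Cox fit. Responder vs non-responder comparisons use the
two-sided Mann–Whitney U with midranks and continuity-corrected normal
approximation.

**Synthetic cohort generator.** `fixture_cohort` plants linear effects on a
latent score that drives all three endpoint flavors — Gaussian continuous
endpoint, logistic responder flag, exponential TTP with hazard
`h₀·exp(score)` censored at its 95th percentile — plus independent decoy
biomarkers. It emulates effect recovery and null behavior, not the
correlation structure of real cohorts: biomarkers are independent, links
are exact, censoring is administrative. Passing recovery tests therefore
demonstrates the statistical machinery, not clinical validity.

## Problem sizes and test conditions

Desk-scale defaults keep the full suite and the acceptance script well
inside interactive budgets: lineage-convergence runs use a 30³ lattice with
sparse mobile founders (120 simulated days, 10 seeds); coupling-invariance
runs use 16³ volumes over 60 days; the demonstration cohort uses 8 patients
× 2 replicates on a 10³ core volume over 105 days with two 3 mg/kg doses.
Larger domains (e.g. the 500×500×10 whole-slide-style slab) are exercised
for geometry bookkeeping only. All randomness flows from explicit seeds;
per-volume streams are spawned from a master seed so adding a volume never
perturbs another's draws.

## Known limitations

- The ODE network is a reduced closure with documented defaults rather
  than a parameterization fitted to clinical data, so absolute cohort
  statistics (e.g. response rates) are illustrative.
- LN equations and antigen→pMHC stoichiometry are saturating placeholders;
  the innate background cancer death rate defaults to 0.
- PD-L2 is ignored; only IL-2 and IFNγ ship in the molecular layer; no
  advection or vascular cytokine exchange.
- T-cell motility is an unbiased random walk (no chemotaxis); cytotoxic →
  effector reversion is absent; Treg lifespan equals the CD8 lifespan.
- Window shifting is z-only; at most two ABM region types are exercised.
- The 2D synapse affinity convention (3D Kd scaled through the synaptic
  volume) is one defensible choice among several; the solver accepts
  (k1, k2, k3) directly so any other convention can be injected.
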