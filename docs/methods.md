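# Methods

This note documents the models, parameter choices, and numerical
decisions behind `polysynergy`, in the order the pipeline runs them.

## Target profile binarization and sensitivity normalization

A kinase is a target of a drug iff its K<sub>d</sub> is at most 50× the
drug's minimal K<sub>d</sub> (inclusive boundary). Missing K<sub>d</sub>
means "not bound at the assayed range" and is never a target — kinome
binding panels report only bound kinases. The stricter deconvolution
rule (below) uses K<sub>d</sub> *strictly below* 10× the minimum; the
two thresholds deliberately differ in boundary semantics. Drug-specific
thresholds are used because inhibitors differ enormously in their
inherent on/off-target potency, so an absolute K<sub>d</sub> cutoff
would conflate potency with selectivity.

Raw drug sensitivity scores (DSS, an AUC-like summary of the
single-agent dose response) are min–max normalized to [0, 1] per screen;
an all-equal screen is rejected as degenerate rather than silently
mapped to a constant.

## The min–max sensitivity predictor

Implemented exactly as described in the README, over integer bitmask
profiles for speed. Decisions a reimplementer must make and how we made
them:

- **Strictness.** All subset/superset relations in the averaging branch
  are strict; profile equality is consumed entirely by the exact-match
  branch.
- **Boundary (pseudo-drug) convention.** When no strict subset
  (superset) training drug exists, y_min = 0 (y_max = 1), i.e. virtual
  drugs with the empty profile ("inhibiting nothing kills nothing") and
  the full universe ("inhibiting everything kills everything"). These
  virtual drugs never enter the averaging when real subsets/supersets
  exist.
- **Tie-breaks.** The argmax (argmin) over equally sensitive
  subset (superset) drugs takes the first in training order; the tests'
  independent brute-force oracle implements the same rule separately.
- **Known non-property.** The predictor is *not* monotone under raising
  an arbitrary strict-subset drug's sensitivity: promoting a low drug to
  the new argmax can pull previously excluded low sensitivities into
  the lower average. It is monotone when the edited drug is already the
  maximal subset drug; the property test asserts exactly that.

## Essential-target search

Greedy forward selection with floating removal, objective = mean
leave-one-out absolute prediction error, where each held-out drug is
predicted from the remaining drugs' profiles projected onto the
candidate set. Strict improvement is required to grow the set (smaller
sets win ties) and candidate ties break to the lexicographically
smallest kinase symbol, so the search is fully deterministic; the `seed`
argument is recorded for provenance only. `max_size` defaults to 20,
the scale of the combination networks this kind of screen supports.
This is a documented deterministic approximation of sequential
forward-floating selection, not a reimplementation of any particular
legacy code.

The combination network partitions the selected kinases into nodes with
identical drug-binding patterns ("indistinguishable" targets merge);
nodes sharing a drug are adjacent. A drug pair is predicted effective if
deleting every node it hits disconnects the remainder (or empties it).
The source material specifies only this breakdown criterion, not a
layout algorithm; the shared-drug adjacency is our reconstruction and is
documented as such.

## Synergy scoring

- **Bliss.** Inhibition is converted to fractions; the expectation is
  independence, E = f₁ + f₂ − f₁f₂, and the score is the mean excess
  over the nonzero-dose subgrid, ×100. A literal product-form
  expectation (E = f₁f₂) is available behind `literal_product=True`
  because it appears in print in this literature, but applied to
  inhibition fractions it is not Bliss independence; both modes are
  regression-tested.
- **Margins.** Single-agent margins are smoothed by 4PL fits by default
  (`use_fitted_margins=False` for raw). A useful fact found while
  validating: because the 4PL family's L/U directions span constants,
  the least-squares fit preserves the margin mean at the data points,
  so the *mean* Bliss excess is nearly identical under fitted and raw
  margins (differences ~1e-7 on clean synthetic surfaces). The choice
  matters for per-cell landscapes and for noisy/non-monotone margins
  where the fit falls back to interpolation.
- **4PL fitting.** y = L + (U−L)/(1+(EC50/x)^s), bounds L ∈ [−20, 50],
  U ∈ [0, 150], s ∈ (0, 10], EC50 ∈ [min dose/10, max dose×10] — assay
  noise routinely exceeds [0, 100], so the asymptote bounds are
  deliberately loose. Initialization: asymptotes from the data range,
  EC50 from the log-linear midpoint crossing. Non-convergence or a flat
  response falls back to monotone interpolation of the raw margin with
  a logged warning.
- **HSA** = y_comb − max(y₁, y₂); used for siRNA/sgRNA experiments where
  single and double treatments share total reagent concentration.
- **siRNA multiplicative synergy** = mean over cross-drug target pairs
  of (y_ij − y_i·y_j) on fractions, ×100.
- Assay transforms: % expression = 100·0.5^(Cp₁−Cp₂)/0.5^(Cp₃−Cp₄);
  viability = CTG_day5/CTG_day1; cytotoxicity = CTX_day5/viability.

## Target-pair deconvolution

Potent targets (strict 10-fold rule) are filtered to expressed genes
(log2 expression ≥ 6; genes missing from the table count as
non-expressed, logged). For two combinations sharing a drug, the
cross-drug unordered distinct-gene pairs are classified: G1 unique to
combination A, G2 shared, G3 unique to combination B. Self-pairs (k, k)
are excluded — double-knockdown experiments test distinct gene pairs.

## Signaling simulation

**Reactions.** Activation A→B compiles to the source-consuming
conversion `A → B` with propensity k_p(B)·X_A (a catalytic variant
`A → A + B` is available behind a flag, as the consuming form is
biologically unusual); inhibition B⊣C to `B + C → ∅` with propensity
k_d(C)·X_B·X_C; every gene self-degrades at k_d(A)·X_A. Genes without
activating inputs receive a constant source at rate k_p (molecules/h) —
without it, root genes decay to zero and the network has no nontrivial
steady state; `compile_reactions(..., source_genes=None)` gives the bare
edge+degradation system.

**Growth and division.** Each cell carries a pGrowth species born at
rate pGrowth·(ln2/t_div)·f(TP53). The TP53 brake is the decreasing Hill
function f(x) = 1/(1+(x/Q)^β) with Q = 65 molecules and β = 7 — the
algebraic form is our minimal reading of "a Hill function regulating
growth-rate reduction" with f(Q) = 0.5; it is a modeling decision, not
an established fact. Division is instantaneous when pGrowth reaches
θ = 2·pGrowth₀ (pGrowth₀ = 100 at birth), which reproduces the
doubling-time behavior exactly when f = 1; every species including
pGrowth is split Binomial(n, ½) between daughters, conserving molecules
exactly. t_div defaults to 38 h (an MDA-MB-231-like doubling time; the
value is config, not data). Default horizon 250 h with viability = mean
cell count over the last 50 h; tests and the analysis scripts run at
150 h for speed (stated wherever used) — transients decay within ~15 h,
so the window is comfortably post-transient either way.

A note on absolute counts: a population started from one newborn cell
approaches the stationary age distribution with a prefactor < 1
(≈ ln 2·θ/E[pg] per cell), so counts at time t are ~0.72·2^(t/t_div)
while the asymptotic *rate* is exactly one doubling per t_div. Tests
therefore assert the rate, and viability ratios cancel the prefactor.

**Engine.** Exact Gillespie per cell with incremental propensity
updates and a periodic full recomputation to cancel float drift; one
`random.Random(seed)` stream drives event times/choices and a
numpy generator (seed+1) the binomial partitions, so runs are bitwise
reproducible. Divisions fire the instant the threshold is crossed,
pre-empting any simultaneous reaction. Beyond `population_cap` tracked
cells (default 2000), divisions keep one daughter at doubled
statistical weight — uniform random subsampling whose weighted cell
count is an unbiased population estimate; cap events are reported.

**Knockout vs knockdown.** Knockout removes every production reaction
of the gene (sources and incoming activations) and zeroes its initial
count; knockdown scales those rates by (1−eff), default eff = 0.8
(siRNA-like). Viability of a perturbation is mean perturbed cell count
over the window divided by the paired-seed control mean.

**ODE twin and calibration.** The same reaction set as deterministic
mass-action ODEs (growth excluded; it enters only through the analytic
factor), integrated with LSODA in chunks until the scaled derivative
norm < 1e-7, then polished by a root find. Rate calibration rescales
each gene's k_d by (X_ss/target)^0.8 (damped, clipped to [0.2, 5] per
iteration) until all steady states are within 5 % of their expression
targets, automating what is otherwise manual k_d/k_p ratio tuning;
non-convergence raises with the offending genes named. Because
inhibition is bimolecular, SSA long-run means differ from the ODE
steady state by covariance corrections; at the demo network's copy
numbers (30–60 molecules) the difference is ≲3 %, within the 10 %
verification band.

**Sensitivity.** Scaled sensitivities S(i,p) = (p/X_i)·∂X_i/∂p by
central differences (±1 %) at the steady state, warm-started from the
base solution; the report ranks parameters by mean |S| over genes.
Perturbed steady-state failures mark the parameter undefined (NaN)
rather than aborting the report.

## Synthetic data: the stated world

- **Screen** (default 41 drugs × 385 kinases, the scale of a kinome
  binding panel): each drug binds 1+Poisson(4) kinases with log-normal
  K_d (median 50 nM, σ_log = 1.2) and a heavy no-bind mass. Essential
  targets are planted among kinases bound by ≥ 3 drugs — a uniformly
  chosen kinase in a sparse 385-kinase panel is usually hit by no drug,
  leaving nothing to recover; an "essential target" of a drug screen is
  by construction one the panel interrogates. Sensitivity is the
  Boolean rule (OR by default) over planted-set coverage plus Gaussian
  noise (σ = 0.05 in the recovery experiments), clipped and rescaled to
  a DSS-like score. The generator forces at least one hitting and one
  missing drug so the screen is never degenerate.
- **Surfaces**: 8×8 grids (0 plus 7 log-spaced doses, 10–10000 nM),
  4PL margins, combination cells = Bliss expectation + planted excess
  + Gaussian noise (σ = 3 points in the noisy experiments).
- **Demo network**: AURKB⊣TP53, ZAK→MAP2K3→MAPK14⊣TP53,
  CSF1R→TGFB1→TP53, with unconnected PKN1/PARP1 bystanders; expression
  targets 30–60 molecules put control TP53 (30) well below Q = 65 and
  the production rates are derived in closed form so the targets are an
  exact ODE steady state. The motif is engineered so AURKB silencing
  de-represses TP53, AURKB+ZAK silencing removes both brakes (TP53 far
  past Q, growth collapses), and CSF1R silencing starves TP53 of
  production (full rescue) — it mirrors that qualitative mechanism
  without claiming any real network's topology.

What a green test does **not** establish: the synthetic screen has
independent binding events (no kinase-family correlation structure),
surfaces have additive uniform excess (no dose-dependent synergy), and
the demo network is a 9-gene DAG (no feedback loops); conclusions about
real data require the corresponding experimental tables.

## File formats

CSV is the canonical interchange format; every tabular reader accepts a
wide layout and a long/tidy fallback (`read_kd_matrix(..., dialect=
"long")` expects `drug,kinase,kd` columns), since published data
tables ship in both shapes — exporting any spreadsheet to
three-column CSV is the conversion path when a wide table's layout is
unknown. Kinase and gene identifiers are opaque, case-sensitive
strings: no symbol aliasing or mapping is ever applied, so upstream
tables must agree on nomenclature. Signed networks travel as
three-column SIF text (`source<TAB>sign<TAB>target`, sign `+`/`-`);
models and result summaries as JSON. `read(write(x)) == x` holds for
every typed product and is property-tested.

## Pipeline reproducibility

One config object carries every threshold (50-fold, 10-fold strict,
log2 ≥ 6, D > 1) and seed; the manifest records the config hash,
package version, and a SHA-256 per output. All generators and the SSA
are seed-deterministic, so re-running a config reproduces outputs byte
for byte.
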