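# Methods

## Problem setting

The package analyses genome-scale metabolic reconstructions of
secondary-metabolite producers under the standard constraint-based
assumptions: mass balance at pseudo-steady state (S·v = 0), reaction
flux bounds (lb ≤ v ≤ ub, mmol·gDW⁻¹·h⁻¹), and linear objectives.
Metabolite concentrations never appear explicitly; they exist only
through the steady-state constraint. Exchange reactions follow the
sign convention uptake < 0 < secretion; a `MediumSpec` therefore stores
positive uptake magnitudes and applying it sets each listed exchange's
lower bound to the negated magnitude, blocking uptake (lb = 0, ub
untouched) on every unlisted exchange when `closed_default` is set.

## Model representation and I/O

Reactions carry stoichiometry, bounds, a parsed GPR tree and two
derived flags: `is_exchange` (single-metabolite boundary reaction) and
`is_gap_fill` (empty GPR and not an exchange — the reaction exists for
network connectivity, not from gene evidence). When a file does not
state bounds, irreversible reactions default to (0, 1000) and
reversible to (−1000, 1000). SBML (Level 3 + fbc preferred, Level 2
fallbacks) is parsed and written through cobrapy's SBML layer and
converted to the package's own types; the native TSV dialect (a
reactions table with equation strings, plus an optional metabolites
table) is implemented directly and is the format of choice for
hand-written fixtures. Identifiers are taken verbatim; duplicates are
validation errors, never silently renamed.

## LP/MILP machinery

All optimizations run on HiGHS through scipy (`linprog` / `milp`), with
primal/dual feasibility tolerances of 1e−9 and a downstream zero-flux
threshold of 1e−6 mmol·gDW⁻¹·h⁻¹ (fluxes below it are "not carrying
flux"). Genome-scale LPs are massively degenerate, so any operation
that *reports a flux vector* (FSEOF profiles, iMAT-adjacent censuses)
uses the parsimonious representative: fluxes are split v = f − r with
f, r ≥ 0, the objective flux is pinned to its optimum within 1e−9
relative, and Σ(f + r) is minimized. This also drives
thermodynamically meaningless cycles to zero. Objective *values* from
plain FBA are unique regardless and are used as-is.

FVA imposes `objective ≥ fraction × optimum` literally, including
fraction 0 (a non-negativity restriction on the objective flux); the
Pareto sweep uses it only to find the clamped objective's span, where
biomass irreversibility makes the distinction immaterial.

iMAT follows the standard indicator formulation: per HIGH reaction two
binaries select forward (v ≥ ε) or reverse (v ≤ −ε) activation with
big-M coefficients taken from that reaction's own bounds; per LOW
reaction one binary forces v = 0; the MILP maximizes the count of
satisfied calls at zero relative MIP gap (integrality is decided by
HiGHS at its default 1e−6 tolerance). The activation threshold
defaults to ε = 0.001 mmol·gDW⁻¹·h⁻¹, configurable; raising ε can only
remove feasible activity patterns, so the optimal score is
non-increasing in ε (tested). When a measured growth rate of zero must
be imposed, callers may use a tiny placeholder (1e−10 h⁻¹) to keep a
maintenance-like flux pattern; with no HIGH/LOW calls at all the MILP
degenerates to a feasibility problem and the census is taken from the
parsimonious vector instead.

## Growth media

Minimal media open the named salt exchanges at a non-limiting 10
mmol·gDW⁻¹·h⁻¹ and one carbon source at its measured uptake; predicted
μ is the biomass FBA optimum, and predictions across media are compared
to measurements by Pearson product-moment correlation (two-sided p;
fewer than three media or zero variance is an error, not a NaN). Salt
ids missing from a model are skipped with a warning because id
conventions differ between reconstruction pipelines. The complex
(yeast-extract-like) medium opens a caller-supplied list of amino-acid
exchanges at a common small uptake (default 0.015 mmol·gDW⁻¹·h⁻¹),
clamps growth to its measured value and maximizes the product reaction.
Amino-acid exchange/transport reactions are assumed present in the
model; the helper does not create internal transporters.

## Pareto fronts

The clamped objective's feasible [min, max] is found first; `n_steps`
evenly spaced clamp values (endpoints included, default 20 — enough for
a smooth front at trivial cost) each fix lb = ub and the free objective
is maximized. Clamp values are feasible by convexity of the feasible
interval, but any numerically infeasible point is recorded with its
status rather than dropped. `n_steps = 2` returns exactly the two
single-objective extremes; the swapped-direction sweep is exposed via
the `direction` argument.

## FSEOF

The enforcement grid runs from the measured base rate to the
theoretical maximum v\*: step k clamps the product at
base + k·(v\* − base)/n for k = 1…n (n = 10 by default), so the grid
includes the endpoint v\* and excludes the baseline, which is recorded
separately as step 0. The product clamp is an equality (lb = ub).
Selection tests |v| against the baseline with the 1e−6 threshold and
requires all above-threshold fluxes in a profile to share one sign, so
a reversible reaction's written direction cannot affect the verdict
(tested by flipping). Filters: gap-fill, exchange, then multi-gene
(GPR containing AND or OR, or ≥ 2 genes); internal transporters with a
single gene are *not* excluded — only true exchange reactions fall
under the nutrient-import filter. Reported gene lists are the union
over surviving single-gene rules, so one gene backing several reactions
is counted once. The report ranks by mean Δ|v| per enforcement step,
ties broken lexicographically by reaction id.

## Expression integration

Quartile thresholds use linear-interpolation quantiles over every gene
present in the table (not only model genes), per time point. GPR
mapping is min over AND and max over OR; a gene absent from the table
is ignored inside OR and makes an AND (hence the reaction)
unclassifiable → MODERATE, as are empty-GPR reactions. Classification
is strict (> Q3 / < Q1).

## Synthetic data

`generate_toy_model` builds the study's structural situation in
miniature: one carbon exchange (default capacity 10 mmol·gDW⁻¹·h⁻¹), a
linear core chain (default 3 steps), a biomass branch draining two
precursor pools at 1/yield carbon per unit growth (default yield 0.1
gDW/mmol, so μ_max = 1.0 h⁻¹), and a product branch assembling three
precursors — analogs of the common, less common and rare extender
units of polyketide synthesis — the last supplied by a single-gene
reaction capped at 0.5 mmol·gDW⁻¹·h⁻¹ (binding, below the
carbon-limited ceiling of 10/3). Closed forms: μ_max = uptake × yield,
q_p,max = cap / s_planted. Decoys give every filter work: a
complex-encoded (AND) conversion and a paralog-encoded (OR) supply on
the product path, a gene-less transporter, and the product exchange.
`ToyModelSpec.random(seed)` jitters uptake (5–15), yield (0.05–0.2),
chain length (2–4) and the supply cap (10–80 % of the carbon ceiling)
while keeping the cap strictly binding. Generation is deterministic
per spec, so identical seeds give byte-identical files.

`generate_expression` plants a three-component log-normal RPKM table:
active genes at median 200, planted-low genes at median 0.5, and
moderate background genes at median 10 (the conventional detection
baseline) padding the table so the empirical Q1/Q3 fall between the
components. Two components alone would place Q3 inside the high
component and break quartile classification — the background tier is a
deliberate design choice, not noise. The default log-scale σ = 0.4
separates components cleanly (≈ 5 % tail overlap at the quartile
boundaries); σ = 0 recovers the planted classes exactly, and recovery
degrades monotonically in σ (tested over 20 seeds).

What the toys do *not* emulate: cofactor/energy coupling, biomass
composition detail, condition-dependent regulation, isotopic or kinetic
effects, and the sheer degeneracy of genome-scale networks. Passing
tests therefore certify the algorithms' correctness on networks whose
answers are provable, not the biological accuracy of any particular
reconstruction.

## Problem sizes and verification

The test suite and the acceptance script run entirely on these
synthetic instances: 20 random networks of ≤ 8 reactions for the
FBA-vs-vertex-enumeration check (the exhaustive oracle enumerates all
bound-assignment vertices), 20 random tiny instances with ≤ 6
classified reactions for the iMAT-vs-brute-force check (3^|HIGH|·2^|LOW|
patterns, LP feasibility each), 20-point Pareto sweeps, and 20 random
toy parameterisations for the FSEOF recovery sweep. cobrapy + GLPK
serves as an independent solver cross-check for FBA optima in the
tests; it is never the computation path. Genome-scale reconstructions
are consumed through the same API (`examples/genome_scale_pipeline.py`)
and are the intended production use.

## Known limitations

- No loopless/thermodynamic constraints, MOMA-style quadratic
  objectives, dynamic FBA, or knock-out search (the target scan
  proposes amplifications only).
- Gap-fill status is a heuristic (empty GPR ∧ not exchange) when the
  source file carries no explicit markup; spontaneous reactions will be
  mislabelled gap-fill.
- The FSEOF product clamp is enforced as an equality; enforcing it as a
  lower bound can admit slightly different profiles on degenerate
  networks.
- iMAT results depend on ε and on the quartile convention; both are
  parameters, and alternative choices are legitimate.
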