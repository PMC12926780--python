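# Methods

This note records the modeling choices behind fluxscape: what each
stage computes, the conventions and defaults it commits to, what the
synthetic fixtures do and do not emulate, and the known limitations.

## Model representation and I/O

Models are held as a minimal structure: metabolites with compartments,
reactions with bounds (mmol·gDW⁻¹·h⁻¹), GPR text, an optional pathway
string, a sparse stoichiometry map, and a linear objective. Reading
and writing of SBML (Level 3 + fbc), COBRA JSON, MATLAB structs, and
YAML is delegated to cobrapy; `.gz`, `.bz2` and `.zip` containers are
unpacked first and must hold exactly one model file. A reaction is
flagged as an **exchange** purely structurally — it touches exactly
one metabolite — independent of naming.

The flat tabular schema (one row per reaction: `reaction_id,
equation_string, lower_bound, upper_bound, gpr_text,
objective_coefficient, in_medium, pathway`) is a reconstruction: no
published column set exists for this kind of flat file, so the schema
was chosen to round-trip bounds, stoichiometry, GPR semantics and
objective exactly. Equation strings use `-->` for irreversible and
`<=>` for reversible reactions (reversible meaning a negative lower
bound), keep compartment suffixes (`A[c]`) inside metabolite ids, and
leave one side empty for exchanges. `in_medium` defaults to "exchange
with negative lower bound" when no medium table is supplied. SBML
round-trips drop the pathway string (cobrapy does not serialize
subsystems to SBML without the groups extension, which is out of
scope); JSON, MAT and tabular routes preserve it.

## Reaction Activity Scores

`or` → sum, `and` → minimum, evaluated recursively over the parsed
rule; `and` binds tighter than `or`, operators are case-insensitive.
Policy decisions where conventions genuinely diverge:

- **Missing genes** are dropped from sums and minima; a node is
  MISSING only when *all* its operands are missing, and a reaction
  with a MISSING score later keeps its original bounds. This is the
  least destructive reading and keeps partially covered datasets
  usable; the alternative (score 0, reaction closed) would zero out
  every reaction touched by an unmeasured gene.
- **Gene matching** is exact string equality after whitespace
  trimming. Identifier conversion (symbol ↔ Ensembl and the like)
  belongs upstream; silent aliasing here would be untraceable.
- **Duplicate gene rows** in the expression table are an error, not
  averaged — averaging would corrupt scores silently.
- **Repeated genes inside one rule** are evaluated independently
  (`g1 or g1` = 2·g1), mirroring the literal Boolean expression.

A coverage fraction (model genes found in the data) is attached to
every RAS matrix and logged; zero overlap is a hard error.

## Normalization and bounds

Normalization divides each reaction's scores by that reaction's
maximum across samples (per-reaction, not global: a global maximum
would make scores incomparable across reactions of different
magnitude). Outputs lie in [0, 1]; a row whose maximum is 0 becomes
MISSING by default (`zero_ras_closes=True` restores the harsher
all-zero reading, which closes the reaction everywhere and frequently
makes models infeasible).

Bound scaling multiplies both bounds by the same factor, so reversible
ranges shrink symmetrically and never change direction, and scaling
never widens a bound. Exchange reactions are exempt from RAS scaling
by default (the medium governs them; `scale_exchanges=True`
overrides). Medium application sets the exchange lower bound of each
listed metabolite to −rate and closes all other uptakes; unmatched
medium metabolites warn rather than fail. In the composed pipeline the
medium is applied first, then RAS scaling — the order only matters
when an exchange reaction carries a GPR and scaling of exchanges is
switched on; with the defaults the two orders commute (asserted on
fixtures).

## Linear programming

All LPs solve with scipy's HiGHS interface. The public contract is
`max|S·v| ≤ 1e-6` and bounds within 1e-6 for every optimal vector
(the solver itself works at ~1e-9; separating solver tolerance from
the API invariant keeps the contract stable if the backend changes).
Optimum-fraction constraints (pFBA, FVA) are applied as
`≥ (1 − 1e-9)·fraction·optimum` to absorb round-off; both default to
fraction 1.0. pFBA splits each flux into non-negative forward/reverse
parts whose bounds are chosen so the difference spans exactly
[lb, ub] even when zero lies outside the range. Degenerate FBA optima
are solver-dependent; tests assert objective values, not individual
fluxes of degenerate solutions (pFBA is used where uniqueness
matters). Infeasibility and unboundedness are reported as statuses,
never exceptions; knockouts that turn the model infeasible report
objective 0 with an `infeasible` flag.

## Sampling

**Corner-based sampling** draws a random objective per sample —
coefficients i.i.d. uniform on [−1, 1] by default, Gaussian available
— and records the optimal vertex. The cost distribution is a
parameter because no canonical choice exists; uniform signs and
magnitudes is the natural uninformative default. Each point carries a
vertex certificate: at least `n − rank(S)` active bound constraints
within 1e-6.

**Hit-and-run** is a single-chain artificial-centering walk: warmup
points are the 2n FVA-extreme solutions at fraction 0, directions are
(random stored point − running center) *projected onto ker(S)*, step
lengths are uniform on the feasible chord, and every `thinning`-th
point (default 100) is kept. The direction projection matters
numerically: round-off stored in past points is amplified when a
direction is normalized from a short difference and then scaled by a
long chord, and without the projection the walk drifts off the
steady-state subspace after a few thousand steps. The iterate is
additionally re-projected every 100 steps. Parallel-chain samplers
from the literature are deliberately not reproduced; this is a plain
single-chain ACHR under a neutral name.

Both samplers require a bounded polytope (checked by FVA at fraction
0) and refuse unbounded regions rather than clipping them — sampling
an unbounded set is ill-defined. Batching runs batch *i* with seed
`seed + i`; sizes differ by at most one.

## Group comparison

Defaults: two-sided Kolmogorov–Smirnov (exact for small samples via
scipy), p ≤ 0.05, fold-change threshold 1.2. The bounded statistic
`(avg1 − avg2)/(|avg1| + |avg2|)` is what is reported and what drives
arrow width; the significance gate interprets the threshold t as a
ratio criterion, `|avg1 − avg2| ≥ (t − 1)·min(|avg1|, |avg2|)`
("at least 20% difference" at t = 1.2), because the bounded statistic
itself lives in [−1, 1] where a 1.2 cut would be meaningless.
`fc_on_eq1=True` instead applies `|FC| ≥ (t−1)/(t+1)` directly.
Sign-discordant mean pairs that pass the p-test are always classified
as sign flips — a direction reversal of a reversible reaction is
qualitatively significant regardless of magnitude. The z-score is the
Welch two-sample z with n−1 variances (undefined when both variances
vanish). No multiple-testing correction is applied by default, keeping
the raw-threshold behavior; Benjamini–Hochberg is available
(`correction="bh"`). Two identical constant samples give p = 1 by
convention. 1-vs-All pools the other groups' samples rather than
averaging pairwise results.

## Map rendering

Arrows are located by element id through a template (default
`R_{reaction_id}`, the convention of Escher-exported SVGs) — how a
given hand-drawn map binds arrows to reactions varies, so the template
is configurable. Width is linear in |FC| over [width_min, width_max]
(defaults 2–12 SVG units); non-significant arrows get light grey at
minimum width. Magnitude maps rescale |mean| or |median| so the
largest value hits width_max (scale-invariant), under a two-color
sequential ramp. Styling only touches matched elements plus a legend
group that is replaced on re-runs, making the operation idempotent;
default colors are orange `#FFA500`, sky blue `#87CEEB`, red, blue,
grey `#BEBEBE`. Net-flux direction is not re-encoded in magnitude
maps: arrowhead conventions vary too much across hand-drawn maps for
a reliable generic rule.

## Synthetic fixtures and what passing tests show

The generators build linear chain/parallel-route models (shared
source and sink) and an independent-branch model (each branch: uptake
exchange → GPR-bearing capacity reaction → conversion → secretion),
all ≤ 20 reactions. Expression matrices use multiplicative lognormal
noise with unit mean and CV 0.2 (non-negative and realistic in shape
for expression data; the value is a package choice and configurable),
around `baseline_mean × planted factor`. The two-group study plants a
3× factor on one branch's genes in 25 samples per group; because
branches are independent and each branch's flux equals its capacity
reaction's normalized RAS times the uptake limit, the ground-truth
set of flux-shifted reactions follows symbolically from the GPR
structure (sum/min monotonicity), not from running the pipeline —
giving an oracle independent of the code under test.

These fixtures emulate the *structure* of real inputs (formats, GPR
shapes, group design, planted effect sizes) but not their hard parts:
no genome-scale degeneracy, no correlated genes, no dropout or batch
effects, no loops or futile cycles. Recovery of the planted effect at
100% precision/recall therefore validates the plumbing and the
statistics under clean separation, not performance on noisy
genome-scale data.

## Problem sizes and numerical defaults

Test and acceptance runs use toy LPs (3–16 reactions), 200 corner
samples, 2000 hit-and-run points on the 1-D fixture, 25 samples per
group, and 50 null runs for the type-I band — sizes chosen so the
whole suite re-runs in well under a minute while every statistical
check retains enough resolution (3-SE bands, binomial vertex-split
band, [0.01, 0.12] type-I band). Steady-state and bound tolerance is
1e-6 throughout the public API; vertex certificates and FVA
containment use the same tolerance.

## Known limitations

- Reaction-level knockouts only; no gene-level deletion logic.
- No loopless FVA, no thermodynamic constraints, no convergence
  diagnostics (R̂/ESS) for the sampler.
- MAT files are read but not written.
- SBML export loses pathway strings (see above).
- The exchange sign convention (uptake negative) is assumed, not
  detected.
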