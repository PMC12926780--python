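# fluxscape

Transcriptomics-constrained metabolic modeling for Python: integrate
gene-expression data into constraint-based (COBRA-style) metabolic
models, explore the constrained flux space by optimization and
sampling, compare flux distributions between sample groups, and paint
the differences onto an SVG metabolic map.

It is aimed at systems biologists who have a genome-scale or
core metabolic model, one expression profile per biological sample
(bulk or single-cell, any non-negative matrix), and want per-sample
flux estimates and a statistically gated picture of which reactions
differ between conditions — without writing solver code.

## The method

**Reaction Activity Scores (RAS).** Each reaction's gene–protein–
reaction (GPR) Boolean rule is evaluated quantitatively on an
expression profile: `or` becomes a **sum** (isoenzymes are redundant,
their capacities add) and `and` a **minimum** (a complex is limited by
its scarcest subunit). Genes missing from the data are dropped from
sums and minima; a rule whose genes are all missing yields a MISSING
score.

**Transcriptional bounds.** RAS values are normalized per reaction by
the maximum across samples, giving scores in [0, 1], and each score
multiplies both flux bounds of its reaction. A growth-medium table
(metabolite, maximal uptake rate) is applied first: the exchange
reaction of each listed metabolite gets lower bound −rate, every other
exchange is closed to uptake (uptake is negative flux).

**Flux simulation.** On each per-sample model `{v : S·v = 0, lb ≤ v ≤
ub}` the package runs FBA, parsimonious FBA (minimal total |v| at the
optimal objective), flux variability analysis, and single-reaction
knockouts — or samples the whole polytope with corner-based sampling
(optimal vertices of random linear objectives) or an
artificial-centering hit-and-run walk, with batching and summary
statistics.

**Enrichment and maps.** For two or more sample groups (all pairs, one
vs. pooled rest, or each vs. a control) every reaction gets a
two-sample test p-value (Kolmogorov–Smirnov by default), a bounded
fold change

```
FC = (avg1 − avg2) / (|avg1| + |avg2|)   ∈ [−1, 1]
```

a Welch z-score, and both group means. A reaction is highlighted only
if it passes both the p-value threshold (default 0.05) and the
fold-change threshold (default 1.2, i.e. at least a 20% difference
between means). Arrows on the map turn orange (up in group 1), sky
blue (down), or red/blue when the flux changes sign between groups;
width scales with |FC|.

## Worked example

```python
from fluxscape import make_twogroup_fixture
from fluxscape.workflow import sample_flux_frame, compare_flux_frame

fx = make_twogroup_fixture(seed=11, n_samples_per_group=25, effect=3.0)
frame = sample_flux_frame(fx["model"], fx["expression"], medium=fx["medium"])
label, table = compare_flux_frame(frame, fx["assignment"])[0]
print(label)
print(table.head(4).to_string(index=False))
```

prints

```
tumor_vs_normal
reaction_id  p_value  fold_change    z_score      avg1      avg2 style_class
      EX_S1 0.000011    -0.501827 -15.053766 -8.512155 -2.823581        down
         U1 0.000011     0.501827  15.053766  8.512155  2.823581          up
         C1 0.000011     0.501827  15.053766  8.512155  2.823581          up
      EX_P1 0.000011     0.501827  15.053766  8.512155  2.823581          up
```

The fixture plants a 3× expression increase on the genes of branch 1
in the `tumor` group; every reaction of that branch is recovered as
significant (the uptake exchange `EX_S1` shows as `down` because
uptake is negative flux), and all other reactions stay
`not_significant`. `style_comparison_map(fx["svg"], table)` then
returns the styled SVG.

The same workflow is available from the shell:

```
fluxscape fixtures --preset twogroup --seed 11 --out-dir fx
fluxscape ras --model fx/model.xml --expression fx/expression.tsv --out ras.tsv
fluxscape ras2bounds --model fx/model.xml --ras ras.tsv --medium fx/medium.tsv --out-dir bounds
fluxscape fluxsim --model fx/model.xml --bounds bounds --method pfba --out fluxes.tsv
fluxscape fluxenrich --fluxes fluxes_T.tsv --groups fx/groups.tsv --mode 1v1 --out-dir cmp
fluxscape fluxmap --svg fx/map.svg --table cmp/comparison_tumor_vs_normal.tsv --out styled.svg
```

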