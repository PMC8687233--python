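# Methods

## Statistical model

For each pathway the analysis combines two independent p-values.

**Over-representation, P_NDE.** The number of DEGs on a pathway is
compared to a hypergeometric null: `m` reference genes (operationalised
as the genes present on the loaded matrix, not the whole genome —
configurable in principle, but what was measured is what can be drawn),
`t` of them on the pathway, `h` DEGs overall, `r` on the pathway;
P_NDE = P(X ≥ r), computed as the survival function of
`scipy.stats.hypergeom` and clamped to [0, 1]. Only genes present in the
expression data count towards `t` and `r`; topology genes without
measurements stay in the graph (with ΔE = 0) but not in the counts.

**Perturbation, P_PERT.** Gene-level perturbation factors satisfy
PF = ΔE + M·PF with M[i,j] = β_ij·w_ij/N_ds(g_j) on each edge
g_j → g_i, solved as (I − M)·PF = ΔE by a direct dense solve. ΔE is the
Welch log fold-change for DEGs and 0 otherwise. The pathway statistic is
t_A = Σ(PF − ΔE). Systems with condition number above 1e12 are reported
as `skipped_singular` rather than regularised — regularisation would
silently change results, and the structurally singular case (every gene
has downstream targets, all activations, so M is column-stochastic) is a
property of the topology worth surfacing.

The null for t_A re-places `n_de` fold-changes, drawn without
replacement from the genome-wide DEG pool, on `n_de` uniformly chosen
measured pathway genes, and recomputes t_A per iteration. Because t_A is
linear in ΔE (t_A = vᵀΔE with v = ((I − M)⁻¹ − I)ᵀ·1), the whole null is
vectorised from one transpose solve; this is an exact reformulation, not
an approximation, and is verified in tests against full per-placement
solves. The two-tailed p-value centres the null at its median and uses
add-one smoothing, p = (#{|t_null − med| ≥ |t_obs − med|} + 1)/(N + 1),
so p ∈ (0, 1] and the downstream logarithm is always defined. Ties count
against the pathway (≥), the conservative direction.

*Centring choice.* The centre is the midpoint of the 45%–55% quantile
bracket of the sampled null rather than the plain sample median. For
continuous nulls the two coincide (to O(δ²) in the bracket half-width);
for discrete nulls whose population median falls exactly between two
atoms — tiny graphs with a near-constant DEG pool — the sample median of
an even-sized draw flips between the atoms with sampling parity, which
would make the p-value non-reproducible at the ±0.25 level. The bracket
midpoint is stable in both regimes.

**Combination and multiplicity.** P_G = c − c·ln c with
c = P_NDE·P_PERT is the exact CDF of a product of two independent
uniforms, so P_G is uniform under the joint null. Across pathways P_G is
Benjamini–Hochberg adjusted (`statsmodels.stats.multitest`); the default
significance call is FDR < 0.01.

## Edge weights

* `unit` (SPIA): w = 1 everywhere.
* `pearson` (PSPIA): sample correlation with an n−1 denominator,
  requiring ≥ 3 samples. The **signed** value is used by default, so a
  negative co-expression flips the effective edge sign via β·w; an
  `abs_weights` switch keeps β as the only sign carrier for users who
  prefer the topology's annotation to win.
* `mi` (MSPIA): plug-in mutual information of per-gene median-binarized
  profiles (≥ median → 1, "overexpressed"; ties → 1; the threshold is
  the only label-free, scale-free choice and is configurable to the
  mean). Log base 2 (bits) by default; the base only rescales all MI
  weights by a constant and is configurable. MI weights are not
  normalised to [0, 1] — MI and Pearson weights deliberately live on
  different scales.

Weights are computed on all samples pooled across conditions
(co-expression convention; maximises n; configurable to either group).
A gene missing from the data, or a zero-variance gene under `pearson`,
falls back to w = 1 — the edge keeps SPIA strength instead of being
silently deleted — and the event is counted in a report.

Forcing every weight to 1 in PSPIA/MSPIA reproduces SPIA bit-for-bit:
the weighting scheme enters only through M, and the bootstrap's random
stream does not depend on the weights.

## DEG calling

Two-sided Welch t-test per gene, test minus control log fold-change, raw
p < α (default 0.05). This is a declared simplification: moderated-t
(limma-style) shrinkage is a DEG front-end refinement orthogonal to the
pathway statistics. The degenerate zero-variance-in-both-groups case
gets p = 1 when means are equal and p = 0 when a noiseless shift is
present.

## Randomness and determinism

All stochastic steps derive from one run seed. Each pathway's bootstrap
uses `SeedSequence([seed, crc32(pathway_id)])`, so adding or removing a
pathway never changes another pathway's p_pert, and two identically
seeded runs write byte-identical result files.

## Synthetic study generator

`wspia.synthetic` emulates a normalised, log-scale two-group microarray
study at toy scale: per-gene Gaussian noise (sd `noise_sd`); disjoint
random pathway blocks; co-expression along edges induced by one latent
factor per connected pathway component, loaded at √ρ with per-gene signs
propagated through the topology (inhibition edges flip the sign), giving
edge-adjacent pairs correlation ≈ ±ρ; and an optional perturbed pathway
whose genes shift by `effect_size` in test samples with the same
coherent sign pattern, so the shift accumulates along the cascade the
propagation model is designed to detect. A `de_fraction` of background
genes shifts with random sign to populate the genome-wide DEG pool.

Pathway topologies default to feed-forward cascades (edges from earlier
to later genes of the block). This mirrors receptor → effector signal
flow and guarantees solvable systems: a dense cyclic digraph in which
every gene has a downstream target and all edges activate makes I − M
exactly singular, so unconstrained random digraphs would mostly produce
skipped pathways. `acyclic=False` restores full ordered-pair sampling
for exercising the singular path.

What the generator does **not** emulate: probe-level effects, batch
effects, heavy-tailed noise, hub-dominated scale-free topologies,
between-pathway gene sharing, or realistic fold-change distributions.
Passing tests therefore demonstrate correctness of the statistical
machinery under its own assumptions, not performance on real microarray
data.

## Calibration regime

The null-calibration check runs the full pipeline on no-signal datasets
with **independent** genes and 60-gene pathways on a 900-gene array, and
verifies the fraction of pathways at P_G < 0.05 against the binomial
99% interval. Two caveats define this regime. First, the hypergeometric
null assumes DEGs land on pathways independently; when genes within a
pathway are strongly co-expressed, false-positive DEGs arrive in
clusters and both P_NDE and P_PERT become anti-conservative (we measure
≈ 13% at nominal 5% with within-block correlation 0.3). This is a known
limitation of DEG-count-based pathway tests in general, inherited here,
and is why calibration is asserted under the model's own null. Second,
small pathways with few expected DEGs make the discrete hypergeometric
tail markedly conservative; the chosen sizes keep it near-continuous.

## Problem sizes

Defaults: 2000 bootstrap iterations (add-one smoothing floor 1/2001),
DEG α = 0.05, FDR threshold 0.01, MI base 2. The validation suite uses
20 fixtures for the reduction check, the full m ≤ 12 grid for the
hypergeometric oracle, 100 random DAGs (≤ 12 genes) for the solver
oracle, 2000 iterations for the bootstrap-vs-enumeration check, 10,000
pairs for the combination-law KS test, 240 pathway-replicates for null
calibration and 50 replicates per method for the detection check —
sizes at which the Monte-Carlo error of each check is far below its
assertion tolerance.

## Known limitations

* KGML relations are mapped by a fixed subtype table
  (activation/expression → +1, inhibition/repression → −1, everything
  else dropped and counted); compound-mediated and binding relations do
  not propagate. This is a deterministic, auditable subset of the richer
  relation-rewriting some R pathway toolkits perform.
* Gene identifiers are used verbatim; no symbol/Entrez conversion.
* The bootstrap null places DEGs uniformly on measured pathway genes;
  hub-aware placement nulls are out of scope.
* P_NDE and P_PERT are combined as if independent; both derive from the
  same DEG set, so P_G is approximate evidence pooling, as in the
  original formulation.
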