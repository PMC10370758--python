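# Methods

This note documents the models and procedures implemented in `helixcov`,
the parameter choices that matter, what the synthetic benchmark does and
does not show, and the numerical conventions.

## Helix decomposition

A consensus structure (WUSS string from `#=GC SS_cons`) is parsed into base
pairs per bracket layer; pseudoknot letter layers are independent stacks.
Helices are maximal runs of stacked pairs: consecutive pairs (i,j), (i′,j′)
belong to the same helix iff i′−i−1 ≤ 2, j−j′−1 ≤ 2 and
(i′−i−1)+(j−j′−1) ≤ 2. This admits a 1×1 internal loop (one unpaired residue
on each strand, often a non-canonical pair) or a 1–2 nt bulge, and splits at
anything larger — a 2×1 or 2×2 loop starts a new helix. Pairs from different
pseudoknot layers never share a helix, since stacking is within-layer by
construction. Decomposition partitions the pair set, and merging any two
adjacent output helices would violate the gap rule.

## Per-pair covariation p-values

**Statistic.** For columns i, j the G-test on the 4×4 joint residue counts,
G = 2 Σ O ln(O/E) with E from the marginal products; sequences with a gap or
N at either column are dropped pairwise. The average product correction
(APC), G′ᵢⱼ = Gᵢⱼ − ḡᵢḡⱼ/ḡ, is applied by default; it absorbs the shared
phylogenetic background and is required for calibrated p-values (disabling
it measurably distorts the null match between data and simulated scores).

**Null.** The null hypothesis is covariation due to shared evolutionary
history alone. It is realised by re-evolving every column independently down
the working tree: a root residue is drawn from the alignment-wide
composition, and exactly the column's Fitch substitution count worth of
forced change events is placed on branches with probability proportional to
branch length. Gap positions are copied from the input. Two design points
deserve emphasis, both found empirically during development and verified by
two-sample tests of null versus decoy score distributions:

* *Alignment-wide, not per-column, stationary composition.* Conditioning
  each null column on its own observed composition shrinks the score
  dispersion across pairs and miscalibrates the pooled p-values; one shared
  composition with per-column variation matched through the Fitch count is
  calibrated.
* *Exact event counts, not rates.* Matching only the expected number of
  substitutions gives the null Poisson dispersion in per-column variation
  and far too many invariant columns; placing exactly the observed count
  makes null columns variation-matched to their data columns.

**Empirical p-values.** Scores from all column pairs of `n_null` simulated
null alignments (default 20; roughly 50,000–65,000 pooled scores for an
80-column alignment) form the reference distribution. The p-value is
empirical with a pseudocount, p = (k+1)/(M+1), floored at 1/(M+1), with an
exponential tail (maximum-likelihood fit to the top 5%) for scores beyond
the sampled maximum. Because G is discrete on small alignments — every pair
touching an invariant column scores in one atom — the pipeline breaks ties
randomly (randomized probability integral transform,
p = (k_> + U·(k_= + 1))/(M+1), seeded), which is exactly Uniform(0,1) under
the null; the deterministic conservative form remains available and is
exactly monotone in the score.

## Working tree and Lancaster weights

A neighbor-joining tree on Jukes-Cantor distances (gaps excluded pairwise;
saturated distances capped at 3.0 substitutions/site with a warning;
negative NJ branches clamped to 0; midpoint-rooted; multifurcations resolved
with zero-length edges) serves two purposes: branch lengths for the null
simulation and Fitch small-parsimony substitution counts. The Lancaster
weight of a pair is the sum of its two per-column Fitch counts — the
per-position reading of "substitutions for the pair"; joint 16-state
parsimony is used only as an oracle bound in tests. Gap/N leaves carry the
full state set and never force substitutions. Only integer counts are
consumed downstream, which is why no likelihood-based tree inference is
attempted; any reasonable tree gives near-identical parsimony counts.

## Covariation power

power(s) is the probability that a truly covarying pair with s observed
substitutions reaches pair E-value < 0.05. It is self-calibrated: simulate
structure-constrained alignments (default 30), run the standard pipeline,
bin the detection indicator by substitution count (bins widened below 50
pairs), fit isotonic regression, and anchor power(0) = 0 — a pair with no
variation can never be detected. Lookups interpolate linearly and clamp at
the calibrated plateau. The weighted-Fisher weights are the powers
normalised to Σw = 2N, making equal powers reduce to Fisher exactly.

## Aggregation conventions

* The Lancaster/weighted-Fisher transform evaluates the inverse CDF at
  1 − pₙ (equivalently the inverse survival function at pₙ), so that small
  p-values map to large statistic contributions and all-weights-2 recovers
  Fisher exactly.
* Pairs with weight 0 (no substitutions, or zero power) contribute neither
  to the statistic nor to the degrees of freedom; a helix whose weights are
  all zero is uninformative and aggregates to p = 1 with a warning.
* Survival functions are evaluated by scipy in the deep tail; aggregated
  p-values are floored at 1e-300. Šidák uses log1p/expm1 for stability and
  equals N·p_min in the small-p limit.
* Helix E-value = aggregated p × number of helices in the (gap-filtered)
  proposed structure; pair E-value = p × size of its hypothesis set (the
  proposed pairs and the remaining tested pairs separately under `two_set`,
  all tested pairs under `one_set`). E-values carry expected-count semantics
  and are not capped at 1. Significance is E < 0.05 throughout.
* Defaults: Lancaster, two-set, 70% gap-column filter, seed 42.

## Synthetic benchmark

The generator emulates the covariation signal of structural RNA families
without indels. A coalescent-shaped random tree with Exp(mean = scale)
branch lengths is shared by a positive/decoy duo. Unpaired sites resample
from their stationary distribution with probability 1 − e^(−t) per branch;
paired site-duos in positives jointly resample one of the six canonical pair
types (AU, UA, CG, GC at 0.225; GU, UG at 0.05) with probability
1 − e^(−λt), the compensatory double substitution that creates covariation
at paired columns only. Decoys run the identical process with every site
unpaired but keep the transferred structure annotation, so decoy helices
exist for false-positive accounting. Default structures are four sequential
hairpins of 4–8 pairs (4 nt loops, 3 nt spacers), sized like typical Rfam
helices.

Default conditions: 20 sequences, λ = 1, branch scale 0.1. The scale was
chosen to reproduce the pairwise-identity statistics of curated
structural-RNA benchmarks (45–90%, median 60–70%): measured on the
generator, scale 0.1 gives mean identity ≈ 0.64 (0.57–0.75 across
replicates). The sensitivity/dominance benchmark instead runs at scale 0.5
(≈ 32% identity, a deliberately hard, deeply diverged regime) with λ = 1,
200 positives and 200 decoys.

What passing tests show: on data generated by this model, per-pair and
helix-level p-values are uniform on decoys, helix E-values have
expected-count calibration at E ≤ 0.05, same-helix decoy p-values are
uncorrelated, and Lancaster aggregation detects at least as many true
helices as the at-least-one-significant-pair baseline. What they do not
show: behaviour under indels and alignment error, non-stationary or
lineage-specific composition, base-pair types outside the six canonical
ones, or R-scape's exact null and statistic family — real-alignment
results (and the published benchmark's absolute sensitivities) depend on
those.

## Known limitations

* No sequence weighting: highly redundant alignments overweight clades in
  both the G statistic and the Fitch counts.
* NJ/JC trees degrade below ~40% identity (distance saturation); the null
  remains approximately calibrated there but Šidák, the most
  tail-sensitive method, drifts first.
* The power curve is self-calibrated on the simulator and transfers to real
  alignments only to the extent the simulator matches them.
* The one-set/two-set distinction here changes only the multiple-testing
  correction scope, not the per-pair p-values themselves.
* External per-pair tables are trusted as-is (p = 0 is rejected at ingest;
  producers should floor at their empirical resolution).
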