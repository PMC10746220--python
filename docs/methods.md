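# Methods

This note documents the models and procedures eukmag implements, the
defaults and why they were chosen, what the synthetic fixtures emulate,
and the numerical/design decisions taken where the underlying
conventions were genuinely open.

## Bin screening and quality tiers

A candidate bin passes the eukaryote screen when `total_length >
2,500,000` bp **and** `euk_length / total_length > 0.90`, where
`euk_length` sums the lengths of contigs domain-called eukaryotic by an
upstream k-mer classifier. Both comparisons are strict: the thresholds
are written as ">2.5 Mbp" and ">90%" in the conventions this package
follows, and boundary bins are measure-zero in practice. Contigs called
`unknown` count toward the denominator (total length) but never toward
eukaryotic length — an unclassified contig is not evidence of
eukaryotic origin.

Eukaryote tiers by BUSCO completeness: >30% highly complete (`EUK_HIGH`),
>10% reported (`EUK_REPORTED`), otherwise candidate. Prokaryote tiers by
completeness c and contamination t: HQ iff c > 90 and t < 5; MQ iff
c ≥ 75 and t < 10; else discard. The MQ band is closed at 75 and open at
90, so a bin at exactly c = 90, t < 5 is MQ: it fails the strict HQ test
but sits inside the medium band.

## ANI dereplication

Genomes are clustered by single linkage on the predicate ANI ≥ 99
(connected components of the thresholded similarity graph). The toolkit
consumes a precomputed symmetric ANI matrix; it does not compute
alignment-based ANI, so the two-step sketch-then-align procedure used
upstream collapses to one input here. Cluster representatives maximize

    S = completeness − 5·contamination + 0.5·log10(N50),

a reduced form of the dRep scoring equation: the strain-heterogeneity
and genome-size terms are dropped because their inputs are out of scope.
Ties break by larger total length, then lexicographic bin id, which
together with canonical cluster ordering makes the output invariant to
input order.

## Taxonomy rules

Percent-identity level cutoffs assign the deepest level whose lower
bound is strictly exceeded: species >95, genus (80, 95], family
(65, 80], order (50, 65], class (30, 50], none at ≤30. The printed
ranges share endpoints; assigning shared boundaries to the shallower
level is the deterministic reading (a hit at exactly 80% identity is
family-level evidence, not genus).

Taxonomy-report descent follows, at each node, the child with the
greatest cumulative mapping percentage while that percentage strictly
exceeds 8%, stopping at a strain-rank node or when no child qualifies.
This "deepest node still above threshold" reading respects the monotone
structure of cumulative report trees; the alternative
("first node exceeding 8%") is available via `first_exceeding=True`.

## Gene-model merging

Correspondence between two exons is defined as same-strand coordinate
overlap of ≥1 bp (configurable via `min_overlap`); the source
convention never defines it, and 1-bp overlap is the weakest defensible
reading. Exon-count agreement is min(|ab|, |ev|) / max(|ab|, |ev|) —
symmetric and dimensionless. At agreement ≥ 0.70 interior ab initio
exons lacking a correspondent are deleted; the original first and last
ab initio exons are always kept (protection applies to the pre-deletion
terminals). Evidence-only exons are added in both branches — the
additive step is not conditioned on the agreement test in our reading —
unless `strict=True`. Post-merge overlapping intervals are unioned, and
a union touched by any evidence exon keeps evidence provenance, since
evidence exons are alignment-backed. Merging is idempotent: re-merging
a merged locus against its own exons is the identity.

## Abundance

RPKM(i, s) = X(i, s) / (l(i) · N(s)) with l in kilobases and N in
millions of reads; the CLI converts bp → kb and reads → millions at the
boundary. CPM rescales each RPKM column to sum to 10⁶ (the scale factor
follows the "counts per million" construction; the constant itself is
the standard one). Samples with zero total RPKM return all-zero columns
with a logged warning rather than an error: deep-water samples that
recruit almost no reads are routine and must not crash a pipeline run.

## Trophic model

**Reference filter.** Profiles with fewer than 500 present KOs are
removed ("fewer than" is literal: exactly 500 is kept). Removing every
profile is an error.

**vita selection.** Per KO, a cross-validated permutation importance:
samples split into two stratified folds; a 500-tree forest grown on
each fold is evaluated per tree on the other fold, permuting each
feature the tree actually splits on and recording the accuracy drop;
drops average over all trees and both fold directions. Under the null,
hold-out importances are symmetric about zero, so the non-positive
importances mirrored to the positive side form an empirical null; a KO
is selected when its upper-tail empirical p (add-one smoothed) is below
0.05. The p-threshold is not fixed by the source conventions; 0.05
matches the cited selection package's default behaviour. The procedure
is deterministic for a fixed seed. Perfectly separating features are
always selected; constant features have importance exactly 0 and never
are; pure-noise features are selected at roughly the nominal rate.

**Classifier.** A Random Forest (500 trees, √p candidate features per
split) on the selected KOs with a class-stratified 75/25 split;
held-out accuracy is reported. `tune_max_features=True` runs a coarse
out-of-bag grid over {√p/2, √p, 2√p} in place of a full hyperparameter
search. Mixotroph predictions are allowed even when rare: the model
keeps all three labels.

**Scores.** For each selected KO and mode, a = (mode references
containing the KO) / (mode references), transformed by g(a) = a if
a > 0.5, else −(0.5 − a). A KO typical of a mode scores up to 1; a KO
typically absent scores down to −0.5, so absence is informative without
outweighing presence. An evaluated entity sums s_k·g(a) over **all**
selected KOs with s_k = ±1 by presence. Summing over all selected KOs
(not only present ones) is the only reading under which the worked
contribution of an absent KO at a = 0.1, namely −1 × −(0.5 − 0.1) =
+0.4, is coherent; it also yields exact antisymmetry
H(complement) = −H. KOs present in an entity but absent from the score
table (never seen in any reference) are dropped with a warning.

**Heterotrophy index.**

    H_ind = H − P          if M − max(H, P) < 50
    H_ind = (H − P) / M    otherwise

The typeset source of this composite is corrupted; sign(H−P)·√((H−P)²)
= H − P is the reading that reproduces the documented −300…300 scale
and sign convention (negative = phototroph-like). The quadratic
alternative sign(H−P)·(H−P)² is available via `quadratic=True`. In
branch 2, M ≥ max(H, P) + 50 > 0, so the division is safe; |H_ind| is
non-increasing in M there, damping the index when mixotrophy signal
dominates. The descriptive bands (phototroph-like / intermediate /
heterotroph-like at ±50) are for reporting only and never override the
forest classification.

## Co-occurrence network

Spearman rho and two-sided p for every unordered MAG pair, midrank tie
handling, pairwise NaN dropping, pairs with fewer than 3 shared samples
marked missing. The filter cascade, in order:

1. p < 1 − (1 − α)^(1/n), the Šidák correction with α = 0.05 and n =
   the number of *measured unordered pairs* (whether n counts ordered or
   unordered comparisons is unstated upstream; unordered is the set
   actually tested);
2. |rho| at or above the 90th percentile — the quantile is computed over
   the **full** measured |rho| distribution, then applied to the
   survivors of stage 1. Computing it on survivors only would make the
   stage a fixed-rank cut that always discards ~90% of whatever
   survives, regardless of structure; the full-distribution reading is
   the one under which a planted correlated block survives intact.
   On small fixtures the stage can be disabled (`percentile=None`): a
   rank-based cut is meaningful for networks with millions of pairs,
   not dozens;
3. |rho| > 0.70 (strict, per the final-network convention);
4. prokaryote–prokaryote pairs dropped, keeping eukaryote-involved
   associations (`keep_prok_prok=True` disables).

Negative correlations are retained through all stages (the filters act
on |rho|) and weight community detection by |rho|; a compositional CPM
matrix anti-correlates unrelated groups, and discarding that signal is
a separate scientific decision (`--positive-only` analyses can subset
the edge table first).

MAG pairs with ANI ≥ 99 **and** rho > 0.70 merge into cluster nodes
(connected components of that relation), intra-cluster edges are
removed, and parallel inter-node edges keep the maximum |rho| — the
strongest detected association, a choice this package makes since the
upstream convention is silent.

Communities come from igraph's multilevel (Louvain-style) modularity
maximization, seeded and with a seed-derived vertex shuffle, so results
are reproducible. Connectedness:

    C_x,x = (edges within x) / (n_x (n_x − 1) / 2)
    C_x,y = |{members of x ∪ y with ≥1 cross edge}| / max(n_x, n_y)

The within-community denominator is the complete-graph edge count
n_x(n_x−1)/2 (the printed form elsewhere mixes x and y subscripts in a
purely-x quantity; "total possible" fixes the reading). The
between-community numerator counts distinct members — a MAG counts the
first time it links to the other community — per the prose definition;
a raw edge-count mode (`between_mode="edge_count"`) preserves the
alternative. Diagonal entries lie in [0, 1]; off-diagonal entries can
exceed 1 when both communities are densely cross-linked, since members
of both sides count against the larger size only. Singleton communities
define C_x,x = 0 with a warning.

Community-environment association: Spearman of per-community summed CPM
against each environmental variable, p multiplied by the number of
comparisons (Bonferroni) and capped at 1, significance flagged at
adjusted p < 0.01.

## Phylogenetic diversity and gain

PD(S) sums the lengths of edges with leaves of S on both sides — exactly
the minimal spanning subtree of S on the unrooted edge set. The root
edge is excluded, so PD is invariant to where the input tree is rooted
(verified by re-rooting tests). Sets with fewer than two leaves span no
edges. Gain(focal | base) = PD(focal ∪ base) − PD(base), with focal and
base disjoint; additivity PD(base) + gain = PD(union) holds exactly.
Percentages: diversity relative to total tree length, gain relative to
the combined-set PD; since the appropriate denominator is
context-dependent, absolute branch-length units are always reported
alongside.

## Synthetic fixtures

The generators produce inputs with the statistical structure each stage
assumes — not simulations of any real survey.

* **Trophic panel** (default 300 references per mode, 2,000 KOs, 300
  mode-informative at occurrence 0.9 in-mode / 0.1 out-of-mode,
  background occurrence 0.5): Bernoulli presence per (reference, KO).
  It emulates the shape of a curated reference-transcriptome panel at
  roughly one-tenth the KO universe. Real panels have correlated KO
  blocks (pathways), class imbalance, and annotation noise that the
  independence assumption ignores; passing recovery tests shows the
  selection/classification machinery works, not that any particular
  accuracy transfers to real transcriptomes.
* **Abundance matrix** (default 60 samples, two planted communities of
  8 MAGs sharing a lognormal latent with sd 1.0 plus member noise
  sd 0.2 in log space, 4 independent background MAGs, one
  environment covariate linked to community 0 plus one pure-noise
  covariate): columns renormalized to 10⁶ so the output is a valid CPM
  matrix. Lognormal latents reflect the heavy-tailed positive skew of
  metagenomic abundances. The closure (renormalization) realistically
  couples the two communities negatively; with only ~20 MAGs this
  compositional effect is far stronger than in a survey with thousands,
  which the tests account for by comparing within- versus
  between-community correlation rather than asserting near-zero
  between-community rho.
* **Toy bins**: random-sequence contigs assembled into bins whose sizes
  and eukaryotic fractions straddle the screening thresholds, including
  exact-boundary bins (one at the length threshold, one at the
  fraction threshold). The thresholds are parameters so tests can run
  at kilobase scale; defaults remain the field values.

All generators are seed-deterministic, and fixture sizes keep the full
test suite within a few minutes on one CPU; the acceptance-style checks
run the trophic recovery at the full default panel (900 references ×
2,000 KOs) and the network recovery across ten seeds.

## Determinism

Every stochastic step (panel generation, fold splitting, permutation,
forest growth, Louvain) flows from an explicit integer seed;
`run_all` writes a provenance manifest (version, seed, thresholds,
per-stage record counts) and two runs with the same config produce
byte-identical outputs.

## Known limitations

* The toolkit consumes upstream outputs; it never validates that, e.g.,
  domain calls or ANI values were computed consistently with each other.
* The dRep-style representative score omits strain heterogeneity and
  size terms; coefficients are arguments if different weights are
  wanted.
* vita p-values are empirical against a finite mirrored null; with very
  few features the null is coarse and selection conservative.
* Between-community connectedness is not bounded by 1 under the
  distinct-member rule (see above); compare values only within one
  counting mode.
* The percentile edge filter is rank-based and should be disabled on
  small networks.
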