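# Methods

## Distance model

Three pairwise distances between gene-sets are implemented. Meet/Min is the
overlap coefficient distance, `1 − |A∩B| / min(|A|,|B|)`: it looks only at
the smaller set, so a set nested in an arbitrarily large superset is at
distance zero. Cohen's kappa treats the two sets as binary membership
indicators over the gene universe and measures chance-corrected agreement,
`1 − (O−E)/(1−E)`; because co-absences enter O and E, the value grows with
the size gap between the sets even under perfect nesting, and slightly
exceeds 1 for below-chance agreement (disjoint sets in a large universe).
Kappa is deliberately left unclamped so that below-chance agreement remains
visible.

The PPI-weighted Meet/Min distance discounts Meet/Min by the normalised
interaction strength between a set's exclusive genes and the other set. Each
gene `x ∈ A−B` contributes the score sum to `B`, normalised so that a gene
fully connected to all of `B` at the maximum network score counts as exactly
one additional overlapping gene. Interactions into the shared region `A∩B`
are down-weighted by `w = min(|A|,|B|)/(|A|+|B|)` — the probability that the
shared endpoint "belongs" to the opposite set — which also caps the influence
of hub genes. The symmetric distance is the minimum over the two directions.
Because the subtraction can push the value below zero when `|A−B|` is large
and edges dense, the final value is clamped to `[0,1]` by default; the raw
value is available with `DistanceSpec(clamp=False)` and through
`distance_trace`, which also exposes `w` and the kappa agreement rates.

Normalisation uses `max(P)`, the largest edge score in the loaded network
(1.0 for unit-normalised inputs); a `max_score_override` exists for
pre-normalised networks where the realised maximum may fall short of the
nominal scale. Consequences: scaling all edge scores by a constant leaves
pMM unchanged, and raising a single cross edge (without changing the
maximum) can only decrease the distance. Genes absent from the network
score zero everywhere; identifiers are opaque, whitespace-trimmed,
case-sensitive strings.

## Fuzzy clustering

Clustering follows the seed-and-merge fuzzy heuristic popularised by
functional-annotation tools: every gene-set's closed neighbourhood under the
cutoff (`d ≤ cutoff`, ties included) is a candidate seed; seeds with fewer
than `min_seed_size = 2` neighbours are dropped; any two groups sharing at
least `merge_fraction = 0.5` of the smaller group's members merge, iterated
to a fixed point, merging the lexicographically first qualifying pair each
round so results are deterministic and independent of input order. Gene-sets
may appear in several clusters; sets in no surviving group are reported as
isolated. All four knobs (cutoff, neighbour minimum, merge fraction, tie
handling through the cutoff) are exposed.

A stricter seed rule requiring a majority of intra-seed pairs to pass the
cutoff was evaluated and rejected: it prevents a large superset whose
subsets are mutually distant from seeding a cluster, destroying the intended
nested-set behaviour (Case 3 below).

`classify_trial` labels a clustering against two known subgroups: MERGED if
one cluster holds both subgroups entirely; SEPARATED if each subgroup lies
wholly inside a cluster and no cluster mixes them; IMPERFECT otherwise
(mixed-but-incomplete clusters, split subgroups, or unclustered members).
The three labels are exhaustive and mutually exclusive by construction.

## Percentile-matched cutoffs

Distance measures live on different scales, so a fixed cutoff is not
comparable across them. The cutoff's quantile in the reference measure's
off-diagonal distance distribution is mapped to the same quantile of each
other measure, using the type-1 (inverse-ECDF) convention so matched cutoffs
are realised distances; the resulting gene-set networks then have identical
edge counts up to rank ties. This underlies all cross-measure comparisons.

## Synthetic benchmark generator

The generator scripts three scenarios over a fixed 10,000-gene universe.

**Cases 1 and 2.** Two gene pools of 60 genes share 20. Each of two
subgroups samples five sets (sizes uniform on 15–40) from its pool. Set *i*
of each subgroup forms a counterpart pair whose overlap fraction — relative
to the smaller set — is drawn uniformly on [0.45, 0.50] (Case 1) or
[0.40, 0.45] (Case 2) and realised as the nearest integer count of genes
taken from the shared 20; remainders come from the pool's exclusive 40
genes, so realised overlaps are exact up to integer rounding. The fraction
is drawn continuously rather than picking a uniform integer count because
the integer-feasible grid would concentrate mass on the boundary fraction
1/2 in a strongly size-dependent way. PPIs are assigned to 40 % of the
eligible gene pairs: within each pool (Case 1) or between the two pools'
exclusive parts (Case 2) — pairs touching a shared gene are not
unambiguously "across" and are left out of the Case-2 population. Edge
scores default to an exponential truncated to [0.15, 0.99] with mean 0.275,
i.e. an average of 0.11 over all eligible pairs at 40 % density — a model of
curated functional-association scores, which pile up just above the
confidence floor; `ppi_score_mean=None` switches to a uniform draw and
`score_sampler` accepts an empirical distribution (e.g. resampled STRING
scores).

**Case 3.** A 200-gene superset contains a 50-gene pool from which five
small sets (10–15 genes) are drawn, guaranteeing nesting and likely mutual
overlap.

`run_trials` regenerates the instance each trial, computes the Meet/Min
matrix, translates the 0.5 cutoff to the other measures by percentile
matching *within that trial*, clusters, and classifies. A single seeded
generator drives all sampling, so runs are bit-reproducible from the
configuration seed.

What the generator emulates — and does not: it reproduces the overlap and
network geometry of functionally coherent pathway groups, but real GSA
collections have heavy-tailed set sizes, hierarchical nesting, annotation
noise and identifier mismatches, none of which appear here. Passing the
simulation tests therefore validates the distance/clustering machinery
under controlled geometry, not end-to-end performance on real collections.

## Numerical and design choices

* Kappa's universe defaults to the union of member genes and is overridable
  (`universe_size`, CLI `--universe-size`); the simulations fix it at 10,000.
* Degenerate inputs raise typed errors: empty gene-sets, a universe smaller
  than a union, kappa with expected agreement 1. An edge-free network is not
  an error — pMM then equals MM.
* Duplicate edge rows keep the maximum score; self-edges are dropped with a
  warning; STRING-style 0–1000 scores are rescaled by 1000 on request.
* The subgroup trials use 500 trials and the nested-set scenario 50 seeded
  trials — large enough that binomial error is a few percent while the whole
  suite runs in seconds.

## Known limitations

* The merge/separation frequencies of Cases 1–2 are sensitive to generator
  conventions that the scenario description underdetermines (integer
  realisation of overlap fractions, the eligible-pair populations, the edge
  score distribution). The package fixes one documented convention each;
  alternative conventions shift the MM merge/separation rates by tens of
  percentage points while leaving the qualitative contrasts intact.
* In the nested-set scenario, kappa's exclusion of the superset is
  structurally near-certain but not logically guaranteed: in rare draws
  (~2 % of trials) several strong small-set overlaps push the
  percentile-matched kappa cutoff above the closest superset pair and the
  superset acquires an edge.
* The fuzzy heuristic is order-canonicalised but remains a heuristic; no
  optimality is claimed, and very dense distance matrices can merge into a
  single large cluster.
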