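# Methods

## The classification problem

Human mtDNA is haploid, maternally inherited, and non-recombining, so its
variation forms a single genealogy. A *haplogroup* is a clade on that
genealogy defined by the variants accumulated along the branch leading to
it. Full-sequence classifiers resolve haplogroups to fine sub-clades but
need sequence data; when only a small genotyping panel is affordable, the
attainable resolution is the set of broad branches the panel can
distinguish. `mitoclass` classifies samples into 46 common African,
European, and Native American/Asian haplogroups from a 63-SNP panel on
rCRS coordinates, reading standard PED/MAP files.

## The reduced tree and panel

The knowledge base is a single JSON document: a `panel` array (one record
per SNP: name, 1-based rCRS position, ancestral and derived allele, QC
blacklist flag) and a `nodes` array in definition order, parents before
children. Each node carries the extra (position, allele) genotypes its
haplogroup requires beyond its parent. Alleles are phased to the *tree
root* (the mtDNA most-recent common ancestor), not to the rCRS: the rCRS
itself belongs to haplogroup H, so on the root→H path the reference
carries the derived state. A fully ancestral genotype vector classifies
to nothing below the root, and the rCRS-like vector classifies to H.

The packaged default tree has 46 non-root haplogroup nodes (the root MRCA
is not counted) spanning the L0–L3 African lineages, the M/N/R
macrohaplogroups, the major European branches (HV/H/V, JT/J/T, U/U5/K, I,
W, X), and Native American/Asian branches (A/A2, B/B2, C/C1, D/D1/D4, E,
F, G, M7, M8, Z, X2a, Y). Each of the 61 usable panel SNPs backs exactly
one node requirement (single-occurrence SNPs are maximally informative);
the two blacklisted markers (MT16189, hypervariable-region assay failure;
MT9540, NumtS cross-amplification) back none and are stripped from every
analysis regardless of their observed call rate. Lineage tags
(African / European / NativeAmerican_Asian / Macro) per node drive the
ancestry-level frequency aggregation. The node count is declared in the
config (`haplogroup_count`) and validated at load, so a curated variant
tree with a different count remains loadable by changing one field.

The per-node alleles follow standard Phylotree-style defining positions
(e.g. 10400C→T for M, 8701G→A for N, 12705T→C for R, 12308A→G for U,
11251A→G plus 15452C→A for JT, 14766T→C for HV, 1736A→G for A, 4883C→T
for D, 3552T→A for C, 10115T→C for L2); the composition is curated for
this package to be internally consistent and to keep sibling requirement
sets disjoint, which the loader lints.

## Reversions and the classification algorithm

Some branches restore an ancestral state: position 10398 mutates to A on
the branch to N and reverts to the ancestral G independently on the J and
K branches. Reversions are encoded as ordinary requirements that
contradict an ancestor's requirement, with *descendant-override*
semantics when requirements are accumulated along a root-to-node path.

Classification is a depth-first descent from the root carrying an
effective requirement map:

1. At each node, merge the node's own requirements into the inherited
   map (overriding on position collisions).
2. If the sample matches the whole map, the node enters the accumulator.
   A missing call never matches — missingness is not evidence, so
   samples missing key SNPs high in the tree come out unclassified
   rather than misassigned.
3. Descend into a child only if every currently unmet position is
   re-required somewhere in that child's subtree. An ordinary mismatch
   therefore prunes the subtree immediately, while a reversion branch
   stays reachable.

After the walk, accumulated haplogroups are ranked by distance from the
root (longer path → more SNPs checked → more specific) and only the
deepest survive; root-only accumulators map to `unclassified`. The
pruning rule makes the descent provably equivalent to the brute-force
alternative — evaluate every node's cumulative (override-merged)
requirements independently and keep the deepest satisfied nodes — which
the test suite and the acceptance script verify on seeded random
genotype vectors. Ties at maximal depth are all reported (joined with
`;` in CSV output); with the default tree's disjoint sibling
requirements a tie cannot arise, but the contract is defined because
curated trees may violate disjointness.

## Input handling and QC

PED files encode two allele tokens per marker even for haploid mtDNA.
Collapse policy: equal non-zero tokens give the allele, `0 0` gives
missing, and a discordant non-zero pair (heteroplasmy-like or assay
artifact) gives missing with a logged warning — silently picking either
allele would fabricate a call, and no published policy exists for the
panel assay. Markers join the panel by rCRS position (the MAP bp
column), never by name. Chromosome codes `26`, `MT`, and `M` are
accepted as mitochondrial; others parse but warn. Per-marker genotyping
efficiency (fraction of samples called) is filtered at an *inclusive*
threshold of 0.90 by default: a marker called in exactly 90% of samples
is retained. Filtering changes marker membership only; calls are masked
in a separate explicit step so the QC report and the classification
input stay auditable.

## Synthetic data

The generator inverts the classifier. A sample "of" haplogroup X carries
the cumulative required alleles of X (override semantics at reversion
positions) and the panel's ancestral allele everywhere else — the unique
background choice for which generate→classify is provably the identity
at zero noise. On top of clean haplotypes it injects:

- per-call i.i.d. missingness (`missing_rate`),
- per-call discordant diploid pairs (`discordant_rate`), written to PED
  as mismatched tokens and read back as missing,
- an optional per-marker knockout (`knockout_markers`) that blanks a
  marker in all samples, emulating the marker-correlated missingness of
  real assay failures (e.g. knocking out the L2-defining marker at
  position 10115 makes the entire L2 branch unreachable).

Founder haplogroups are drawn uniformly over the 30 terminal nodes
unless weights are given. Trio families (father, mother, child) give the
child the mother's haplotype and truth label before noise; sex codes and
PAT/MAT columns are populated so founder filtering is testable. All
randomness flows from one `numpy` generator seeded by the config, so
fixtures are byte-identical across runs.

What the generator does *not* emulate: linkage of missingness across
markers within a sample (except via knockout), heteroplasmy fractions,
genotyping error that produces a *wrong concordant* call (a clean
mismatched haplotype), private variants off the panel, and realistic
population haplogroup frequencies. Passing recovery tests therefore
shows the algorithm and plumbing are correct, not that the panel
resolves real populations at any particular accuracy.

## Concordance protocol and frequencies

Two call sets are compared over their shared samples; samples labelled
unclassified/unknown in *either* set are excluded from the denominator
and counted separately. Labels agree when identical, or when one is a
finer resolution of the other: if both labels are reduced-tree nodes the
test is ancestor–descendant on one root path (handles JT vs J/T and HV
vs H correctly); for foreign labels a string rule applies — one label
must extend the other and the first extra character must continue the
Phylotree letter/digit alternation, so `A2x` refines `A2` but `HV` does
not refine `H`. The rule is symmetric in both directions.

Haplogroup frequency summaries exclude offspring (samples whose PED
maternal id names another sample in the same family) because a child's
mtDNA duplicates its mother's, and exclude unclassified samples from
the denominator. Lineage frequencies are exact sums of member-label
frequencies via the node lineage tags.

## Numerical and interface choices

- Percent concordance is printed to one decimal place.
- CSV output uses `\n` line endings and deterministic ordering, so
  repeated runs are byte-identical.
- Result CSV columns: `sample_id, haplogroup, path, status`, with the
  root-to-call path joined by `" -> "`.
- Seeds are plain integers into `numpy.random.default_rng`.

## Problem sizes used in the shipped checks

The test suite and the acceptance script exercise the classifier against
the brute-force oracle on 1,000 random genotype vectors, the closure
property on all 46 nodes, the missingness degradation curve at rates
{0, 0.2, 0.5, 1.0} with 200 samples per rate, the QC boundary on a
100-sample set, and file round-trips on 50–100-sample datasets — sizes
at which every property is exact rather than statistical, chosen because
the properties verified (equivalence, closure, monotonicity, boundary
inclusivity) do not sharpen with larger n.

## Known limitations

- Resolution stops at the 46 broad haplogroups; no sub-haplogroup calls.
- Asian lineages are represented only at broad level, and haplogroup B's
  primary defining event (the 8281–8289 deletion) is not a SNP and is
  not targeted; B is recognized via coding-region proxies.
- Robustness to missing data is intrinsically limited by the small panel:
  one missing key SNP near the root can unclassify a sample.
- The packaged tree is a curated reconstruction of a reduced phylogeny;
  users with their own panel can supply a different JSON config, which
  is validated with the same invariants.
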