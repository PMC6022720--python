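# mitoclass

Broad mitochondrial haplogroup classification from a small custom SNP
panel.

Human mtDNA is maternally inherited and non-recombining, so its variation
forms a single phylogeny whose clades — haplogroups — track continental
maternal ancestry. Sequence-based classifiers resolve fine sub-clades but
need full or partial mtDNA sequence, which is cost-prohibitive for large
cohorts. `mitoclass` targets the high-throughput regime: it assigns the
46 common African, European, and Native American/Asian haplogroups from a
63-SNP panel on revised Cambridge Reference Sequence (rCRS) coordinates,
reading standard PED/MAP genotype files, with per-marker genotyping-
efficiency QC, a call-set concordance protocol, and a ground-truth
synthetic data generator for validation.

## Algorithm

The knowledge base is a reduced phylogenetic tree: each haplogroup node
*h* carries the extra required genotypes G(h) = {(pos, allele), ...}
beyond its parent. A sample's calls enter at the root (the mtDNA MRCA);
descending the tree, requirements accumulate with descendant override at
shared positions — this encodes reversions such as the 10398 A→G back
mutation on the J and K branches. A node whose accumulated requirements
are all matched (a missing call never matches) enters an accumulator; a
subtree is pruned only when some unmet position is never re-required
inside it. Accumulated haplogroups are ranked by path length from the
root — a longer path means more SNPs checked, hence a more specific
call — and only the deepest survive. If nothing beyond the root is
satisfied, the sample is `unclassified`. This descent is exactly
equivalent to evaluating every node's cumulative requirements
independently and keeping the deepest satisfied nodes, a property the
test suite checks against an independent brute-force oracle.

Two panel markers (MT16189, MT9540) are blacklisted — hypervariable-
region assay failure and NumtS cross-amplification respectively — and
are excluded before classification; remaining markers are filtered at a
genotyping efficiency ≥ 0.90 (inclusive) by default.

## Worked example

Simulate a 90-sample cohort of 30 mother/father/child trios with 5%
missing calls, classify it, and compare calls against the simulation
truth:

```sh
mitoclass simulate --ped mxl.ped --map mxl.map --out truth.csv \
    --n-samples 90 --n-trios 30 --missing-rate 0.05 --seed 7
mitoclass classify --ped mxl.ped --map mxl.map --out calls.csv
mitoclass concord --calls-a calls.csv --calls-b truth.csv --out concord.csv
```

which prints

```
dropped 2 markers (2 blacklisted, 0 low call rate): MT9540, MT16189
classified 84/90 samples -> calls.csv
percent concordant: 100.0
```

`calls.csv` holds one row per sample with the assigned haplogroup and
its root-to-node path:

```
sample_id,haplogroup,path,status
IND0001,I,MRCA -> L3 -> N -> I,classified
IND0002,J,MRCA -> L3 -> N -> R -> JT -> J,classified
```

Six samples lost a key SNP to missingness and are `unclassified`; they
are excluded from the concordance denominator (`n_compared` = 84 in
`concord.csv`). Concordance is 100% rather than lower because a sample
degraded by missing data to an *ancestor* of its true haplogroup (e.g.
called L3 when the truth is L3e) still counts as concordant under the
finer-resolution rule — the two labels lie on one root-to-node path.

From Python, the same pipeline plus a founder-only frequency summary:

```python
from mitoclass import (default_tree, read_dataset, drop_blacklisted,
                       filter_by_call_rate, restrict_to_markers,
                       classify_dataset, haplogroup_frequencies)

tree = default_tree()
marker_map, samples = read_dataset("mxl.ped", "mxl.map")
marker_map, _ = drop_blacklisted(marker_map, tree.panel)
marker_map, _ = filter_by_call_rate(samples, marker_map, 0.90)
results = classify_dataset(tree, restrict_to_markers(samples, marker_map))
label_freq, lineage_freq = haplogroup_frequencies(results, samples, tree,
                                                  founders_only=True)
```

`haplogroup_frequencies` drops the 30 children (their mtDNA duplicates
their mothers') and the unclassified samples, leaving 56 founders; for
the run above `lineage_freq` is
`{'European': 0.25, 'NativeAmerican_Asian': 0.268, 'African': 0.464,
'Macro': 0.018}` — matching the uniform-over-leaves draw of the
simulator rather than any real population.

Custom trees/panels are plain JSON (see
`src/mitoclass/data/default_tree.json`) passed via `--tree`.

## Layout

- `src/mitoclass/tree_model.py` — tree/panel model, JSON config loading
  and validation
- `src/mitoclass/genotype_io.py` — PED/MAP reading and writing, diploid
  collapse, call-rate QC
- `src/mitoclass/classifier.py` — the accumulator classifier
- `src/mitoclass/synthetic_data.py` — ground-truth simulator (trios,
  missingness, discordance, marker knockout)
- `src/mitoclass/concordance.py` — call-set agreement and founder
  frequency summaries
- `src/mitoclass/cli.py` — `mitoclass classify | simulate | concord`
- `docs/methods.md` — model, assumptions, design choices, limitations
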