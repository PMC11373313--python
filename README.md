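# mulnet

Polyploid species-network inference from collections of multilabeled
(MUL) gene trees, robust to incomplete lineage sorting. The pipeline:

1. **Cluster census** — extract clade clusters (label multisets) with
   per-tree multiplicities and cross-tree frequencies from rooted Newick
   gene trees (`mulnet.clusters`).
2. **Maximum-weight cluster selection** — build an approximate-compatibility
   graph over (cluster, multiplicity) records, weight each record by
   `multiplicity * frequency * |cluster|^0.65`, and select a maximum-weight
   mutually compatible subset by exact integer programming (HiGHS via
   scipy), with an exhaustive oracle for validation (`mulnet.selection`).
3. **Greedy consensus MUL-tree** — realize the selected clusters on the
   target leaf multiset by bounded backtracking (with a joint-realization
   fallback), then resolve multifurcations by maximum-weight binary
   refinement (`mulnet.consensus`).
4. **Network folding** — merge near-isomorphic equal-cluster clades
   (isomorphism codes, then normalized graph edit distance against a
   threshold `delta`, default 0.3) into reticulation nodes, choosing
   representatives by gene-tree-supported clade scores (`mulnet.folding`).

Supporting modules: `mulnet.phylo` (MUL-trees, networks, Newick and
extended-Newick `#H` I/O, unfolding), `mulnet.metrics` (normalized GED
between MUL-trees, a path-multiplicity network distance, normalized rooted
RF), and `mulnet.simulate` (multispecies-coalescent gene-tree simulation on
species MUL-trees with tunable ILS, rooted-NNI perturbation, scenario
presets, random topology generators).

## CLI

```sh
# sample 1000 gene trees from a 5-taxon, 1-reticulation scenario
mulnet simulate --preset D --ils low -n 1000 --seed 1 -o sim/

# infer the consensus MUL-tree and network
mulnet infer sim/gene_trees.nwk -o out/

# compare against the truth
mulnet compare out/network.enwk sim/true_network.enwk

# fold an existing MUL-tree, exact-isomorphism mode
mulnet fold multree.nwk --delta 0 -o network.enwk
```

Key flags: `--delta` (near-isomorphism threshold, default 0.3),
`--min-frequency` (cluster frequency filter, default 1), `--alpha`
(cluster-size exponent, default 0.65), `--ged-cap` (exact GED node cap,
default 12), `--binarize-reticulations`, `--leaf-multiset FILE`
(TSV `label<TAB>count` target multiset; default is the per-label maximum
over the input). Every run writes a `manifest.json` with the full
configuration and input digests. An empirical-style configuration with
heavy frequency filtering would be, e.g.,
`mulnet infer genes.nwk --min-frequency 21 --delta 0.2`.

## Formats

- Gene trees / MUL-trees: rooted Newick, one per line; repeated leaf
  labels allowed; branch lengths optional (used only by the simulator, in
  coalescent units).
- Networks: extended Newick with `#H<k>` hybrid tags; each reticulation's
  subtree is written once in full, other occurrences are tag references.
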