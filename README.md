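# pseudolock

Comparative-evolution and assay-scoring toolkit for pseudoenzyme calls.

When a protein keeps an enzyme fold but has lost catalysis — as the
Ser/Thr "phosphatase" PHLPP2 has — the case rests on several independent
lines of quantitative evidence: the decay of catalytic residues across a
phylogeny, repeated loss of the gene in whole lineages, a somatic
mutation profile indistinguishable from functionally inert genes, and
biochemical assays whose residual activity traces to contaminants.
`pseudolock` implements that evidence chain as a tested, reusable
library for molecular evolution and enzymology groups:

* **Dollo parsimony mapping** — single-gain/multiple-loss histories of
  binary characters (genes, domains, active sites) on rooted trees,
  with per-edge gain/loss annotation. For a character gained once, the
  most-parsimonious history puts the gain above the MRCA of carriers
  and one loss on each maximal carrier-free subtree; the loss count is
  provably minimal and unique.
* **Active-site integrity calling** — PPM/PP2C catalytic sites need the
  M1 and M2 metal ions; sequences are called active/pseudo from
  conservation of the required coordinating residues, with a dedicated
  flag for the aspartate→cysteine M2 substitution that converts a
  catalytic site into a structural zinc site. Sequence-logo matrices
  (residue frequencies, information content in bits) summarize motif
  conservation.
* **Phylogenomic profiling** — genes ranked by the phi coefficient
  (Pearson correlation of binary presence/absence profiles,
  φ = (n₁₁n₀₀ − n₁₀n₀₁)/√(r₁r₀c₁c₀)) against a query, with a
  phylogeny-aware permutation p-value that re-places the gene's Dollo
  losses instead of shuffling tips.
* **Mutation-burden comparison** — synonymous/nonsynonymous rates per
  1,000 aa, binomial hotspot detection with full-gene FDR correction,
  copy-number gain/loss skew, and a TSG-like / oncogene-like /
  neutral-like class call.
* **Assay scoring** — phosphate-calibration fitting, endpoint and
  initial-rate computation with a 3-SD detectability rule, okadaic-acid
  contaminant attribution (near-total inhibition by a sub-stoichiometric
  inhibitor implicates a contaminant, not the target), and MMTS:IAA
  differential-alkylation accessibility calls.
* **Synthetic data** — every input above can be generated with known
  ground truth, so the whole pipeline is exercised end to end without
  downloads.

## Worked example: PHLPP2 loss across jawed vertebrates

The built-in dataset scores PHLPP2 presence/absence on a coarse
gnathostome species tree:

```python
from pseudolock.datasets import gnathostome_phlpp2
from pseudolock.dollo import infer_dollo, count_independent_losses

tree, states = gnathostome_phlpp2()
rec = infer_dollo(tree, states, "PHLPP2")
print("gain edge:", rec.gain_edge)
print("loss edges:", sorted(rec.loss_edges))
print("independent losses:", count_independent_losses(rec))
```

prints

```
gain edge: gnathostomata
loss edges: ['caecilians', 'softshell_turtles', 'squamata', 'tortoises']
independent losses: 4
```

i.e. the gene was present in the gnathostome ancestor and was lost four
times independently — in caecilians, in squamates, and twice inside
turtles on distinct edges (soft-shelled turtles and tortoises, with sea
turtles retaining it in between). The same run is available as a
pipeline config: `pseudolock run --config examples/gnathostome_demo.yaml`.

A profiling screen on simulated data, with three genes planted to
coevolve with the query:

```bash
pseudolock sim profile --out-dir demo --n-tips 30 --n-genes 12 \
    --n-coevolving 3 --flip-noise 0.02 --seed 5
pseudolock profile --tree demo/tree.nwk --matrix demo/profile_matrix.tsv \
    --query query --n-perm 199 --seed 1 --out demo/rank.tsv
```

```
gene    phi       p      q      rank
g03     1.000     0.015  0.090  1
g01     0.929     0.005  0.060  2
g02     0.926     0.030  0.120  3
g11     0.632     1.000  1.000  4
g06     0.190     0.320  0.669  5
```

The three planted genes (g01–g03) occupy the top ranks; phi below 1
reflects the 2% flip noise, and the permutation p-values are computed
against a null that preserves each gene's gain edge and loss count on
the tree.

Other subcommands (`dollo`, `sites`, `burden`, `assay`, `alkyl`, `run`)
wrap the corresponding library modules; see `pseudolock --help`.

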