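# dtli — reconciliation with duplications, transfers, losses and ILS

`dtli` infers the evolutionary history of a gene family by reconciling a
rooted binary gene tree with a rooted species tree that may contain
polytomies. It is aimed at comparative genomicists analysing gene
families across prokaryotic or eukaryotic genomes, where gene trees
disagree with the species phylogeny because of gene **d**uplication,
horizontal **t**ransfer, **l**oss, and **i**ncomplete lineage sorting at
rapid radiations.

The score of an annotated reconciliation is the weighted event sum

    pi = delta * n_D + tau * n_T + lambda * n_L

with speciations and deep coalescences free. Polytomies in the species
tree mark lineages where ILS is entertained: any gene-tree branching
consistent with some binary resolution of the polytomy costs nothing.
A divergence at gene node `g` mapped to species `s` is a duplication
exactly when the species children of `s` that vertically inherit the two
gene children's descendants are **not** disjoint; disjoint inheritance
sets mean a transfer (one child incomparable to `s`), a speciation
(binary `s`) or a deep coalescence (polytomy). At binary nodes the test
reduces to classical lca reconciliation.

The tool's distinguishing features:

* enumerates **all** minimum-cost histories, not an arbitrary one, and
  flags *degenerate* families whose optima disagree in event counts;
* tests each history for **temporal feasibility** (a transfer's donor
  and recipient must have coexisted) via an acyclicity test on a timing
  graph, and reports only feasible histories;
* handles non-binary species trees under all four model variants
  DT / DTI / DTL / DTLI (the "L" scores losses, the "I" admits
  polytomies and coalescence);
* batch survey tooling: rooting by event parsimony, per-model event
  tables, transfer matrices and transfer-highway detection;
* a seeded simulator of gene families with planted, exactly replayable
  D/T/L/ILS histories, plus an exhaustive oracle for small instances.

## Worked example

The gene tree `((gA,gB),(gC,gD))` conflicts with the species tree
`(A,(B,C,D))`: grouping `gA` with `gB` crosses from outside to inside
the polytomy, which no binary resolution can explain. With duplication
cost 3, loss cost 2 and transfer cost 7:

```
$ dtli reconcile gene.nwk species.nwk -t 7 --map map.tsv
{
  "score": 9.0,
  "n_optimal": 2,
  "n_feasible": 2,
  "degenerate": true,
  "status": null,
  "truncated": false,
  "counts_per_history": [
    [0, 1, 1, 1],
    [1, 0, 3, 1]
  ]
}
```

Two optimal histories tie at score 9 — one transfer plus one loss
(`0, 1, 1` duplications/transfers/losses, plus one coalescence) and one
duplication plus three losses — and both are temporally feasible. The
family is *degenerate*: a survey protocol should not pick one of these
at random. Lowering the transfer cost to 2.5 makes the transfer history
the unique optimum at score 4.5. With `--out-prefix` the tool writes
each history as NHX-annotated Newick (species assignments, event codes
D/T/S/C, donors/recipients, per-edge loss records) plus a per-event TSV
and a JSON summary.

Other subcommands: `dtli root` (event-parsimony rooting over all edges),
`dtli batch` (model-by-cost survey tables with the survey retention
protocol), `dtli highways` (outlier species pairs in a transfer matrix),
`dtli simulate` (planted histories). The same functionality is available
as a library (`dtli.first_pass`, `dtli.second_pass`,
`dtli.filter_feasible`, `dtli.report.batch_reconcile`, ...).

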