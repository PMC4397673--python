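# tfnetminer

Integrated transcription-factor (TF) regulatory-network analysis for
two-condition expression studies, of the kind used to nominate master
regulators of direct cell-fate conversion (e.g. fibroblast → induced neural
stem cell). Given an expression matrix, a TF→target catalog (ChIP-derived,
ChEA-style) and a protein–protein interaction (PPI) layer (BioGRID-style),
the pipeline:

1. calls differentially expressed (DE) genes by a restrictive fold-change
   rule (default FC ≥ 3);
2. nominates **DE-TFs** by target over-representation — one-sided
   hypergeometric `P(X ≥ k)` over the measured universe — combined with the
   TF's own ≥ 2-fold expression change;
3. assembles a colored mixed network: directed `TF → target` edges restricted
   to DE targets, plus PPI edges whose *both* interactors are DE, nodes
   colored up/down;
4. censuses all connected colored 3-node subgraphs and scores each canonical
   class against a degree-preserving edge-switching null
   (`z = (N_real − μ_null)/σ_null`, FANMOD-style);
5. ranks hubs by six centrality parameters (degree, eccentricity, closeness,
   betweenness, stress, centroid — CentiScaPe's sextet on the undirected
   union graph);
6. detects dense complexes in the TF PPI network by k-core vertex weighting
   and seeded growth (MCODE-style, score = density × size);
7. finds *active modules*: connected subnetworks maximizing the
   background-corrected aggregate score `Z_A = Σ_i Φ⁻¹(1 − p_i)/√|A|`
   (jActiveModules-style, calibrated against searches on permuted node
   scores);
8. scores each TF per pathway as the fraction of that pathway's DE genes it
   regulates, and
9. reports **master regulators**: TFs supported by ≥ 2 of the three analyses
   (hubs / complexes / active modules), with a cross-study consensus rule
   (present in all studies, concordant direction) when several studies are
   compared.

Because the original GEO inputs are not bundled, the package ships a
first-class synthetic-study generator (`tfnetminer.synthetic_data`) that
plants every signal the pipeline is supposed to find — DE genes with a known
fold-change distribution, TFs with boosted regulons, PPI cliques, a low-p
connected module — so that every stage has an exact recovery benchmark.

## Worked example

```bash
tfnetminer simulate --out-dir demo --seed 11 --n-genes 1000 --n-tfs 100
tfnetminer run-all \
    --expression demo/expression.tsv --groups demo/groups.tsv \
    --catalog demo/tf_targets.gmt --ppi demo/ppi.tsv \
    --pathways demo/pathways.gmt --seed 11 --out-dir demo/results
```

prints

```json
{
  "n_de_genes": 100,
  "n_de_tfs": 5,
  "network_nodes": 87,
  "network_edges": 181,
  "master_regulators": ["Tf001", "Tf003", "Tf004", "Tf005", "Tf002"]
}
```

The generator planted five enriched TFs (`Tf001`–`Tf005`): they regulate DE
genes far beyond chance, are themselves upregulated, form a PPI clique and
sit inside the low-p module — and all five come back as master regulators.
`demo/results/` holds the per-stage tables; e.g. `complexes.tsv` reports the
planted clique as the top complex,

```
rank  score  size  members
1     5.0    5     Tf001,Tf002,Tf003,Tf004,Tf005
```

and `motifs.tsv` lists each colored triad class with its null statistics
(`A→B; A→C [up,down,down]` flagged at z = 2.8, empirical p = 0.008 in this
run). Every stage can also be run separately (`tfnetminer de`, `enrich-tf`,
`build-net`, `motifs`, `centrality`, `mcode`, `active-modules`, `rank-tfs`,
`consensus`) on files you provide; the library API (`tfnetminer.run_study`,
`tfnetminer.compare_studies`) exposes the same pipeline to Python.

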