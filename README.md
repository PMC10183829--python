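# phyloprof

Comparative phylogenomics and motif-conservation analysis of a
ubiquitin-like-modifier pathway and its receptor, rebuilt as a tested,
reusable pipeline that runs entirely on synthetic data, together with the
supporting biophysical calculations (binding isotherm fitting, NMR
chemical-shift-perturbation analysis, remnant-adduct masses).

## What it does

* **synthetic_data** — generates, from a seed, a complete study: a rooted
  species tree, per-taxon proteomes with correlated gene-family losses,
  rate-inflated paralogs, composition-matched decoys, truncated fragments,
  one ortholog hidden inside a nucleotide genome, and receptor sequences
  whose disordered region carries shuffled-AIM motifs (`I[DS]W[GD]`) only
  in taxa that retain the modifier family. Ground truth is emitted
  alongside.
* **homology_search** — affine-gap Smith-Waterman with Karlin-Altschul
  E-values, iterative PSSM profile construction and re-search with a
  calibrated extreme-value null, and a six-frame-translation genome rescue
  stage for unannotated orthologs.
* **msa_processing** — progressive alignment on an NJ guide tree, column
  trimming by non-gap fraction (default 30%), fragment filtering
  (rows < 50% data), Henikoff position-based weights.
* **phylo** — Poisson-corrected distances, neighbor joining, midpoint-rooted
  paralog screening, and Dollo-parsimony gene-loss mapping (single gain at
  the root, losses as maximal all-absent subtrees).
* **coevolution** — presence/absence matrix assembly with stage provenance,
  pairwise phi coefficients, Ward-D2/Euclidean clustering.
* **conservation_motifs** — single-group and two-group per-column
  conservation scores, weighted sequence-logo counts with information
  content, cAIM/sAIM motif scanning, point mutation, and sAIM-to-cAIM
  conversion (`IDWD -> WDDI`, `IDWG -> WDGI`).
* **biophys_calc** — exact 1:1 ligand-depletion binding isotherms with
  nonlinear Kd fitting, CSP computation/classification, intensity ratios,
  and monoisotopic remnant-adduct masses.
* **pipeline_runner** — the end-to-end orchestration and CLI.

## CLI

Every stage is a subcommand of `phyloprof`:

```bash
phyloprof simulate --n-taxa 12 --seed 1 --out fixture/
phyloprof run --seed 1 --out results/study/
phyloprof search queries.fasta fixture/ --evalue 1e-5
phyloprof align seqs.fasta | phyloprof trim /dev/stdin --gap-threshold 0.3
phyloprof losses species_tree.nwk presence.tsv
phyloprof coevolve presence.tsv --dendrogram dendro.nwk
phyloprof conserve receptor_alignment.fasta --groups groups.tsv
phyloprof scan receptor.fasta --pattern saim
phyloprof bind-fit titration.tsv --labeled-conc 50e-9
phyloprof csp free.tsv bound.tsv --thresholds 0.025 0.04
phyloprof mass VG
```

`phyloprof run` executes simulate → pairwise search → align/trim/filter →
gene trees + paralog screen → profile build/search → genome rescue →
presence/absence assembly → Dollo losses → phi + clustering → two-group
conservation + motif scan, and writes TSV/newick/JSON outputs plus a
manifest with the config and seed.

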