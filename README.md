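# clckit

In-silico characterization of CLC-family anion channel / antiporter
proteins: conserved-motif scanning, selectivity-filter and glutamate-based
functional classification, sorting-signal and CBS-domain detection,
physicochemical summaries (length, mass, pI, GRAVY, hydropathy/TM sketch),
pairwise identity, JTT phylogenetics with bootstrap and subgroup
assignment, and in-silico point mutagenesis — all testable end to end on
synthetic sequences.

## Package layout

| module | responsibility |
| --- | --- |
| `clckit.seqio` | FASTA I/O, CDS translation, point substitutions (`C544T` notation) |
| `clckit.motifscan` | degenerate motif scanning (`GxGxPE`, `GKxGPxxH`, `PxxGxLF`) and sorting signals (`YxxΦ`, `DxxLL`, `[DE]xxxL[LI]`) |
| `clckit.classify` | anion-specificity call from the filter's second residue (P → nitrate, S → chloride), antiporter/channel call from the two conserved glutamates, CBS placement, full annotation reports |
| `clckit.physchem` | average mass, Bjellqvist-pKa bisection pI, Kyte-Doolittle GRAVY and hydropathy-window TM calling |
| `clckit.align` | affine-gap global/local alignment (BLOSUM62, open 10 / extend 0.5, free end gaps) and percent identity |
| `clckit.phylo` | JTT model, ML pairwise distances, neighbor joining, pruning likelihood, NNI search, site bootstrap, subgroup assignment |
| `clckit.synthdata` | blueprint-driven synthetic CLC-like proteins with exact ground truth, reverse translation, sequence evolution along trees |
| `clckit.cli_report` | `clckit` CLI and TSV/JSON reporting |

## CLI

```sh
# family-table style annotation
clckit annotate --input proteins.fasta --out-tsv table.tsv --out-json evidence.json \
    [--references refs.json] [--tm-window 19] [--tm-threshold 1.6] [--skip-bad]

# phylogeny with bootstrap supports and optional subgroup assignment
clckit tree --input aligned.fasta --out tree.nwk --support-table support.tsv \
    --bootstrap 100 --seed 1 [--nni-rounds 2] \
    [--anchors-i AtCLCa,AtCLCd --anchors-ii AtCLCe,AtCLCf --subgroup-table sub.tsv]

# in-silico point mutagenesis with protein-level diff
clckit mutate --cds cds.fasta --sub C544T --out mutated.fasta --diff diff.json

# synthetic data generation
clckit simulate --blueprint blueprint.json --seed 7 --out synthetic.fasta --truth truth.tsv
```

Reference bundles are a FASTA plus a JSON sidecar:

```json
{
  "fasta": "refs.fasta",
  "anchor_ref": {"id": "EcCLC", "gating": 148, "proton": 203},
  "filter_ref": {"id": "AtCLCa", "start": 165, "end": 170},
  "cbs": [{"id": "cbs1", "domain": "CBS1"}],
  "homologs": ["AtCLCa", "AtCLCb"]
}
```

## Notes on method choices

* The TM caller is a classic hydropathy sliding-window method (window 19,
  threshold 1.6, min span 10) and is labelled an approximation of
  probabilistic topology predictors everywhere it surfaces.
* pI uses a single documented pKa set (Bjellqvist/ExPASy-style) rather than
  averaging multiple web tools; agreement is tolerance-based (±0.15).
* Bootstrap replicate trees are NJ on ML distances (not a full ML search
  per replicate); rates are uniform across sites.
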