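# bactopan

Comparative-genomics analytics for bacterial genome sets: gene-family
construction under a 50/50 amino-acid homology rule, pan/core-genome
accumulation curves with power-function fits, fragment-based average
nucleotide identity (ANI) and filtered best-hit average amino acid identity
(AAI), host-grouped core-gene-pool partitioning (Venn regions and COG
category tabulation), and tree node-depth statistics with a Wilcoxon
two-sample comparison. A genome-evolution simulator supplies desk-scale
inputs with full ground truth, so the whole pipeline is testable without any
downloads.

## Layout

| module | contents |
| --- | --- |
| `bactopan.align` | Smith-Waterman local alignment (numba kernel, seeded window mode for fragment-vs-genome search), BLOSUM62/nucleotide scoring, six-frame translation, optional external BLAST adapter |
| `bactopan.families` | pairwise homology verdicts (>50% identity, >50% longer-gene coverage), single/complete-linkage clustering, representative selection, six-frame rescue of unannotated ORFs |
| `bactopan.pancore` | presence/absence matrix, pan/core accumulation curves (exhaustive for ≤6 genomes, seeded permutations otherwise), power-law fits |
| `bactopan.aniaai` | 1020-nt fragment ANI (30% identity / 70% coverage retention, reciprocal mean) and filtered best-hit AAI |
| `bactopan.phylo` | Newick parser/writer, outgroup rerooting, nodes-to-MRCA statistic, exact/normal Wilcoxon rank-sum test, alignment concatenation |
| `bactopan.hostcore` | per-host core sets, Venn partition, COG category distributions |
| `bactopan.simulate` | Yule-tree genome-clade simulator with gene gain/loss and per-site substitution; emits FASTA + truth JSON |
| `bactopan.io` / `bactopan.pipeline` / `bactopan.cli` | FASTA/TSV/Newick I/O, run configuration, manifest-based stage orchestration, command-line interface |

## CLI

```sh
# synthetic clade with ground truth
bactopan simulate --n-genomes 10 --families 40 --gain 1 --loss 0.3 \
    --sub-rate 0.02 --seed 7 --out data/

# gene families and presence matrix
bactopan families --proteins data/proteins --out out/fam \
    [--rescue --assemblies data/assemblies] [--linkage single|complete] [--exact]

# pan/core curves and power fits
bactopan pancore --matrix out/fam/presence.tsv --permutations 100 --seed 7 --out out/pc

# pairwise distance matrices
bactopan ani --assemblies data/assemblies --out out/ani.tsv
bactopan aai --proteomes data/proteins --out out/aai.tsv

# host-grouped core sets and Venn regions
bactopan hostcore --matrix out/fam/presence.tsv --hosts data/hosts.tsv \
    --groups bee,human --out out/hc

# node depths and Wilcoxon comparison
bactopan treestats --tree data/tree.nwk --hosts data/hosts.tsv \
    --compare bee,human --out out/ts

# everything, with manifest-based stage skipping
bactopan run --input-dir data/ --out out/full --seed 7 [--force]
```

## Notes

* Identity percentages use the gap-inclusive denominator (identical columns
  over all aligned columns); ambiguity codes never count as identities.
* Affine gaps: a gap of length L costs `-(gap_open + (L-1)·gap_extend)`.
* ANI/AAI are reciprocal means of the two directional values; one-way mode is
  available via `reciprocal=False`.
* All randomness flows from explicit seeds; fixed seeds give byte-identical
  outputs, including simulator FASTA files.
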