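# fragscan

Gene prediction in short, error-prone reads — a Python reimplementation of
the FragGeneScan (FGS) gene-prediction model, as a library plus a
backward-compatible command line tool.

Shotgun metagenomics produces fragments that carry *partial* protein-coding
regions (start or stop codon missing at the read edge) and sequencing
errors that shift the reading frame. `fragscan` locates complete and
partial genes on both strands of each input sequence and emits, per gene,
its metadata (coordinates, strand, frame, score, indel positions), its
frame-corrected DNA and its protein translation.

## The model

Decoding uses the Viterbi algorithm over a hidden Markov model with a
fixed inventory of *s* = 49 states:

* six codon-periodic **match** states per strand (`M1..M6`, `M1'..M6'`),
  covering two successive codons, with emissions
  P(base | preceding dinucleotide) per period — the codon-usage signal;
* six **insertion** states per strand (`I1..I6`, …) for extra read bases
  (the codon period is held) and six implicit **deletion** states per
  strand, realised as skip transitions that advance the period by two
  while consuming one base;
* one **non-coding** state `R` with its own emission table;
* four 3-base **boundary composites** (forward/reverse start/stop codons,
  12 single-base states), scored by positional weight matrices over a
  window centred on the boundary codon.

Because *s* is fixed, decoding costs O(s²·n) — linear in sequence length.
Emission tables are trained per integer GC-percentage bin; each sequence
is decoded with the tables of its own GC bin. Transition rates (gene
density, gene length, indel error rates) come from a named *condition*
(`complete`, `sanger_5`, `454_10`, `illumina_10`, …). The distribution
ships a synthetic default training set (see
`src/fragscan/data/train_synthetic/PROVENANCE`); point `-r` at any
training directory in the documented text format for production use.

## Command line

```sh
fragscan -s reads.fa -o predictions -w 0 -t illumina_5 -p 4
```

| flag | meaning |
|------|---------|
| `-s` | input FASTA (`-` = stdin; gzip transparent) |
| `-o` | output base: writes `BASE.out` (metadata), `BASE.ffn` (DNA), `BASE.faa` (protein); `-` = stdout |
| `-w` | `0` short reads, `1` complete genomes |
| `-t` | error-model condition (e.g. `complete`, `454_10`) |
| `-p` | worker processes; output order is preserved for any count |
| `-r` | custom training directory (default: packaged data) |
| `-m`/`-n`/`-a` | individual metadata/DNA/protein sinks; unselected products are never computed |
| `-u` | emit results as they finish (drops in-order reporting) |

## Worked example

```python
from fragscan import fixtures, viterbi_decode, extract_genes, render_dna, translate

params = fixtures.generate_params(seed=1, gene_strength=6.0)
reads, truth = fixtures.generate_reads(params, n=1, length=300,
                                       insert_rate=0.0, delete_rate=0.0, seed=7)
read = reads[0]
path = viterbi_decode(params, read.seq)
for gene in extract_genes(path, read.seq, read.id):
    dna = render_dna(gene, formatted=False)
    print(gene.start, gene.end, gene.strand, gene.frame, round(gene.score, 3))
    print(translate(dna, gene.strand, complete_start=gene.has_start)[:40])
```

prints

```
45 245 - 2 0.85
MSDVTKYPGSGSVRYPVPYVTNTCFKLRYPFKFKFKYPYP
```

i.e. one reverse-strand gene spanning bases 45–245 of the read in frame 2,
with a mean per-base log-odds of 0.85 versus the non-coding model, and
the first 40 residues of its translation. The planted ground truth for
this read (`truth[0].genes[0]`) is exactly the same interval and strand.

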