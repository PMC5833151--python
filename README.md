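# bioutils

Four pipe-composable command-line utilities for everyday molecular-biology
data wrangling, following the UNIX pipes-and-filters convention: each command
reads a file argument or standard input, performs exactly one operation, and
writes the payload to standard output so invocations chain with `|`.

| command   | object                      | default input format |
|-----------|-----------------------------|----------------------|
| `bioseq`  | sequences                   | FASTA (or GenBank via `-i genbank`) |
| `bioaln`  | multiple alignments         | CLUSTAL W (or FASTA/PHYLIP via `-i`) |
| `biopop`  | aligned allelic sequences   | FASTA                |
| `biotree` | phylogenetic trees          | Newick               |

## Usage

Each command supports `--help` / `-h` / `--man`. A selection:

```sh
bioseq -n seqs.fasta                  # number of sequences
bioseq -l seqs.fasta                  # per-sequence lengths
bioseq -p 'id:B31,N40' seqs.fasta     # pick by id (also order:1-3, re:B31)
bioseq -s '10,20' seqs.fasta          # 1-based inclusive sub-sequence
bioseq -t6 seqs.fasta                 # six-frame translation
bioseq -r seqs.fasta                  # reverse-complement (IUPAC aware)
bioseq -g seqs.fasta                  # remove gaps
bioseq --restrict EcoRI seqs.fasta    # in silico digest

bioaln -a aln.aln                     # average pairwise percent identity
bioaln -s '20,-' aln.aln              # slice columns ( '-' = open end )
bioaln -o phylip aln.aln              # format conversion (bare -o converts)
bioaln -A a.aln b.aln                 # concatenate same-id alignments
bioaln -P cds.fas pep.aln             # codon alignment from aligned proteins
bioaln -b --seed 7 aln.aln            # bootstrap columns
bioaln --shuffle-sites aln.aln        # permute column order
bioaln --mutate-sites 0.05 aln.aln    # per-residue mutations

biopop -s pop.fasta                   # segregating sites
biopop -p pop.fasta                   # mean pairwise differences (pi)
biopop -m pop.fasta                   # mismatch distribution
biopop -c pop.fasta                   # coding SNP classification
biopop -t 'pi,theta' pop.fasta        # named statistics incl. Watterson's theta

biotree -l tree.nwk                   # total tree length
biotree -m tree.nwk                   # midpoint rooting
biotree -r 'otu1' tree.nwk            # outgroup rooting
biotree -d 'id1,id2' tree.nwk         # delete OTUs
biotree -s 'id1,id2,id3' tree.nwk     # spanning subtree (or internal node name)
biotree -D 75 tree.nwk                # collapse branches with support < 75
biotree --dist-all tree.nwk           # patristic distance matrix
biotree --depth tree.nwk              # root-to-tip depth per OTU
biotree -t tree.nwk                   # ASCII preview
```

Commands compose; a file argument of `-` (or none) means standard input:

```sh
bioaln -o fasta aln.aln | bioseq -p 're:B31' | bioseq -g | bioseq -t1
biotree -m tree.nwk | biotree -D 90 | biotree -d 'B31,N40'
```

All statistics share a single site-masking rule (`biopop`): columns with any
gap or ambiguity character are excluded from every estimator, so
denominators are consistent across S, pi, theta, and the mismatch
distribution.

## Library use

The CLI is a thin layer over importable modules:

- `bioutils.io_formats` — FASTA/GenBank/CLUSTAL/PHYLIP/Newick readers and writers
- `bioutils.sequence_ops`, `bioutils.alignment_ops` — sequence/alignment transforms
- `bioutils.popgen_stats` — S, pi, Watterson's theta, mismatch, coding-SNP classes
- `bioutils.tree_ops` — rooting, pruning, collapsing, distances, rendering
- `bioutils.fixtures` — seeded synthetic-data generators (CDS sets, allelic
  samples with known diversity, random support-labeled trees)

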