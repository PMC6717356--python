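# tm7pop

Mining, classification and population genetics of seven-transmembrane (7TM)
receptor gene repertoires, in three connected stages:

1. **Repertoire mining** (`tm7pop.mining`) — translated homology search of a
   protein query panel against a genome assembly (built-in Smith–Waterman
   engine with Karlin–Altschul e-values, or imported 12-column tabular
   results), hit filtering (≥300 nt) and merging, in-frame ORF extension,
   Kyte–Doolittle transmembrane-helix prediction, and classification of each
   candidate locus as *intact*, *partial* (truncated by a scaffold edge or
   assembly gap), *pseudogene* (nonsense/frameshift), or *short_complete*.
2. **Comparative contrasts** (`tm7pop.phylo`) — dated species trees built
   from node-age tables, Felsenstein's phylogenetically independent
   contrasts, and Spearman rank correlation of gene-count contrasts against
   a binary (0/1) lifestyle code.
3. **Two-population genetics** (`tm7pop.popgen`, `tm7pop.snps`) — per-locus
   π, Watterson's θ, Tajima's D and Fu & Li's D* with p-values from 10,000
   coalescent replicates conditioned on S, Hudson's FST (1 − Hw/Hb), the
   nearest-neighbor statistic Snn with a label-permutation test, per-SNP
   Fisher exact tests of allele-frequency differences with
   Benjamini–Hochberg FDR, coding-effect annotation, and mapping of
   significant nonsynonymous SNPs onto predicted membrane topology.

A seeded synthetic-data module (`tm7pop.simulate`) generates every input the
pipeline consumes — genomes with implanted genes of every category among
decoys (with a machine-readable truth table), Brownian-motion traits on
trees, and two-population coalescent alignments — so the whole analysis is
testable offline.

## CLI

```bash
# synthetic inputs
tm7pop simulate genome --seed 1 --scaffold-len 200000 --out sim/
tm7pop simulate twopop --seed 1 --n1 32 --n2 26 --theta 5 --out sim/

# mining: GFF3 + CDS/protein FASTA + summary TSV
tm7pop mine --genome sim/genome.fa --evalue 1e-5 --min-hit-nt 300 --out mined/

# independent contrasts (tree with lengths, or topology + node ages)
tm7pop pic --tree tree.nwk --node-ages ages.tsv --traits traits.tsv --out pic/

# population genetics over a directory of per-locus alignments
# (allele ids carry a |population suffix, or pass --popmap map.tsv)
tm7pop popgen --loci loci/ --noncoding noncoding/ --seed 1 --out popgen/
```

Every command writes its full configuration (`run_config.yaml`) next to its
outputs and is byte-identical on rerun given the same seed and config.

## Layout

```
src/tm7pop/
  mining/        genome & panel I/O, 6-frame translation, search, ORF
                 extension, TM prediction, classification, pipeline
  phylo.py       trees, contrasts, Spearman correlation
  popgen.py      diversity, neutrality tests, coalescent null, FST, Snn, FDR
  snps.py        SNP calling, effects, Fisher exact test, topology mapping
  simulate.py    seeded genome / trait / coalescent generators
  runs.py, cli.py, config.py
  data/          bundled reference panel (regenerate with
                 scripts/make_reference_panel.py)
tests/           pytest suite incl. acceptance criteria
scripts/         acceptance.py, make_reference_panel.py
```
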