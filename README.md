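# delkit

Design and in-silico verification of marker-replacement gene deletion
constructs for haploid fungi.

The package covers the complete desk workflow behind a genome-scale
knockout resource:

- **`genome_io`** — FASTA/GFF3 loading with strict validation, and
  strand-aware extraction of the 0.6–1 kb homology flanks around each ORF
  (or around a kinase-domain sub-interval for large genes).
- **`cassette_design`** — the constrained 5f/5r/3f/3r primer quartet.
  Inner primers are anchored with their 3′ termini within 30 bp of the
  start/stop codon (widened to 75 bp when no candidate passes the
  physico-chemical bounds), outer primers keep each flank amplicon within
  600–1000 bp. Inner primers carry 5′ tails complementary to the marker
  cassette, outer primers tails complementary to the gapped vector.
  Melting temperatures use nearest-neighbor thermodynamics at 50 mM
  monovalent salt, vectorized over every candidate window (exact agreement
  with `Bio.SeqUtils.MeltingTemp.Tm_NN` is asserted in the test suite).
- **`assembly_sim`** — construct assembly by simulated yeast gap-repair
  recombination into a gapped shuttle vector, the fusion-PCR alternative
  route, and final amplification with the outer primers. Both routes are
  byte-identical by construction and by test.
- **`insilico_pcr`** — primer binding-site search (mismatch-tolerant,
  3′-exact), PCR product prediction, wild-type → null locus editing, and
  diagnostic assay design with external primers: alleles are distinguished
  by product size on a gel, or — when the size difference is below the gel
  threshold — by packaged restriction enzymes that cut only within the
  marker of the null allele.
- **`rescue`** — the heterokaryon-rescue decision procedure classifying
  transformants (haploid null / heterokaryon / diploid / ectopic /
  inconclusive) from plate growth, streak stability and diagnostic-PCR
  allele calls, and aggregating them into per-gene essentiality calls.
- **`kinome_summary`** — a packaged 131-kinase deletion/phenotype dataset
  (`src/delkit/data/kinome_table.tsv`) with its headline statistics
  (25/128 essential = 19.5%, 43/103 non-essential with a phenotype, group
  tallies, …).
- **`synthetic_data`** — deterministic synthetic genomes, markers, vectors
  and transformant observation sets with known ground truth, so every
  other module is testable offline.

## CLI

```sh
# generate a 200-gene synthetic genome with marker, vector and truth table
delkit synth --seed 1 --out-dir work/synth

# design primers and assemble constructs for every annotated gene
delkit design --genome work/synth/genome.fasta --gff work/synth/genes.gff3 \
    --marker work/synth/marker.fasta --vector work/synth/vector.fasta \
    --out-dir work/design

# call gene essentiality from a transformant observation TSV
delkit classify --observations obs.tsv --out calls.tsv

# summarize the packaged kinome dataset
delkit kinome --json-out kinome.json
```

Design parameters (primer length/Tm/GC bounds, flank bounds, windows, tail
length, …) can be supplied as YAML via `delkit design --config`.

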