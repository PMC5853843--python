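# carbshell

Analysis toolkit for β-carboxysome shell genes in cyanobacterial genomes:

* **profile_classifier** — builds per-class position-specific log-odds
  profiles from seed alignments and assigns Pfam00936-domain proteins to
  shell-protein classes (CcmK1–6, CcmO, EutM outgroup, …) by best local
  alignment bit score, including the length-based CcmK1/CcmK2 split
  (100–107 aa → CcmK2, 108–118 aa → CcmK1).
* **locus_assembly** — groups carboxysome genes into loci per genome using
  ordinal-gene adjacency rules (single non-carboxysome insertions tolerated
  inside a locus; a gene with no carboxysome neighbour within 10 ORFs is a
  satellite), identifies the main carboxysome locus (MCL) and classifies the
  genomic position of *ccmO*.
* **cooccurrence** — per-class genome coverage, observed/expected
  co-occurrence ratios (expected = n_A·n_B/N), uncorrected Pearson χ² with
  significance stars, and Venn region counts.
* **coexpression** — mean pairwise Pearson correlation of focal shell genes
  (*ccmO*, *ccmK1/2*, *ccmK3/4*, *rbcL*) with MCL genes from expression
  matrices (log2 data linearized first), aggregated by *ccmO* position.
* **sequence_ops** — pairwise identity, >99 %-identity redundancy reduction,
  gap-fraction column trimming, p-distance neighbor joining (scikit-bio
  backend) with class-monophyly checks, per-column information content.
* **synthetic_data** — seeded generators for genomes (realistic MCL +
  satellite architectures with exact class-constraint enforcement),
  class-labelled protein sequences, seed alignments and latent-factor
  expression matrices, so the whole pipeline is testable offline.
* **io_formats** — FASTA / TSV gene-table / report readers and writers,
  sequence QC (>20 % 'X' filter), JSON run configuration.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests
(locus-region partitioning vs an O(n²) oracle, NJ additivity, χ² closed
form) and `tests/test_acceptance.py` with one test per acceptance criterion.

## CLI

```sh
carbshell simulate  --spec spec.json --seed 1 --out simdir/
carbshell classify  --seeds seeds/ --in proteins.fasta --out classes.tsv
carbshell loci      --genes genes.tsv --out loci.tsv --summary summary.tsv
carbshell cooccur   --genes genes.tsv --out cooccur.tsv
carbshell coexpress --expr expr.tsv --roles roles.tsv --scale log2 --out coexpr.json
```

All subcommands accept `--config` (JSON, overridden by CLI flags), `--seed`
and `--log-level`; outputs embed the config hash and seed and are
byte-identical across runs with the same seed.

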