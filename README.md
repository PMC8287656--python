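# mitocomp

A comparative-analysis toolkit for fungal mitochondrial genomes. It
ingests annotated GenBank records and computes, for a cohort of circular
mitogenomes:

- **Annotation summaries** — PCG / tRNA / rRNA / intron / intronic-ORF
  counts and gene lengths (`mito_io`)
- **Base composition** — GC content, AT/GC strand skews, sliding-window
  skew profiles (`composition`)
- **Distances** — per-gene pairwise Kimura 2-parameter distances with
  pairwise deletion, plus a neighbor-joining tree utility (`distances`)
- **Selection screening** — Nei–Gojobori (1986) Ka/Ks with
  protein-guided codon alignment, pathway-averaged difference counts,
  Jukes–Cantor correction, and positive-selection flags (`selection`)
- **Intron position classes** — insertion sites mapped onto a reference
  CDS through the alignment, classes named `P<position>`, common/rare
  classification at the strict > 1/5 prevalence threshold, and
  disjunct-distribution flagging (`intron_pcl`)
- **Gene order** — circular, orientation-aware gene orders over a
  15 core PCG + 2 rRNA panel, canonicalization, breakpoint distances,
  rearranged-gene classification, plurality ancestor (`gene_order`)
- **Repeats** — seed-and-extend detection of interspersed duplications
  (direct and inverted) and cross-genome shared fragments with
  Karlin–Altschul E-values, a deterministic tandem-repeat period scan,
  and genome-coverage fractions (`repeats`)
- **Cohort statistics** — comparative tables with genome region
  partitions and the size-vs-intron-count correlation (`summary_stats`)
- **Synthetic data** — a generator for annotated synthetic mitogenomes
  (target composition, planted gene orders, introns, duplications,
  tandem arrays, codon-aware mutation with per-gene syn/nonsyn rates)
  recorded in a ground-truth manifest, so every stage is testable
  without downloads (`synthetic_data`)

## CLI

```sh
mitocomp summarize genomes/*.gb -o summary.tsv
mitocomp composition genomes/*.gb
mitocomp k2p genomes/*.gb --genes cox1,cob,rps3
mitocomp kaks genomes/*.gb --genes rps3
mitocomp pcl genomes/*.gb --reference ref_cox1.fasta --host-gene cox1
mitocomp generearrange genomes/*.gb --ancestor auto
mitocomp repeats genome.gb
mitocomp xfrag genome.gb nuclear.fasta
mitocomp cohort genomes/*.gb --correlate
mitocomp synth --spec spec.yaml --seed 17 -o outdir/
mitocomp all genomes/*.gb --reference ref_cox1.fasta -o bundle/
```

All tables are tab-separated with fixed column order; reruns are
byte-identical for identical inputs.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: NG86 and
breakpoint brute-force oracle equivalence, K2P closed-form checks, and
parameter recovery (intron position classes, gene orders, planted
repeats, correlation calibration, selection flags) on synthetic cohorts.

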