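# viropost

Post-detection processing for viromics — the bespoke computational stages
that sit *between* the standard external tools of a viral-metagenomics
workflow (virus detection, genome-quality estimation, read mapping,
binning) and the ecology-ready tables a study actually needs.

Given the plain-text files those tools exchange (FASTA contigs,
geNomad-style virus summaries, CheckV-style quality summaries, BLAST
tabular alignments, per-sample coverage tables, bin membership tables),
`viropost` performs:

* **Provirus reconciliation** — a provirus predicted inside a host contig
  is trimmed to its viral region and re-scored in a second detection
  round; the re-scored records replace their parents so every metric
  reflects viral sequence only.
* **Multi-tier viral-contig filtration** — score presets
  (conservative: virus score ≥ 0.8, length ≥ 2,500 bp, ≥ 1 hallmark gene;
  relaxed: ≥ 0.7, ≥ 2,500 bp, ≥ 0), gene-content filters (viral genes ≥ 1,
  host/viral gene ratio ≤ 1), and a final sequence-quality rule
  (> 5 kb, or > 1 kb and at least medium quality).
* **Species-level vOTU clustering** — local alignments of each sequence
  pair are merged into a global average nucleotide identity
  (ANI = Σᵢ pidentᵢ·lenᵢ / Σᵢ lenᵢ) and aligned fractions computed on the
  union of aligned intervals; greedy longest-first centroid clustering
  then groups sequences at ANI ≥ 95 % and AF ≥ 85 % of the shorter
  genome, with the longest member as representative.
* **Abundance matrices with horizontal-coverage filtration** — mean
  depth, covered fraction and read counts per (vOTU, sample), assembled
  into a complete matrix and filtered at covered-fraction thresholds
  0.1 / 0.5 / 0.9.
* **Viral-bin curation** — bins filtered on protein redundancy
  (conservative keeps < 2, relaxed keeps ≤ 5, with an explicit NCLDV
  exemption), multi-scaffold bins concatenated with 10-N linkers, and
  kept bins combined with unbinned vOTUs into one table.
* **Synthetic fixtures** — deterministic generators for every input
  format with known ground truth (planted clusters at controlled
  divergence, planted filter compositions, planted coverage), so the
  whole pipeline is testable with no downloads and no external binaries.

It does **not** run geNomad, CheckV, BLAST, read mappers, CoverM or
vRhyme — it consumes and produces their file formats.

## Worked example

Merge local alignments into global ANI and cluster three phage genomes:

```python
from viropost import AlignmentRow, compute_pairwise_ani, greedy_cluster

lengths = {"phage_A": 41000, "phage_B": 38500, "phage_C": 35200}
alignments = [
    AlignmentRow("phage_B", "phage_A", 96.4, 21000, q_start=1, q_end=21000,
                 t_start=1, t_end=21000),
    AlignmentRow("phage_B", "phage_A", 97.8, 14000, q_start=21500, q_end=35499,
                 t_start=24001, t_end=38000),
    AlignmentRow("phage_C", "phage_A", 82.1, 30000, q_start=1, q_end=30000,
                 t_start=30000, t_end=1),   # reverse-strand hit
]
pairs = compute_pairwise_ani(alignments, lengths)
for p in pairs:
    print(f"{p.query_id} vs {p.target_id}: ANI={p.ani:.2f}  "
          f"qcov={p.qcov:.3f}  tcov={p.tcov:.3f}  ({p.n_alns} alignments)")
clusters = greedy_cluster(pairs, lengths)
for c in clusters:
    print(f"vOTU rep {c.representative_id}: members {c.member_ids}")
```

prints

```
phage_B vs phage_A: ANI=96.96  qcov=0.909  tcov=0.854  (2 alignments)
phage_C vs phage_A: ANI=82.10  qcov=0.852  tcov=0.732  (1 alignments)
vOTU rep phage_A: members ['phage_A', 'phage_B']
vOTU rep phage_C: members ['phage_C']
```

phage_B's two alignments average to 96.96 % identity weighted by length;
its AF (coverage of the shorter genome, here qcov = 0.909) and ANI both
clear the species thresholds, so it joins phage_A's vOTU. phage_C, at
82 % identity, founds its own.

The same stages are available as a CLI over a working directory
(`viropost --help`): `simulate`, `validate`, `detect-post`,
`filter-genes`, `cluster`, `coverage`, `votu-table`, `bin-post`,
`summarize`. A complete synthetic run:

```bash
viropost simulate --outdir work/inputs --seed 3
viropost detect-post  --workdir work --metadata work/inputs/metadata.tsv
viropost filter-genes --workdir work --metadata work/inputs/metadata.tsv
viropost cluster      --workdir work --metadata work/inputs/metadata.tsv \
                      --blast work/inputs/blast.tsv
viropost coverage     --workdir work --metadata work/inputs/metadata.tsv
viropost votu-table   --workdir work --metadata work/inputs/metadata.tsv
viropost bin-post     --workdir work --bins work/inputs/bins.tsv
```

Outputs land in numbered stage folders (`02_CHECK_V`, `03_CLUSTERING`,
`04_READ_MAPPING`, `05_VOTU_TABLES`, `07_BINNING`), each with a
plain-text summary report. Re-running with the same seed reproduces every
table byte for byte.

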