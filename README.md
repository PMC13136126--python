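# luxminer

Discovery and characterization of *N*-acyl homoserine lactone (AHL)
quorum-sensing genes in bacterial genomes.

Many bacteria regulate group behavior through AHLs: a LuxI-family synthase
produces the signal and a LuxR-family regulator — an N-terminal
autoinducer-binding domain (ABD) plus a C-terminal helix-turn-helix (HTH) —
responds to it. Outside the well-studied Pseudomonadota, these genes often
appear in non-canonical arrangements: *luxI* "solos" with no regulator in
the local neighborhood (~3 kb), and abundant HTH-only LuxR proteins lacking
a recognizable ABD. `luxminer` provides a tested, reproducible pipeline for
mining such loci and for screening culture extracts for the AHLs themselves:

- **curation** — filter a reference protein collection into LuxI/LuxR
  training sets (bacteria, 100–500 aa, required InterPro domains, keyword
  exclusions) with exclusion reports and deduplication;
- **profiles** — build position-specific scoring profiles with empirically
  calibrated e-values (Gumbel null from seeded shuffles), estimate
  false-positive rates against negative sets, and suggest an inclusion
  cutoff (default 1.0×10⁻¹⁰) as the geometric mean of false-hit e-values;
  a pyhmmer (HMMER3) engine can be swapped in behind the same schema;
- **genome_scan** — translate annotated CDS (table 11, 1-based inclusive
  coordinates) and emit coordinate-anchored homolog hits with typical-length
  flags (LuxI ~157–257 aa, LuxR ~210–272 aa);
- **architecture** — classify LuxR hits as ABD+HTH (canonical), HTH-only,
  ABD-only or none, from InterProScan TSVs or built-in mini-profiles;
- **topology** — signed intergenic distances (negative = overlap, 0 =
  abutting), orientation (co-directional/convergent/divergent), cognate
  *luxI/R* pair calling within a 3 kb window, solo calls with exact
  nearest-partner distances, and ±3/±10 kb neighborhood inventories with
  functional category tags;
- **phylo** — gap-threshold alignment trimming (keep coverage ≥ 0.5),
  neighbor-joining trees, unrooted monophyly tests, annotated Newick/iTOL
  export, and a hook for external maximum-likelihood engines;
- **mrm** — AHL mass arithmetic (Cn-HSL = C(n+4)H(2(n+4)−3)NO3; 3-oxo
  variant +O −2H) and LC-MRM-MS transition matching on the diagnostic
  homoserine-lactone-ring product ion at m/z 102, with "putative unknown
  AHL" verdicts for off-grid precursors;
- **simulate** — ground-truthed synthetic families, decoys, planted-locus
  genomes and MRM peak lists, so the whole pipeline is testable offline.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Generate a synthetic genome with planted loci, calibrate both family
profiles against 1,000 decoys, scan, classify, and resolve topology:

```sh
luxminer simulate  --seed 13 --out fx
luxminer calibrate --curated fx/luxi_family.fasta --negatives fx/decoys.fasta \
                   --family LuxI --out cal
luxminer calibrate --curated fx/luxr_family.fasta --negatives fx/decoys.fasta \
                   --family LuxR --out cal
luxminer scan      --genome fx/genome.fasta --gff fx/genome.gff3 \
                   --profile cal/LuxI.profile.json --profile cal/LuxR.profile.json \
                   --out out
luxminer architecture --hits out/hits.tsv --domains fx/planted_domains.tsv --out out
luxminer topology  --hits out/hits.tsv --gff fx/genome.gff3 \
                   --architecture out/architecture.tsv --out out
luxminer report    --results out --genome-id synthetic --out report
```

which prints, stage by stage:

```
LuxI: fpr=0.2000% over 1000 negatives; suggested cutoff 3.15
LuxR: fpr=0.5000% over 1000 negatives; suggested cutoff 3.27
37 proteins scanned, 28 hits
classified 24 LuxR proteins
3 pairs, 22 solos
genome_id  n_luxI  n_luxR  n_canonical  n_hth_only  n_pairs  n_solos
synthetic       4      24            3          21        3       22
```

The false-positive rates are fractions of the decoy set reaching the
conventional reporting threshold (e ≤ 10); every planted family gene is
recovered and no decoy passes the 1e-10 inclusion cutoff. `out/pairs.tsv`
holds the three planted cognate pairs with their exact geometry — e.g. the
convergent pair on contig_A at a 77 bp intergenic distance:

```
  seq_id luxI_locus luxR_locus  distance_bp    orientation luxR_architecture
contig_A     A_luxI     A_luxR           77     convergent         CANONICAL
contig_B     B_rpaI     B_rpaR           82 co_directional         CANONICAL
contig_B     B_lasI     B_lasR           92 co_directional         CANONICAL
```

while `out/solos.tsv` lists the solitary synthase and the 21 scattered
HTH-only regulators with their exact nearest-partner distances.

For MRM screening, `luxminer mrm --peaks peaklist.csv --out out` matches a
(sample, precursor m/z, product m/z, retention time, peak area) table
against the ten-standard AHL panel and writes verdicts, a Detected/– matrix
and relative peak areas.

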