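# Methods

`luxminer` implements a genome-mining and analytical-chemistry workflow for
*N*-acyl homoserine lactone (AHL) quorum sensing: curate LuxI (AHL synthase)
and LuxR (AHL-responsive regulator) reference sets, build calibrated family
profiles, scan annotated genomes for homologs, classify LuxR domain
architecture, resolve the genomic topology of the hits (cognate *luxI/R*
pairs vs. solos and their neighborhoods), place homologs on trees, and match
LC-MRM-MS peak lists against an AHL standards panel. A synthetic-data
generator supplies ground truth for every stage.

## Reference curation

Curation is the mechanical part of building family training sets from a
protein collection with metadata: bacterial lineage required, length within
100–500 aa inclusive (most LuxI/R proteins are ~200–300 aa), at least one
family domain annotation (LuxI: IPR001690; LuxR: IPR000792 for the HTH,
IPR005143/IPR036693 — integrating PF03472 — for the autoinducer-binding
domain), and case-insensitive description-keyword exclusion (LuxR default
drops "two-component" entries, which can belong to non-AHL systems).
Deduplication removes repeated accessions and repeated identical sequences,
first occurrence winning. Every exclusion carries a machine-readable reason
code. The residual manual, judgment-based part of real curation cannot be
formalized and is out of scope.

## Profile models and e-value calibration

The search engine contract is: score any protein, report a bit score and an
e-value, deterministically. The built-in engine is a position-specific
scoring matrix (PSSM), not a profile HMM: alignment column frequencies with
add-0.5 pseudocounts per residue, log2 odds against a uniform background,
insert-like columns (gap fraction > 0.5) dropped. Training sequences of
unequal length are first aligned by a pluggable aligner (MAFFT when
available). A query is scored by its best gap-free local segment against
the matrix (a gap-free Smith–Waterman over all diagonals), so a protein
containing only one family domain — e.g. an HTH-only LuxR — still scores
its conserved segment at full strength.

E-values are empirical and fitted per model at build time: 200 seeded
random fragments drawn from the pooled training-residue composition are
scored, and a Gumbel law is moment-fit to those null scores (location from
the mean minus Euler–Mascheroni times scale, scale from the standard
deviation). Per-query e-values apply the standard search-space correction
(query length × model length relative to the null's reference space) and
are multiplied by the number of sequences in the scan, so they compose like
whole-database e-values. Per-model calibration keeps every e-value a pure
function of the model and makes scans of large decoy sets cheap. The
default inclusion cutoff is 1.0e-10.

Calibration against a negative set counts "false hits" at a conventional
reporting threshold (default e ≤ 10 over the whole negative set), reports
the false-positive rate, and suggests an inclusion cutoff equal to the
geometric mean of the false-hit e-values (10 to the mean of their log10
values), falling back to the 1e-10 default when no negative reaches the
reporting threshold. Negative sets can be downsampled stratified by genus
(≥1 per genus) to preserve phylogenetic breadth.

An external engine (pyhmmer/HMMER3 Plan-7) is wired behind the same
hit-table schema; in the test suite it serves as an independent cross-check
of the builtin engine's family/decoy separation, never as its replacement.

## Genome scanning

Annotation is required input (FASTA+GFF3 or GenBank); there is no ab initio
gene calling. Coordinates are 1-based inclusive throughout. CDS are
translated with table 11 after reverse-complementing minus-strand features;
trailing stops are removed; features with internal stops ("pseudogene") or
non-codon lengths ("partial") are excluded with logged reasons; supplied
translations are trusted (mismatches log a warning). Hits are at most one
per feature per family, sorted by e-value, and carry an advisory length
class: LuxI typical within 157–257 aa, LuxR within 210–272 aa, inclusive —
a flag, never a filter.

## Architecture classification

LuxR hits are classified on the 2×2 presence table of autoinducer-binding
domain (IPR005143/IPR036693/PF03472) and HTH (IPR000792): CANONICAL,
HTH_ONLY, ABD_ONLY, NONE. Domain evidence comes either from a consumed
InterProScan TSV or from built-in ABD/HTH mini-profiles scanned with the
package's own engine (domain presence threshold e ≤ 1e-5, configurable; no
published value exists for this, so a conventional domain-call threshold is
used). The expected N-terminal-ABD/C-terminal-HTH order is checked only as
an anomaly flag, since classification in this workflow is by presence.

## Topology

The signed intergenic distance collapses gaps and overlaps into one scalar:
abutting = 0, disjoint = bases strictly between, overlapping = −overlap.
Orientation from the strand pair of the positionally ordered features:
co-directional (same strand), convergent (+ then −, 3′ ends facing),
divergent (− then +). Cognate pairing searches |distance| ≤ window
(default 3000 bp, the conventional "local neighborhood" scale) with a
global greedy matching preferring CANONICAL partner architecture, then
smallest |distance|, then smallest e-value — deterministic and independent
of hit order. Unpaired hits become solos carrying the exact nearest
same-contig partner distance (undefined across contigs, never a large
sentinel number). Neighborhood inventories list annotated genes overlapping
±flank (3 kb and 10 kb scales) with signed genome-coordinate offsets and a
first-match keyword categorization of product text (redox/electron
transfer, sulfur–tRNA, secondary metabolism, stress sensing, regulator,
transport, hypothetical, other).

## Phylogenetics

Gap-threshold trimming keeps a column iff its non-gap coverage is ≥ the
threshold (default 0.5, boundary inclusive; recorded in run metadata).
Pairwise distances (p-distance or Poisson-corrected) ignore columns gapped
or 'X' in either member; a pair with no comparable columns is an error
naming the pair. Trees are neighbor joining (scikit-bio's agglomeration)
with taxa fed in lexicographic order for reproducible tie-breaking and
negative NJ branch lengths clamped to zero. Monophyly of a leaf set is
tested in the unrooted sense — the bipartition (set | complement) must be
induced by some edge; singletons, singleton complements and the full set
are monophyletic by convention. Maximum-likelihood inference, model
selection and bootstrap are deliberately delegated to an external-engine
hook that consumes the trimmed alignment and returns Newick; re-implementing
ML search is out of proportion to its role here. Annotated export writes
Newick plus a leaf-annotation TSV and an iTOL-style binary dataset
(canonical vs HTH-only).

## MRM screening

AHL formulas follow from the scaffold: Cn-HSL = C(n+4)H(2(n+4)−3)NO3,
3-oxo-Cn-HSL = C(n+4)H(2(n+4)−5)NO4 (n ≥ 4). Nominal integer masses mirror
unit-resolution triple-quadrupole practice; monoisotopic masses are carried
to 4 decimals. All AHLs share the diagnostic product ion — the protonated
homoserine lactone ring, C4H7NO2+H at nominal m/z 102. A peak matches a
standard iff product ≈ 102 (±mz_tol), precursor within ±mz_tol of the
standard's [M+H]+, and retention time within ±rt_tol when the standard has
one. Defaults mz_tol = 0.5 Da, rt_tol = 0.2 min (unit-resolution
quadrupole practice; both configurable and logged). A peak with the
diagnostic product but no precursor match is a "putative unknown AHL (t_R)";
anything else is ignored; each peak gets exactly one verdict. C7-HSL and
3-oxo-C6-HSL share nominal [M+H]+ 214 — they are resolved by retention time
and flagged ambiguous when no retention time discriminates. The presence
matrix reports Detected/– per analyte × sample; peak areas are carried for
relative comparison only.

## Synthetic data

Families are i.i.d. mutated copies (per-site substitution to one of the 19
other residues) of a seeded uniform-random ancestor; the default rate 0.1
yields ~81% mean pairwise identity (closed form (1−r)² + r²/19), i.e. a
well-conserved protein family. Decoys are uniform-composition random
proteins of 100–400 aa, independent of any family. Canonical LuxR members
are an ABD segment (160 aa) concatenated with an HTH segment (60 aa);
HTH-only members replace the ABD with unrelated sequence; LuxI members are
200 aa — all inside the families' typical length windows. Genome plans
place back-translated members (uniform synonymous codons, table 11, TAA
stop) at specified gaps/overlaps and strands in random background DNA, with
neighbor genes carrying realistic product strings (cysteine desulfurase,
electron transfer flavoprotein, monooxygenase, sensor histidine kinase,
hypothetical protein, ...). The default plan spans the canonical layout
repertoire: a convergent pair 77 bp apart, two co-directional pairs with
regulators 82 and 92 bp upstream of their synthases, a solo synthase in a
redox/sulfur neighborhood with a flavoprotein gene 124 bp downstream whose
partner overlaps it by 46 bp, and 20 scattered HTH-only regulators, each
>3 kb from any partner. When two planted genes overlap, the later one owns
the shared bases, so the earlier one's reading frame is broken there —
realistic for the annotation consumer, and the proteome extractor excludes
it with a logged reason. MRM peak lists plant standards at their reference
retention times with ≤0.1 Da / ≤0.05 min jitter, optional off-grid
diagnostic peaks (true unknowns), and noise peaks whose product ions stay
≥2 Da from 102.

What the generator does not emulate: realistic genome composition and codon
bias, repeats and assembly artifacts, sequence-level homology between decoys
and real protein space, indel evolution within families, chromatographic
peak shapes. Passing tests therefore demonstrate the correctness of the
arithmetic, calibration machinery and ground-truth recovery under the
planted geometry — not database-level sensitivity/specificity on real
proteomes, which depends on the reference snapshot used for training.

## Problem sizes and numerical choices

The shipped tests and examples use 20–30-member families, 1,000-decoy
calibrations, four-contig plans with ~40 genes, and 4–8-leaf tree oracles —
sizes at which every oracle can be brute-forced while each stage still
exercises its full code path. Determinism is pinned throughout: seeded
generators, seeded model nulls, lexicographic tie-breaks in pairing and NJ,
and stable sorts in every emitted table.

## Known limitations

- The builtin engine is gap-free; homologs whose conserved regions are
  interrupted by long indels score only their best single segment.
- E-value calibration assumes the query composition resembles the null's;
  strongly biased proteomes shift the null and the e-values with it.
- Per-genome homolog counts on real genomes depend on the training
  snapshot of the reference databases and are not reproducible from the
  machinery alone.
- The "convergent/divergent" vocabulary is strand-derived; transcriptional
  reality (promoter placement, operons) is not modeled.
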