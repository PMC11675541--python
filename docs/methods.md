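# Methods

`retrokit` identifies retrocopies — gene duplicates created by reverse
transcription of a parental mRNA and genomic reinsertion — in an annotated
genome, and analyses their evolution and expression. This note documents the
models, the parameters that matter, the synthetic-data generator, and the
numerical choices, in the order the pipeline runs them.

## Identification model

A retrocopy is recognisable as a genomic stretch that aligns to an annotated
protein but lacks the introns of the source gene. The caller therefore works
at the protein level:

1. **Six-frame alignment.** Every annotated protein (longest transcript per
   gene; longest = longest CDS in nucleotides, ties broken by transcript id)
   is aligned locally against both strands of the genome with a
   frameshift-tolerant dynamic program: a match consumes one amino acid and
   3 nt; consumes of 2 or 4 nt are allowed at a frameshift penalty of 15;
   scoring is BLOSUM62 with affine gaps costing `11 + 2k` (query gaps per
   residue, target insertions per nucleotide). These values transliterate the
   classic translated-search settings for this kind of screen. Because
   retrocopies are intronless, no spliced alignment is attempted — a retained
   intron simply shows up as a long target insertion, which is exactly the
   signal the intron-loss test consumes. For genome-scale targets an exact
   peptide 5-mer index restricts the DP to seed windows; targets below 10 kb
   are solved exhaustively (this path is verified against a brute-force DP
   oracle).
2. **Candidate filtering.** Hits survive at amino-acid identity > 50%,
   query coverage > 50% and > 50 aligned residues. All thresholds in the
   pipeline are strict inequalities, matching the comparative wording of the
   screening criteria they implement.
3. **Merging.** Same-contig, same-strand, same-query fragments less than
   40 bp apart merge transitively into one candidate locus (fragments of one
   copy, not unrelated hits; opposite-strand hits never merge).
4. **Parent assignment.** Each locus (extended by 150 bp of context) is
   re-aligned against every gene whose CDS spans at least two segments —
   copies of single-exon genes are indistinguishable from DNA-level
   duplicates, so only multi-exon CDS genes can be parents. Genes whose own
   annotation overlaps the locus are excluded: a locus's own (retrogene or
   chimeric) annotation would otherwise compete with the true parent at an
   identical score. Ties break on score, then identity, then alignment
   length, then gene id.
5. **Intron loss.** Each parent intron is mapped to its protein coordinate
   (cumulative CDS length / 3). An intron counts as lost when that position
   lies at least 5 aa inside the aligned span and the alignment shows no
   target insertion of at least half the intron's genomic length within 2 aa
   of it. Both the end margin and the half-length tolerance are `CallerParams`
   knobs; the defaults were chosen so that truncated copies do not claim
   introns at their break points and DNA-level copies (which retain introns
   as insertions) never pass. Records are retained only when they lost at
   least 2 introns, at least one longer than 50 bp.
6. **Dedup.** Loci reached via different query proteins (a planted
   retrogene's own annotation rediscovers its locus) collapse to the
   best-scoring record per overlapping cluster.
7. **False-positive filters.** Parents with more than 10 retrocopies are
   purged together with their records (promiscuous families are dominated by
   repeat artefacts). A record is also dropped when the genome contains two
   or more additional near-identical copies (identity > 80%, coverage > 80%,
   > 80 aa) outside the record and its parent — the signature of segmental or
   TE-driven DNA duplication rather than retroposition. "Multiple" is read
   minimally as ≥ 2 extra copies and is configurable.
8. **Classification.** Frameshift (net indel in the aligned span not
   divisible by 3) or a premature stop (in-frame stop before 90% of the
   aligned parent span; horizon configurable) makes a retropseudogene.
   Otherwise the copy is chimeric when it overlaps an annotated transcript
   with ≥ 2 exons, a retrogene when the overlapping transcript is single-exon,
   and `intact_unannotated` when no annotation overlaps.

Coordinates are 0-based half-open everywhere internally; GFF3 converts at the
boundary. Repeat context is profiled as per-class (SINE/LINE/LTR/DNA/other)
base-coverage proportions over the 10 kb flanks on each side, clipped at
contig bounds with the denominator reduced accordingly.

## Molecular evolution

**Ka/Ks** uses Nei–Gojobori (1986) counting on the codon alignment implied by
the in-frame columns of the parent–locus alignment: per-codon
synonymous-site fractions averaged over both sequences (mutations to stop
codons count as nonsynonymous), observed differences averaged over all
orderings of the single-nucleotide steps with stop-passing pathways excluded
whenever a stop-free pathway exists, and Jukes–Cantor correction
`d = -3/4 ln(1 - 4p/3)`. `p >= 3/4` flags saturation; the ratio is undefined
("NA") when Ks = 0 or saturated. The implementation is tested to 1e-9
against a brute-force pathway-enumeration oracle, and a model-likelihood
alternative was deliberately not used: NG86 is fully specifiable and
oracle-testable. A copy is **young** when Ks < 2, old otherwise.

**Orthology** between two species' retrocopy sequences is called from global
nucleotide alignment (both orientations tried) at identity > 80%, coverage
> 80% (aligned columns over the longer sequence) and > 50 bp. The screening
criteria mix amino-acid identity wording with a bp length; we implement the
nucleotide reading by default and expose an amino-acid mode
(`OrthologyThresholds.level = "aa"`).

A worked example tree (eight lepidopteran species) and a branch/count/period
table ship as package data (`retrokit.molecular_evolution.example_species_tree`
/ `example_period_table`), so the rate arithmetic can be rerun without
constructing inputs.

**Origination branches** come from Dollo parsimony: a retrocopy originates on
the branch above the most recent common ancestor of all species carrying it
(terminal branch for single-species presence). Rates are counts per million
years on externally supplied period spans; the mean rate averages the
unrounded per-branch rates. Ks is reported alongside but not used for
dating — the presence profile alone places the origin.

**Chromosomal traffic.** The null expectation for movement class S→D is
`total × (genes on S / total genes) × (length of D / total length excluding
S)` computed per chromosome and aggregated into Z→A, A→Z and A→A — the
standard gene-traffic null of source proportional to gene content and
destination proportional to available target length. Excess is
`(observed − expected) / expected × 100`. The table builder also accepts
externally supplied expected counts, so published tables can be re-derived
without committing to this null.

## Expression

FPKM matrices are genes × (tissue, stage) samples. "Expressed" defaults to
FPKM > 0 — the only cutoff the screening rules state explicitly (a pair is
dropped when the retrocopy row is all zero) — and is a parameter everywhere.
A record is tissue-specific at a stage when it is expressed in exactly one
tissue there; testis excess is the testis-specific count over the mean of the
other tissues. Parent–retrocopy correlation is Pearson's R with two-sided
p-values, Benjamini–Hochberg adjusted across pairs; categories follow the
|R| bands (strong > 0.8, weak 0.3–0.8, mirror for negative) and are assigned
only at q < 0.05 (raw-p gating available, since the source criteria mix both
phrasings). `Y = log(1+R)/(1−R)` is read as `ln((1+R)/(1−R))` — the literal
alternative (divide a logarithm by `1−R`) is dimensionally incoherent with
its use as a variance-stabilised correlation. Group comparisons
(young/old/parent) use two-sided Mann–Whitney U with BH adjustment; the
criteria state only significance stars, so the test choice is ours and a
Welch t-test is available by flag. The 2^−ΔΔCt utility is plain arithmetic.

## Synthetic data generator

The generator emulates the data the identification assumes, not any
particular genome:

- **Genes.** Random 120 kb contigs (3 by default) carrying 24 non-overlapping
  genes of 3–6 exons; exon CDS lengths 90–330 nt on codon boundaries (all
  phase 0 — a simplification that makes intron protein positions integral),
  introns 60–700 bp, both strands. Genes need ≥ 3 exons to be eligible
  parents, because retention demands ≥ 2 lost introns.
- **Events.** 20 retro events by default: the parent's spliced CDS is written
  over intergenic background (overwriting, not inserting, so no coordinates
  shift), ≥ 2 kb from any feature, with per-site substitution probability
  0.02 by default (0 and 0.05 in the recovery suites). Event classes are
  drawn once per event: frameshift (1–2 bp indel) 2%, premature stop 3%,
  chimeric 55%, annotated retrogene 28%, remainder unannotated — mirroring
  the class proportions a catalog of this kind reports. Chimeric copies land
  ≤ 200 bp downstream of a host gene and receive a new 2-exon annotation
  (host exon + inserted CDS); retrogene copies receive a single-exon
  annotation. TE flanks (SINE/LINE/LTR/other at 35/45/15/5%) of 0.3–1.5 kb
  are placed within 500 bp on a random side and emitted as repeat
  annotation. Five DNA-level duplications (whole gene, introns retained) act
  as negative controls. Parents cycle through a random permutation rather
  than being drawn independently: three or more identical copies of one gene
  are indistinguishable from a segmental amplification and would be removed
  by the DNA-duplication filter, which is correct behaviour but would make
  "perfect recovery" unattainable by construction.
- **Expression.** Log-normal FPKM over 8 tissues × 6 stages. Retrocopy rows
  draw a correlation component against their parent's log-latent — strong
  (ρ = 0.93, sample R ≈ 0.9 after exponentiation), weak (ρ = 0.55) or
  independent, with default weights 0.05/0.30/0.65 matching the reported
  category proportions. A configurable fraction (0.3) is expressed in a
  single tissue only, with testis favoured by a 4.83× weight (the reported
  testis excess); one pair is all-zero to mirror the dropped unexpressed
  pair.

What the generator does **not** emulate: real repeat landscapes (TE flanks
are random sequence, only their labels matter), alignment-ambiguous
paralogous families, UTRs and alternative splicing, sequencing noise in
FPKM, and phylogenetically correlated divergence across species (orthology
tests use paired fixtures sharing planted events instead of forward
simulation). Passing recovery tests therefore demonstrates correctness of
the calling logic under the stated generative model, not performance on real
assemblies.

## Problem sizes and determinism

The recovery suites run on 3 × 120 kb genomes with 20 planted events and
5 controls; unit fixtures use 2 × 60–70 kb with 6–8 events. These sizes keep
each full pipeline run within about a minute while leaving every filter with
work to do. All randomness flows through `numpy.random.default_rng` seeds
carried in the configs; the same seed reproduces byte-identical fixture
bundles and pipeline outputs.

## Known limitations

- Retrocopies of single-exon parents are invisible by construction (the
  method requires lost introns), as are copies whose parent is unannotated.
- The frameshift DP scores a 2-nt consume against 'X' rather than a partial
  codon; scores around frameshifts are therefore approximate, though
  detection (net indel mod 3) is exact on the traceback.
- The DNA-duplication filter cannot distinguish a genuine young multi-copy
  retrocopy family (≥ 3 near-identical copies) from a segmental
  amplification; such families are removed.
- NG86 saturates near Ks ≈ 3; old copies close to saturation return flagged,
  undefined estimates rather than values.
- The traffic null treats retroposition as independent of chromatin context
  and insertion biases; it is a neutral-shuffle baseline only.
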