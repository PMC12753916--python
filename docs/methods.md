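# Methods

## Mutant protein construction

Coordinates are 1-based inclusive in all I/O tables (VCF/annotation
convention) and 0-based half-open internally. The variant table carries a
`cdna_pos` column mapping each coding variant into its transcript;
re-implementing an annotator is out of scope.

* **Missense SNVs** substitute one residue. The mutated CDS is translated
  and required to differ from wild type at exactly one position
  (synonymous or multi-residue outcomes are rejected); the mutated
  interval is that single codon.
* **Frameshift indels** (|Δlen| not divisible by 3) re-translate the
  mutated cDNA from the start codon to the first stop. The mutated
  interval runs from the first residue differing from wild type through
  the last residue before the stop — every such residue is novel, hence
  tumour-specific. Frames that lose the start codon or stop before any
  novel residue raise "null protein".
* **Fusions** concatenate the 5' partner's coding prefix
  (`cdna[cds_start:five_break]`) with the 3' partner's suffix
  (`cdna[three_break:]`) and translate to the first stop. In-frame events
  must break on a codon boundary of the 5' CDS (otherwise "unresolvable
  frame"); their mutated interval is the two residues flanking the
  junction. Frameshift fusions mark everything from the junction codon to
  the stop.
* **Non-coding variants** build a window of `flank` (default 100) bases
  either side of the substituted allele, clipped at contig ends, and
  translate all six frames with stops kept as `*` cleavage points.
  Fragments shorter than `min_len` (default 8, the shortest class I mer —
  shorter fragments cannot yield peptides) or whose codons never touch
  the mutated base are discarded.

Stop-gain/stop-loss and in-frame indels are not constructed; pre-translated
records for them can be supplied directly, since every downstream stage
operates on `MutantProteinRecord`.

## Peptide tiling and wild-type screening

Candidates are all substrings of the requested lengths (8–11 for class I,
15–18 for class II) whose window overlaps the mutated interval — the
"m−n to m+n" window with n = L−1, which leaves no free parameter. Output
is deduplicated per record and ordered by (start, length). An interior
missense residue therefore yields 8+9+10+11 = 38 class I candidates.
Peptides occurring verbatim anywhere in the reference proteome are
removed; by default this screen applies to coding-derived peptides too
(a frameshift tail can coincidentally recreate reference sequence), with
a flag to restrict it to non-coding origins.

## Proteogenomic database and MS evidence

Targets are reference + contaminant + mutant proteins; each target gets
one decoy built by reversing every strict-tryptic fragment in place while
keeping its C-terminal K/R fixed (pseudo-reverse), preserving length,
composition and tryptic terminus statistics. Full-sequence reversal is
available as an option. The spectral search itself is consumed, not
re-implemented: input is a post-search peptide table, with the 1% FDR
enforced at ingestion (q ≤ 0.01) and modified peptides matched on their
stripped sequence. A candidate counts as protein-level supported when an
identified peptide and the candidate contain one another and that
identification is a substring of a mutant entry but of no
reference/contaminant entry; one supporting peptide suffices. I/L
folding is off by default (MS cannot distinguish them; exact matching is
the conservative choice) and available via a flag.

## Filter cascade

Stages run in a fixed order, each recording input/output counts, each
individually disableable, all thresholds configurable. Boundary semantics
follow the published inequalities verbatim: SB iff %Rank ≤ 0.5, WB iff
0.5 < %Rank ≤ 2 (class I), binder iff %Rank < 10 (class II, strict);
expression passes iff TPM > 0 (the quantity is TPM — the "nM" unit
sometimes attached to expression thresholds is a typo); TESLA passes iff
affinity < 34 nM (strict) and TPM > 33 (strict); similarity passes iff
best percent identity > 50 (strict). TPM is looked up at transcript
level with a gene-level-maximum fallback; candidates with no expression
row get TPM 0 with a warning. Similarity is
identities / alignment columns × 100 from a local Smith–Waterman
alignment with BLOSUM62, gap open 11 / extend 1 (the BLAST protein
defaults; the alignment parameters are otherwise unspecified upstream).
Note this is identity over the *local* alignment, so short exact
submatches can score high; the threshold's discriminative power comes
from the curated positive set being small and specific.

The final stage ranks class I survivors by CNN immunogenicity score
(ties: lower %Rank, then lexicographic) with optional top-k or
minimum-score truncation; class II candidates, which the model does not
cover, exit ranked by %Rank.

## Immunogenicity model

Each (peptide, allele) pair is encoded positionally: 20-dim one-hot plus
22 physicochemical descriptors per residue (42 features/position),
peptides right-zero-padded to 11 positions, the allele represented by its
34-residue pseudosequence. The 22 descriptors are curated published
scales spanning hydrophobicity, helix/turn and strand propensities,
polarity/charge/volume/accessibility, composition and other structural
properties; any 22-column residue table can be substituted via TSV. Each
descriptor is standardized to mean 0 / sd 1 over the 20 residues so no
scale dominates.

Architecture: one convolution (kernel 3, 64 filters, ReLU, global
max-pool) per branch; pooled features concatenated with the two global
scalars (TAP transport score and %Rank_EL, min-max scaled on the training
split to prevent scale domination); fully connected 130→128→64→2 with
dropout 0.5 and 0.3 after the hidden layers; softmax cross-entropy.
Training: Adam, learning rate 1e-4, weight decay 1e-3 (L2 on weight
matrices), batch size 256, 50 epochs, stratified 80/20 train/validation
split; a 60/20/20 variant with a held-out test partition is available via
`test_fraction`. The implementation is plain numpy with hand-written
gradients — the model is small enough that a tensor framework buys
nothing, and a single seeded RNG drives initialisation, shuffling and
dropout, making training bit-reproducible on one device. Metrics: AUC,
AUPR, accuracy, precision, recall on the held-out split.

## Synthetic training data

`make_synthetic_dataset` stands in for curated epitope databases.
Positives carry planted anchors (default leucine at P2 and valine at the
C terminus, the canonical anchor positions of many class I grooves,
planted with probability 1) and shifted globals (TAP ~ N(0.8, 0.6),
%Rank ~ Exp(mean 1)); negatives are uniform random 8–11-mers with
background globals (TAP ~ N(0, 0.6), %Rank ~ Exp(mean 8), capped at 100).
Alleles are invented names with random 34-mer pseudosequences. The
default class sizes used in the acceptance run (4,106 / 6,728) mirror a
realistically imbalanced training corpus. With `motif=None` and
`shift_globals=False` the dataset carries no signal and a correctly
implemented trainer must stay at chance AUC.

What this generator does *not* emulate: real anchor-preference structure
per allele, peptide–pseudosequence interaction effects, label noise, and
the redundancy/homology structure of curated epitope sets. A model
passing these tests demonstrably learns planted sequence and global
signal; that says nothing about its accuracy on real immunogenicity data.

## Fixture bundle

`generate_fixture_bundle` writes every pipeline input with planted truth:
5 transcripts (tiny scale; CDS of 40–60 sense codons, 9-nt UTRs), a
1,200-nt contig, variants of every class, one in-frame fusion, emulated
predictor tables whose values straddle every decision boundary (%Rank
pools containing 0.5/2/10 exactly, affinities containing 33.9/34, TPM
containing 33/34), MS identifications including a shared and an
above-FDR row, and a positive set containing exact copies of half the
"golden" record's peptides plus low-complexity padding. One golden
missense record is engineered to survive every stage (rank 0.4, affinity
20 nM, TPM 120, a 30-residue mutant-specific identification spanning its
mutation). The manifest evaluates each stage as a literal flat predicate
over the written tables; the test suite re-derives those sets
independently, including similarity via direct aligner calls.

## Numerical and design choices

* Peptide padding is right-sided zeros; pad rows are all-zero and the
  one-hot block of a real residue sums to exactly 1.
* Deterministic tie-breaks everywhere: tiles by (start, length),
  annotated rows by (record_id, peptide, allele), scores by
  (−score, %Rank, peptide); stable mergesort throughout.
* Degenerate inputs fail loudly: empty epitope lists, single-class
  training data, negative %Rank, duplicate (peptide, allele) binding
  rows, duplicate database ids, reference-allele mismatches.
* Construct grammar: k epitopes ⇔ k−1 linkers; parsing handles both
  annotated dash-separated listings and plain concatenated ORF strings.
  Epitopes containing the AAY linker internally make plain-string
  splitting ambiguous (a warning at assembly; parse from the element
  template in that case). The MITD element ships as a synthetic
  placeholder marking the element boundary — the real trafficking-domain
  sequence is user-supplied, as is the CD40L adjuvant domain. Poly(A)
  defaults to 130 nt within the 120–150 design window.
* Problem sizes: the bundled scales (tiny ≈ 5 transcripts / 12 variants,
  small ≈ 50/200) and the acceptance run's synthetic corpus were chosen
  as the smallest sizes at which every code path (all origin classes,
  both MHC classes, every cascade boundary) is exercised.

## Limitations

Read alignment, variant calling, fusion detection, HLA typing, the
binding/processing predictors themselves, spectral search, immune
simulation and structure modelling are all consumed as inputs, not
implemented. The CNN's reported metrics describe synthetic separable
data only. Class II immunogenicity is not modelled. Fusion junction
frame resolution uses the codon-boundary rule above; real fusion
annotation is messier.
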