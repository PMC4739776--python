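# Methods

## Model and assumptions

`ribocall` treats translated ORF identification as a supervised
classification problem on two read-geometry signals that elongating
ribosomes imprint on ribosome-profiling data and other RNA-protective
complexes do not:

* **3-nt periodicity.** After A-site assignment, reads from a translated
  ORF concentrate on one codon sub-position (roughly 65/24/11% across the
  three positions in cycloheximide data). Off-frame ORFs overlapping a
  translated frame inherit a shifted, minority-position profile.
* **Coverage uniformity (PME).** Elongating ribosomes traverse the whole
  ORF, so reads spread across codons; RNAs protected in non-ribosomal
  complexes (e.g. snoRNPs) pile up at one position. PME is the Shannon
  entropy of per-region read fractions normalized by its maximum,
  `log2(n_regions)`.

The tool assumes alignments are pre-filtered for rRNA and multi-mappers,
that annotated CDSs are correct enough to calibrate offsets, and that one
offset per read length applies dataset-wide.

## Coordinate conventions

All genomic coordinates are 0-based half-open (genePred native; GTF starts
shifted by −1 on read, and the GTF stop codon is folded back into the CDS
span). Transcript positions run 5′→3′ of the RNA regardless of genomic
strand, so ORF arithmetic is strand-free. ORF spans include the stop
codon; all features are computed with the stop codon excluded, and the
encoded peptide length L excludes it as well. Sequences are stored as DNA
(U→T on input); start codons are reported in the RNA alphabet.

## A-site offset calibration

For each read length ℓ, candidate offsets o ∈ [0, 24] are scored by the
fraction of shifted A-sites (5′ end + o, transcript space) that are
in-frame over CDS interiors. Interiors exclude the first and last 15 nt of
each canonical ORF to avoid initiation/termination pileups. Because o and
o±3 tie on frame alone, candidates within 0.02 of the best in-frame
fraction are re-ranked by the A-site mass they place on annotated first
codons (initiation pausing marks the true offset); remaining ties go to
the smaller offset. Lengths with fewer than 100 supporting reads (default)
or best in-frame fraction < 0.5 are dropped from the table — a read whose
length has no calibrated offset is discarded downstream. Calibration with
no reads on any CDS transcript raises an error instructing the user to
supply a default table.

Shifts are performed in transcript coordinates, so a 5′ end three bases
before a splice junction with a 15-nt offset lands 12 nt into the next
exon. A read overlapping several transcripts contributes to each; the
classifier operates per-ORF, so no double-count correction is attempted.

## PME details

Region length is 1 codon when N > L, otherwise ⌊L/N⌋ codons; the number of
regions is ⌊L / region length⌋ and remainder codons join the last region
(L = 10, N = 3 gives regions of 3, 3 and 4 codons). `max H` is
`log2(n_regions)`, the idealized continuous uniform, even when N is not
divisible by the region count. Degenerate inputs are defined, not errors:
N = 0 or a single region yields PME = 0 and the ORF is flagged
unexpressed/unevaluable. The entropy uses the standard negative sum with
0·log 0 := 0, keeping PME in [0, 1].

## Classifier

Features are (f₁, f₂, PME); f₃ is omitted as redundant with f₁ + f₂.
Training pools follow the method's construction — positives: canonical
ORFs; negatives: AUG-started off-frame ORFs inside coding regions plus
candidate ORFs on short non-coding RNAs — all under the expression filter
(RPKM > 1 and strictly more than 10 reads). Default sampling sizes are
600/300 (train) and 600/300 (test), drawn disjointly without replacement
from a mandatory seed; tests and the simulator-scale analyses shrink these
to the available pools.

The SVM uses an RBF kernel with C ∈ {0.1, 1, 10, 100} and γ ∈ {0.01, 0.1,
1, 10} selected by 5-fold stratified cross-validated ROC AUC. Simulated
(and well-behaved real) training sets are separable, tying much of the
grid at AUC 1; ties are broken toward the most local kernel (largest γ,
then smallest C), because on the bounded [0, 1] feature scale the tied
smooth models extrapolate aggressively into the region between the
training clusters — exactly where noisy untranslated ORFs fall — while the
local model leaves them below the calling cutoff. Probabilities are Platt
sigmoid-calibrated inside cross-validation on the selected kernel. Calls
use probability ≥ 0.7. Among called ORFs sharing a stop, the
representative start restricts to AUG members when present, takes the
5′-most, and advances downstream whenever the inter-start window holds no
A-site reads.

## Quantification

The Poisson expression null gives transcript *t* rate λ_t = library size ×
length_t / Σ lengths over the tested set (an effective-transcriptome rate;
an intergenic background rate can be substituted by passing different
lengths). p = P(Poisson(λ_t) ≥ observed), BH-corrected across tested
transcripts; expressed means q < 10⁻³ and > 10 reads, or encoding a called
peptide. TE requires > 10 reads in both libraries over the same span and
at least 50% of the span free of other-type ORF overlap (per-nucleotide
mask); zero RNA RPKM with an otherwise eligible ORF is flagged infinite
and excluded from summaries. The cytosol:nucleus ratio uses ε = 0 with
explicit exclusion of zero denominators (pseudocount mode optional) and a
floor of more than 50 total RNA-seq reads.

## NG86 Ka/Ks

Site counts enumerate the nine point mutations per codon, with mutations
creating stop codons counted nonsynonymous. Differences average over all
minimal mutational pathways (1/2/6 orderings); pathways through stop
intermediates are excluded, falling back to all pathways when every one is
blocked. Sites are averaged across the two sequences; pS = Sd/S and
pN = Nd/N are Jukes–Cantor corrected (−¾ ln(1 − 4p/3)); p ≥ ¾ raises a
saturation error and Ks = 0 flags the ratio undefined rather than
dividing. Inputs are gapless codon alignments — homolog pairing and
alignment (Liftover/BLASTP in the original workflow) are out of scope.
Ambiguous-base codons are skipped. The genetic code table is configurable
(NCBI table 1 default).

## Synthetic data: what it emulates, what it does not

The generator plants, per seed: multi-exon mRNAs (1–4 exons, random
strand) with clean canonical CDSs and optional translated uORFs/dORFs;
lncRNAs with a translated ORF in a configurable fraction; pseudogene-like
transcripts with untranslated ORFs; and sub-200-nt short-ncRNA
contaminants carrying single-A-site pileups. Translated ORFs receive
per-codon ~uniform reads with the 65/24/11 phase mix, a mild 3× initiation
boost at the first codon, lengths 24–31 nt (peaked at 28) and true offsets
12–18 nt; untranslated ORFs receive sparse phase-random reads (~40 per
ORF); RNA-seq coverage is phase-free uniform. An 11-nt all-frame stop
cassette insulates planted uORFs/dORFs so their stop is not first
reachable from an upstream start inside read-rich regions — real
transcriptomes do produce such merged stop groups, so representative-start
behavior there is exercised separately in unit tests rather than through
the generator. Reads are emitted pre-aligned (SAM with spliced CIGARs and
reference-matching sequences); sequencing error, rRNA contamination, UMI
structure and fragment-bias are not modeled. Passing recovery tests on
these data therefore demonstrates correctness of the pipeline's logic, not
robustness to real-library artifacts.

Default scales (e.g. 40–110 mRNAs, ~300 reads per translated ORF, ~200
per contaminant) give tens of thousands of reads per run — large enough
that per-length offset support exceeds the 100-read floor and per-ORF
binomial noise on f₁ is small, while keeping any simulation under a few
seconds.

## Numerical and design choices

* Offset tie tolerance 0.02 on in-frame fraction; support floor 100 reads;
  in-frame floor 0.5; interior trim 15 nt.
* Read-length window 24–31 nt, configurable.
* Biotype rules: overlap means ≥ 1 shared exonic base on the same strand;
  lncRNA requires introns or length > 500 nt; short ncRNA < 200 nt;
  precedence mRNA → short_ncRNA → pseudogene → lncRNA → unclassified.
* Near-cognate starts (CUG/GUG/UUG) are allowed for all ORF classes,
  configurable.
* Discovery floor 6 aa (shorter peptides give PME too few codons);
  reporting can further threshold at 10 or 100 aa.
* An off-frame ORF starting inside the CDS and ending past it is typed
  `internal`.
* Strict inequalities on read floors: exactly 10 reads fails "> 10 reads";
  exactly 50 total reads fails the cytosol:nucleus floor.

## Known limitations

* The genome-position index hashes every exonic base; appropriate for the
  targeted transcriptome scales, not for whole-genome hash-free streaming.
* One offset per read length; no per-sample or 5′-context refinement.
* The classifier is per-ORF and ignores shared reads between overlapping
  transcripts and isoforms.
* Harringtonine data are accepted for metagene QC only; initiation-site
  peak calling is out of scope.
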