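# Methods

This note documents the models and procedures implemented in `gisland`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions that matter for
reproducing its output.

## Coordinates and sequence conventions

All internal coordinates are 0-based half-open on the forward strand;
readers and writers convert at the boundary (GenBank and GFF3 are 1-based
inclusive, BED is half-open).  On circular replicons a feature may wrap
the origin and is stored unwrapped (`start < length <= end`).  Ambiguity
codes other than N are preserved in sequences but treated as N — i.e.
excluded — by every composition statistic; GC fraction is
`(#G + #C) / (#A + #C + #G + #T)`.  Percentages in reports are rounded
half-up to one decimal.  Pseudogenes are parsed but excluded from
codon-usage and proteome-level analyses, mirroring annotation tables that
separate pseudogenes from intact genes.

## GC z-scores

Per-ORF GC is computed on the coding strand and standardised against the
mean and *population* standard deviation of the whole ORF set: the ORF
set is the complete population of interest, not a sample, and the
population SD makes thresholds such as "2.5 SD below the average"
reproducible exactly.  The default low-GC evidence threshold is
z ≤ −2.0: the most extreme genes of a genuinely alien region can sit at
−2.5 or below, but −2.0 admits the whole region; precision is recovered
at the island-calling stage, not at the flag level.

## GC-skew and skew reversals

Windowed skew is `(G − C)/(G + C)` per window (0 where a window has no
G or C), default window 10 kb and step 1 kb, smoothed by a centred
5-window moving average.  These defaults resolve the two replichores of a
Mb-scale chromosome while staying meaningful on a 77 kb plasmid (the
pipeline shrinks the window to length/10 on short replicons).  A reversal
is a boundary between opposite-sign smoothed runs each persisting at
least 5 windows; on circular profiles the run structure is examined
circularly so a flip at the coordinate origin is not missed.  The
cumulative per-base (G − C) sum has its global minimum at the replication
origin and maximum at the terminus under the standard two-replichore
model; both extrema are reported as ori/ter candidates, and every
persistent reversal is also exported as a "disruption" interval, the
island-evidence form of locally anomalous strand bias.  Both the
window-level and the cumulative detector are exposed because either
reading of "disruption of GC-skew" is defensible.

## CAI, bootstrap eCAI, normalised CAI

The reference codon-usage table counts codons over all intact ORFs of the
host replicon.  Relative adaptiveness is `w = count / max count` within
each synonymous family (bacterial code, table 11), with zero counts
replaced by 0.5 *before* computing w so that every w is positive and CAI
can be computed in log space (Sharp–Li convention).  Stop codons are
never scored; Met (ATG) and Trp (TGG) are excluded as single-codon
families carrying no usage information.

The expected CAI asks: what CAI would a random gene encoding this exact
protein get against this table?  The null re-encodes the query's
amino-acid sequence with synonymous codons drawn uniformly — the
least-informative null, which makes the "5% level of significance"
operational without further modelling choices — `n_boot` times and takes
the 95th percentile of the resulting CAI distribution.  Defaults:
`n_boot = 500`, `quantile = 0.95`, deterministic given a seed.  The
genome-wide recovery loops use `n_boot = 200`, which changes the
percentile estimate by less than the seed-to-seed spread while keeping
100-replicate calibrations fast.  The normalised CAI is CAI/eCAI and the
foreign flag is exactly `normalised < 1.00`.  Because the E-CAI
literature offers both amino-acid-preserving and nucleotide-Markov
generators, exact third-party normalised values are not promised — only
the <1.00 / ≥1.00 classification, which is what downstream island calling
consumes.

## Motif scanning, cytochrome census, in-silico PCR

Patterns are IUPAC strings with `(x|y)` alternation groups, scanned with
overlaps on both strands; circular scans include origin-spanning matches.
The c-type cytochrome census counts all (overlapping) CxxCH occurrences
per protein — heme attachment is positional, so each occurrence is a
potential binding site; note that census counts can shift by small
integers versus conventions that forbid overlaps.  The homology screen
retains a candidate iff at least one reference hit exists and ≥50% of its
hits (e-value ≤ 1e−5) are labelled c-type cytochromes; "lacking over
50%" is read literally, so exactly 50% retains.  Screening is single-pass
homology search, not iterative profile search; profile iteration is out
of scope, and on the synthetic benchmark the single pass separates
planted cytochromes from decoys essentially perfectly.

In-silico PCR matches the forward primer on the plus strand and the
reverse primer as its reverse complement downstream; product length
counts both primers inclusively, default ceiling 10 kb.  Exact annealing
is required by default; when mismatches are enabled they are never
permitted in the three terminal 3′ bases of either primer, mimicking
polymerase extension specificity.

## Local alignment, AAI, diffing

Protein alignment is optimal Smith–Waterman with affine gaps via
Biopython's C PairwiseAligner; identity is identical columns divided by
alignment length including gaps (the denominator convention is stated
because published identity figures rarely state theirs; expect ±1-point
differences against tools that divide by the shorter sequence).
Significance follows Karlin–Altschul `E = K·m·n·e^{−λS}` with the
published gapped constants for BLOSUM62 11/1 (λ = 0.267, K = 0.041) and
BLOSUM45 14/2 (λ = 0.195, K = 0.032); for database searches n is the
total residue count of the database.  Best hits take the highest bit
score with ties broken by lexicographically lower subject id, so results
are deterministic.  AAI is the mean best-hit identity, one-way (A→B) as
in top-hit accounting; reciprocal-best filtering is available but off by
default.

Near-identical nucleotide sequences (e.g. two assemblies of the same
plasmid) are diffed by anchoring on 31-mers unique to both sequences,
chaining anchors colinearly (longest increasing subsequence, overlapping
anchors pruned), refusing when anchors cover <50% of the reference, and
aligning inter-anchor gaps globally (edit-distance alignment); emitted
SNP/insertion/deletion records are checked on every call to reconstruct
the query exactly from the reference.

## Repeats and tandem duplications

Maximal exact repeats use seed-and-extend over a k-mer index with
k = the minimum reported length (default 15, the scale of the repeat
motifs relevant to plasmid replicon regions), chosen over suffix
structures because desk-scale inputs make the simple algorithm fully
oracle-verifiable.  A pair is maximal when one-base extension breaks the
match.  Inverted repeats are reported with disjoint arms and inward
extension stops when the arms would cross; this convention avoids
degenerate self-pairings on perfect palindromes and is what
terminal-inverted-repeat detection needs.  Tandem duplications merge
direct-repeat seeds sharing one diagonal offset across the single-base
interruptions that substitutions cause, cap the block at the duplication
period, and score the two blocks by global-alignment identity rounded to
one decimal (identical columns / alignment length) — the precision at
which near-identical duplicated blocks are conventionally reported.

## Island calling and origin prediction

Evidence is three-valued (True/False/unknown): an absent input — no
reference proteomes, say — leaves its flag unknown, which counts neither
toward nor against the hot threshold, so missing data cannot silently
strengthen or weaken calls.  An ORF is hot with ≥2 True flags
(`min_flags`); runs of hot ORFs tolerate ≤2 interleaved cold ORFs
(`max_gap_orfs`) and become islands with ≥4 hot ORFs (`min_orfs`).  The
source material for such analyses says only "and/or" about how many
evidence types suffice, so `min_flags = 2` is a design choice balancing
the ~5% marginal false-flag rates of the individual evidence types; the
false-positive calibration (below) validates it.  Tightening any
threshold can only reduce the number of calls (property-tested).

Origin candidates are windows (default ±1 kb) around cumulative-skew
extrema, persistent reversals, and free-standing DnaA-box clusters,
requiring ≥2 box matches (`TT(C|A)TCCAC(A|G)`, both strands) and scored
by box count then by cumulative-skew extremity normalised to the
cumulative range.  A cumulative range within random-walk noise
(4·√(G+C count)) scores 0 — a flat-skew replicon still reports its box
clusters, flagged as low confidence.

## The synthetic generator

The generator emits the study conditions the detectors are calibrated
under: a host of ~300 kb (desk scale for a 3.9 Mb-class analysis) at
54.8% GC with a Dirichlet-biased host codon regime (concentration 0.25,
i.e. strongly biased usage typical of a fast-growing bacterium), genes of
300 ± 80 codons on random strands separated by 50–200 bp spacers, a
replichore G/C tilt of amplitude 0.2 flipping at the planted origin
(terminus at the coordinate origin), and planted features: a 30-ORF
island at 37% GC under a uniform-synonymous (alien) regime, a 4-box DnaA
cluster at the origin, tandem duplications (default 2,466 bp with 5
substitutions placed ≥50 bp from the block edges and from each other, so
the duplicated span is recoverable exactly), primer sites, cytochromes
with prescribed CxxCH counts homologous to a generated labelled reference
set, CxxCH decoys with no homologs, and optional diverged reference
proteomes (default 30% per-site divergence) for AAI/presence tests.
Codon-level GC targets are met by solving a one-parameter exponential
tilt over synonymous families against a fixed typical bacterial
amino-acid composition (achievable coding GC ≈ 0.30–0.68).  Generation is
fully deterministic per seed, and every planted feature is recorded in a
TSV-serialisable ground truth.

Not emulated: indels within genes, codon autocorrelation, repeat-rich or
low-complexity DNA, amelioration gradients, mobile-element gene content,
or any regulatory structure.  Recovery rates measured here therefore
characterise the detectors under clean, fully specified composition
signals — an upper bound on, not an estimate of, performance on real
genomes.

## Calibration results recomputed by `scripts/acceptance.py`

The acceptance script re-measures, from freshly generated data: exact
agreement of the aligner with a quadratic DP oracle (1,000 pairs ≤60 aa,
both scoring systems), of the repeat finder with an exhaustive
diagonal-scanning oracle (100 seeded 2 kb sequences), and of the pattern
scanner with a positional oracle; island recovery (interval Jaccard ≥0.8)
and origin localisation (±5 kb) over 100 seeded replicons; recovered
duplication length/identity; cytochrome screen accuracy over 100 planted
cases; the empirical fraction of uniform-null genes passing the eCAI cut
(nominal 0.05); and the island false-positive rate on island-free
genomes.  The problem sizes above are the package's chosen desk-scale
study conditions; the verification paths that need the deposited
multi-megabase accessions run only when those flat files are supplied
locally.

## Known limitations

* The homology screen approximates an iterative profile search with a
  single alignment pass; distant cytochrome homologs below pairwise
  detectability would be rejected.
* E-values use two precomputed Karlin–Altschul parameter sets; other
  matrix/gap combinations raise rather than extrapolate.
* The tandem-duplication extender assumes substitution-dominated
  divergence between blocks (indels between blocks shift the diagonal
  offset and fragment the merge).
* Island calling operates on ORF runs; islands shorter than `min_orfs`
  genes or lacking two independent evidence types are not callable under
  defaults.
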