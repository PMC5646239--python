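# Methods

## The problem

Endogenous viral elements (EVEs) are virus-derived sequences fixed in host
germlines; exogenous viral DNA can also end up in a whole-genome shotgun
(WGS) assembly simply because the virus was present in the sequenced sample.
Telling the two apart matters: an EVE is a fossil, an exogenous sequence is
(probably) a circulating virus.  `evescreen` implements the complete desk
workflow for this question on parvovirus-like sequences: a translated
homology screen over assembly contigs, merging of hits into candidate loci,
genus-level classification, ORF/motif annotation, degradation-based
EVE-versus-exogenous adjudication, and distance-based phylogenetic placement
with bootstrap support.

## Screening model

Every contig is translated in all six frames (standard genetic code; any
codon containing `N` becomes `X`; stops are rendered `*`).  Every probe —
a curated polypeptide labelled with genus (`taxon`) and gene (`NS`
replicase / `VP` capsid) — is aligned against every frame with an exhaustive
affine-gap Smith–Waterman. There is no heuristic seeding: at desk scale,
full dynamic programming is affordable and guarantees that arbitrarily
divergent loci score optimally.

Scoring: BLOSUM62 over the 20 amino acids, with two policy entries.  `X`
scores 0 against everything; `*` scores −4 against everything, and
alignments are *not* split at stops.  A degraded EVE must remain alignable
as one piece — its stop codons are evidence to be counted downstream, not
alignment boundaries.  Gap model: a gap of length L costs
`gap_open + (L−1)·gap_extend`, defaults 11/1; default score threshold 60;
all parameters config-exposed.  Within each probe × frame, *all*
non-overlapping local alignments at or above the threshold are kept (the
optimum is extracted, masked in the subject, and the DP re-run): the
multi-fragment chains of a frameshifted locus are precisely the evidence the
adjudicator needs.

Hits on one contig and strand within `max_gap_nt` (default 1000) merge into
a locus regardless of frame.  Two hygiene rules, both standard screening
practice, govern how hits are *interpreted*:

- **Shadow filter.** The reverse-complement reading of a real viral gene
  often aligns weakly to the probe family.  A locus ≥80% covered by an
  opposite-strand locus with at least twice its score is discarded as an
  antisense shadow.
- **Fragment chaining.** Gene-structure evidence (gene spans, stop counts,
  frameshift counts, gene content) is computed from the best collinear
  fragment chain per probe — fragments must advance along both probe and
  contig, with bounded overlap (30 aa / 90 nt) — restricted to probes of the
  assigned taxon.  Weak off-diagonal echoes of a probe, and marginal hits
  from other genera, say nothing about the locus's own gene structure.

Genus assignment uses an explicit score-margin rule standing in for
reciprocal-best-hit confirmation: the taxon of the best-scoring hit wins iff
it beats every other taxon's best score by ≥ `margin_min` (default 30);
otherwise the locus is `unclassified`.

## Annotation and adjudication

ORFs are deterministic: ATG-initiated, stop-terminated (interval includes
the stop codon), standard code, minimum 100 aa by default; stop-free
stretches touching a contig end are reported as incomplete calls for
truncated contigs.  Per gene, the complete ORF that best *covers* the gene's
hit span is selected — coverage rather than raw length, because slightly
overlapping NS/VP genes mean the long replicase ORF also touches the capsid
span.  A gene counts as full-length when its ORF covers ≥80% of the gene's
hit span and the span contains no stops.

Motif scanning is exact-match with `X` as a two-sided wildcard.  Default
replicase (NS1) set: `HVH`, `HIH` (endonuclease metal coordination),
`GPXNTGKS`, `GPASTGKS` (helicase P-loop).  Default capsid set: the
canonical parvoviral phospholipase A2 signatures `YXGXG` (calcium loop) and
`HDXXY` (catalytic), scanned in the N-terminal third of VP.  Both sets are
config-overridable.

The integrity report counts: internal stops (`*` in the union of
chain-covered peptide regions, per gene); frameshifts (frame changes between
consecutive fragments of the *same probe* — NS and VP legitimately occupy
different frames whenever their ORFs overlap by a non-multiple of 3, so
cross-gene and cross-probe frame differences are not evidence); repeat
overlap (from an externally supplied repeat/TE annotation — no repeat finder
is implemented); and an externally asserted host-flank flag.

Adjudication is a pure function: any degradation flag ⇒ `putative_eve`;
no flags plus at least one full-length gene ORF ⇒ `putative_exogenous`;
otherwise `ambiguous` (typically a truncated contig).

Gene overlap is frame-agnostic signed interval arithmetic on the two ORF
intervals: positive = overlap nt, negative = gap nt.

## Phylogenetics

Maximum-likelihood inference is deliberately out of scope; the implemented
stand-in is: optimal affine-gap global (Needleman–Wunsch) pairwise
alignment; percent identity = matches / aligned columns after trimming
terminal-gap overhangs; center-star progressive MSA (center = maximal summed
pairwise identity, once-a-gap-always-a-gap merging); p-distances over
mutually ungapped columns; canonical neighbor joining (Q-criterion,
deterministic lowest-index tie-breaks, negative branch lengths clamped to
zero with the deficit moved to the sister edge).  NJ is exact on additive
matrices — that exactness is the module's primary correctness oracle, and it
is also cross-checked against dendropy's NJ on noisy matrices.

Support comes from a column bootstrap: resample alignment columns with
replacement, rebuild the NJ tree, and report the percentage of replicates
containing each original bipartition.  Trees are midpoint rooted (root at
the midpoint of the longest leaf-to-leaf path; all leaf-to-leaf path lengths
are preserved) and tips carry host-class/geography annotations from a
metadata table, serialized as NHX comments in newick.  A conserved-region
hook (`region_aa`) can restrict the MSA to columns spanning a coordinate
window on a chosen reference row.

## What the generator emulates

The synthetic module is the package's test substrate and defines its study
conditions.  It emulates:

- **Host background**: i.i.d. nucleotide contigs at configurable GC
  (default 0.41), 6 contigs of 7–9 kb by default.
- **Genome architecture**: one planted locus per contig — a ~660 aa
  replicase followed by a ~500 aa capsid on one random strand, ORFs
  overlapping by 8, 10 or 11 nt, with the capsid start codon inside the
  replicase stop region in a different frame.  The overlap junction is
  solved exactly: the replicase frame reads through the shared nucleotides
  and meets its first stop codon precisely at the overlap's final 3 nt,
  which the construction places inside the capsid's codons.  An overlap
  divisible by 3 is rejected as geometrically impossible (it would force
  both genes into one frame, where the replicase stop becomes an internal
  capsid stop) — which is why the feasible "slight overlap" regime is
  {8, 10, 11} rather than 8–11 inclusive.
- **Divergence**: planted proteins are evolved from library probes by
  site-independent uniform substitution (probability = divergence, default
  0.3, replacement uniform over the other 19 residues; no rate matrix — the
  regime, not the process, is what matters here), then reverse-translated
  with uniform synonymous codons.
- **Degradation** (EVE-like plantings): engineered stop codons in the
  replicase body (default 2), frameshifting single-nt deletions in the
  capsid (default 1), and optionally a fixed synthetic 300 nt repeat
  element inserted into the replicase and emitted as a BED annotation, so
  the repeat-overlap adjudication path is testable without a repeat finder.
- **Insulation**: each planted cassette is flanked by 12 nt triple-frame
  stop insulators so that called ORFs cannot bleed into background sequence
  and ground-truth ORF coordinates are exact.  Constructions are validated
  by re-running the ORF caller and resampled on the rare failure (an
  accidental upstream in-frame ATG).

A deterministic synthetic probe library (fixed internal seed, independent of
run seeds) stands in for a curated reference set: two chapparvovirus NS
probes carrying the four NS1 motifs verbatim, two chapparvovirus VP probes
carrying the PLA2 motifs in their N-terminal third, and unrelated NS/VP
probes for three other genera so genus assignment has real competitors.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: repeat-rich and low-complexity host backgrounds,
codon-usage and composition bias, assembly artefacts (chimeras, collapsed
duplications, truncated contigs except as tested explicitly), insertion-site
target-site duplications, and realistic substitution processes.  Sensitivity
of 1.0 at ≤40% divergence on this substrate bounds the aligner's behaviour,
not the false-negative rate of a real WGS screen.

## Problem sizes and numerics

Default evaluation sizes, chosen to keep a full run on one CPU in minutes:
6-contig ~50 kb assemblies, 10 probes, 20 replicate seeds for recovery
statistics; 100 random 5–8 leaf additive matrices for NJ exactness; 500
random peptide pairs (length ≤ 8) against an independent memoized-recursion
scoring reference; 100-replicate bootstraps on 12-taxon, 160-column protein
families.  DP kernels are integer-scored and numba-compiled; all ties are
broken deterministically (first maximum in row-major scan; diagonal over
gap in traceback; lexicographic pair order in NJ and midpoint rooting).
Every stochastic step takes an explicit seed and identical config + seed
reproduces byte-identical outputs.

## Known limitations

- Exhaustive DP scales as (probe aa) × (contig nt × 2); it is meant for
  desk-scale screening, not hundreds of genomes.
- E-value statistics are not computed; the raw-score threshold is explicit
  but not length-normalized.
- NJ on p-distances underestimates deep divergences relative to ML with a
  substitution model; the tree is a placement aid, not a final phylogeny.
- The EVE adjudication is conservative about `flank_genomic`: host-flank
  evidence must be asserted by the caller (e.g. from orthology of flanking
  sequence); the pipeline itself only sees degradation signals.
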