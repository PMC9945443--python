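# Methods

## Coordinate model

All construct coordinates are 0-based half-open. Guide-relative positions
use the small-RNA convention: position 0 is the target nucleotide pairing
the guide's 5′-most nucleotide (nt 1), and the nucleotide pairing guide
nt k sits at −(k−1). Because the guide anneals antisense to its site,
positions increase 5′→3′ along the construct and a site of guide length
L occupies −(L−1)..0. Slicer cleavage falls between the nucleotides pairing
guide nt 10 and 11 (positions −10 | −9): the downstream (pre-piRNA)
fragment starts at −9, the upstream (by-product) fragment ends at −10, and
a by-product with its 5′ end at −26 (−28) is therefore 17 (19) nt. Cleavage
inference inverts this: a 5′-end pile-up at p\* within the paired window
[−(L−1), 0] implies cleavage after guide nt k = 1 − p\*. The search is
restricted to that window because only those positions correspond to a
guide index — on a tandem reporter the next site's fragments also produce a
(smaller) 5′-end peak at +36 in the previous site's frame.

## Reporter and guide defaults

The true sequence of the targeting piRNA is not public, so the default
guide is a fixed synthetic 30-mer chosen to preserve the sequence-level
facts that matter: it begins with U (the piRNA 1U bias), nt 10 = C and
nt 11 = A, so that pre-piRNAs from perfect sites begin with G and those
from the default bulge sites begin with C. Sites are exact reverse
complements of the guide; bulge sites substitute non-complementary,
non-wobble transversions at the positions pairing guide nt 10 and 11
(G:U wobble would arguably still pair, so it is avoided by construction).
The default layout is 10 tandem 30-nt sites separated by a fixed 15-nt
spacer — a 45-nt repeat unit, matching the observed inter-cleavage
fragment size — inside fixed 50/60-nt UTR-like flanks. Only the repeat
unit is constrained by data; the actual spacer and flank sequences are
package choices.

## Library simulator

The simulator emulates a PIWI-IP small-RNA library as a labelled mixture:

| class | default share | geometry |
|---|---|---|
| mature | 0.80 | pool species prefixes; lengths ≈ round(N(mode, 1.5)), mode 26 (MILI-like) or 30 (MIWI-like); 90 % of species start with U |
| pre | 0.08 | one site's cut to one nt before the next cut; last site: 45 nt downstream |
| byproduct | 0.05 | ends at −10; 5′ offset −26 or −28 (1:1 by default) |
| phased | 0.00 | head-to-tail 26–30-nt pieces from a cut; off by default because its absence is the phenomenon of interest |
| background | 0.07 | uniform construct positions, 15–35 nt |

Class counts are allocated deterministically (largest remainder); all
randomness flows through one seeded generator, and a fixed seed gives
byte-identical FASTQ. A constant-quality Phred string and an optional
appended 3′ adapter complete the records. The simulator reproduces the
*positional* structure of a real IP library, not its amplification biases,
sequencing errors, ligation biases, or genome-wide read diversity — passing
tests therefore demonstrate that the analysis recovers planted signal
exactly, not that it is robust to every artefact of real data. The
`mature` pool is synthetic; real libraries draw from thousands of genomic
piRNA loci.

## Read preprocessing

Trimming implements a deterministic subset of standard small-RNA adapter
clipping with the conventional parameter set (3′ adapter
AGATCGGAAGAGCACACGTCT, minimum length 15 nt, error rate ≤ 0.2, minimum
overlap 4, quality cutoff 10): BWA-style 3′ quality trimming first
(a no-op on constant-quality simulated data, but implemented), then a
semi-global alignment of the adapter against the read allowing
substitutions and indels, with `N` in the read matching any adapter base.
Candidate occurrences are ranked by (fewest errors, longest overlap —
counted in adapter bases — leftmost start); exact hits take an O(n) fast
path that is provably consistent with this ranking. Whether quality
trimming preceded adapter search in typical published runs is ambiguous;
the order here is fixed and documented. Error-tolerant trimming is not
idempotent in general — after a genuine hit is removed, the insert's own
3′ suffix can fall within the error budget of a short adapter prefix —
so the test suite asserts monotonicity plus idempotence on inserts that
cannot mimic the adapter.

## Mapping and normalization

Reads are placed by exhaustive exact substring search (zero mismatches,
all occurrences kept — with no mismatches every hit is tied). The default
is sense-strand only, since reporter-derived fragments are sense;
antisense search is a flag. A read's count is split evenly across its
hits (weight 1/n) and normalized to reads per million; the library size
denominator is the number of reads surviving preprocessing (the exact
denominator used in published rpm figures is rarely stated — it is
configurable here). Reads spanning the construct end are unmapped; there
is no circularity. The ≥ 0.05 rpm display filter is applied only to the
per-site read listing, never to the statistics.

## Site assignment and metaplots

A hit enters a site's frame when its 5′ end lies within the site window,
default −(L+15)..+(repeat+5) = −45..+50. Windows of adjacent tandem sites
overlap by design: an inter-cleavage fragment belongs to the site that cut
its 5′ end *and* appears at +36 in the previous site's frame. Per-site
coverages count a hit fully in every window it enters; the cross-site
metaplot divides each hit's rpm by the number of windows entered, so the
metaplot plus the intersite bucket conserve total mapped rpm exactly
(hits outside every window are kept in that bucket, never dropped).
"Body" coverage is interpreted as per-position summed rpm over full read
extents and implemented alongside 5′/3′-end coverage; the length-by-start
matrix's row marginals equal the 5′-end metaplot by construction.

## Classification and phasing

Each site-assigned read gets exactly one category, evaluated in fixed
priority order — pre-piRNA (p5 = −9 ± tol) > by-product (p3 = −10 ± tol) >
mature-like (26–30 nt) > phased-candidate > unclassified — because
slicer-end evidence is the primary signal: a 17-nt read starting at −26
necessarily ends at −10 and is a by-product, not a short mature read.
`tol` defaults to 0 (slicer ends are nucleotide-exact); it exists for
noisy real data. The −26 and −28 by-product 5′ ends are treated as one
category with a length spectrum rather than two protein states.

Phasing detection measures two fractions downstream of each cut:
(a) the head-to-tail fraction — rpm of piRNA-sized (26–30 nt) reads whose
5′ end continues a chain anchored at the cut (each link one past the
previous link's 3′ end). Chain links must themselves be piRNA-sized, and
5′ ends coinciding with the next tandem site's cut are excluded: adjacency
there is created by slicing at the next site, and without both
restrictions chance adjacency among background reads seeds spurious
chains on dense data. (b) The mature-size fraction — among reads starting
at the cut, the rpm share that is piRNA-sized rather than running to the
next cut. Both thresholds default to 5 %; the verdict is "phasing absent"
only when both fractions fall below threshold, "insufficient data" when
no slicer products or downstream reads exist. The thresholds are
configuration, reported alongside the raw fractions, since the underlying
biology is reported qualitatively.

## Complementarity scan

Each pool piRNA is anchored with its 5′ end at the site anchor (position
0) and compared base-by-base by strict Watson–Crick complementarity; G:U
wobble counts as a mismatch by default (a flag counts it as a match).
The registration is ungapped and anchored; an optional ±s slide takes the
minimum-mismatch register. Positions beyond the site are marked overhang
and excluded from the mismatch count. Profiles are reported up to a
mismatch ceiling, sorted by (mismatches, −abundance).

## Problem sizes and numerical choices

The shipped demos use 8,000-read libraries and a 1,000-entry pool, which
reproduce every qualitative contrast in about a second. The acceptance
script uses 5,000-read slicer-product libraries and, for the length-mode
recoveries, 50,000 mature reads per library — comfortably past the point
where the 26/30-nt histogram modes are stable across seeds. Modal
statistics break ties toward the smaller position/length deterministically;
cleavage-site ties warn and return the smaller guide index. rpm values are
exact ratios of integers over the library size; no floating-point
tolerance enters any classification decision.

## Known limitations

* The simulator's mature pool and decoy background are synthetic; mapping
  rates and rpm magnitudes are not comparable to real libraries, only the
  positional signatures are.
* Exact (zero-mismatch) mapping means a single sequencing error unmaps a
  read; real-data use should expect lower sensitivity than an aligner with
  mismatch allowance, by design matching the original zero-mismatch
  analysis contract.
* The phasing verdict is a thresholded heuristic over two interpretable
  fractions, not a statistical test; with very shallow libraries it
  returns "insufficient data" rather than a verdict.
* Genome-scale alignment, long-RNA quantification and differential
  expression are out of scope.
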