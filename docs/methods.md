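# Methods

## Scope and conventions

All coordinates are 0-based, half-open. Input sequences are uppercased;
cDNA is treated as the sense strand as given. DNA records may contain
IUPAC ambiguity codes and protein records the usual ambiguity letters
(X, B, Z, ...): such records are retained, but every counting window or
tiling cell that overlaps an ambiguous position is skipped, matching
the exact-match semantics used throughout. Output tables are TSV with
`#`-prefixed comment headers recording the tool version and the full
parameter set; `--deterministic` drops the timestamp line so identical
runs are byte-identical.

## Dinucleotide bias statistics

Counts use overlapping windows (width 2, step 1) that never cross
record boundaries, pooled over all records — ratios are computed on
pooled totals, not averaged per record. For a same-composition pair
(XY, YX) with counts k and m, the ratio is k/m with reference value 1
(no bias). The 95% CI treats k as a binomial draw out of n = k + m and
maps a Wilson score interval on the proportion to the odds scale. The
Wilson interval was chosen for its behavior at extreme proportions;
the mapping is monotone, so the odds interval brackets the ratio
whenever n > 0. A zero denominator yields a flagged undefined result,
never a division error.

Two caveats are deliberate: (1) overlapping windows are autocorrelated,
so the binomial model is an approximation — the test suite measures its
calibration on simulated genomes (coverage of the 95% interval is
~96-97% at 1 Mb, slightly conservative); (2) the *mean asymmetry*
statistic averages max(r, 1/r) over the four pairs so that biases in
either direction accumulate; log-ratios are also exposed
(`RatioResult.log_ratio`) since an "average ratio" does not itself fix
an orientation convention.

Region analysis pools 5'UTR / CDS / 3'UTR sub-sequences across
transcripts (per a user-supplied length annotation table) and reports,
per region, the mean asymmetry and the L1 distance between the region's
normalized 16-dinucleotide frequency vector and a reference genome's
(0 = identical, 2 = disjoint). The positional gradient splits each
transcript into B ≥ 2 equal relative-position bins (transcripts shorter
than B are skipped with a warning) and reports pooled mean asymmetry
per bin in 5'→3' order.

## Interactivity and the frequency surface

Dinucleotides are classed HIGH = {CA, AT, GC, AG}, LOW = {AC, TA, CG,
GA}; everything else is UNCLASSED. Two interactivity definitions
coexist and are both exposed: for arbitrary sequences, the overlapping-
window fraction HIGH/(HIGH+LOW), NaN when every window is UNCLASSED;
for constructed probes, the exact fraction of HIGH construction units.
Probes of length L concatenate ⌊L/2⌋ dinucleotide units — the number of
HIGH units is round(level × units), shuffled, each unit drawn uniformly
from its class — and odd lengths append one uniform terminal base that
does not enter the unit label. Defaults follow the study conditions:
lengths 10–16 nt and 48 probes per (length, level) cell with levels
{0, 0.25, 0.5, 0.75, 1}.

Occurrences are exact substring matches on the sense strand, overlaps
counted (`--both-strands` adds the reverse complement). Cell values are
means over the cell's probes of occurrences × 10⁶ / total cDNA length
(per probe per Mb); raw binned means, no smoothing. The interactivity
variance at a length is the population variance of
log10(frequency + pseudocount) across interactivity bins (pseudocount
1 per Mb, configurable); the pooled value averages over lengths. It is
0 iff all of a length's cells are equal and grows with the spread of
the surface.

## The multitarget search

Targets are tiled into cells of exactly 12 nt (DNA) or 4 aa (protein).
Sliding mode (default) emits a cell at every offset, so no match is
lost to tiling phase; block mode (offsets 0, c, 2c, ...) is provided
for comparison and always yields a subset of sliding-mode results.
Cells present in ≥ min_targets (default 2) distinct targets seed the
search.

A hit is a *maximal* shared substring: no single-character extension is
present in all of the hit's member targets. An extension that loses
some members but keeps ≥ min_targets is a different hit and is reported
separately. `find_multitarget` enumerates all maximal hits by a
complete exploration: starting from seed cells with their full
occurrence lists, every one-character extension that retains
≥ min_targets members is visited exactly once (occurrence lists shrink
monotonically, so the walk terminates), and a string is emitted when no
extension preserves its member set. Because every shared substring of
length ≥ cell size contains a seed cell, the enumeration is exhaustive;
the test suite checks set-equality against a brute-force oracle on
random instances. The single-seed `extend` operation instead applies a
simpler greedy rule (prefer the extension keeping the most occurrences,
ties broken lexicographically); its result is always one maximal hit,
but when two extensions both preserve the member set only one branch is
followed.

Exclusivity keeps hits with zero exact occurrences in any background
record (reverse complement included for DNA under `--both-strands`);
no mismatch tolerance is offered, by design. Target and background
collections must be disjoint by record id. An empty background retains
all hits with a logged caveat. Ranking is (member-target count
descending, length descending, sequence lexicographic) — deterministic
and invariant to input order.

Antisense design takes the reverse complement of a DNA hit as the
oligo core and renders it with 3+3 modified wings by default — `*`
between every pair of monomers, `+` before each wing monomer. Cores
longer than 16 nt are flagged, since shorter modified oligos retain
more activity in vivo. Localization labels each member occurrence by
the region containing its start offset and normalizes counts per
nucleotide by (distinct targets × average region length), defaulting to
200 / 1340 / 800 nt for 5'UTR / CDS / 3'UTR — typical mRNA averages;
proportions normalize the three rates to sum 1.

## Synthetic data

First-order Markov chains are sufficient to control every statistic in
the package, all of which are dinucleotide-level; higher orders are out
of scope. `markov_from_ratios` solves the inverse problem: the
stationary joint dinucleotide matrix F must satisfy the requested pair
ratios, row sums = column sums (stationarity), and total mass 1 — all
linear — so F is found by a small linear program that additionally
(a) minimizes the deviation of unrequested pairs from ratio 1,
(b) applies a weak pull toward the uniform matrix (weight 0.05) so the
chain stays high-entropy rather than emitting low-complexity repeats,
and (c) floors every entry at 1% for ergodicity. Requested ratios are
met exactly (checked to 1e−3); infeasible requests raise.

A structural fact worth noting: stationarity makes the net flows of the
three A-containing pairs cancel (G[A,C] + G[A,G] + G[A,T] = 0), so no
first-order chain can hold CA/AC ≠ 1 while pinning AT/TA and AG/GA at
exactly 1. Requesting CA/AC = 2 alone therefore yields a chain in which
one of the other A-pairs deviates from 1 (the LP places the imbalance);
requesting all four pairs as (2, 1, 1, 1) raises as infeasible.
Mutually cancelling enrichments such as all four ratios = 3 (the
HIGH-enriched genome used in the surface analyses) are feasible and met
exactly.

Transcript simulation concatenates three independently generated
regions (defaults 200 / 1340 / 800 nt) from per-region models, with
matching annotations. Panel simulation writes each planted motif into
its carriers at random non-overlapping offsets (exactly one occurrence
per carrier) and redraws non-carriers and background until free of
every motif (cap 1000 redraws per record, then an error — never a
silently contaminated fixture). With `clean=True` (default) the panel
is additionally redrawn until no non-planted cell-size window is shared
between any two targets and no motif is flankable by a character common
to all its carriers: the planted motifs are then provably the panel's
only shared-exclusive sequences and are maximal, giving exact ground
truth for sensitivity/false-hit measurements. Motifs must be at least
cell-size long (shorter ones could be neither excluded reliably nor
recovered).

What the generators do *not* emulate: gene structure (introns, splice
sites), codon constraints, repeat families, GC isochores, or any
higher-order composition structure. Passing tests therefore demonstrate
correctness of the algorithms and calibration of the statistics under
first-order composition control — not performance on real genomes,
where background sharing and low-complexity sequence are far heavier-
tailed.

## Problem sizes and numerical choices

The simulation-backed checks use 1 Mb genomes (20 seeds per condition)
for ratio recovery and calibration, 2 Mb genomes for the interactivity
surface, 200 transcripts for region similarity, and 50 random instances
(≤ 10 targets × ≤ 500 characters) for oracle equivalence — sizes at
which every estimate is stable while a full run stays around a minute.
Wilson CIs come from statsmodels; occurrence scanning uses string
search (`str.find`) with overlap-permitting restarts; dinucleotide
counting is vectorized over base codes with ambiguity masking. All
generators are pure functions of (parameters, seed); derived seeds stay
below 2³¹.

## Known limitations

- Exclusivity is exact-match only; near-matches in background (one
  mismatch off-targets) are not screened.
- The binomial CI ignores window autocorrelation; at genome scale it is
  mildly conservative, but heavy local repeat structure could distort
  it.
- The interactivity score ignores UNCLASSED windows entirely, so
  homopolymer-rich sequences are scored on few windows or not at all.
- The complete exploration is exponential-free only because occurrence
  lists shrink; pathological inputs (many near-identical targets) scale
  with the number of distinct shared substrings, which can approach
  quadratic in target length.
- Thermodynamics (Tm), chemistry optimization, protein topology and
  structure prediction are out of scope; designs are sequence-level
  candidates only.
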