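# mtseq

Toolkit for two linked sequence analyses:

1. **Dinucleotide mutational bias and "sequence interactivity".**
   Complex genomes show strand-asymmetric dinucleotide usage: of each
   same-base-composition pair, one order is systematically enriched
   (CA ≫ AC, AT ≫ TA, GC ≫ CG, AG ≫ GA). `mtseq` quantifies these
   biases as count ratios with binomial 95% confidence intervals,
   measures how the bias varies along transcripts (5'UTR → CDS →
   3'UTR), and scores short sequences by *relative interactivity* — the
   fraction of their dinucleotides drawn from the high-frequency set
   {CA, AT, GC, AG} versus the low-frequency set {AC, TA, CG, GA} — a
   proxy for how often complementary partner sequences occur in a
   transcriptome.

2. **Multitarget shared-sequence search.** For a disease panel (a set
   of cDNAs or proteins), find every maximal subsequence shared by two
   or more panel members and absent from every record of a background
   collection. Targets are tiled into cells of 12 nt (DNA) or 4 aa
   (protein) so that non-shared flanking sequence cannot suppress a
   match, shared cells are extended to maximal shared substrings, and
   the result is screened for exclusivity. DNA hits are emitted as
   antisense gapmer designs (`+` marks modified wing monomers, `*`
   phosphorothioate linkages); protein hits are candidate multitarget
   peptides. Hit positions are localized to 5'UTR / CDS / 3'UTR with
   per-nucleotide normalization.

The package is aimed at researchers designing single reagents —
antisense oligonucleotides or peptides — that engage several disease
gene products at once, and at anyone studying composition bias in
genomes or transcript regions. A synthetic-data module generates
Markov-chain genomes with controlled dinucleotide ratios, structured
transcripts, and planted-motif panels with exact ground truth, so the
entire pipeline is testable without downloading any genome.

## The statistics in brief

For dinucleotide pair (XY, YX) with pooled counts `k = n(XY)` and
`m = n(YX)`, the bias ratio is `r = k/m`; its CI treats `k` as binomial
out of `n = k + m` trials and maps the Wilson score interval on
`p = k/n` to the odds scale `p/(1−p) = r`. The orientation-free
*mean asymmetry* is the average of `max(r, 1/r)` over the four pairs
(1.0 ⇔ no bias). The *interactivity variance* of a probe-occurrence
surface is the variance of `log10(frequency + pseudocount)` across
interactivity levels at fixed probe length, averaged over lengths — it
measures how strongly composition drives occurrence frequency.

A hit of the search is *maximal*: no one-character extension is still
present in all of its member targets. A longer variant shared by fewer
(but ≥ 2) members is reported as its own hit. The search is verified in
the test suite against a brute-force enumeration of all maximal
shared-exclusive substrings.

## Worked example

Render a published-style gapmer (antisense core `TTGATGGGGAACTTGG`,
3-nt modified wings):

```sh
$ mtseq gapmer --seq TTGATGGGGAACTTGG
+T*+T*+G*A*T*G*G*G*G*A*A*C*T*+T*+G*+G
```

Simulate a 1 Mb genome with CA/AC bias 2.0 and estimate the ratios:

```sh
$ echo '{"length": 1000000, "ratios": {"CA/AC": 2.0}}' > genome.json
$ mtseq simulate genome --spec genome.json --seed 1 --out-prefix genome
$ mtseq dinuc --fasta genome.fasta --out ratios.tsv --deterministic
```

`ratios.tsv` (abridged):

```
pair    ratio   ci_low  ci_high n
CA/AC   2.0289  1.9807  2.0782  30119
AT/TA   0.9954  0.9845  1.0065  125501
AG/GA   1.1694  1.1569  1.1820  134700
GC/CG   1.0034  0.9944  1.0124  190654
```

The CA/AC interval contains the design value 2.0. AT/TA and GC/CG sit
at 1; AG/GA absorbs the flow imbalance that stationarity forces on the
three A-containing pairs (see `docs/methods.md`).

Build a planted-motif panel and recover the motif as a gapmer:

```sh
$ cat > panel.json <<'JSON'
{"n_targets": 5, "n_background": 3, "seq_length": 200,
 "planted_motifs": {"CCAAGTTCCCCATCAA": ["T1", "T2", "T4"]}}
JSON
$ mtseq simulate panel --spec panel.json --seed 17 --out-prefix panel
$ mtseq find --targets panel.targets.fasta --background panel.background.fasta \
    --out hits.tsv --deterministic
```

`hits.tsv` then contains the single hit `CCAAGTTCCCCATCAA` (members
T1/T2/T4, `exclusive=True`) with antisense core `TTGATGGGGAACTTGG` and
the gapmer rendering shown above.

The same operations are available as a library
(`mtseq.find_multitarget`, `mtseq.same_composition_ratios`,
`mtseq.frequency_surface`, `mtseq.simulate_panel`, ...).

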