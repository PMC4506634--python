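"""Dinucleotide composition statistics.

Overlapping dinucleotide counts, same-base-composition ratios (CA/AC,
AT/TA, AG/GA, GC/CG) with binomial 95% confidence intervals, region-vs-
genome composition similarity, and the 5'->3' positional bias gradient.

The same-composition ratio of a dinucleotide pair compares the counts of
two dinucleotides with identical base content but opposite order; it
equals 1 for an i.i.d. sequence and deviates under strand-asymmetric
mutational bias. Confidence intervals treat the numerator count as a
binomial draw out of numerator+denominator trials: a Wilson score
interval on the proportion p is mapped to the odds scale p/(1-p), which
is the ratio itself. Dinucleotide windows overlap by one base, so the
binomial model is an approximation; its calibration is exercised by the
test suite on simulated genomes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .seqio import Alphabet, AlphabetError, RegionAnnotation, SequenceRecord, check_annotation

logger = logging.getLogger(__name__)

__all__ = [
    "DINUCLEOTIDES",
    "SAME_COMPOSITION_PAIRS",
    "DinucStats",
    "RatioResult",
    "RegionReport",
    "count_dinucleotides",
    "same_composition_ratios",
    "mean_asymmetry",
    "region_similarity",
    "binned_stats",
    "positional_gradient",
]

DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")

#: (numerator, denominator) for the four same-base-composition ratios.
SAME_COMPOSITION_PAIRS = (("CA", "AC"), ("AT", "TA"), ("AG", "GA"), ("GC", "CG"))

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


@dataclass(frozen=True)
class DinucStats:
    """Overlapping dinucleotide counts pooled over a set of sequences.

    ``total`` is the number of classed (unambiguous) dinucleotide
    positions; for a single clean sequence of length L it equals L-1.
    """

    counts: dict[str, int]
    total: int

    def __getitem__(self, dinuc: str) -> int:
        return self.counts[dinuc]

    def frequency_vector(self) -> np.ndarray:
        """16-vector of dinucleotide frequencies (order: AA..TT), sum 1."""
        v = np.array([self.counts[d] for d in DINUCLEOTIDES], dtype=float)
        if self.total == 0:
            raise ValueError("no classed dinucleotide positions")
        return v / v.sum()

    def __add__(self, other: "DinucStats") -> "DinucStats":
        merged = {d: self.counts[d] + other.counts[d] for d in DINUCLEOTIDES}
        return DinucStats(merged, self.total + other.total)


@dataclass(frozen=True)
class RatioResult:
    """One same-composition ratio with its Wilson 95% CI on the odds scale."""

    pair: str              # e.g. "CA/AC"
    numerator: int
    denominator: int
    ratio: float           # nan when undefined
    ci_low: float
    ci_high: float
    n: int                 # numerator + denominator
    defined: bool

    @property
    def log_ratio(self) -> float:
        return math.log(self.ratio) if self.defined and self.ratio > 0 else math.nan


def _count_one(seq: str) -> tuple[np.ndarray, int]:
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if len(codes) < 2:
        return np.zeros(16, dtype=np.int64), 0
    left, right = codes[:-1], codes[1:]
    valid = (left >= 0) & (right >= 0)
    pair_codes = left[valid].astype(np.int64) * 4 + right[valid]
    counts = np.bincount(pair_codes, minlength=16)
    return counts, int(valid.sum())


def count_dinucleotides(records) -> DinucStats:
    """Count overlapping dinucleotides (width 2, step 1) over DNA records.

    Windows never cross record boundaries; windows containing ambiguity
    codes are skipped.
    """
    if isinstance(records, SequenceRecord):
        records = [records]
    counts = np.zeros(16, dtype=np.int64)
    total = 0
    for rec in records:
        if isinstance(rec, SequenceRecord):
            if rec.alphabet is not Alphabet.DNA:
                raise AlphabetError(
                    f"count_dinucleotides requires DNA records, got {rec.alphabet} for {rec.id!r}"
                )
            seq = rec.seq
        else:
            seq = str(rec).upper()
        c, t = _count_one(seq)
        counts += c
        total += t
    return DinucStats(dict(zip(DINUCLEOTIDES, counts.tolist())), total)


def _wilson_odds_ci(k: int, n: int, alpha: float) -> tuple[float, float]:
    """Wilson CI on the proportion k/n mapped to the odds scale p/(1-p)."""
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    odds_lo = lo / (1.0 - lo) if lo < 1.0 else math.inf
    odds_hi = hi / (1.0 - hi) if hi < 1.0 else math.inf
    return odds_lo, odds_hi


def same_composition_ratios(stats: DinucStats, alpha: float = 0.05) -> list[RatioResult]:
    """The four same-composition ratios with binomial CIs.

    A pair whose denominator count is zero is reported with
    ``defined=False`` and NaN ratio rather than dividing by zero. The
    no-bias reference value is ratio 1.
    """
    results = []
    for num, den in SAME_COMPOSITION_PAIRS:
        k, m = stats[num], stats[den]
        n = k + m
        if m == 0 or n == 0:
            results.append(
                RatioResult(f"{num}/{den}", k, m, math.nan, math.nan, math.nan, n, False)
            )
            continue
        ratio = k / m
        lo, hi = _wilson_odds_ci(k, n, alpha)
        results.append(RatioResult(f"{num}/{den}", k, m, ratio, lo, hi, n, True))
    return results


def mean_asymmetry(stats: DinucStats, alpha: float = 0.05) -> float:
    """Average orientation-free asymmetry over the four pairs.

    For each pair the asymmetry is max(r, 1/r), so bias in either
    direction accumulates; the result is 1.0 iff all four ratios are 1.
    """
    ratios = same_composition_ratios(stats, alpha=alpha)
    undefined = [r.pair for r in ratios if not r.defined or r.ratio == 0]
    if undefined:
        raise ValueError(f"undefined same-composition ratio(s): {undefined}")
    return float(np.mean([max(r.ratio, 1.0 / r.ratio) for r in ratios]))


@dataclass(frozen=True)
class RegionReport:
    """Per-region composition summary relative to a reference genome."""

    region: str
    stats: DinucStats
    asymmetry: float
    l1_distance: float  # L1 distance to the reference 16-dim frequency vector


def region_similarity(
    transcripts: list[SequenceRecord],
    annotations: list[RegionAnnotation],
    reference: DinucStats,
) -> dict[str, RegionReport]:
    """Compare 5'UTR / CDS / 3'UTR composition with a reference genome.

    Sub-sequences are pooled across transcripts per region; each region
    is summarized by its mean asymmetry and the L1 distance between its
    normalized 16-dinucleotide frequency vector and the reference's
    (0 = identical composition, 2 = disjoint support).
    """
    by_id = {a.transcript_id: a for a in annotations}
    region_seqs: dict[str, list[str]] = {"UTR5": [], "CDS": [], "UTR3": []}
    for rec in transcripts:
        ann = by_id.get(rec.id)
        if ann is None:
            raise ValueError(f"transcript {rec.id!r} has no region annotation")
        check_annotation(rec, ann)
        for region, (start, end) in ann.intervals().items():
            if end > start:
                region_seqs[region].append(rec.seq[start:end])
    ref_vec = reference.frequency_vector()
    reports = {}
    for region, seqs in region_seqs.items():
        stats = count_dinucleotides(seqs)
        if stats.total == 0:
            logger.warning("region %s is empty; skipped", region)
            continue
        l1 = float(np.abs(stats.frequency_vector() - ref_vec).sum())
        try:
            asym = mean_asymmetry(stats)
        except ValueError:  # a pair with zero counts in this region
            asym = math.nan
        reports[region] = RegionReport(region, stats, asym, l1)
    return reports


def binned_stats(transcripts: list[SequenceRecord], bins: int) -> list[DinucStats]:
    """Pooled dinucleotide counts per relative 5'->3' position bin.

    Each transcript is split into ``bins`` equal-length segments; counts
    are pooled per bin across transcripts. Transcripts shorter than
    ``bins`` are skipped with a warning.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    pooled = [DinucStats(dict.fromkeys(DINUCLEOTIDES, 0), 0) for _ in range(bins)]
    for rec in transcripts:
        L = len(rec)
        if L < bins:
            logger.warning("transcript %s shorter than %d bins; skipped", rec.id, bins)
            continue
        edges = np.linspace(0, L, bins + 1).round().astype(int)
        for b in range(bins):
            seg = rec.seq[edges[b] : edges[b + 1]]
            pooled[b] = pooled[b] + count_dinucleotides([seg])
    return pooled


def positional_gradient(transcripts: list[SequenceRecord], bins: int = 5) -> list[float]:
    """Mean asymmetry per relative 5'->3' position bin (see binned_stats)."""
    return [mean_asymmetry(s) for s in binned_stats(transcripts, bins)]
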