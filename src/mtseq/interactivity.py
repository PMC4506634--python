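"""Relative interactivity of short sequences.

"Relative interactivity" scores a DNA sequence by the fraction of its
dinucleotides drawn from the genome-wide high-frequency set
{CA, AT, GC, AG} versus the low-frequency set {AC, TA, CG, GA} — a proxy
for how often complementary partner sequences exist in a transcriptome.
This module builds probe collections at controlled interactivity levels,
counts their exact occurrences in a cDNA collection, and summarizes the
result as a (length x interactivity) frequency surface together with a
variance statistic that quantifies how strongly composition drives
occurrence frequency.

Two interactivity definitions coexist and are both exposed:

* ``relative_interactivity(seq)`` — measured on an arbitrary sequence via
  overlapping windows, ignoring UNCLASSED windows;
* ``Probe.unit_interactivity`` — the construction-time fraction of
  high-frequency dinucleotide *units* (non-overlapping), exact by design.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqio import AlphabetError, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "HIGH_FREQUENCY",
    "LOW_FREQUENCY",
    "Probe",
    "SurfaceCell",
    "classify_dinucleotide",
    "relative_interactivity",
    "generate_probes",
    "count_occurrences",
    "frequency_surface",
    "interactivity_variance",
]

#: Dinucleotides over-represented in complex genomes.
HIGH_FREQUENCY = ("CA", "AT", "GC", "AG")
#: Their same-composition mirror images, under-represented.
LOW_FREQUENCY = ("AC", "TA", "CG", "GA")

_HIGH = frozenset(HIGH_FREQUENCY)
_LOW = frozenset(LOW_FREQUENCY)


def classify_dinucleotide(d: str) -> str:
    """Classify a dinucleotide as ``HIGH``, ``LOW`` or ``UNCLASSED``."""
    d = d.upper()
    if len(d) != 2 or any(ch not in "ACGT" for ch in d):
        if len(d) == 2 and all(ch in "ACGTNRYSWKMBDHV" for ch in d):
            return "UNCLASSED"
        raise AlphabetError(f"not a DNA dinucleotide: {d!r}")
    if d in _HIGH:
        return "HIGH"
    if d in _LOW:
        return "LOW"
    return "UNCLASSED"


def relative_interactivity(seq: str) -> float:
    """HIGH / (HIGH + LOW) over all overlapping dinucleotide windows.

    Returns NaN when every window is UNCLASSED (e.g. homopolymers).
    """
    seq = seq.upper()
    if len(seq) < 2:
        raise ValueError("relative_interactivity requires a sequence of length >= 2")
    high = low = 0
    for i in range(len(seq) - 1):
        cls = classify_dinucleotide(seq[i : i + 2])
        if cls == "HIGH":
            high += 1
        elif cls == "LOW":
            low += 1
    if high + low == 0:
        return math.nan
    return high / (high + low)


@dataclass(frozen=True)
class Probe:
    """A constructed oligomer with a unit-level interactivity label.

    ``units`` are the non-overlapping dinucleotide building blocks;
    ``unit_interactivity`` is the exact fraction of HIGH units. Odd
    lengths carry one terminal single base that is not a unit.
    """

    seq: str
    unit_interactivity: float
    units: tuple[str, ...]

    def __post_init__(self) -> None:
        joined = "".join(self.units)
        if not self.seq.startswith(joined):
            raise ValueError("probe sequence does not decompose into its units")
        if len(self.seq) - len(joined) > 1:
            raise ValueError("at most one terminal non-unit base allowed")

    def __len__(self) -> int:
        return len(self.seq)


def generate_probes(
    lengths: Sequence[int] = range(10, 17),
    levels: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n: int = 1,
    seed: int = 0,
) -> list[Probe]:
    """Build ``n`` random probes per (length, interactivity level).

    Each probe concatenates ``length // 2`` dinucleotide units; the number
    of HIGH units is ``round(level * n_units)`` (the remainder are LOW),
    their order is shuffled, and each unit is drawn uniformly from its
    set. Odd lengths get one terminal base drawn uniformly from ACGT;
    ``unit_interactivity`` is computed over full units only. Deterministic
    under a fixed seed.
    """
    if not levels:
        raise ValueError("at least one interactivity level required")
    if n < 1:
        raise ValueError("n must be >= 1")
    for lv in levels:
        if not 0.0 <= lv <= 1.0:
            raise ValueError(f"interactivity level {lv} outside [0, 1]")
    rng = np.random.default_rng(seed)
    probes: list[Probe] = []
    for length in lengths:
        if length < 2:
            raise ValueError(f"probe length {length} < 2")
        n_units = length // 2
        for level in levels:
            n_high = round(level * n_units)
            for _ in range(n):
                kinds = np.array([True] * n_high + [False] * (n_units - n_high))
                rng.shuffle(kinds)
                units = tuple(
                    HIGH_FREQUENCY[rng.integers(4)] if k else LOW_FREQUENCY[rng.integers(4)]
                    for k in kinds
                )
                seq = "".join(units)
                if length % 2:
                    seq += "ACGT"[rng.integers(4)]
                probes.append(Probe(seq, n_high / n_units, units))
    return probes


def count_occurrences(
    probe: str,
    cdna: Iterable[SequenceRecord | str],
    both_strands: bool = False,
) -> int:
    """Exact, possibly overlapping, occurrences of ``probe`` across records.

    Counts on the sense strand as given; with ``both_strands`` the reverse
    complement of the probe is counted as well.
    """
    probe = probe.upper()
    if len(probe) < 2:
        raise ValueError("probe length must be >= 2")
    queries = [probe]
    if both_strands:
        rc = reverse_complement(probe)
        if rc != probe:
            queries.append(rc)
    total = 0
    empty = True
    for rec in cdna:
        empty = False
        hay = rec.seq if isinstance(rec, SequenceRecord) else str(rec).upper()
        for q in queries:
            start = hay.find(q)
            while start != -1:
                total += 1
                start = hay.find(q, start + 1)
    if empty:
        logger.warning("count_occurrences called with an empty cDNA collection")
    return total


@dataclass(frozen=True)
class SurfaceCell:
    """Mean occurrence frequency at one (length, interactivity) bin."""

    length: int
    interactivity_bin: float
    mean_frequency: float  # occurrences per probe per Mb of cDNA
    n_probes: int


def frequency_surface(
    probes: Iterable[Probe],
    cdna: Sequence[SequenceRecord],
    both_strands: bool = False,
) -> list[SurfaceCell]:
    """Occurrence frequency binned by probe length and interactivity level.

    ``mean_frequency`` is the mean over the bin's probes of
    (occurrence count x 1e6 / total cDNA length in nt): occurrences per
    probe per megabase. Raw binned means; no smoothing.
    """
    total_nt = sum(len(r) for r in cdna)
    if total_nt == 0:
        raise ValueError("cDNA collection has zero total length")
    groups: dict[tuple[int, float], list[float]] = {}
    for p in probes:
        count = count_occurrences(p.seq, cdna, both_strands=both_strands)
        groups.setdefault((len(p), p.unit_interactivity), []).append(
            count * 1e6 / total_nt
        )
    cells = [
        SurfaceCell(length, level, float(np.mean(freqs)), len(freqs))
        for (length, level), freqs in sorted(groups.items())
    ]
    return cells


def interactivity_variance(
    surface: Iterable[SurfaceCell], pseudocount: float = 1.0
) -> tuple[dict[int, float], float]:
    """Spread of log-frequencies across interactivity bins, per length.

    For each length: the population variance of
    log10(mean_frequency + pseudocount) across its interactivity bins
    (pseudocount in occurrences per Mb). Returns (per-length dict,
    pooled mean over lengths). Zero iff all of a length's cells are
    equal; monotone in the spread of the surface.
    """
    by_length: dict[int, list[float]] = {}
    for cell in surface:
        by_length.setdefault(cell.length, []).append(cell.mean_frequency)
    if not by_length:
        raise ValueError("empty surface")
    per_length = {}
    for length, freqs in sorted(by_length.items()):
        if len(freqs) < 2:
            raise ValueError(
                f"length {length} has a single interactivity bin; variance undefined"
            )
        logs = np.log10(np.asarray(freqs) + pseudocount)
        per_length[length] = float(np.var(logs))
    pooled = float(np.mean(list(per_length.values())))
    return per_length, pooled
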