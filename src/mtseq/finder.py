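"""Multitarget shared-sequence search and antisense/gapmer design.

The search finds short sequences present in two or more target gene
products (cDNAs or proteins of a disease panel) and absent from every
sequence in a background collection — candidates for single molecules
that engage several disease genes at once. Alignment algorithms are
hampered here by the negative influence of non-shared flanking sequence,
so instead each target is tiled into fixed-width cells (12 nt for DNA,
4 aa for protein), cells occurring in >= 2 distinct targets are used as
seeds, seeds are extended to maximal shared substrings, and the result
is filtered for exclusivity against the background. DNA hits are turned
into antisense gapmer designs rendered in the standard notation:
``*`` for phosphorothioate linkages between every pair of monomers and
``+`` prefixing conformationally restricted wing monomers (LNA/MOE/
tricyclo-DNA), e.g. ``+T*+T*+G*A*T*...*+G*+G``.

A hit is *maximal* when no single-character extension to the left or
right is still present in all of the hit's member targets; an extension
shared by fewer (but still >= min_targets) members is reported as its
own, separate hit. ``find_multitarget`` enumerates all maximal hits by a
complete breadth-wise exploration of shared substrings, which the test
suite verifies against a brute-force oracle; the single-seed ``extend``
operation applies the simpler greedy rule.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .seqio import (
    Alphabet,
    AlphabetError,
    RegionAnnotation,
    SequenceRecord,
    reverse_complement,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CELL_SIZE",
    "DEFAULT_AVG_REGION_LENGTHS",
    "Cell",
    "SharedHit",
    "GapmerDesign",
    "RegionLocalization",
    "tile",
    "shared_cells",
    "extend",
    "exclusivity_filter",
    "design_antisense",
    "format_gapmer",
    "locate_hits",
    "find_multitarget",
    "verify_hits",
]

#: Default tiling cell width per alphabet: 12 nt for DNA, 4 aa for protein.
DEFAULT_CELL_SIZE = {Alphabet.DNA: 12, Alphabet.PROTEIN: 4}

#: Average 5'UTR / CDS / 3'UTR lengths (nt) used for per-nucleotide
#: normalization of hit localization.
DEFAULT_AVG_REGION_LENGTHS = {"UTR5": 200, "CDS": 1340, "UTR3": 800}

#: Antisense oligos longer than this are flagged (shorter oligos with
#: restricted-monomer wings retain potency in vivo).
MAX_RECOMMENDED_OLIGO = 16

_CORE_CHARS = {
    Alphabet.DNA: frozenset("ACGT"),
    Alphabet.PROTEIN: frozenset("ACDEFGHIKLMNPQRSTVWY"),
}


@dataclass(frozen=True)
class Cell:
    """A fixed-width window of a target sequence (0-based start)."""

    seq: str
    source_id: str
    offset: int


@dataclass(frozen=True)
class SharedHit:
    """A maximal subsequence common to >= 2 targets.

    ``members`` records every occurrence as (target_id, 0-based offset);
    ``exclusive`` is None until the background filter has run.
    """

    seq: str
    members: tuple[tuple[str, int], ...]
    exclusive: bool | None = None
    region_labels: tuple[str, ...] | None = None

    @property
    def n_targets(self) -> int:
        return len({tid for tid, _ in self.members})

    def __len__(self) -> int:
        return len(self.seq)


def tile(record: SequenceRecord, cell_size: int, mode: str = "sliding") -> list[Cell]:
    """Tile a record into cells of exactly ``cell_size`` characters.

    ``sliding`` emits one cell per offset (all phases — no boundary
    losses, maximizing search sensitivity); ``block`` emits
    non-overlapping cells at offsets 0, cell_size, 2*cell_size, ...
    Cells containing ambiguity characters are skipped. A record shorter
    than ``cell_size`` yields an empty list with a warning.
    """
    if cell_size < 2:
        raise ValueError("cell_size must be >= 2")
    if mode not in ("sliding", "block"):
        raise ValueError(f"unknown tiling mode {mode!r}")
    if len(record) < cell_size:
        logger.warning(
            "record %s (length %d) shorter than cell size %d; no cells",
            record.id, len(record), cell_size,
        )
        return []
    core = _CORE_CHARS[record.alphabet]
    step = 1 if mode == "sliding" else cell_size
    cells = []
    for off in range(0, len(record) - cell_size + 1, step):
        window = record.seq[off : off + cell_size]
        if all(ch in core for ch in window):
            cells.append(Cell(window, record.id, off))
    return cells


def shared_cells(
    targets: Sequence[SequenceRecord],
    cell_size: int,
    min_targets: int = 2,
    mode: str = "sliding",
) -> dict[str, list[tuple[str, int]]]:
    """Cell sequences occurring in >= ``min_targets`` distinct targets.

    Returns a map cell-seq -> list of every (target_id, offset)
    occurrence among the tiled cells.
    """
    if min_targets < 2:
        raise ValueError("min_targets must be >= 2: a shared sequence needs >= 2 carriers")
    if len(targets) < min_targets:
        raise ValueError(
            f"need at least {min_targets} targets, got {len(targets)}"
        )
    occ: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for rec in targets:
        for cell in tile(rec, cell_size, mode=mode):
            occ[cell.seq].append((cell.source_id, cell.offset))
    return {
        seq: members
        for seq, members in occ.items()
        if len({tid for tid, _ in members}) >= min_targets
    }


def _all_occurrences(query: str, targets: Sequence[SequenceRecord]) -> list[tuple[str, int]]:
    occs = []
    for rec in targets:
        start = rec.seq.find(query)
        while start != -1:
            occs.append((rec.id, start))
            start = rec.seq.find(query, start + 1)
    return occs


def _extensions(
    seq: str,
    occs: list[tuple[str, int]],
    seqs: Mapping[str, str],
    core: frozenset[str],
):
    """Group occurrence lists of every single-character extension.

    Yields (new_seq, new_occs) for each right extension ``seq + c`` and
    left extension ``c + seq`` actually present; extensions into
    ambiguity characters are not taken (exact-match semantics over the
    core alphabet only).
    """
    right: dict[str, list[tuple[str, int]]] = defaultdict(list)
    left: dict[str, list[tuple[str, int]]] = defaultdict(list)
    L = len(seq)
    for tid, off in occs:
        t = seqs[tid]
        if off + L < len(t) and t[off + L] in core:
            right[t[off + L]].append((tid, off))
        if off > 0 and t[off - 1] in core:
            left[t[off - 1]].append((tid, off - 1))
    for c in sorted(right):
        yield seq + c, right[c]
    for c in sorted(left):
        yield c + seq, left[c]


def _member_ids(occs: Iterable[tuple[str, int]]) -> frozenset[str]:
    return frozenset(tid for tid, _ in occs)


def extend(
    seed: str,
    targets: Sequence[SequenceRecord],
    min_targets: int = 2,
) -> SharedHit:
    """Greedily extend a seed to a maximal shared substring.

    Repeatedly tries a one-character extension (right, then left) that is
    still present in every current member target, preferring the
    extension retaining the most occurrences (ties broken
    lexicographically); stops when any further extension would drop a
    member. The result is maximal: no single-character extension of it is
    shared by all of its members.
    """
    seqs = {r.id: r.seq for r in targets}
    core = _CORE_CHARS[targets[0].alphabet]
    occs = _all_occurrences(seed, targets)
    members = _member_ids(occs)
    if len(members) < min_targets:
        raise ValueError(
            f"seed {seed!r} occurs in {len(members)} target(s); needs >= {min_targets}"
        )
    cur_seq, cur_occs = seed, occs
    while True:
        candidates = [
            (new_seq, new_occs)
            for new_seq, new_occs in _extensions(cur_seq, cur_occs, seqs, core)
            if _member_ids(new_occs) == members
        ]
        if not candidates:
            break
        cur_seq, cur_occs = max(candidates, key=lambda sn: (len(sn[1]), sn[0]))
    return SharedHit(cur_seq, tuple(sorted(cur_occs)))


def _explore_maximal(
    targets: Sequence[SequenceRecord],
    cell_size: int,
    min_targets: int,
    mode: str = "sliding",
) -> list[SharedHit]:
    """Enumerate all maximal shared substrings reachable from seed cells.

    Complete search: every shared substring with >= min_targets members
    is visited at most once; a substring is emitted when no
    single-character extension preserves its full member set.
    """
    seqs = {r.id: r.seq for r in targets}
    core = _CORE_CHARS[targets[0].alphabet]
    seeds = shared_cells(targets, cell_size, min_targets=min_targets, mode=mode)
    # seed occurrence lists from tiling cover every occurrence in sliding
    # mode; in block mode re-scan so extension bookkeeping stays exact.
    stack: list[tuple[str, list[tuple[str, int]]]] = []
    for seq in seeds:
        stack.append((seq, _all_occurrences(seq, targets)))
    visited: set[str] = set()
    hits: list[SharedHit] = []
    while stack:
        seq, occs = stack.pop()
        if seq in visited:
            continue
        visited.add(seq)
        members = _member_ids(occs)
        maximal = True
        for new_seq, new_occs in _extensions(seq, occs, seqs, core):
            new_members = _member_ids(new_occs)
            if new_members == members:
                maximal = False
            if len(new_members) >= min_targets and new_seq not in visited:
                stack.append((new_seq, new_occs))
        if maximal:
            hits.append(SharedHit(seq, tuple(sorted(occs))))
    return hits


def exclusivity_filter(
    hits: Iterable[SharedHit],
    background: Sequence[SequenceRecord],
    both_strands: bool = False,
) -> list[SharedHit]:
    """Keep hits with zero exact occurrences in any background record.

    With ``both_strands`` (DNA) the reverse complement of each hit is
    screened as well. Target/background record sets must be disjoint by
    id (checked by the caller for full runs); an empty background retains
    all hits with a logged caveat.
    """
    background = list(background)
    if not background:
        logger.warning("empty background: exclusivity unscreened, all hits retained")
    kept = []
    for hit in hits:
        queries = [hit.seq]
        if both_strands:
            rc = reverse_complement(hit.seq)
            if rc != hit.seq:
                queries.append(rc)
        found = any(q in rec.seq for rec in background for q in queries)
        if not found:
            kept.append(replace(hit, exclusive=True))
    return kept


@dataclass(frozen=True)
class GapmerDesign:
    """An antisense gapmer: DNA core with modified wing monomers."""

    core: str      # antisense sequence, 5'->3'
    wing5: int
    wing3: int
    rendered: str

    @property
    def over_length(self) -> bool:
        return len(self.core) > MAX_RECOMMENDED_OLIGO


def format_gapmer(core: str, wing5: int = 3, wing3: int = 3) -> str:
    """Render a gapmer: ``*`` between all monomers, ``+`` on wing monomers.

    Stripping '+' and '*' from the result reconstructs the core.
    """
    core = core.upper()
    if wing5 < 0 or wing3 < 0 or wing5 + wing3 > len(core):
        raise ValueError(
            f"wings {wing5}+{wing3} exceed core length {len(core)}"
        )
    marked = [
        ("+" if i < wing5 or i >= len(core) - wing3 else "") + base
        for i, base in enumerate(core)
    ]
    return "*".join(marked)


def design_antisense(hit: SharedHit, wing5: int = 3, wing3: int = 3) -> GapmerDesign:
    """Antisense gapmer for a DNA hit: reverse complement plus wings."""
    try:
        core = reverse_complement(hit.seq)
    except AlphabetError as exc:
        raise AlphabetError(
            f"antisense design requires a DNA hit: {exc}"
        ) from exc
    if len(core) > MAX_RECOMMENDED_OLIGO:
        logger.warning(
            "hit %s is %d nt; oligos over %d nt lose potency — consider trimming",
            hit.seq, len(core), MAX_RECOMMENDED_OLIGO,
        )
    return GapmerDesign(core, wing5, wing3, format_gapmer(core, wing5, wing3))


@dataclass(frozen=True)
class RegionLocalization:
    """Per-region hit-occurrence localization, normalized per nucleotide."""

    counts: dict[str, int]          # occurrences starting in each region
    per_nt_rate: dict[str, float]   # counts / (n_targets * avg region length)
    proportions: dict[str, float]   # per_nt_rate normalized to sum 1
    n_targets: int
    labels: dict[str, tuple[str, ...]]  # hit seq -> per-member region labels


def locate_hits(
    hits: Sequence[SharedHit],
    annotations: Sequence[RegionAnnotation],
    avg_region_lengths: Mapping[str, float] = DEFAULT_AVG_REGION_LENGTHS,
    n_targets: int | None = None,
) -> RegionLocalization:
    """Localize hit occurrences to 5'UTR / CDS / 3'UTR.

    Each member occurrence is labeled by the region containing its start
    offset. The per-nucleotide rate of a region divides its occurrence
    count by (number of distinct targets x average region length); the
    defaults (200 / 1340 / 800 nt) are typical mRNA region sizes.
    Relative proportions normalize the rates to sum 1.
    """
    by_id = {a.transcript_id: a for a in annotations}
    counts = {"UTR5": 0, "CDS": 0, "UTR3": 0}
    labels: dict[str, tuple[str, ...]] = {}
    seen_targets: set[str] = set()
    for hit in hits:
        hit_labels = []
        for tid, off in hit.members:
            ann = by_id.get(tid)
            if ann is None:
                raise ValueError(f"member target {tid!r} has no region annotation")
            region = ann.region_of(off)
            counts[region] += 1
            hit_labels.append(region)
            seen_targets.add(tid)
        labels[hit.seq] = tuple(hit_labels)
    nt = n_targets if n_targets is not None else max(len(seen_targets), 1)
    rates = {
        region: counts[region] / (nt * avg_region_lengths[region])
        for region in counts
    }
    total = sum(rates.values())
    proportions = {
        region: (rates[region] / total if total > 0 else 0.0) for region in rates
    }
    return RegionLocalization(counts, rates, proportions, nt, labels)


def _check_disjoint(
    targets: Sequence[SequenceRecord], background: Sequence[SequenceRecord]
) -> None:
    overlap = {r.id for r in targets} & {r.id for r in background}
    if overlap:
        raise ValueError(
            f"targets and background must be disjoint by id; shared: {sorted(overlap)}"
        )


def find_multitarget(
    targets: Sequence[SequenceRecord],
    background: Sequence[SequenceRecord],
    cell_size: int | None = None,
    min_targets: int = 2,
    mode: str = "sliding",
    both_strands: bool = False,
) -> list[SharedHit]:
    """The full search: tile, seed, extend, deduplicate, screen, rank.

    Returns every maximal substring of length >= cell_size present in
    >= ``min_targets`` distinct targets and absent from all background
    records, ranked by (number of member targets desc, length desc,
    sequence). Deterministic and invariant to record order.
    """
    if not targets:
        raise ValueError("no target records")
    _check_disjoint(targets, background)
    alphabet = targets[0].alphabet
    if any(r.alphabet is not alphabet for r in targets):
        raise AlphabetError("mixed alphabets in target collection")
    if cell_size is None:
        cell_size = DEFAULT_CELL_SIZE[alphabet]
    hits = _explore_maximal(targets, cell_size, min_targets, mode=mode)
    hits = exclusivity_filter(hits, background, both_strands=both_strands)
    hits.sort(key=lambda h: (-h.n_targets, -len(h.seq), h.seq))
    return hits


def verify_hits(
    hits: Iterable[SharedHit],
    targets: Sequence[SequenceRecord],
    background: Sequence[SequenceRecord],
    min_targets: int = 2,
    both_strands: bool = False,
) -> None:
    """Post-hoc verifier: every reported occurrence is real, membership
    reaches ``min_targets`` distinct targets, and no background record
    contains the hit. Raises AssertionError on any violation."""
    seqs = {r.id: r.seq for r in targets}
    for hit in hits:
        for tid, off in hit.members:
            if seqs[tid][off : off + len(hit.seq)] != hit.seq:
                raise AssertionError(f"hit {hit.seq!r}: occurrence ({tid},{off}) is wrong")
        if hit.n_targets < min_targets:
            raise AssertionError(f"hit {hit.seq!r}: only {hit.n_targets} member targets")
        queries = [hit.seq]
        if both_strands:
            queries.append(reverse_complement(hit.seq))
        for rec in background:
            for q in queries:
                if q in rec.seq:
                    raise AssertionError(f"hit {hit.seq!r} found in background {rec.id!r}")
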