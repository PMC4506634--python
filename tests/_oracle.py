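"""Independent brute-force oracles used to cross-check the finder.

These deliberately avoid the package's seed-and-extend machinery: shared
substrings are enumerated length by length with plain substring checks,
so agreement with ``find_multitarget`` is a genuine two-route test.
"""

from __future__ import annotations

import numpy as np

from mtseq import Alphabet, SequenceRecord

DNA = "ACGT"
AA = "ACDEFGHIKLMNPQRSTVWY"


def naive_count(probe: str, seqs: list[str]) -> int:
    """Position-by-position overlapping occurrence count."""
    total = 0
    for s in seqs:
        for i in range(len(s) - len(probe) + 1):
            if s[i : i + len(probe)] == probe:
                total += 1
    return total


def brute_force_hits(
    targets: list[SequenceRecord],
    background: list[SequenceRecord],
    cell_size: int,
    min_targets: int = 2,
    both_strands: bool = False,
):
    """All maximal shared-exclusive substrings, by exhaustive enumeration.

    Enumerates every substring of length >= cell_size occurring in
    >= min_targets distinct targets (stopping at the first length with
    no shared substrings, since a shared (L+1)-mer implies a shared
    L-mer), keeps the maximal ones (no one-character extension present
    in all members), drops any found in the background, and returns
    {seq: sorted occurrence tuple}.
    """
    from mtseq import reverse_complement

    letters = DNA if targets[0].alphabet is Alphabet.DNA else AA
    seqs = {r.id: r.seq for r in targets}
    shared: dict[str, set[str]] = {}
    max_len = max(len(s) for s in seqs.values())
    for L in range(cell_size, max_len + 1):
        level: dict[str, set[str]] = {}
        for tid, s in seqs.items():
            for i in range(len(s) - L + 1):
                w = s[i : i + L]
                if all(ch in letters for ch in w):
                    level.setdefault(w, set()).add(tid)
        cur = {w: ids for w, ids in level.items() if len(ids) >= min_targets}
        if not cur:
            break
        shared.update(cur)

    hits: dict[str, tuple] = {}
    for s, members in shared.items():
        maximal = True
        for c in letters:
            if all((c + s) in seqs[t] for t in members):
                maximal = False
                break
            if all((s + c) in seqs[t] for t in members):
                maximal = False
                break
        if not maximal:
            continue
        queries = [s]
        if both_strands and targets[0].alphabet is Alphabet.DNA:
            queries.append(reverse_complement(s))
        if any(q in rec.seq for rec in background for q in queries):
            continue
        occs = []
        for tid, t in seqs.items():
            start = t.find(s)
            while start != -1:
                occs.append((tid, start))
                start = t.find(s, start + 1)
        hits[s] = tuple(sorted(occs))
    return hits


def random_instance(rng: np.random.Generator, alphabet: Alphabet):
    """A random finder instance with occasionally planted shared content.

    Up to 10 targets of up to 500 characters, a small background, and
    0-3 substrings copied into random subsets of targets (sometimes
    also into a background record, making them non-exclusive).
    """
    letters = DNA if alphabet is Alphabet.DNA else AA
    cell = 12 if alphabet is Alphabet.DNA else 4
    n_targets = int(rng.integers(3, 11))
    n_bg = int(rng.integers(0, 5))
    length = int(rng.integers(60, 501))

    def rand_seq(n):
        return "".join(letters[i] for i in rng.integers(0, len(letters), size=n))

    targets = [rand_seq(length) for _ in range(n_targets)]
    background = [rand_seq(length) for _ in range(n_bg)]
    for _ in range(int(rng.integers(0, 4))):
        m_len = int(rng.integers(cell, cell + 12))
        motif = rand_seq(m_len)
        k = int(rng.integers(2, n_targets + 1))
        for t in rng.choice(n_targets, size=k, replace=False):
            off = int(rng.integers(0, length - m_len + 1))
            targets[t] = targets[t][:off] + motif + targets[t][off + m_len:]
        if n_bg and rng.random() < 0.3:  # sometimes spoil exclusivity
            b = int(rng.integers(0, n_bg))
            off = int(rng.integers(0, length - m_len + 1))
            background[b] = background[b][:off] + motif + background[b][off + m_len:]
    return (
        [SequenceRecord(f"T{i + 1}", s, alphabet) for i, s in enumerate(targets)],
        [SequenceRecord(f"B{i + 1}", s, alphabet) for i, s in enumerate(background)],
        cell,
    )
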