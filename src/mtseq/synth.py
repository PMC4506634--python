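"""Synthetic genomes, transcripts and disease panels with known truth.

Every analysis in this package can be exercised without downloads:

* first-order Markov chains generate DNA with controlled dinucleotide
  composition — ``markov_from_ratios`` solves the inverse problem of
  building a chain whose stationary dinucleotide frequencies achieve
  requested same-composition ratios (CA/AC etc.);
* ``simulate_transcripts`` builds mRNA-like records with 5'UTR / CDS /
  3'UTR structure, each region drawn from its own model, so that
  region-composition analyses have a known answer by construction;
* ``simulate_panel`` builds disease-panel fixtures: target and
  background collections with motifs planted in chosen carrier targets
  and guaranteed (by rejection sampling) absent everywhere else, giving
  exact ground truth for the multitarget search.

First-order chains suffice because every statistic in the package is
dinucleotide-level. All generators are pure functions of their
parameters and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .seqio import Alphabet, RegionAnnotation, SequenceRecord, reverse_complement
from .dinuc import SAME_COMPOSITION_PAIRS

logger = logging.getLogger(__name__)

__all__ = [
    "MarkovModel",
    "PanelSpec",
    "uniform_model",
    "markov_from_ratios",
    "simulate_sequence",
    "simulate_transcripts",
    "simulate_panel",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Redraws allowed per record before motif exclusion gives up.
MAX_REDRAWS = 1000


@dataclass(frozen=True)
class MarkovModel:
    """First-order base chain: initial distribution + transition matrix.

    ``transition[i, j]`` is P(next base = j | current base = i) with
    bases ordered A, C, G, T. Under stationarity the expected frequency
    of dinucleotide XY is pi(X) * transition(X -> Y).
    """

    initial: np.ndarray
    transition: np.ndarray

    def __post_init__(self) -> None:
        initial = np.asarray(self.initial, dtype=float)
        transition = np.asarray(self.transition, dtype=float)
        object.__setattr__(self, "initial", initial)
        object.__setattr__(self, "transition", transition)
        if initial.shape != (4,) or transition.shape != (4, 4):
            raise ValueError("initial must be length 4, transition 4x4")
        if np.any(initial < 0) or np.any(transition < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")
        if np.any(np.abs(transition.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition rows must sum to 1")

    def stationary(self) -> np.ndarray:
        """Stationary base distribution (left eigenvector, eigenvalue 1)."""
        w, v = np.linalg.eig(self.transition.T)
        k = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, k])
        pi = np.abs(pi)
        return pi / pi.sum()

    def stationary_dinucleotide_matrix(self) -> np.ndarray:
        """Expected stationary dinucleotide frequencies F[X, Y] (sum 1)."""
        pi = self.stationary()
        return pi[:, None] * self.transition

    def expected_ratio(self, numerator: str, denominator: str) -> float:
        """Stationary same-composition ratio, e.g. ('CA', 'AC')."""
        F = self.stationary_dinucleotide_matrix()
        i, j = _BASE_INDEX[numerator[0]], _BASE_INDEX[numerator[1]]
        k, l = _BASE_INDEX[denominator[0]], _BASE_INDEX[denominator[1]]
        return float(F[i, j] / F[k, l])


def uniform_model() -> MarkovModel:
    """The i.i.d. uniform chain (all ratios 1)."""
    return MarkovModel(np.full(4, 0.25), np.full((4, 4), 0.25))


def markov_from_ratios(
    target_ratios: dict[str, float],
    tol: float = 1e-3,
) -> MarkovModel:
    """Build a chain whose stationary dinucleotide ratios hit targets.

    ``target_ratios`` maps pair names ("CA/AC", "AT/TA", "AG/GA",
    "GC/CG") to desired ratios. Requested pairs are met exactly; pairs
    not requested are kept as close to 1 as stationarity allows.

    The joint stationary dinucleotide matrix F must satisfy the
    requested ratios (F[C,A] = r * F[A,C], ...), the stationarity
    condition (row sums equal column sums) and sum to 1 — all linear
    constraints — so F is found by a small linear program minimizing
    the unrequested pairs' deviation from ratio 1, with a floor on
    every entry to keep the chain ergodic. The chain is then
    transition[i, j] = F[i, j] / rowsum(i) with initial = rowsum, whose
    analytic stationary dinucleotide matrix reproduces F exactly.

    Note a structural limit of first-order chains: stationarity makes
    the net flows of the three A-containing pairs sum to zero, so e.g.
    CA/AC = 2 forces AT/TA or AG/GA away from 1. Requesting all four
    ratios as (r, 1, 1, 1) with r != 1 is therefore infeasible and
    raises; request only the pairs you need pinned.

    Raises if any ratio is non-positive or the constraint set admits no
    strictly positive matrix (infeasible ratio combination).
    """
    pair_names = {f"{a}/{b}": (a, b) for a, b in SAME_COMPOSITION_PAIRS}
    hard: dict[str, float] = {}
    for name, r in target_ratios.items():
        key = name if name in pair_names else "/".join(reversed(name.split("/")))
        if key not in pair_names:
            raise ValueError(f"unknown same-composition pair {name!r}")
        if key != name and r > 0:  # given as denominator/numerator, invert
            r = 1.0 / r
        if not (r > 0) or not np.isfinite(r):
            raise ValueError(f"ratio for {name} must be positive and finite, got {r}")
        hard[key] = float(r)

    def cell(d: str) -> int:
        return 4 * _BASE_INDEX[d[0]] + _BASE_INDEX[d[1]]

    soft = [name for name in pair_names if name not in hard]
    n_soft = len(soft)
    # variables: x(16) = vec(F), one slack per soft pair, then 16
    # uniform-pull slacks u_ij >= |x_ij - 1/16| that keep the matrix
    # high-entropy (without them the LP can return a degenerate chain
    # that emits low-complexity sequence)
    nv = 16 + n_soft + 16
    A_eq = np.zeros((len(hard) + 4, nv))
    b_eq = np.zeros(len(hard) + 4)
    row = 0
    for name, r in hard.items():
        a, b_ = pair_names[name]
        A_eq[row, cell(a)] = 1.0
        A_eq[row, cell(b_)] = -r
        row += 1
    for i in range(3):  # row sum i == col sum i (4th is implied)
        A_eq[row, 4 * i : 4 * i + 4] += 1.0
        A_eq[row, [i, i + 4, i + 8, i + 12]] -= 1.0
        row += 1
    A_eq[row, :16] = 1.0
    b_eq[row] = 1.0
    # slack_p >= |F_num - F_den| per soft pair; u_ij >= |x_ij - 1/16|
    A_ub = np.zeros((2 * n_soft + 32, nv))
    b_ub = np.zeros(2 * n_soft + 32)
    for p, name in enumerate(soft):
        a, b_ = pair_names[name]
        A_ub[2 * p, cell(a)] = 1.0
        A_ub[2 * p, cell(b_)] = -1.0
        A_ub[2 * p, 16 + p] = -1.0
        A_ub[2 * p + 1, cell(a)] = -1.0
        A_ub[2 * p + 1, cell(b_)] = 1.0
        A_ub[2 * p + 1, 16 + p] = -1.0
    for i in range(16):
        r0 = 2 * n_soft + 2 * i
        A_ub[r0, i] = 1.0
        A_ub[r0, 16 + n_soft + i] = -1.0
        b_ub[r0] = 1.0 / 16.0
        A_ub[r0 + 1, i] = -1.0
        A_ub[r0 + 1, 16 + n_soft + i] = -1.0
        b_ub[r0 + 1] = -1.0 / 16.0
    obj = np.zeros(nv)
    obj[16 : 16 + n_soft] = 1.0
    obj[16 + n_soft :] = 0.05  # weak pull toward the uniform matrix
    floor = 1.0 / 100.0  # every dinucleotide kept at >= 1% for ergodicity
    bounds = [(floor, 1.0)] * 16 + [(0.0, 1.0)] * (n_soft + 16)
    res = linprog(obj, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(
            f"infeasible ratio combination {hard}: no strictly positive "
            "stationary dinucleotide matrix satisfies ratio + stationarity "
            "constraints (note: pinning all four pairs to (r,1,1,1) with "
            "r != 1 is structurally impossible for a first-order chain)"
        )
    F = res.x[:16].reshape(4, 4)
    for name, r in hard.items():
        a, b_ = pair_names[name]
        if abs(F.flat[cell(a)] / F.flat[cell(b_)] - r) >= tol:
            raise RuntimeError(f"markov_from_ratios outside tolerance for {name}")
    pi = F.sum(axis=1)
    transition = F / pi[:, None]
    return MarkovModel(pi, transition)


def simulate_sequence(
    model: MarkovModel, length: int, seed: int, record_id: str = "sim"
) -> SequenceRecord:
    """Simulate one DNA record from a first-order chain (seeded)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    cum = [tuple(np.cumsum(row)) for row in model.transition]
    us = rng.random(length)
    init_cum = tuple(np.cumsum(model.initial))
    state = _pick(init_cum, us[0])
    out = [state]
    append = out.append
    for u in us[1:].tolist():
        c = cum[state]
        state = 0 if u < c[0] else 1 if u < c[1] else 2 if u < c[2] else 3
        append(state)
    seq = "".join(_BASES[s] for s in out)
    return SequenceRecord(record_id, seq, Alphabet.DNA)


def _pick(cum: tuple, u: float) -> int:
    for i, c in enumerate(cum):
        if u < c:
            return i
    return len(cum) - 1


def simulate_transcripts(
    model5: MarkovModel,
    model_cds: MarkovModel,
    model3: MarkovModel,
    n: int,
    region_lengths: tuple[int, int, int] = (200, 1340, 800),
    seed: int = 0,
    id_prefix: str = "tx",
) -> tuple[list[SequenceRecord], list[RegionAnnotation]]:
    """Simulate transcripts with 5'UTR / CDS / 3'UTR structure.

    Each transcript concatenates three independently generated region
    sequences; the default region lengths (200 / 1340 / 800 nt) are
    typical mRNA averages. Returns records plus matching annotations.
    """
    l5, lc, l3 = region_lengths
    if min(l5, lc, l3) < 0:
        raise ValueError("region lengths must be non-negative")
    if l5 + lc + l3 == 0:
        raise ValueError("at least one region length must be positive")
    rng = np.random.default_rng(seed)
    records, annotations = [], []
    for i in range(n):
        parts = []
        for model, length in ((model5, l5), (model_cds, lc), (model3, l3)):
            if length > 0:
                sub = int(rng.integers(0, 2**31 - 1))
                parts.append(simulate_sequence(model, length, sub).seq)
        tid = f"{id_prefix}{i + 1}"
        records.append(SequenceRecord(tid, "".join(parts), Alphabet.DNA))
        annotations.append(RegionAnnotation(tid, l5, lc, l3))
    return records, annotations


@dataclass(frozen=True)
class PanelSpec:
    """Blueprint for a planted-motif disease panel.

    ``planted_motifs`` maps each motif string to the target ids that
    carry it. ``clean`` additionally guarantees (by redraw) that no
    *other* window of ``cell_size`` characters is shared between any two
    targets and that each planted motif is maximal (its carriers do not
    all agree on a flanking character), so the planted motifs are
    exactly the panel's shared-sequence ground truth.
    """

    n_targets: int
    n_background: int
    seq_length: int
    planted_motifs: dict[str, tuple[str, ...]] = field(default_factory=dict)
    alphabet: Alphabet = Alphabet.DNA
    cell_size: int | None = None
    clean: bool = True
    both_strands: bool = False
    seed: int = 0
    id_prefix: str = "T"
    bg_prefix: str = "B"

    def target_ids(self) -> list[str]:
        return [f"{self.id_prefix}{i + 1}" for i in range(self.n_targets)]

    def background_ids(self) -> list[str]:
        return [f"{self.bg_prefix}{i + 1}" for i in range(self.n_background)]


def _random_seq(rng: np.random.Generator, length: int, alphabet: Alphabet,
                model: MarkovModel | None) -> str:
    if alphabet is Alphabet.PROTEIN:
        return "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length))
    if model is None:
        return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
    sub = int(rng.integers(0, 2**31 - 1))
    return simulate_sequence(model, length, sub).seq


def _contains_any(seq: str, motifs, both_strands: bool) -> bool:
    for m in motifs:
        if m in seq:
            return True
        if both_strands and reverse_complement(m) in seq:
            return True
    return False


def _plant(
    rng: np.random.Generator,
    base_seq: str,
    carried: list[str],
) -> tuple[str, dict[str, int]] | None:
    """Overwrite carried motifs into a sequence at non-overlapping offsets."""
    L = len(base_seq)
    placed: dict[str, int] = {}
    taken: list[tuple[int, int]] = []
    for m in carried:
        ok = False
        for _ in range(100):
            off = int(rng.integers(0, L - len(m) + 1))
            span = (off, off + len(m))
            if all(span[1] <= s or span[0] >= e for s, e in taken):
                taken.append(span)
                placed[m] = off
                ok = True
                break
        if not ok:
            return None
    chars = list(base_seq)
    for m, off in placed.items():
        chars[off : off + len(m)] = m
    return "".join(chars), placed


def _count_substring(hay: str, needle: str) -> int:
    n, start = 0, hay.find(needle)
    while start != -1:
        n += 1
        start = hay.find(needle, start + 1)
    return n


def simulate_panel(
    spec: PanelSpec,
    model: MarkovModel | None = None,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[dict]]:
    """Build a planted-motif panel: (targets, background, truth table).

    Motifs are written into their carriers at random offsets; background
    records and non-carrier targets are redrawn until free of every
    planted motif (and of its reverse complement when ``both_strands``).
    Each carrier contains its motif exactly once, at the recorded offset.
    The truth table lists one row per (motif, carrier) with that offset.
    With ``spec.clean`` the panel is additionally redrawn until the
    planted motifs are its *only* shared sequences of cell size or
    longer, and are maximal.

    DNA records come from ``model`` (i.i.d. uniform when None); protein
    records are i.i.d. uniform over the 20 amino acids.
    """
    from .finder import DEFAULT_CELL_SIZE  # local import avoids a cycle

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    alphabet = spec.alphabet
    motifs = [m.upper() for m in spec.planted_motifs]
    carriers_of = {
        m.upper(): tuple(c) for m, c in spec.planted_motifs.items()
    }
    cell_size = spec.cell_size or DEFAULT_CELL_SIZE[alphabet]
    target_ids = spec.target_ids()
    for m in motifs:
        if len(m) >= spec.seq_length:
            raise ValueError(f"motif {m!r} not shorter than seq_length {spec.seq_length}")
        if len(m) < cell_size:
            raise ValueError(
                f"motif {m!r} shorter than cell size {cell_size}: it could "
                "neither be excluded reliably nor recovered by the search"
            )
        unknown = set(carriers_of[m]) - set(target_ids)
        if unknown:
            raise ValueError(f"motif {m!r}: carriers {sorted(unknown)} not in target ids")
    for a in motifs:
        for b in motifs:
            if a != b and a in b:
                raise ValueError(f"motif {a!r} is a substring of motif {b!r}")

    carried_by: dict[str, list[str]] = {tid: [] for tid in target_ids}
    for m in motifs:
        for tid in carriers_of[m]:
            carried_by[tid].append(m)

    def draw_target(tid: str) -> tuple[str, dict[str, int]]:
        carried = carried_by[tid]
        forbidden = [m for m in motifs if m not in carried]
        for _ in range(MAX_REDRAWS):
            base = _random_seq(rng, spec.seq_length, alphabet, model)
            planted = _plant(rng, base, carried)
            if planted is None:
                continue
            seq, offsets = planted
            if _contains_any(seq, forbidden, spec.both_strands):
                continue
            if any(_count_substring(seq, m) != 1 for m in carried):
                continue
            if spec.both_strands and any(
                reverse_complement(m) in seq for m in carried
            ):
                continue
            return seq, offsets
        raise RuntimeError(
            f"could not draw target {tid} free of non-carried motifs "
            f"after {MAX_REDRAWS} attempts"
        )

    def draw_background() -> str:
        for _ in range(MAX_REDRAWS):
            seq = _random_seq(rng, spec.seq_length, alphabet, model)
            if not _contains_any(seq, motifs, spec.both_strands):
                return seq
        raise RuntimeError(
            f"could not draw a background record free of all motifs "
            f"after {MAX_REDRAWS} attempts (motifs too short to exclude?)"
        )

    target_seqs: dict[str, str] = {}
    offsets_of: dict[str, dict[str, int]] = {}
    for tid in target_ids:
        target_seqs[tid], offsets_of[tid] = draw_target(tid)

    if spec.clean:
        for round_ in range(MAX_REDRAWS):
            bad = _clean_violation(target_seqs, offsets_of, motifs, carriers_of, cell_size)
            if bad is None:
                break
            target_seqs[bad], offsets_of[bad] = draw_target(bad)
        else:
            raise RuntimeError("could not build a clean panel; try longer motifs")

    targets = [
        SequenceRecord(tid, target_seqs[tid], alphabet) for tid in target_ids
    ]
    background = [
        SequenceRecord(bid, draw_background(), alphabet)
        for bid in spec.background_ids()
    ]
    truth = [
        {"motif": m, "target_id": tid, "offset": offsets_of[tid][m]}
        for m in motifs
        for tid in carriers_of[m]
    ]
    # post-hoc exact-match audit of the exclusion guarantee
    for m in motifs:
        for rec in background:
            assert m not in rec.seq
        for rec in targets:
            carried = rec.id in carriers_of[m]
            assert (m in rec.seq) == carried, (m, rec.id)
    return targets, background, truth


def _clean_violation(
    target_seqs: dict[str, str],
    offsets_of: dict[str, dict[str, int]],
    motifs: list[str],
    carriers_of: dict[str, tuple[str, ...]],
    cell_size: int,
) -> str | None:
    """Return a target id to redraw, or None if the panel is clean.

    Clean means: (1) every window of ``cell_size`` characters shared by
    two targets lies inside a motif both carry; (2) no motif is
    extendable — its carriers do not all agree on the character
    immediately before (or after) their planted occurrence.
    """
    allowed: dict[str, frozenset[str]] = {}
    for m in motifs:
        carriers = frozenset(carriers_of[m])
        for i in range(len(m) - cell_size + 1):
            w = m[i : i + cell_size]
            allowed[w] = allowed.get(w, frozenset()) | carriers
    window_owners: dict[str, set[str]] = {}
    for tid, seq in target_seqs.items():
        for i in range(len(seq) - cell_size + 1):
            window_owners.setdefault(seq[i : i + cell_size], set()).add(tid)
    for w, owners in window_owners.items():
        if len(owners) >= 2 and not owners <= allowed.get(w, frozenset()):
            # redraw the last involved target (deterministic choice)
            return sorted(owners)[-1]
    for m in motifs:
        carriers = carriers_of[m]
        if len(carriers) < 2:
            continue
        for side in (-1, +1):
            flanks = []
            for tid in carriers:
                off = offsets_of[tid][m]
                pos = off - 1 if side < 0 else off + len(m)
                seq = target_seqs[tid]
                flanks.append(seq[pos] if 0 <= pos < len(seq) else None)
            if None not in flanks and len(set(flanks)) == 1:
                return sorted(carriers)[-1]
    return None
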