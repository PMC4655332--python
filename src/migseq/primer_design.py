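"""ISSR primer-set design by combinatorial string rules.

Enumerates candidate inter-simple-sequence-repeat (ISSR) primers — a 12-base
SSR core (a 2-base motif repeated six times or a 3-base motif repeated four
times) plus a 2-base 3' anchor — applies a series of string-level rejection
rules (no thermodynamics), attaches the constant Illumina-adapter tails, and
assembles multiplex-compatible sets in which no primer's 3' end can prime on
another primer.

Rule summary (roman numerals follow the published numbering):

  i    the 14-nt annealing part is itself a pure repeat (period <= 3);
  ii   it is exactly one base away from some pure 14-mer SSR;
  iii  the 3'-terminal three bases are all G/C;
  iv   it contains fewer than three distinct bases;
  v    the reverse complement of the 3'-terminal 4-mer occurs within it.

A candidate may match several rules; the primary label reported is the one
consistent with the published worked examples, which requires the internal
evaluation order i, v, iii, iv, ii (e.g. (ACC)4GG ends in CGG, all G/C, but
is classified as a rule-v self-complementarity failure).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from . import constants as C
from ._seq import hamming, require_dna, revcomp

RULE_DESCRIPTIONS = {
    "i": "annealing part is only a repeated sequence",
    "ii": "only one base difference from a simple sequence repeat",
    "iii": "GC rich on the three bases of the 3' end",
    "iv": "fewer than three different bases",
    "v": "reverse-complement of the 3'-terminal four bases occurs internally",
    "vi": "3'-end reverse-complement (>=4 bases) hit in own or counterpart primer",
}

# first-match order consistent with all published rejection examples
_RULE_EVAL_ORDER = ("i", "v", "iii", "iv", "ii")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Anchor:
    """Two-base 3' anchor; the last base must be C or G, and CG/GC are excluded."""

    seq: str

    def __post_init__(self):
        require_dna(self.seq, "anchor")
        if self.seq not in C.ANCHORS:
            raise ValueError(f"inadmissible anchor {self.seq!r}; allowed: {C.ANCHORS}")


@dataclass(frozen=True)
class CoreMotif:
    """SSR core motif (2 or 3 bases) repeated to a 12-base primer core."""

    seq: str
    repeat_count: int
    set_membership: str  # "main" | "alternative"

    def __post_init__(self):
        require_dna(self.seq, "core motif")
        if len(self.seq) * self.repeat_count != 12:
            raise ValueError("core motif must repeat to exactly 12 bases")
        if self.set_membership not in ("main", "alternative"):
            raise ValueError(f"invalid set membership {self.set_membership!r}")

    @property
    def core_seq(self) -> str:
        return self.seq * self.repeat_count


@dataclass(frozen=True)
class PrimerCandidate:
    """A core motif + anchor with its 14-nt genomic-annealing sequence."""

    core: CoreMotif
    anchor: Anchor
    annealing_seq: str
    rejection: Optional[tuple] = None  # (rule id, reason) or None
    matched_rules: tuple = ()

    def __post_init__(self):
        expected = self.core.core_seq + self.anchor.seq
        if self.annealing_seq != expected or len(self.annealing_seq) != C.ANNEALING_LEN:
            raise ValueError("annealing_seq must be core repeated plus anchor (14 nt)")

    @property
    def passed(self) -> bool:
        return self.rejection is None

    @property
    def base_name(self) -> str:
        return f"({self.core.seq})_{self.core.repeat_count}{self.anchor.seq}"


@dataclass(frozen=True)
class TailedPrimer:
    """31-nt 1st-PCR primer: 14 nt tail + 3 nt 2nd-PCR anchor + 14 nt annealing."""

    candidate: PrimerCandidate
    direction: str  # "forward" | "reverse"
    tail: str
    pcr2_anchor: str
    full_seq: str
    name: str

    def __post_init__(self):
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.full_seq != self.tail + self.pcr2_anchor + self.candidate.annealing_seq:
            raise ValueError("full_seq must be tail + 2nd-PCR anchor + annealing part")
        if len(self.full_seq) != C.TAILED_PRIMER_LEN:
            raise ValueError("tailed primer must be 31 nt")

    @property
    def annealing_seq(self) -> str:
        return self.candidate.annealing_seq


@dataclass
class PrimerSet:
    """A multiplex set of forward/reverse tailed primer pairs."""

    name: str
    members: list  # list[tuple[TailedPrimer, TailedPrimer]]
    compatibility_ok: bool = True
    conflict_log: list = field(default_factory=list)

    def all_primers(self) -> list:
        return [p for pair in self.members for p in pair]

    def annealing_seqs(self) -> list:
        return [pair[0].annealing_seq for pair in self.members]

    def __len__(self) -> int:
        return len(self.members)


class InfeasibleSetError(RuntimeError):
    """Raised when no conflict-free set of the requested size exists; carries
    the maximal conflict-free set found in ``max_set``."""

    def __init__(self, message, max_set: PrimerSet):
        super().__init__(message)
        self.max_set = max_set


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def enumerate_anchors() -> list:
    """The fixed admissible anchor list (lexicographic)."""
    return [Anchor(a) for a in sorted(C.ANCHORS)]


def _rotations(motif: str) -> list:
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def enumerate_core_motifs(set_membership: str) -> list:
    """Admissible core motifs of one set.

    Three-distinct-base trimers: all 24 permutations, split into reverse-
    complement halves (the lexicographically smaller member of each pair is
    "main").  Dimers: AC/CA (main) and TG/GT (alternative); polypurine,
    polypyrimidine, GC-rich and GC-poor dimers are excluded.  Two-distinct-base
    trimers: the AAC- and CCA-rotation classes (main) and their reverse
    complements (alternative).
    """
    if set_membership not in ("main", "alternative"):
        raise ValueError(f"set_membership must be 'main' or 'alternative', got {set_membership!r}")

    three_distinct = ["".join(p) for p in itertools.permutations("ACGT", 3)]
    main3 = sorted(m for m in three_distinct if m < revcomp(m))
    alt3 = sorted(revcomp(m) for m in main3)

    main2 = ["AC", "CA"]
    alt2 = ["TG", "GT"]

    main3_2 = sorted(set(_rotations("AAC") + _rotations("CCA")))
    alt3_2 = sorted({revcomp(m) for m in main3_2})

    if set_membership == "main":
        motifs = [(m, 6) for m in main2] + [(m, 4) for m in main3 + main3_2]
    else:
        motifs = [(m, 6) for m in alt2] + [(m, 4) for m in alt3 + alt3_2]
    motifs.sort(key=lambda t: (len(t[0]), t[0]))
    return [CoreMotif(m, k, set_membership) for m, k in motifs]


def make_candidate(core: CoreMotif, anchor: Anchor) -> PrimerCandidate:
    return PrimerCandidate(core=core, anchor=anchor, annealing_seq=core.core_seq + anchor.seq)


def candidate_from_parts(motif: str, repeat_count: int, anchor: str,
                         set_membership: str = "main") -> PrimerCandidate:
    """Convenience constructor used for published primers and tests."""
    return make_candidate(CoreMotif(motif, repeat_count, set_membership), Anchor(anchor))


# ---------------------------------------------------------------------------
# rejection rules
# ---------------------------------------------------------------------------

def _pure_repeat_14mers() -> frozenset:
    """All 14-mers that are pure extensions of a 2- or 3-letter motif."""
    out = set()
    for k in (2, 3):
        for motif in ("".join(p) for p in itertools.product("ACGT", repeat=k)):
            out.add((motif * C.ANNEALING_LEN)[: C.ANNEALING_LEN])
    return frozenset(out)


_PURE_14MERS = _pure_repeat_14mers()


def _rule_i(seq: str) -> bool:
    return any(all(seq[j] == seq[j - p] for j in range(p, len(seq))) for p in (1, 2, 3))


def _rule_ii(seq: str) -> bool:
    return any(hamming(seq, pure) == 1 for pure in _PURE_14MERS)


def _rule_iii(seq: str) -> bool:
    return all(b in "GC" for b in seq[-3:])


def _rule_iv(seq: str) -> bool:
    return len(set(seq)) < 3


def _rule_v(seq: str) -> bool:
    return revcomp(seq[-4:]) in seq


_RULE_FUNCS = {"i": _rule_i, "ii": _rule_ii, "iii": _rule_iii, "iv": _rule_iv, "v": _rule_v}


def apply_rejection_rules(candidate: PrimerCandidate) -> PrimerCandidate:
    """Return the candidate with its ``rejection`` field populated (or None).

    The primary rule id is the first match in the order i, v, iii, iv, ii
    (see module docstring); all matched rules are kept in ``matched_rules``.
    """
    seq = candidate.annealing_seq
    if len(seq) != C.ANNEALING_LEN:
        raise ValueError("candidate annealing sequence must be 14 nt")
    matched = tuple(r for r in _RULE_EVAL_ORDER if _RULE_FUNCS[r](seq))
    rejection = (matched[0], RULE_DESCRIPTIONS[matched[0]]) if matched else None
    return replace(candidate, rejection=rejection, matched_rules=matched)


# ---------------------------------------------------------------------------
# tail attachment and dimer screens
# ---------------------------------------------------------------------------

def attach_tails(candidate: PrimerCandidate):
    """Both direction variants of a candidate (forward, reverse)."""
    fwd = TailedPrimer(
        candidate=candidate, direction="forward",
        tail=C.FORWARD_TAIL, pcr2_anchor=C.FORWARD_PCR2_ANCHOR,
        full_seq=C.FORWARD_TAIL + C.FORWARD_PCR2_ANCHOR + candidate.annealing_seq,
        name=candidate.base_name + "-f",
    )
    rev = TailedPrimer(
        candidate=candidate, direction="reverse",
        tail=C.REVERSE_TAIL, pcr2_anchor=C.REVERSE_PCR2_ANCHOR,
        full_seq=C.REVERSE_TAIL + C.REVERSE_PCR2_ANCHOR + candidate.annealing_seq,
        name=candidate.base_name + "-r",
    )
    return fwd, rev


def check_tailed_self_dimer(primer: TailedPrimer, counterpart: TailedPrimer,
                            max_window: int = 6):
    """Step-6 screen: fail iff the reverse complement of a 3'-terminal window of
    more than three bases (4..max_window) occurs in either full sequence.

    A match of a longer window implies a match of the 4-mer window, so the scan
    over window lengths is redundant but kept explicit for the conflict report.
    """
    conflicts = []
    for w in range(4, max_window + 1):
        probe = revcomp(primer.full_seq[-w:])
        for other in (primer, counterpart):
            pos = other.full_seq.find(probe)
            if pos != -1:
                conflicts.append((primer.name, other.name, probe))
    return (len(conflicts) == 0), conflicts


def _step7_pair_conflicts(a: TailedPrimer, b: TailedPrimer):
    """Step-7 rule: the reverse complement of a's 3'-terminal 3-mer must not
    occur anywhere within b's full sequence."""
    probe = revcomp(a.full_seq[-3:])
    if probe in b.full_seq:
        return (a.name, b.name, probe)
    return None


def step7_conflicts(primers: Sequence[TailedPrimer]) -> list:
    """All ordered 3'-terminal-3-mer reverse-complement conflicts in a set."""
    out = []
    for a in primers:
        for b in primers:
            if a.full_seq == b.full_seq:
                continue
            hit = _step7_pair_conflicts(a, b)
            if hit:
                out.append(hit)
    return out


# ---------------------------------------------------------------------------
# multiplex set assembly
# ---------------------------------------------------------------------------

def _pairs_compatible(p: tuple, q: tuple) -> bool:
    for a in p:
        for b in q:
            if _step7_pair_conflicts(a, b) or _step7_pair_conflicts(b, a):
                return False
    return True


def select_multiplex_set(candidates: Sequence[tuple], target_size: int = None,
                         strategy: str = "greedy", seed: int = None,
                         n_restarts: int = 0, validate: bool = False,
                         name: str = "custom") -> PrimerSet:
    """Assemble (or validate) a multiplex-compatible primer set.

    ``candidates`` is a sequence of (forward, reverse) TailedPrimer pairs.  In
    validate mode the supplied set is checked as-is and returned with its
    conflict log.  Otherwise a deterministic greedy pass over lexicographically
    ordered candidates builds a conflict-free set of ``target_size`` pairs;
    optional seeded random restarts search alternative orders.  If the target
    is infeasible an :class:`InfeasibleSetError` carrying the maximal set found
    is raised.
    """
    candidates = list(candidates)
    if validate:
        primers = [p for pair in candidates for p in pair]
        log = step7_conflicts(primers)
        return PrimerSet(name=name, members=candidates,
                         compatibility_ok=not log, conflict_log=log)

    if target_size is None:
        target_size = len(candidates)
    if target_size < 1:
        raise ValueError("target_size must be >= 1")

    # pairs whose own two directions conflict can never be members
    usable = [pair for pair in candidates
              if not step7_conflicts(list(pair))]

    def greedy(order):
        chosen = []
        for pair in order:
            if len(chosen) == target_size:
                break
            if all(_pairs_compatible(pair, q) for q in chosen):
                chosen.append(pair)
        return chosen

    base_order = sorted(usable, key=lambda pair: pair[0].annealing_seq)
    best = greedy(base_order)
    if len(best) < target_size and n_restarts:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            order = list(base_order)
            rng.shuffle(order)
            trial = greedy(order)
            if len(trial) > len(best):
                best = trial
            if len(best) >= target_size:
                break

    result = PrimerSet(name=name, members=best, compatibility_ok=True, conflict_log=[])
    if len(best) < target_size:
        raise InfeasibleSetError(
            f"no conflict-free set of size {target_size}; maximal set found has "
            f"{len(best)} pairs", result)
    return result


# ---------------------------------------------------------------------------
# full design pipeline and published set
# ---------------------------------------------------------------------------

def design_candidates(set_membership: str = "main"):
    """Enumerate anchor x motif candidates and apply the rejection rules.

    Returns (passed, rejected) lists of :class:`PrimerCandidate`.
    """
    passed, rejected = [], []
    for motif in enumerate_core_motifs(set_membership):
        for anchor in enumerate_anchors():
            cand = apply_rejection_rules(make_candidate(motif, anchor))
            (passed if cand.passed else rejected).append(cand)
    return passed, rejected


def design_primer_pool(set_membership: str = "main"):
    """Candidates surviving rules i-v and the step-6 tailed self-dimer screen,
    as (forward, reverse) pairs in deterministic order."""
    passed, _ = design_candidates(set_membership)
    pool = []
    for cand in passed:
        fwd, rev = attach_tails(cand)
        ok_f, _ = check_tailed_self_dimer(fwd, rev)
        ok_r, _ = check_tailed_self_dimer(rev, fwd)
        if ok_f and ok_r:
            pool.append((fwd, rev))
    pool.sort(key=lambda pair: pair[0].annealing_seq)
    return pool


def design_set(set_membership: str = "main", target_size: int = 8,
               seed: int = None, n_restarts: int = 20) -> PrimerSet:
    """End-to-end design: enumerate, reject, tail, and select a multiplex set."""
    pool = design_primer_pool(set_membership)
    return select_multiplex_set(pool, target_size=target_size, seed=seed,
                                n_restarts=n_restarts, name=set_membership)


def _classify_membership(motif: str) -> str:
    for membership in ("main", "alternative"):
        if motif in {m.seq for m in enumerate_core_motifs(membership)}:
            return membership
    return "main"


def published_set1() -> PrimerSet:
    """The published recommended multiplex set (set-1), eight primer pairs."""
    members = []
    for motif, count, anchor in C.SET1_DEFINITIONS:
        cand = apply_rejection_rules(
            candidate_from_parts(motif, count, anchor, _classify_membership(motif)))
        members.append(attach_tails(cand))
    return select_multiplex_set(members, validate=True, name="set-1")


def indexed_reverse_pcr2_primer(index: str) -> str:
    """Fill the six-base sample index into the 2nd-PCR reverse primer template."""
    require_dna(index, "index")
    if len(index) != C.INDEX_LEN:
        raise ValueError("index must be six bases")
    return C.INDEXED_REVERSE_PCR2_TEMPLATE.replace("x" * C.INDEX_LEN, index)


def primer_set_to_table(pset: PrimerSet):
    """Rows (name, direction, full_seq, core, anchor, set) for TSV export."""
    rows = []
    for fwd, rev in pset.members:
        for p in (fwd, rev):
            rows.append({
                "name": p.name,
                "direction": p.direction,
                "full_seq": p.full_seq,
                "core": p.candidate.core.seq,
                "anchor": p.candidate.anchor.seq,
                "set": pset.name,
            })
    return rows
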