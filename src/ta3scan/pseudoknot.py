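"""H-type pseudoknot prediction for antitoxin-repeat-scale RNAs.

An H-type pseudoknot consists of two crossing helices: stem S1 (segments
a1/b1) and stem S2 (a2/b2) occurring in the order a1 < a2 < b1 < b2 along the
sequence, with loops L1 (between a1 and a2) and L2 (between b1 and b2). The
predictor scores structures by weighted base-pair counts (G:C 3, A:U 2,
G:U 1) and searches exhaustively over all crossing, base-disjoint helix
pairs — tractable and fully auditable for repeats of ~36 nt.

Noncanonical pairs (e.g. the U·U pair closing stem S2 in the antitoxin
repeat crystal structure) are annotation-only: they are added by
`annotate_noncanonical`, never predicted de novo.

The repeat numbering convention runs -3..32 (including 0): a 4-nt 5'
overhang (-3..0), a 25-nt core (1..25) and a 7-nt 3' overhang (26..32).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "ToxIRepeat",
    "Helix",
    "PseudoknotStructure",
    "IminoCount",
    "enumerate_helices",
    "predict_h_pseudoknot",
    "annotate_noncanonical",
    "count_iminos",
    "to_bracket",
    "parse_bracket",
    "DEFAULT_SCORING",
]

DEFAULT_SCORING = {"GC": 3, "AU": 2, "GU": 1}

_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

# per-pair-geometry count of hydrogen-bonded, exchange-protected imino protons
_IMINOS_PER_CLASS = {"GC": 1, "AU": 1, "GU": 2, "UU": 2}


def _norm_rna(seq: str) -> str:
    seq = seq.upper()
    if "T" in seq:
        warnings.warn("DNA alphabet detected; converting T -> U", stacklevel=3)
        seq = seq.replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid RNA letters: {sorted(bad)}")
    return seq


def _pair_class(a: str, b: str) -> str:
    key = "".join(sorted((a, b)))
    return {"CG": "GC", "AU": "AU", "GU": "GU", "UU": "UU", "AA": "AA", "CC": "CC", "GG": "GG", "AC": "AC", "AG": "AG", "CU": "CU"}[key]


@dataclass(frozen=True)
class ToxIRepeat:
    """A full-length antitoxin repeat with the -3..32 numbering convention.

    The first base is position -3; position 0 exists, so index = position + 3.
    """

    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", _norm_rna(self.sequence))
        if len(self.sequence) != 36:
            raise ValueError("full numbering requires a 36-nt repeat")

    def index(self, position: int) -> int:
        if not -3 <= position <= 32:
            raise ValueError(f"position {position} outside -3..32")
        return position + 3

    def position(self, index: int) -> int:
        if not 0 <= index < 36:
            raise ValueError(f"index {index} out of range")
        return index - 3

    @property
    def core(self) -> str:
        """Positions 1..25: the pseudoknot-forming core."""
        return self.sequence[self.index(1) : self.index(25) + 1]


@dataclass(frozen=True)
class Helix:
    """A contiguous helix: pairs (i+t, j-t) for t in 0..length-1."""

    i: int
    j: int
    length: int

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("helix length < 1")
        if not self.i + self.length - 1 < self.j - self.length + 1:
            raise ValueError("helix strands overlap (self-crossing)")

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [(self.i + t, self.j - t) for t in range(self.length)]

    @property
    def strand5(self) -> tuple[int, int]:
        return (self.i, self.i + self.length)

    @property
    def strand3(self) -> tuple[int, int]:
        return (self.j - self.length + 1, self.j + 1)

    def bases(self) -> set[int]:
        out = set(range(*self.strand5))
        out |= set(range(*self.strand3))
        return out

    def pair_classes(self, seq: str) -> list[str]:
        return [_pair_class(seq[a], seq[b]) for a, b in self.pairs]

    def score(self, seq: str, scoring: dict[str, int]) -> int:
        return sum(scoring.get(c, 0) for c in self.pair_classes(seq))


def enumerate_helices(seq: str, min_bp: int = 3, allow_gu: bool = True, maximal_only: bool = True) -> list[Helix]:
    """All helices of >= min_bp contiguous pairs under {A:U, G:C, G:U}.

    With ``maximal_only`` (default) only helices that cannot be extended
    outward or inward are returned; otherwise every contiguous sub-helix of
    length >= min_bp is enumerated (the substrate for pseudoknot search).
    """
    seq = _norm_rna(seq)
    if len(seq) > 200:
        raise ValueError("sequence too long (> 200 nt)")
    if allow_gu:
        allowed = set(_CANONICAL)
    else:
        allowed = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}

    def paired(i: int, j: int) -> bool:
        return (seq[i], seq[j]) in allowed

    n = len(seq)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if not paired(i, j):
                continue
            # maximal run starting outward at (i, j)
            if i > 0 and j < n - 1 and paired(i - 1, j + 1):
                continue  # not outer-maximal; covered by the outer start
            k = 0
            while i + k < j - k and paired(i + k, j - k):
                k += 1
            if k >= min_bp:
                out.append(Helix(i=i, j=j, length=k))
    if not maximal_only:
        subs = set()
        for h in out:
            for length in range(min_bp, h.length + 1):
                for off in range(h.length - length + 1):
                    subs.add((h.i + off, h.j - off, length))
        out = [Helix(i=a, j=b, length=L) for a, b, L in sorted(subs)]
    else:
        out.sort(key=lambda h: (h.i, h.j))
    return out


@dataclass
class PseudoknotStructure:
    """Two crossing stems S1/S2 plus optional annotated noncanonical pairs."""

    sequence: str
    s1: Helix
    s2: Helix
    noncanonical: list[tuple[int, int]] = field(default_factory=list)
    scoring: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SCORING))

    def __post_init__(self):
        self.sequence = _norm_rna(self.sequence)
        if not _crossing(self.s1, self.s2):
            raise ValueError("S1 and S2 do not form a crossing (H-type) topology")
        if self.s1.bases() & self.s2.bases():
            raise ValueError("a base participates in both stems")
        used = self.s1.bases() | self.s2.bases()
        for a, b in self.noncanonical:
            if not (0 <= a < len(self.sequence) and 0 <= b < len(self.sequence)):
                raise ValueError(f"annotated pair ({a}, {b}) out of range")
            if a in used or b in used:
                raise ValueError(f"annotated pair ({a}, {b}) clashes with a paired base")
            used |= {a, b}

    @property
    def loop1(self) -> tuple[int, int]:
        return (self.s1.strand5[1], self.s2.strand5[0])

    @property
    def loop2(self) -> tuple[int, int]:
        return (self.s1.strand3[1], self.s2.strand3[0])

    @property
    def n_pairs(self) -> int:
        return self.s1.length + self.s2.length + len(self.noncanonical)

    @property
    def score(self) -> int:
        return self.s1.score(self.sequence, self.scoring) + self.s2.score(self.sequence, self.scoring)

    def all_pairs(self) -> list[tuple[int, int, str]]:
        out = [(a, b, c) for (a, b), c in zip(self.s1.pairs, self.s1.pair_classes(self.sequence))]
        out += [(a, b, c) for (a, b), c in zip(self.s2.pairs, self.s2.pair_classes(self.sequence))]
        for a, b in self.noncanonical:
            out.append((a, b, _pair_class(self.sequence[a], self.sequence[b])))
        return out


def _crossing(h1: Helix, h2: Helix) -> bool:
    """True iff every pair of h1 crosses every pair of h2 (order a1 a2 b1 b2)."""
    a1, a2 = h1.strand5, h2.strand5
    b1, b2 = h1.strand3, h2.strand3
    return a1[1] <= a2[0] and a2[1] <= b1[0] and b1[1] <= b2[0]


def predict_h_pseudoknot(
    seq: str,
    scoring: dict[str, int] | None = None,
    min_bp: int = 3,
    allow_gu: bool = True,
) -> PseudoknotStructure | None:
    """Maximum-score H-type pseudoknot over all crossing helix pairs.

    Ties are broken by more total base pairs, then by the 5'-most S1.
    Returns ``None`` when no crossing helix pair exists.
    """
    seq = _norm_rna(seq)
    if len(seq) > 100:
        raise ValueError("exhaustive search bound exceeded (> 100 nt)")
    if scoring is None:
        scoring = dict(DEFAULT_SCORING)
    helices = enumerate_helices(seq, min_bp=min_bp, allow_gu=allow_gu, maximal_only=False)
    scored = sorted(
        ((h.score(seq, scoring), h) for h in helices), key=lambda t: -t[0]
    )
    best = None
    best_key = None
    top = scored[0][0] if scored else 0
    for sc1, h1 in scored:
        if best_key is not None and sc1 + top < best_key[0]:
            break  # no pair from here on can beat the incumbent
        for sc2, h2 in scored:
            total = sc1 + sc2
            if best_key is not None and total < best_key[0]:
                break
            first, second = (h1, h2) if h1.i < h2.i else (h2, h1)
            if not _crossing(first, second):
                continue
            key = (total, first.length + second.length, -first.i)
            if best_key is None or key > best_key:
                best_key = key
                best = (first, second)
    if best is None:
        return None
    return PseudoknotStructure(sequence=seq, s1=best[0], s2=best[1], scoring=scoring)


def annotate_noncanonical(
    structure: PseudoknotStructure,
    pairs: list[tuple[int, int]],
    override: bool = False,
) -> PseudoknotStructure:
    """Return a copy of `structure` carrying extra pairs labelled noncanonical.

    Positions must be unpaired in the input unless ``override`` is set.
    """
    if not pairs:
        return structure
    used = structure.s1.bases() | structure.s2.bases()
    for a, b in pairs:
        if not (0 <= a < len(structure.sequence) and 0 <= b < len(structure.sequence)):
            raise ValueError(f"annotated pair ({a}, {b}) out of range")
        if (a in used or b in used) and not override:
            raise ValueError(f"position in pair ({a}, {b}) is already canonically paired")
    return replace(structure, noncanonical=list(structure.noncanonical) + list(pairs))


@dataclass
class IminoCount:
    """Predicted count of hydrogen-bonded imino protons (1D NMR observables)."""

    total: int
    per_pair: list[tuple[int, int, str, int]]  # (i, j, class, iminos)

    def __post_init__(self):
        if self.total != sum(p[3] for p in self.per_pair):
            raise ValueError("total != sum of per-pair contributions")


def count_iminos(structure: PseudoknotStructure) -> IminoCount:
    """Count hydrogen-bonded iminos: G:C and A:U contribute 1 (G N1-H / U
    N3-H), G:U and U:U contribute 2 (both iminos hydrogen-bonded)."""
    per_pair = []
    for a, b, cls in structure.all_pairs():
        if cls not in _IMINOS_PER_CLASS:
            raise ValueError(f"unknown pair class {cls!r} for pair ({a}, {b})")
        per_pair.append((a, b, cls, _IMINOS_PER_CLASS[cls]))
    return IminoCount(total=sum(p[3] for p in per_pair), per_pair=per_pair)


_BRACKETS = {"s1": "()", "s2": "[]", "nc": "{}"}


def to_bracket(structure: PseudoknotStructure) -> str:
    """Extended dot-bracket: S1 as (), S2 as [], noncanonical pairs as {}."""
    n = len(structure.sequence)
    chars = ["."] * n
    groups = [
        (structure.s1.pairs, "()"),
        (structure.s2.pairs, "[]"),
        (structure.noncanonical, "{}"),
    ]
    for pairs, (op, cl) in groups:
        for a, b in pairs:
            if chars[a] != "." or chars[b] != ".":
                raise ValueError(f"conflicting pairs at ({a}, {b})")
            chars[a], chars[b] = op, cl
    return "".join(chars)


def parse_bracket(seq: str, bracket: str) -> PseudoknotStructure:
    """Parse an extended dot-bracket string back into a structure."""
    if len(seq) != len(bracket):
        raise ValueError("sequence and bracket string lengths differ")
    stacks: dict[str, list[int]] = {"()": [], "[]": [], "{}": []}
    pairs: dict[str, list[tuple[int, int]]] = {"()": [], "[]": [], "{}": []}
    for idx, ch in enumerate(bracket):
        for kind in stacks:
            if ch == kind[0]:
                stacks[kind].append(idx)
            elif ch == kind[1]:
                if not stacks[kind]:
                    raise ValueError(f"unbalanced {ch!r} at {idx}")
                pairs[kind].append((stacks[kind].pop(), idx))
    for kind, st in stacks.items():
        if st:
            raise ValueError(f"unbalanced {kind[0]!r}")

    def as_helix(plist: list[tuple[int, int]]) -> Helix:
        plist = sorted(plist)
        i0, j0 = plist[0]
        for t, (a, b) in enumerate(plist):
            if a != i0 + t or b != j0 - t:
                raise ValueError("bracket pairs do not form one contiguous helix")
        return Helix(i=i0, j=j0, length=len(plist))

    s1 = as_helix(pairs["()"])
    s2 = as_helix(pairs["[]"])
    return PseudoknotStructure(sequence=seq, s1=s1, s2=s2, noncanonical=sorted(pairs["{}"]))
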