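"""Annotation of candidate type III toxin-antitoxin loci.

A functional locus is expected to carry, in order on the toxin strand:

1. a sigma-70 promoter (-35 ``TTGACA`` and -10 ``TATAAT`` boxes, each with at
   most 2 mismatches, separated by a 15-19 nt spacer);
2. a tandem array of antitoxin repeats downstream of the -10 box, scored with
   the Tandem-Repeat-Finder weights (match +2, mismatch -7, indel -7,
   reporting threshold 50) under wraparound dynamic programming;
3. an intrinsic (rho-independent) terminator hairpin between the repeats and
   the toxin ORF (stem >= 4 bp, loop 3-8 nt, U-tract);
4. the toxin open reading frame (ATG/GTG start, first in-frame stop).

`classify_locus` combines the four elements into a verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PromoterHit",
    "RepeatFinderParams",
    "RepeatArray",
    "TerminatorHit",
    "OrfHit",
    "TALocusAnnotation",
    "extract_flanks",
    "scan_promoter",
    "find_tandem_repeats",
    "find_terminator",
    "find_orf",
    "classify_locus",
    "annotate_ta_locus",
    "revcomp",
]

MINUS35 = "TTGACA"
MINUS10 = "TATAAT"
SPACER_RANGE = (15, 19)
MAX_BOX_MISMATCHES = 2

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODONS = {"ATG", "GTG"}

# paired-base weights for terminator scoring
_PAIR_SCORE = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _norm_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# flank extraction


@dataclass
class FlankRegion:
    """A genomic window around an ORF, with its offset in genome space."""

    sequence: str
    genome_start: int  # 0-based offset of the window in the genome
    orf_interval: tuple[int, int]  # in genome coordinates

    def to_genome(self, pos: int) -> int:
        return pos + self.genome_start

    def to_region(self, pos: int) -> int:
        return pos - self.genome_start


def extract_flanks(genome: str, orf_interval: tuple[int, int], up: int = 1000, down: int = 1000) -> FlankRegion:
    """Extract the ORF plus up/down nt of flanking genome, clipped at the ends."""
    start, end = orf_interval
    if not (0 <= start < end <= len(genome)):
        raise ValueError(f"ORF interval {orf_interval} outside genome of length {len(genome)}")
    w_start = max(0, start - up)
    w_end = min(len(genome), end + down)
    return FlankRegion(sequence=genome[w_start:w_end], genome_start=w_start, orf_interval=orf_interval)


# ---------------------------------------------------------------------------
# promoter scan


@dataclass
class PromoterHit:
    """A -35/-10 box pair. `score` is the total consensus matches (max 12)."""

    minus35: tuple[int, int]
    minus10: tuple[int, int]
    spacer: int
    mismatches: tuple[int, int]  # (-35 box, -10 box)
    score: int

    def __post_init__(self):
        if self.minus35[1] > self.minus10[0]:
            raise ValueError("-35 box must lie upstream of the -10 box")
        if self.spacer != self.minus10[0] - self.minus35[1]:
            raise ValueError("spacer inconsistent with box intervals")


def _mismatches(window: str, consensus: str) -> int:
    return sum(a != b for a, b in zip(window, consensus))


def scan_promoter(
    seq: str,
    max_mismatches: int = MAX_BOX_MISMATCHES,
    spacer_range: tuple[int, int] = SPACER_RANGE,
    minus35: str = MINUS35,
    minus10: str = MINUS10,
) -> list[PromoterHit]:
    """All -35/-10 placements with <= max_mismatches per box and a valid
    spacer, sorted by score (desc), then leftmost -35 start."""
    seq = _norm_dna(seq)
    if len(seq) < 30:
        raise ValueError("sequence too short for a promoter scan (< 30 nt)")
    hits = []
    n35, n10 = len(minus35), len(minus10)
    for i in range(len(seq) - n35 + 1):
        mm35 = _mismatches(seq[i : i + n35], minus35)
        if mm35 > max_mismatches:
            continue
        for spacer in range(spacer_range[0], spacer_range[1] + 1):
            j = i + n35 + spacer
            if j + n10 > len(seq):
                break
            mm10 = _mismatches(seq[j : j + n10], minus10)
            if mm10 > max_mismatches:
                continue
            hits.append(
                PromoterHit(
                    minus35=(i, i + n35),
                    minus10=(j, j + n10),
                    spacer=spacer,
                    mismatches=(mm35, mm10),
                    score=(n35 - mm35) + (n10 - mm10),
                )
            )
    hits.sort(key=lambda h: (-h.score, h.minus35[0], h.minus10[0]))
    return hits


# ---------------------------------------------------------------------------
# tandem repeats


@dataclass
class RepeatFinderParams:
    """Tandem-Repeat-Finder style scoring weights (stored as magnitudes)."""

    match: int = 2
    mismatch: int = 7
    indel: int = 7
    min_score: int = 50

    def __post_init__(self):
        if not (self.match > 0 and self.mismatch > 0 and self.indel > 0 and self.min_score > 0):
            raise ValueError("all repeat-finder parameters must be positive")


@dataclass
class RepeatArray:
    """A detected tandem array."""

    interval: tuple[int, int]
    period: int
    copies: float  # aligned length / period, rounded to 1 decimal
    consensus: str
    score: int

    def __post_init__(self):
        if self.copies < 1.0:
            raise ValueError("copies < 1.0")


def _consensus_for(seq: str, start: int, end: int, period: int, anchor: int) -> str:
    """Majority base per period position over [start, end); ties go to the
    base occurring earliest in the region. Phase 0 sits at `anchor`."""
    cols: list[dict[str, list]] = [dict() for _ in range(period)]
    for x in range(start, end):
        phase = (x - anchor) % period
        base = seq[x]
        cols[phase].setdefault(base, []).append(x)
    out = []
    for col in cols:
        if not col:
            out.append("A")
            continue
        best = min(col.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))
        out.append(best[0])
    return "".join(out)


def _wraparound_local(seq: str, consensus: str, params: RepeatFinderParams):
    """Local alignment of `seq` against tandem copies of `consensus` with
    wraparound on the consensus (TRF-style scoring). Returns
    (score, start, end) where [start, end) is the aligned sequence span."""
    n, p = len(seq), len(consensus)
    match, mism, indel = params.match, -params.mismatch, -params.indel
    NEG = -(10 ** 9)
    # M[j]: best score of an alignment whose last column matches seq[i-1] to
    # consensus phase j; I[j]: ends in a sequence insertion at phase j.
    M = [NEG] * p
    I = [NEG] * p
    SM = [0] * p  # start position of the alignment ending at M[j]
    SI = [0] * p
    best = (0, 0, 0)
    for i in range(1, n + 1):
        ch = seq[i - 1]
        newM = [NEG] * p
        newI = [NEG] * p
        nSM = [0] * p
        nSI = [0] * p
        # deletion state (consensus consumed, not sequence) for the previous
        # row, propagated cyclically within the row: two passes.
        D = [NEG] * p
        SD = [0] * p
        for _ in range(2):
            for j in range(p):
                jm = (j - 1) % p
                cand = []
                if M[jm] > NEG:
                    cand.append((M[jm] + indel, SM[jm]))
                if D[jm] > NEG:
                    cand.append((D[jm] + indel, SD[jm]))
                if cand:
                    v, s = max(cand, key=lambda t: t[0])
                    if v > D[j]:
                        D[j], SD[j] = v, s
        for j in range(p):
            jm = (j - 1) % p
            sub = match if ch == consensus[j] else mism
            # start fresh, or continue from match/insert/delete at phase j-1
            v, s = 0, i - 1
            if M[jm] > v:
                v, s = M[jm], SM[jm]
            if I[jm] > v:
                v, s = I[jm], SI[jm]
            if D[jm] > v:
                v, s = D[jm], SD[jm]
            newM[j] = v + sub
            nSM[j] = s
            # insertion: extra sequence base at phase j
            cand = []
            if M[j] > NEG:
                cand.append((M[j] + indel, SM[j]))
            if I[j] > NEG:
                cand.append((I[j] + indel, SI[j]))
            if cand:
                newI[j], nSI[j] = max(cand, key=lambda t: t[0])
        M, I, SM, SI = newM, newI, nSM, nSI
        for j in range(p):
            if M[j] > best[0]:
                best = (M[j], SM[j], i)
    return best


def find_tandem_repeats(
    seq: str,
    params: RepeatFinderParams | None = None,
    k: int = 7,
    max_period: int = 100,
    min_copies: float = 2.0,
) -> list[RepeatArray]:
    """Detect tandem repeat arrays.

    Candidate periods are proposed from exact k-mer recurrences at each
    distance; each candidate is refined by wraparound local alignment of the
    region against its majority consensus. Arrays scoring >= min_score are
    reported; overlapping reports are resolved best-score-first (ties to the
    leftmost array, then the shorter period).

    `min_copies` requires the aligned span to cover at least that many
    periods (default 2): an alignment spanning barely one period matches its
    own consensus trivially and carries no evidence of periodicity.
    """
    if params is None:
        params = RepeatFinderParams()
    seq = _norm_dna(seq)
    n = len(seq)
    if n < 20:
        raise ValueError("sequence too short for repeat detection (< 20 nt)")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    candidates: list[RepeatArray] = []
    for d in range(3, min(max_period, n - k) + 1):
        eq = arr[: n - d] == arr[d:]
        if len(eq) < k:
            continue
        # positions i where seq[i:i+k] == seq[i+d:i+d+k]
        run = np.convolve(eq.astype(int), np.ones(k, dtype=int), mode="valid") == k
        support = np.flatnonzero(run)
        if support.size == 0:
            continue
        # group support positions into runs, merging gaps <= d
        groups = []
        g_start = support[0]
        prev = support[0]
        for pos in support[1:]:
            if pos - prev <= d:
                prev = pos
            else:
                groups.append((g_start, prev))
                g_start = prev = pos
        groups.append((g_start, prev))
        for a, b in groups:
            region_start, region_end = a, min(n, b + k + d)
            consensus = _consensus_for(seq, region_start, region_end, d, a)
            w_start = max(0, region_start - d)
            w_end = min(n, region_end + d)
            window = seq[w_start:w_end]
            score, s_rel, e_rel = _wraparound_local(window, consensus, params)
            if e_rel - s_rel >= d:
                # refinement pass: rebuild the consensus from the aligned
                # interval itself (anchored at the array start), realign
                s_abs, e_abs = w_start + s_rel, w_start + e_rel
                consensus = _consensus_for(seq, s_abs, e_abs, d, s_abs)
                score, s_rel, e_rel = _wraparound_local(window, consensus, params)
            if score < params.min_score:
                continue
            s_abs, e_abs = int(w_start + s_rel), int(w_start + e_rel)
            if (e_abs - s_abs) < min_copies * d:
                continue
            copies = float(round((e_abs - s_abs) / d, 1))
            candidates.append(
                RepeatArray(
                    interval=(s_abs, e_abs),
                    period=int(d),
                    copies=copies,
                    consensus=consensus,
                    score=int(score),
                )
            )
    # overlap resolution: greedy by score, then leftmost, then shorter period
    candidates.sort(key=lambda r: (-r.score, r.interval[0], r.period))
    kept: list[RepeatArray] = []
    for cand in candidates:
        if all(cand.interval[1] <= r.interval[0] or cand.interval[0] >= r.interval[1] for r in kept):
            kept.append(cand)
    kept.sort(key=lambda r: r.interval[0])
    return kept


# ---------------------------------------------------------------------------
# terminator


@dataclass
class TerminatorHit:
    """An intrinsic-terminator hairpin call."""

    hairpin: tuple[int, int]  # full stem-loop-stem interval
    stem: int
    loop: int
    u_tract: int  # count of T/U in the 5 nt after the stem
    score: int  # 3*(G:C) + 2*(A:T) + 1*(G:T)

    def __post_init__(self):
        if self.stem < 4 or not (3 <= self.loop <= 8) or self.u_tract < 3:
            raise ValueError("terminator hit violates stem/loop/U-tract bounds")


def find_terminator(
    seq: str,
    min_stem: int = 4,
    loop_range: tuple[int, int] = (3, 8),
    min_u: int = 3,
    u_window: int = 5,
) -> list[TerminatorHit]:
    """Hairpin terminators: maximally extended stems (Watson-Crick + G:T
    wobble) around every candidate loop, followed within `u_window` nt by at
    least `min_u` T/U. Best score first, ties leftmost."""
    seq = _norm_dna(seq)
    if len(seq) < 15:
        raise ValueError("sequence too short for a terminator scan (< 15 nt)")
    n = len(seq)
    hits = []
    for loop in range(loop_range[0], loop_range[1] + 1):
        for ls in range(1, n - loop):  # loop occupies [ls, ls+loop)
            # extend stem outward from the loop
            k = 0
            while True:
                i = ls - 1 - k
                j = ls + loop + k
                if i < 0 or j >= n:
                    break
                if (seq[i], seq[j]) not in _PAIR_SCORE:
                    break
                k += 1
            # choose the largest stem length >= min_stem whose U-tract passes
            found = None
            for stem in range(k, min_stem - 1, -1):
                end = ls + loop + stem
                tail = seq[end : end + u_window]
                u = tail.count("T")
                if u >= min_u:
                    found = (stem, u)
                    break
            if found is None:
                continue
            stem, u = found
            start = ls - stem
            end = ls + loop + stem
            score = sum(_PAIR_SCORE[(seq[start + t], seq[end - 1 - t])] for t in range(stem))
            hits.append(TerminatorHit(hairpin=(start, end), stem=stem, loop=loop, u_tract=u, score=score))
    # one hit per hairpin window: a wider loop with a shorter stem over the
    # same interval is the same hairpin read differently — keep the best
    uniq: dict[tuple[int, int], TerminatorHit] = {}
    for h in hits:
        prev = uniq.get(h.hairpin)
        if prev is None or (h.score, h.stem) > (prev.score, prev.stem):
            uniq[h.hairpin] = h
    out = list(uniq.values())
    out.sort(key=lambda h: (-h.score, h.hairpin[0], h.loop))
    return out


# ---------------------------------------------------------------------------
# ORFs


@dataclass
class OrfHit:
    """An open reading frame; length is in codons and includes the stop."""

    interval: tuple[int, int]
    strand: str
    start_codon: str
    length: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


def _scan_orfs_forward(seq: str, min_len: int) -> list[tuple[int, int, str]]:
    out = []
    n = len(seq)
    for frame in range(3):
        stops_after: dict[int, int] = {}
        # precompute next in-frame stop for this frame
        stop_positions = [i for i in range(frame, n - 2, 3) if seq[i : i + 3] in STOP_CODONS]
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in START_CODONS:
                stop = next((s for s in stop_positions if s > i), None)
                if stop is None:
                    continue
                length = (stop + 3 - i) // 3
                if length >= min_len:
                    out.append((i, stop + 3, codon))
    return out


def find_orf(seq: str, strand: str = "both", min_len: int = 30) -> list[OrfHit]:
    """ORFs from an ATG/GTG start to the first in-frame stop, on the
    requested strand(s), sorted by length (desc) then start coordinate.

    Coordinates are always on the forward strand of `seq`.
    """
    seq = _norm_dna(seq)
    hits = []
    if strand in ("+", "both"):
        for s, e, codon in _scan_orfs_forward(seq, min_len):
            hits.append(OrfHit(interval=(s, e), strand="+", start_codon=codon, length=(e - s) // 3))
    if strand in ("-", "both"):
        rc = revcomp(seq)
        n = len(seq)
        for s, e, codon in _scan_orfs_forward(rc, min_len):
            hits.append(OrfHit(interval=(n - e, n - s), strand="-", start_codon=codon, length=(e - s) // 3))
    hits.sort(key=lambda h: (-h.length, h.interval[0], h.strand))
    return hits


# ---------------------------------------------------------------------------
# classification


@dataclass
class TALocusAnnotation:
    """The combined four-element annotation and its verdict.

    All element coordinates are given on the ORF (toxin) strand; `strand`
    records the orientation of that strand relative to the input sequence.
    """

    promoter: PromoterHit | None
    repeats: RepeatArray | None
    terminator: TerminatorHit | None
    orf: OrfHit | None
    verdict: str = "incomplete"
    failures: list[str] = field(default_factory=list)
    strand: str = "+"

    @property
    def is_functional_candidate(self) -> bool:
        return self.verdict == "functional-candidate"


def classify_locus(
    promoter: PromoterHit | None,
    repeats: RepeatArray | None,
    terminator: TerminatorHit | None,
    orf: OrfHit | None,
) -> TALocusAnnotation:
    """Apply the four-element test: all elements present and ordered
    promoter < repeats < terminator < ORF, with the repeat array downstream
    of the -10 box. Failure reasons are machine-readable strings."""
    failures = []
    for name, el in [("promoter", promoter), ("repeats", repeats), ("terminator", terminator), ("orf", orf)]:
        if el is None:
            failures.append(f"missing {name}")
    if orf is not None and orf.strand == "-":
        raise ValueError("elements must be given on the ORF strand (forward); reverse-complement first")
    if not failures:
        if not promoter.minus10[1] <= repeats.interval[0]:
            failures.append("order violation (ii): repeat array not downstream of the -10 box")
        if not repeats.interval[1] <= terminator.hairpin[0]:
            failures.append("order violation (iii): terminator not between repeats and ORF")
        if not terminator.hairpin[1] <= orf.interval[0]:
            failures.append("order violation (iv): ORF start not downstream of the terminator")
    verdict = "functional-candidate" if not failures else "incomplete"
    return TALocusAnnotation(promoter, repeats, terminator, orf, verdict=verdict, failures=failures)


def annotate_ta_locus(
    seq: str,
    params: RepeatFinderParams | None = None,
    orf_min_len: int = 30,
    strand: str = "both",
) -> TALocusAnnotation:
    """Scan a sequence for all four elements and classify it.

    Elements are chosen jointly: the longest ORF, the best repeat array
    upstream of it, the best terminator between the two, and the best
    promoter whose -10 box ends before the repeat array starts. With
    ``strand="both"`` the scan is run on the forward strand first and on the
    reverse complement if the forward strand yields no functional candidate;
    coordinates are always reported on the ORF strand.
    """
    if strand == "both":
        fwd = annotate_ta_locus(seq, params=params, orf_min_len=orf_min_len, strand="+")
        if fwd.is_functional_candidate:
            return fwd
        rev = annotate_ta_locus(revcomp(seq), params=params, orf_min_len=orf_min_len, strand="+")
        if rev.is_functional_candidate:
            rev.strand = "-"
            return rev
        return fwd
    seq = _norm_dna(seq)
    orfs = [o for o in find_orf(seq, strand="+", min_len=orf_min_len)]
    orf = orfs[0] if orfs else None
    limit = orf.interval[0] if orf else len(seq)
    arrays = [r for r in find_tandem_repeats(seq, params=params) if r.interval[1] <= limit]
    arrays.sort(key=lambda r: (-r.score, r.interval[0]))
    repeats = arrays[0] if arrays else None
    terminator = None
    if repeats is not None and orf is not None:
        terms = [
            t
            for t in find_terminator(seq)
            if repeats.interval[1] <= t.hairpin[0] and t.hairpin[1] <= orf.interval[0]
        ]
        terminator = terms[0] if terms else None
    promoter = None
    if repeats is not None:
        proms = [p for p in scan_promoter(seq) if p.minus10[1] <= repeats.interval[0]]
        promoter = proms[0] if proms else None
    return classify_locus(promoter, repeats, terminator, orf)
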