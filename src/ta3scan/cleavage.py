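"""Endoribonuclease cleavage-site scanning and in-silico digestion.

The toxin cuts A-rich consensus sequences; the characterized consensus for
the *E. coli* cluster-1/2 systems is GAA|AU (cut between the third and
fourth A), with AA|AU and AAA|AA the consensi reported for the
*P. atrosepticum* and *B. thuringiensis* systems. Cleavage is
metal-independent and leaves a 2',3'-cyclic phosphate on the upstream
fragment and a 5'-OH on the downstream fragment.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CleavageMotif",
    "CleavageSite",
    "Fragment",
    "scan_cleavage_sites",
    "digest",
    "MOTIF_EC",
    "MOTIF_PA",
    "MOTIF_BT",
]


def _norm_rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid RNA letters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class CleavageMotif:
    """A cleavage consensus; the cut falls after `cut_offset` bases of the pattern."""

    pattern: str
    cut_offset: int

    def __post_init__(self):
        object.__setattr__(self, "pattern", _norm_rna(self.pattern))
        if not 0 < self.cut_offset < len(self.pattern):
            raise ValueError("cut_offset must lie strictly inside the pattern")


MOTIF_EC = CleavageMotif("GAAAU", 3)  # GAA|AU, clusters 1/2
MOTIF_PA = CleavageMotif("AAAU", 2)  # AA|AU
MOTIF_BT = CleavageMotif("AAAAA", 3)  # AAA|AA


@dataclass(frozen=True)
class CleavageSite:
    """One motif occurrence; `cut` is a between-nucleotide coordinate."""

    start: int
    end: int
    cut: int


@dataclass(frozen=True)
class Fragment:
    """A digestion product with end-chemistry labels.

    Internal cuts leave a 2',3'-cyclic phosphate upstream and a 5'-OH
    downstream; the precursor's own termini are labelled "native".
    """

    sequence: str
    interval: tuple[int, int]
    left_end: str  # "native" | "5'-OH"
    right_end: str  # "native" | "2',3'-cyclic-phosphate"


def scan_cleavage_sites(rna: str, motif: CleavageMotif = MOTIF_EC) -> list[CleavageSite]:
    """All (possibly overlapping) motif occurrences with their cut coordinates."""
    rna = _norm_rna(rna)
    pattern, plen = motif.pattern, len(motif.pattern)
    sites = []
    start = 0
    while True:
        idx = rna.find(pattern, start)
        if idx == -1:
            break
        sites.append(CleavageSite(start=idx, end=idx + plen, cut=idx + motif.cut_offset))
        start = idx + 1  # overlapping occurrences allowed
    return sites


def digest(
    rna: str,
    motif: CleavageMotif = MOTIF_EC,
    protected: set[int] | None = None,
) -> list[Fragment]:
    """Cut at all non-overlapping sites, chosen greedily left to right.

    `protected` optionally masks paired positions (e.g. from a predicted
    pseudoknot): a site any of whose pattern positions is protected is
    skipped. k accepted cuts produce k+1 fragments whose concatenation
    equals the input.
    """
    rna = _norm_rna(rna)
    sites = scan_cleavage_sites(rna, motif)
    accepted = []
    last_end = -1
    for site in sites:
        if site.start < last_end:
            continue
        if protected is not None and any(p in protected for p in range(site.start, site.end)):
            continue
        accepted.append(site)
        last_end = site.end
    cuts = [s.cut for s in accepted]
    bounds = [0] + cuts + [len(rna)]
    fragments = []
    for idx in range(len(bounds) - 1):
        a, b = bounds[idx], bounds[idx + 1]
        fragments.append(
            Fragment(
                sequence=rna[a:b],
                interval=(a, b),
                left_end="native" if idx == 0 else "5'-OH",
                right_end="native" if idx == len(bounds) - 2 else "2',3'-cyclic-phosphate",
            )
        )
    return fragments
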