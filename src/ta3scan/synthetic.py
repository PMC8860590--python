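"""Synthetic inputs for every pipeline stage.

Three generators:

* `make_toxin_family` — protein families with controlled within- and
  between-cluster identity (substitution-only, so realized identities are
  analytically exact up to rounding);
* `make_ta_locus` — a complete toxin-antitoxin locus (promoter, tandem
  antitoxin repeat array, intrinsic terminator, toxin ORF) with ground-truth
  coordinates;
* `make_itc_dataset` — noisy titration isotherms from a binding model.

The default 36-nt repeat unit is a designed sequence with the architecture
of a cluster-1 antitoxin repeat: a 4-nt 5' overhang starting AU, a 25-nt
core folding into an H-type pseudoknot (S1 = 4 bp, S2 = 3 canonical bp plus
an annotatable U12-U22 pair), and a 7-nt 3' overhang ending GAA, so that the
GAA|AU cleavage site spans consecutive repeats and the cut falls exactly on
the unit boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotate import MINUS10, MINUS35, annotate_ta_locus, find_orf
from .io import Feature
from .itc import BindingModel, Isotherm, TitrationSetup, simulate_isotherm

__all__ = [
    "FamilySpec",
    "LocusSpec",
    "GroundTruth",
    "make_toxin_family",
    "make_ta_locus",
    "make_itc_dataset",
    "DEFAULT_REPEAT_UNIT_RNA",
    "DEFAULT_REPEAT_UNIT_DNA",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
DNA = "ACGT"

# 5' overhang (-3..0) | core (1..25) | 3' overhang (26..32)
DEFAULT_REPEAT_UNIT_RNA = "AUCA" + "AGGCCAUUGCAUGCCUGAAAGUUGC" + "CCUUGAA"
DEFAULT_REPEAT_UNIT_DNA = DEFAULT_REPEAT_UNIT_RNA.replace("U", "T")

_NON_STOP_CODONS = [
    a + b + c
    for a in DNA
    for b in DNA
    for c in DNA
    if a + b + c not in {"TAA", "TAG", "TGA"}
]


@dataclass
class GroundTruth:
    """Element coordinates (0-based, half-open) and/or cluster labels."""

    elements: dict[str, tuple[int, int]] = field(default_factory=dict)
    cluster_labels: dict[str, int] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_gff3_features(self, seqid: str) -> list[Feature]:
        type_map = {
            "promoter_-35": "promoter_-35",
            "promoter_-10": "promoter_-10",
            "repeats": "tandem_repeat_array",
            "terminator": "terminator",
            "orf": "CDS",
        }
        feats = []
        for name, (start, end) in self.elements.items():
            feats.append(Feature(seqid=seqid, type=type_map.get(name, name), start=start, end=end))
        return feats


# ---------------------------------------------------------------------------
# protein families


@dataclass
class FamilySpec:
    """Design of a multi-cluster protein family."""

    n_clusters: int
    members_per_cluster: list[int]
    seq_length: int = 150
    within_identity: float = 0.97
    between_identity: float = 0.80
    seed: int = 0

    def __post_init__(self):
        if self.within_identity <= self.between_identity:
            raise ValueError("within_identity must exceed between_identity")
        if self.seq_length < 30:
            raise ValueError("seq_length must be >= 30")
        if self.n_clusters < 1 or len(self.members_per_cluster) != self.n_clusters:
            raise ValueError("members_per_cluster must list one count per cluster")
        if any(m < 1 for m in self.members_per_cluster):
            raise ValueError("all member counts must be >= 1")


def _mutate(seq: list[str], positions, rng: np.random.Generator) -> list[str]:
    out = list(seq)
    for pos in positions:
        choices = [a for a in AA20 if a != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return out


def make_toxin_family(spec: FamilySpec) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Generate a labelled protein family.

    Each cluster descends from one ancestor; ancestors diverge from a common
    root at disjoint position sets so that pairwise ancestor identity equals
    `between_identity` exactly, and members mutate disjoint sets within a
    cluster so realized within-cluster identity equals `within_identity` (up
    to rounding of the mutation counts). Deterministic under `seed`.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.seq_length
    m = int(round((1 - spec.within_identity) * L / 2))
    # member-level between-cluster distance = 2 d (ancestors) + 2 m (members);
    # discount the member mutations so realized between-identity hits the spec
    d = max(1, int(round((1 - spec.between_identity) * L / 2)) - m)
    if spec.n_clusters * d > L:
        raise ValueError("between_identity too low for this sequence length and cluster count")
    root = [AA20[i] for i in rng.integers(len(AA20), size=L)]
    pool = rng.permutation(L)
    ancestor_positions = [pool[c * d : (c + 1) * d] for c in range(spec.n_clusters)]
    remaining = pool[spec.n_clusters * d :]
    records: list[tuple[str, str]] = []
    labels: dict[str, int] = {}
    for c in range(spec.n_clusters):
        ancestor = _mutate(root, ancestor_positions[c], rng)
        n_members = spec.members_per_cluster[c]
        if m * n_members > len(remaining):
            raise ValueError("within_identity too low for this sequence length")
        member_pool = rng.permutation(remaining)
        for i in range(n_members):
            positions = member_pool[i * m : (i + 1) * m]
            member = _mutate(ancestor, positions, rng)
            name = f"C{c + 1}_M{i + 1}"
            records.append((name, "".join(member)))
            labels[name] = c + 1
    return records, GroundTruth(cluster_labels=labels)


# ---------------------------------------------------------------------------
# TA loci


@dataclass
class LocusSpec:
    """Design of one synthetic toxin-antitoxin locus."""

    repeat_unit: str = DEFAULT_REPEAT_UNIT_DNA
    copies: float = 4.6
    promoter_mismatches: int = 0
    spacer: int = 17
    terminator_stem: int = 6
    terminator_loop: int = 4
    orf_length: int = 60  # codons, excluding start and stop
    flank_length: int = 400
    seed: int = 0
    orf_protein: str | None = None  # optional explicit protein to encode

    def __post_init__(self):
        self.repeat_unit = self.repeat_unit.upper().replace("U", "T")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if len(self.repeat_unit) < 10:
            raise ValueError("repeat unit must be >= 10 nt")
        if not 15 <= self.spacer <= 19:
            raise ValueError("spacer must be 15-19 nt")
        if not 0 <= self.promoter_mismatches <= 2:
            raise ValueError("promoter mismatches per box must be 0-2")
        if self.terminator_stem < 4 or not (3 <= self.terminator_loop <= 8):
            raise ValueError("terminator stem >= 4 bp and loop 3-8 nt required")
        if self.orf_length < 28:
            raise ValueError("orf_length must be >= 28 codons")


_CODON = {  # one unambiguous codon per amino acid (no stops constructible)
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

_COMP = str.maketrans("ACGT", "TGCA")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(DNA[i] for i in rng.integers(4, size=n))


def _other_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in DNA if b != base]
    return choices[rng.integers(3)]


def _mutate_box(box: str, n_mut: int, rng: np.random.Generator) -> str:
    positions = rng.permutation(len(box))[:n_mut]
    chars = list(box)
    for pos in positions:
        choices = [b for b in DNA if b != chars[pos]]
        chars[pos] = choices[rng.integers(3)]
    return "".join(chars)


def _build_orf(spec: LocusSpec, rng: np.random.Generator) -> str:
    if spec.orf_protein is not None:
        body = "".join(_CODON[a] for a in spec.orf_protein.upper())
    else:
        body = "".join(
            _NON_STOP_CODONS[i]
            for i in rng.integers(len(_NON_STOP_CODONS), size=spec.orf_length)
        )
    return "ATG" + body + "TAA"


def _assemble(spec: LocusSpec, rng: np.random.Generator):
    unit = spec.repeat_unit
    repeat_len = math.floor(spec.copies * len(unit))
    n_tiles = math.ceil(repeat_len / len(unit))
    repeats = (unit * n_tiles)[:repeat_len]
    m35 = _mutate_box(MINUS35, spec.promoter_mismatches, rng)
    m10 = _mutate_box(MINUS10, spec.promoter_mismatches, rng)
    spacer_seq = _random_dna(rng, spec.spacer)
    # gap1 carries stop codons in all three frames (blocks upstream ORF
    # read-through into the stop-free frames of the repeat array) and ends
    # with three bases that break the repeat phase, so the detected array
    # cannot extend into it.
    guard_left = "".join(
        _other_base(unit[(j - 3) % len(unit)], rng) for j in range(3)
    )
    gap1 = "TTAATTAATTAA" + guard_left
    # gap2 starts with three phase-breaking bases and ends in C so the
    # terminator hairpin cannot extend into it
    guard_right = "".join(
        _other_base(unit[(repeat_len + j) % len(unit)], rng) for j in range(3)
    )
    gap2 = guard_right + _random_dna(rng, 4) + "C"
    stem = "".join("GC"[i] for i in rng.integers(2, size=spec.terminator_stem))
    loop = "A" * spec.terminator_loop
    terminator = stem + loop + stem.translate(_COMP)[::-1] + "TTTTT"
    gap3 = _random_dna(rng, 10)
    orf = _build_orf(spec, rng)
    upstream_elements = (
        len(m35) + spec.spacer + len(m10) + len(gap1) + repeat_len + len(gap2) + len(terminator) + len(gap3)
    )
    pad5_len = spec.flank_length - upstream_elements
    if pad5_len < 0:
        raise ValueError("flank_length smaller than the construct upstream of the ORF")
    pad5 = _random_dna(rng, pad5_len)
    pad3 = _random_dna(rng, 100)
    seq = pad5 + m35 + spacer_seq + m10 + gap1 + repeats + gap2 + terminator + gap3 + orf + pad3
    pos = pad5_len
    elements = {}
    elements["promoter_-35"] = (pos, pos + len(m35))
    pos += len(m35) + spec.spacer
    elements["promoter_-10"] = (pos, pos + len(m10))
    pos += len(m10) + len(gap1)
    elements["repeats"] = (pos, pos + repeat_len)
    pos += repeat_len + len(gap2)
    # terminator ground truth = the hairpin (stem-loop-stem), excluding U-tract
    hairpin_len = 2 * spec.terminator_stem + spec.terminator_loop
    elements["terminator"] = (pos, pos + hairpin_len)
    pos += len(terminator) + len(gap3)
    elements["orf"] = (pos, pos + len(orf))
    truth = GroundTruth(
        elements=elements,
        extras={
            "period": len(unit),
            "copies": round(repeat_len / len(unit), 1),
            "unit": unit,
        },
    )
    return seq, truth


def _has_decoys(seq: str, truth: GroundTruth) -> bool:
    """Reject assemblies where random padding planted a confounder: a forward
    ORF longer than the designed one, or scanner winners that displace the
    planted elements."""
    orf_iv = truth.elements["orf"]
    planted_len = (orf_iv[1] - orf_iv[0]) // 3
    for orf in find_orf(seq, strand="+", min_len=planted_len):
        if orf.interval != orf_iv and orf.length >= planted_len:
            return True
    if truth.extras.get("copies", 2.0) < 2.0:
        # a sub-two-copy region carries no periodicity signal, so the full
        # annotation cannot succeed; only the ORF decoy check applies
        return False
    ann = annotate_ta_locus(seq)
    if not ann.is_functional_candidate:
        return True
    if ann.repeats.interval != truth.elements["repeats"]:
        return True
    if ann.promoter.minus35 != truth.elements["promoter_-35"]:
        return True
    if ann.terminator.hairpin != truth.elements["terminator"]:
        return True
    if ann.orf.interval != orf_iv:
        return True
    return False


def make_ta_locus(spec: LocusSpec, max_tries: int = 50) -> tuple[str, GroundTruth]:
    """Generate a synthetic locus and its ground truth.

    The repeat region holds floor(copies x unit length) nt tiled from the
    start of the unit. Random padding is redrawn (deterministically, from
    the same seeded generator) if it happens to plant a decoy element that
    would displace a designed one — the generator emulates a clean,
    unambiguous locus.
    """
    rng = np.random.default_rng(spec.seed)
    last = None
    for _ in range(max_tries):
        seq, truth = _assemble(spec, rng)
        if not _has_decoys(seq, truth):
            return seq, truth
        last = (seq, truth)
    raise RuntimeError("could not assemble a decoy-free locus; widen flanks or change seed")


def make_repeat_array_fixture(
    unit: str = DEFAULT_REPEAT_UNIT_DNA,
    copies: float = 4.6,
    flank: int = 100,
    seed: int = 0,
) -> tuple[str, tuple[int, int]]:
    """A tandem array of floor(copies x |unit|) nt inside random flanks.

    The three flank bases adjacent to the array on each side are constrained
    to break the repeat phase, so the flanks are random sequence and not an
    accidental continuation of the array; detected boundaries then coincide
    with the construction.
    """
    unit = unit.upper().replace("U", "T")
    rng = np.random.default_rng(seed)
    repeat_len = math.floor(copies * len(unit))
    region = (unit * math.ceil(copies + 1))[:repeat_len]

    def guarded(n: int, phases: list[int]) -> str:
        # phases: phase index of each of the last `len(phases)` positions
        chars = list(_random_dna(rng, n))
        for offset, phase in phases:
            forbidden = unit[phase % len(unit)]
            if chars[offset] == forbidden:
                choices = [b for b in DNA if b != forbidden]
                chars[offset] = choices[rng.integers(3)]
        return "".join(chars)

    left = guarded(flank, [(flank - 1 - t, -1 - t) for t in range(3)])
    right = guarded(flank, [(t, repeat_len + t) for t in range(3)])
    return left + region + right, (flank, flank + repeat_len)


# ---------------------------------------------------------------------------
# ITC datasets


def make_itc_dataset(
    model: BindingModel,
    setup: TitrationSetup,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> Isotherm:
    """Simulate an isotherm and add i.i.d. Gaussian noise (sd in ucal) to
    the raw heats; normalized heats are recomputed consistently."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    iso = simulate_isotherm(model, setup)
    if noise_sd == 0:
        return iso
    rng = np.random.default_rng(seed)
    df = iso.data.copy()
    noise = rng.normal(0.0, noise_sd, size=len(df))
    df["heat_ucal"] = df["heat_ucal"] + noise
    mol_injected = df["volume_uL"] * 1e-6 * setup.syringe_conc_uM * 1e-6
    df["ndh_kcal_per_mol"] = df["heat_ucal"] * 1e-9 / mol_injected
    meta = dict(iso.meta)
    meta.update({"noise_sd_ucal": noise_sd, "seed": seed})
    return Isotherm(df, meta=meta)
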