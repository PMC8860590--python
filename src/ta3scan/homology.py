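"""Homology screening and identity-based clustering of toxin protein families.

The screen mirrors a BlastP-style workflow: optimal local alignment under
BLOSUM-45 with affine gaps, an E-value estimated from a shuffle null with an
extreme-value (Gumbel) fit, and hit filtering at E-value < 1e-4 and query
coverage > 60%. Families are then delimited by single-linkage clustering of
pairwise global-alignment identities.

Gap costs follow the BLAST convention: a gap of length k costs
``gap_open + k * gap_extend``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "AlignmentResult",
    "IdentityMatrix",
    "Clustering",
    "local_align",
    "estimate_evalue",
    "filter_hits",
    "identity_matrix",
    "cluster_by_identity",
]

AA20 = set("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0
EVALUE_MAX = 1e-4
COVERAGE_MIN = 0.6


def _blosum45_x0():
    """BLOSUM-45 with every score involving X set to 0."""
    m = substitution_matrices.load("BLOSUM45")
    arr = np.array(m)
    alphabet = m.alphabet
    xi = alphabet.index("X")
    arr[xi, :] = 0.0
    arr[:, xi] = 0.0
    out = substitution_matrices.Array(alphabet=alphabet, dims=2, data=arr)
    return out


_MATRIX = _blosum45_x0()


@dataclass
class AlignmentResult:
    """A local alignment hit between a query and a subject protein."""

    query: str
    subject: str
    score: float
    identity: float
    query_coverage: float
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    evalue: float = float("inf")

    def __post_init__(self):
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity out of [0, 1]")
        if not (0.0 <= self.query_coverage <= 1.0):
            raise ValueError("coverage out of [0, 1]")
        if self.evalue < 0:
            raise ValueError("evalue < 0")


def _check_protein(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"empty {name} sequence")
    seq = seq.upper()
    bad = set(seq) - AA20 - {"X"}
    if bad:
        raise ValueError(f"unknown residues in {name}: {sorted(bad)}")
    return seq


def _make_aligner(mode: str, matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _alignment_stats(alignment, qlen: int):
    """identity (matches / aligned columns) and query coverage from a traceback."""
    matches = 0
    aligned_cols = 0
    qcov = 0
    q = str(alignment.query)
    s = str(alignment.target)
    # target = subject (first argument of align()), query = the query protein
    for (ts, te), (qs, qe) in zip(alignment.aligned[0], alignment.aligned[1]):
        aligned_cols += te - ts
        qcov += qe - qs
        for a, b in zip(s[ts:te], q[qs:qe]):
            if a == b:
                matches += 1
    identity = matches / aligned_cols if aligned_cols else 0.0
    coverage = qcov / qlen
    return identity, coverage


def local_align(
    query: str,
    subject: str,
    matrix=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult | None:
    """Optimal local (Smith-Waterman) alignment of two proteins.

    Returns ``None`` when the best local score is <= 0 ("no alignment", e.g.
    for disjoint-alphabet sequences). Ties between co-optimal tracebacks are
    broken by smallest query start, then shortest alignment.
    """
    query = _check_protein(query, "query")
    subject = _check_protein(subject, "subject")
    if matrix is None:
        matrix = _MATRIX
    aligner = _make_aligner("local", matrix, gap_open, gap_extend)
    # biopython's first argument is the "target"; use subject as target so
    # coordinates come out as (subject, query) and swap below.
    alignments = aligner.align(subject, query)
    if alignments.score <= 0:
        return None
    try:
        n = min(len(alignments), 64)
    except OverflowError:  # astronomically many co-optimal tracebacks
        n = 1
    best = None
    best_key = None
    for idx in range(n):
        aln = alignments[idx]
        tblocks, qblocks = aln.aligned
        qstart, qend = int(qblocks[0][0]), int(qblocks[-1][1])
        sstart, send = int(tblocks[0][0]), int(tblocks[-1][1])
        key = (qstart, (qend - qstart) + (send - sstart))
        if best_key is None or key < best_key:
            best_key = key
            best = aln
    tblocks, qblocks = best.aligned
    identity, coverage = _alignment_stats(best, len(query))
    return AlignmentResult(
        query="query",
        subject="subject",
        score=float(alignments.score),
        identity=identity,
        query_coverage=coverage,
        query_interval=(int(qblocks[0][0]), int(qblocks[-1][1])),
        subject_interval=(int(tblocks[0][0]), int(tblocks[-1][1])),
    )


def estimate_evalue(
    result: AlignmentResult,
    query: str,
    subject_set: list[str],
    n_shuffles: int = 100,
    seed: int = 0,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """E-value for an alignment score from a shuffle null.

    Subjects are shuffled (composition-preserving) and re-aligned against the
    query; a Gumbel distribution is fitted to the null scores and
    E = database size x P(null score >= observed). This stands in for the
    analytic Karlin-Altschul statistics of BLAST.
    """
    if n_shuffles < 50:
        raise ValueError("n_shuffles must be >= 50")
    rng = random.Random(seed)
    null_scores = []
    for i in range(n_shuffles):
        subject = subject_set[i % len(subject_set)]
        chars = list(subject)
        rng.shuffle(chars)
        hit = local_align(query, "".join(chars), gap_open=gap_open, gap_extend=gap_extend)
        null_scores.append(0.0 if hit is None else hit.score)
    null_scores = np.asarray(null_scores)
    if np.ptp(null_scores) == 0:
        raise ValueError("degenerate shuffle null: zero score variance")
    loc, scale = stats.gumbel_r.fit(null_scores)
    p = stats.gumbel_r.sf(result.score, loc=loc, scale=scale)
    return float(len(subject_set) * p)


def filter_hits(
    hits: list[AlignmentResult],
    evalue_max: float = EVALUE_MAX,
    coverage_min: float = COVERAGE_MIN,
) -> list[AlignmentResult]:
    """Keep hits with evalue < evalue_max AND coverage > coverage_min.

    Both inequalities are strict, so a hit at exactly 60% coverage is dropped.
    Input order is preserved.
    """
    if not (evalue_max > 0 and 0 <= coverage_min <= 1):
        raise ValueError("thresholds out of range")
    return [h for h in hits if h.evalue < evalue_max and h.query_coverage > coverage_min]


@dataclass
class IdentityMatrix:
    """Symmetric pairwise global-alignment identity matrix with unit diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("diagonal != 1")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("values out of [0, 1]")
        self.values = v


def _global_identity(a: str, b: str, aligner) -> float:
    aln = aligner.align(a, b)[0]
    matches = 0
    aligned_cols = 0
    for (ts, te), (qs, qe) in zip(aln.aligned[0], aln.aligned[1]):
        aligned_cols += te - ts
        for x, y in zip(a[ts:te], b[qs:qe]):
            if x == y:
                matches += 1
    return matches / aligned_cols if aligned_cols else 0.0


def identity_matrix(seqs: dict[str, str] | list[tuple[str, str]]) -> IdentityMatrix:
    """Pairwise global-alignment identities for a set of labelled proteins.

    The identity denominator is the number of aligned (both non-gap) columns,
    which excludes terminal overhangs.
    """
    if isinstance(seqs, dict):
        items = list(seqs.items())
    else:
        items = list(seqs)
    labels = [k for k, _ in items]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate labels")
    if len(items) < 2:
        raise ValueError("need >= 2 sequences")
    sequences = [_check_protein(v, k) for k, v in items]
    aligner = _make_aligner("global", _MATRIX, DEFAULT_GAP_OPEN, DEFAULT_GAP_EXTEND)
    n = len(items)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ident = _global_identity(sequences[i], sequences[j], aligner)
            values[i, j] = values[j, i] = ident
    return IdentityMatrix(labels=labels, values=values)


@dataclass
class Clustering:
    """A partition of sequence labels into identity clusters.

    Cluster ids are 1-based and ordered by descending cluster size, ties
    broken by the smallest member label.
    """

    assignments: dict[str, int]
    singletons: dict[str, bool] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))

    def members(self, cluster_id: int) -> list[str]:
        return sorted(k for k, v in self.assignments.items() if v == cluster_id)


def cluster_by_identity(matrix: IdentityMatrix, threshold: float = 0.90) -> Clustering:
    """Single-linkage clusters: connected components of the graph with an
    edge wherever pairwise identity >= threshold."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    adj = (matrix.values >= threshold).astype(int)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups: dict[int, list[str]] = {}
    for label, comp in zip(matrix.labels, labels):
        groups.setdefault(int(comp), []).append(label)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    assignments = {}
    singletons = {}
    for cid, group in enumerate(ordered, start=1):
        for label in group:
            assignments[label] = cid
            singletons[label] = len(group) == 1
    return Clustering(assignments=assignments, singletons=singletons)
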