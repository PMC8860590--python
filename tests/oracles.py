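"""Independent brute-force oracles used to validate the package algorithms.

Every function here is written from the problem definition, not from the
implementation it checks, and is only feasible on tiny inputs.
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices

_B45 = substitution_matrices.load("BLOSUM45")


def sub_score(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_B45[a][b])


def smith_waterman(query: str, subject: str, gap_open: float = 10.0, gap_extend: float = 1.0) -> float:
    """Plain three-state affine-gap local alignment, gap cost open + k*extend."""
    n, m = len(query), len(subject)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] - gap_open - gap_extend, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open - gap_extend, Iy[i][j - 1] - gap_extend)
            s = sub_score(query[i - 1], subject[j - 1])
            M[i][j] = max(0.0, s + max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]))
            best = max(best, M[i][j], Ix[i][j], Iy[i][j])
    return best


def connected_components(labels, values, threshold):
    """BFS components of the thresholded identity graph."""
    n = len(labels)
    seen = [False] * n
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            u = stack.pop()
            comp.append(labels[u])
            for v in range(n):
                if not seen[v] and values[u][v] >= threshold:
                    seen[v] = True
                    stack.append(v)
        comps.append(sorted(comp))
    return sorted(comps)


def promoter_scan(seq, minus35="TTGACA", minus10="TATAAT", max_mm=2, spacer=(15, 19)):
    """All box placements by direct double loop."""
    hits = []
    for i in range(len(seq) - 5):
        w35 = seq[i : i + 6]
        if len(w35) < 6:
            continue
        mm35 = sum(a != b for a, b in zip(w35, minus35))
        if mm35 > max_mm:
            continue
        for j in range(i + 6 + spacer[0], min(i + 6 + spacer[1], len(seq) - 6) + 1):
            w10 = seq[j : j + 6]
            mm10 = sum(a != b for a, b in zip(w10, minus10))
            if mm10 > max_mm:
                continue
            hits.append(((i, i + 6), (j, j + 6), j - (i + 6), (12 - mm35 - mm10)))
    return sorted(hits)


def best_repeat_score(seq, min_period=3, max_period=None):
    """Best substitution-only tandem-array score over all (start, end, period,
    consensus) choices, scored match +2 / mismatch -7 against the majority
    consensus of the window. Exponential-free but O(n^3 * sigma); tiny only."""
    n = len(seq)
    if max_period is None:
        max_period = n // 2
    best = 0
    for p in range(min_period, max_period + 1):
        for s in range(n):
            for e in range(s + 2 * p, n + 1):
                # majority consensus per phase, ties to earliest occurrence
                cols = [{} for _ in range(p)]
                for x in range(s, e):
                    cols[(x - s) % p].setdefault(seq[x], []).append(x)
                cons = [
                    min(c.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))[0] if c else "A"
                    for c in cols
                ]
                score = sum(2 if seq[x] == cons[(x - s) % p] else -7 for x in range(s, e))
                best = max(best, score)
    return best


PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def all_helices(seq, min_bp=3):
    """Every contiguous helix of >= min_bp pairs (including sub-helices)."""
    n = len(seq)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            k = 0
            while i + k < j - k and (seq[i + k], seq[j - k]) in PAIRS:
                k += 1
                if k >= min_bp:
                    out.append((i, j, k))
    return out


def maximal_helices(seq, min_bp=3):
    """Outer- and inner-maximal helices only."""
    full = {}
    n = len(seq)
    for i in range(n):
        for j in range(i + 1, n):
            if (seq[i], seq[j]) not in PAIRS:
                continue
            if i > 0 and j < n - 1 and (seq[i - 1], seq[j + 1]) in PAIRS:
                continue
            k = 0
            while i + k < j - k and (seq[i + k], seq[j - k]) in PAIRS:
                k += 1
            if k >= min_bp:
                full[(i, j)] = k
    return sorted((i, j, k) for (i, j), k in full.items())


def _weight(a, b, scoring):
    key = "".join(sorted((a, b)))
    return {"CG": scoring["GC"], "AU": scoring["AU"], "GU": scoring["GU"]}.get(key, 0)


def best_pseudoknot(seq, scoring=None, min_bp=3):
    """Maximum-score crossing helix pair by full enumeration.

    Returns (score, n_pairs, helix1, helix2) or None.
    """
    if scoring is None:
        scoring = {"GC": 3, "AU": 2, "GU": 1}
    helices = all_helices(seq, min_bp=min_bp)
    best = None
    for h1, h2 in itertools.permutations(helices, 2):
        i1, j1, k1 = h1
        i2, j2, k2 = h2
        if i1 >= i2:
            continue
        # order: a1 < a2 < b1 < b2, all disjoint
        if not (i1 + k1 - 1 < i2 and i2 + k2 - 1 < j1 - k1 + 1 and j1 < j2 - k2 + 1):
            continue
        score = sum(_weight(seq[i1 + t], seq[j1 - t], scoring) for t in range(k1))
        score += sum(_weight(seq[i2 + t], seq[j2 - t], scoring) for t in range(k2))
        key = (score, k1 + k2, -i1)
        if best is None or key > best[0]:
            best = (key, h1, h2)
    if best is None:
        return None
    (score, npairs, negi), h1, h2 = best
    return score, npairs, h1, h2


def terminator_scan(seq, min_stem=4, loops=(3, 8), min_u=3, u_window=5):
    """Maximal hairpins with a U-tract, by direct enumeration."""
    pair_ok = {("G", "C"), ("C", "G"), ("A", "T"), ("T", "A"), ("G", "T"), ("T", "G")}
    weight = {("G", "C"): 3, ("C", "G"): 3, ("A", "T"): 2, ("T", "A"): 2, ("G", "T"): 1, ("T", "G"): 1}
    n = len(seq)
    found = {}
    for loop in range(loops[0], loops[1] + 1):
        for ls in range(1, n - loop):
            k = 0
            while ls - 1 - k >= 0 and ls + loop + k < n and (seq[ls - 1 - k], seq[ls + loop + k]) in pair_ok:
                k += 1
            for stem in range(k, min_stem - 1, -1):
                end = ls + loop + stem
                u = seq[end : end + u_window].count("T")
                if u >= min_u:
                    start = ls - stem
                    score = sum(weight[(seq[start + t], seq[end - 1 - t])] for t in range(stem))
                    prev = found.get((start, end))
                    if prev is None or (score, stem) > (prev[1], prev[2]):
                        found[(start, end)] = (u, score, stem, loop)
                    break
    return sorted((iv, stem, loop, u, sc) for iv, (u, sc, stem, loop) in found.items())


def six_frame_orfs(seq, min_len=30):
    """All (start, first in-frame stop) ORFs on both strands, forward coords."""
    comp = str.maketrans("ACGT", "TGCA")
    out = []
    for strand, s in (("+", seq), ("-", seq.translate(comp)[::-1])):
        n = len(s)
        for frame in range(3):
            for i in range(frame, n - 2, 3):
                if s[i : i + 3] in {"ATG", "GTG"}:
                    for j in range(i + 3, n - 2, 3):
                        if s[j : j + 3] in {"TAA", "TAG", "TGA"}:
                            if (j + 3 - i) // 3 >= min_len:
                                if strand == "+":
                                    out.append((i, j + 3, "+"))
                                else:
                                    out.append((n - (j + 3), n - i, "-"))
                            break
    return sorted(set(out))
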