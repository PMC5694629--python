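"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives a quantity from first principles (explicit dynamic
programming, exhaustive enumeration, literal formulas) without touching the
package's computation paths, so agreement is evidence of correctness rather
than tautology.
"""
from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")

_NEG = float("-inf")


def _sub_score(x: str, y: str, sub) -> float:
    if sub is None:
        raise ValueError
    return float(sub[x, y])


def gotoh_local(a: str, b: str, gap_open: float = 11.0,
                gap_extend: float = 1.0, sub=BLOSUM62,
                match: float | None = None, mismatch: float | None = None
                ) -> tuple[float, str, str]:
    """Smith-Waterman-Gotoh local alignment with affine gaps, by explicit DP.

    A gap of length L costs gap_open + (L - 1) * gap_extend.  Returns
    (score, gapped_a, gapped_b); score 0 means no positive segment.
    """
    def s(x, y):
        if match is not None:
            return match if x == y else mismatch
        return _sub_score(x, y, sub)

    n, m = len(a), len(b)
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), _NEG)
    Iy = np.full((n + 1, m + 1), _NEG)
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 start,1 M,2 Ix,3 Iy
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 from M, 2 from Ix
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cands = [(0.0, 0), (M[i - 1, j - 1], 1), (Ix[i - 1, j - 1], 2),
                     (Iy[i - 1, j - 1], 3)]
            best, ptr = max(cands, key=lambda t: t[0])
            M[i, j] = s(a[i - 1], b[j - 1]) + best
            ptr_m[i, j] = ptr
            ox, ex = M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend
            Ix[i, j], ptr_x[i, j] = (ox, 1) if ox >= ex else (ex, 2)
            oy, ey = M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend
            Iy[i, j], ptr_y[i, j] = (oy, 1) if oy >= ey else (ey, 2)
    score = float(M.max())
    if score <= 0:
        return 0.0, "", ""
    i, j = np.unravel_index(np.argmax(M), M.shape)
    out_a, out_b = [], []
    state = 1
    while True:
        if state == 1:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = ptr_m[i, j]
            i, j = i - 1, j - 1
            if prev == 0:
                break
            state = prev
        elif state == 2:
            out_a.append(a[i - 1])
            out_b.append("-")
            state = ptr_x[i, j]
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            state = ptr_y[i, j]
            j -= 1
    return score, "".join(reversed(out_a)), "".join(reversed(out_b))


def gotoh_endsfree(a: str, b: str, match: float = 2.0, mismatch: float = -3.0,
                   gap_open: float = 5.0, gap_extend: float = 2.0
                   ) -> tuple[float, str, str]:
    """Global alignment with free end gaps, explicit affine DP.

    Returns (score, gapped_a, gapped_b) covering only the aligned core; the
    free terminal overhangs are omitted, matching an identity computation
    that excludes terminal-gap columns.
    """
    def s(x, y):
        return match if x == y else mismatch

    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)
    Iy = np.full((n + 1, m + 1), _NEG)
    M[0, :] = 0.0
    M[:, 0] = 0.0
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cands = [(M[i - 1, j - 1], 1), (Ix[i - 1, j - 1], 2),
                     (Iy[i - 1, j - 1], 3)]
            best, ptr = max(cands, key=lambda t: t[0])
            start = (i == 1 or j == 1)
            if start and 0.0 > best:
                best, ptr = 0.0, 0
            M[i, j] = s(a[i - 1], b[j - 1]) + best
            ptr_m[i, j] = ptr
            ox, ex = M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend
            Ix[i, j], ptr_x[i, j] = (ox, 1) if ox >= ex else (ex, 2)
            oy, ey = M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend
            Iy[i, j], ptr_y[i, j] = (oy, 1) if oy >= ey else (ey, 2)
    # trailing end gaps are free: best M over last row and last column
    end_cells = [(M[i, m], i, m) for i in range(1, n + 1)]
    end_cells += [(M[n, j], n, j) for j in range(1, m + 1)]
    score, i, j = max(end_cells, key=lambda t: t[0])
    out_a, out_b = [], []
    state = 1
    while i > 0 and j > 0:
        if state == 1:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = ptr_m[i, j]
            i, j = i - 1, j - 1
            if prev == 0:
                break
            state = prev
        elif state == 2:
            out_a.append(a[i - 1])
            out_b.append("-")
            state = ptr_x[i, j]
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            state = ptr_y[i, j]
            j -= 1
    return float(score), "".join(reversed(out_a)), "".join(reversed(out_b))


def identity_percent(gapped_a: str, gapped_b: str) -> float:
    """Matches over aligned columns, internal gaps counted as mismatches."""
    assert len(gapped_a) == len(gapped_b) and gapped_a
    matches = sum(1 for x, y in zip(gapped_a, gapped_b) if x == y)
    return 100.0 * matches / len(gapped_a)


def brute_force_rbh(proteome_a, proteome_b, min_identity: float = 30.0,
                    min_coverage: float = 0.7) -> set[tuple[str, str]]:
    """Reciprocal best hits by exhaustive all-vs-all oracle alignment."""
    def stats(x, y):
        score, ga, gb = gotoh_local(x.residues, y.residues)
        if score <= 0:
            return None
        cov_x = len(ga.replace("-", "")) / len(x.residues)
        cov_y = len(gb.replace("-", "")) / len(y.residues)
        return score, len(ga), identity_percent(ga, gb), cov_x, cov_y

    table = {}
    for x in proteome_a:
        for y in proteome_b:
            st = stats(x, y)
            if st is not None:
                table[(x.id, y.id)] = st

    def best(candidates):
        return min(candidates, key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))[0]

    pairs = set()
    for x in proteome_a:
        cands = {y_id: st for (x_id, y_id), st in table.items()
                 if x_id == x.id}
        if not cands:
            continue
        y_id = best(cands.items())
        back = {x_id: st for (x_id, yy), st in table.items() if yy == y_id}
        if best(back.items()) != x.id:
            continue
        score, length, ident, cov_x, cov_y = table[(x.id, y_id)]
        shorter_cov = cov_x if len(proteome_a[x.id]) <= \
            len(proteome_b[y_id]) else cov_y
        if ident >= min_identity and shorter_cov >= min_coverage:
            pairs.add((x.id, y_id))
    return pairs


def spearman_rho(x, y) -> float:
    """Rank-correlation oracle: average ranks, then the Pearson formula."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx)
                    * sum((b - my) ** 2 for b in ry))
    return num / den


def bh_stepup(p) -> list[float]:
    """q_i = min over ranks j >= rank(i) of m * p_(j) / j, capped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)]
        q[idx] = min(1.0, min(candidates))
    return q


def tajima_nei(x: str, y: str) -> float:
    """Literal transcription of the equal-input distance formula."""
    sites = [(a, b) for a, b in zip(x, y) if a in "ACGT" and b in "ACGT"]
    n = len(sites)
    nd = sum(1 for a, b in sites if a != b)
    p = nd / n
    if p == 0:
        return 0.0
    freqs = {c: 0 for c in "ACGT"}
    for a, b in sites:
        freqs[a] += 1
        freqs[b] += 1
    g = {c: freqs[c] / (2 * n) for c in "ACGT"}
    h = 0.0
    for c1, c2 in combinations("ACGT", 2):
        x12 = sum(1 for a, b in sites if {a, b} == {c1, c2}) / n
        if x12:
            h += x12 ** 2 / (2 * g[c1] * g[c2])
    b_coef = 0.5 * (1 - sum(v ** 2 for v in g.values()) + p ** 2 / h)
    return -b_coef * math.log(1 - p / b_coef)


def bray_curtis(a, b) -> float:
    num = sum(abs(x - y) for x, y in zip(a, b))
    den = sum(x + y for x, y in zip(a, b))
    return num / den


def complete_linkage_merges(dist: np.ndarray, labels: list[str]
                            ) -> list[tuple[frozenset, frozenset]]:
    """Naive agglomeration: repeatedly merge the pair of clusters whose
    complete-linkage (maximum) distance is smallest."""
    clusters = [frozenset({lab}) for lab in labels]
    index = {lab: i for i, lab in enumerate(labels)}

    def d(c1, c2):
        return max(dist[index[a], index[b]] for a in c1 for b in c2)

    merges = []
    while len(clusters) > 1:
        best = min(((i, j) for i in range(len(clusters))
                    for j in range(i + 1, len(clusters))),
                   key=lambda ij: d(clusters[ij[0]], clusters[ij[1]]))
        c1, c2 = clusters[best[0]], clusters[best[1]]
        merges.append((c1, c2) if min(c1) <= min(c2) else (c2, c1))
        clusters = [c for k, c in enumerate(clusters) if k not in best]
        clusters.append(c1 | c2)
    return merges
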