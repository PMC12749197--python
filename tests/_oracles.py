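"""Independent brute-force oracles used by the test suite.

These are deliberately written in a different style from the package
implementations (explicit interval enumeration, reverse-complement string
comparison, O(n^2) double loops, exhaustive permutations) so that agreement
between the two routes is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np

COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def revcomp(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


def _pairs_ok(left: str, right: str, allow_gu: bool) -> bool:
    ok = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    if allow_gu:
        ok |= {("G", "U"), ("U", "G")}
    return all((a, b) in ok for a, b in zip(left, reversed(right)))


def brute_force_candidates(seq: str, min_stem: int = 4, max_span: int = 60,
                           allow_gu: bool = True, spacing: int = 6):
    """Exhaustively enumerate nested-stem/bulge/CGA elements.

    Returns a set of signatures (outer arms, inner arms, cga, lone C) using
    0-based inclusive interval tuples.
    """
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    found = set()
    # all placements of two arm intervals for the outer stem
    for k1 in range(min_stem, n // 2 + 1):
        for i in range(n - 2 * k1 + 1):
            for j_end in range(i + 2 * k1 - 1, min(n, i + max_span)):
                o_left = (i, i + k1 - 1)
                o_right = (j_end - k1 + 1, j_end)
                if o_right[0] <= o_left[1]:
                    continue
                if not _pairs_ok(seq[o_left[0]:o_left[1] + 1], seq[o_right[0]:o_right[1] + 1], allow_gu):
                    continue
                # all nested inner stems
                for k2 in range(min_stem, n // 2 + 1):
                    for a in range(o_left[1] + 1, o_right[0]):
                        for b_end in range(a + 2 * k2 - 1, o_right[0]):
                            i_left = (a, a + k2 - 1)
                            i_right = (b_end - k2 + 1, b_end)
                            if i_right[0] <= i_left[1]:
                                continue
                            if not _pairs_ok(seq[i_left[0]:i_left[1] + 1], seq[i_right[0]:i_right[1] + 1], allow_gu):
                                continue
                            bl = i_left[0] - (o_left[1] + 1)
                            br = o_right[0] - 1 - i_right[1]
                            if bl + br < 1 or abs(bl - br) < 1:
                                continue
                            arm = set(range(*o_left)) | {o_left[1]} | set(range(*o_right)) | {o_right[1]} \
                                | set(range(*i_left)) | {i_left[1]} | set(range(*i_right)) | {i_right[1]}
                            motif = None
                            for p in range(i, j_end - 1):
                                if seq[p:p + 3] != "CGA" or {p, p + 1, p + 2} & arm:
                                    continue
                                for q in range(i, j_end + 1):
                                    if seq[q] != "C" or q in arm:
                                        continue
                                    if q > 0 and seq[q - 1] == "C":
                                        continue
                                    if q < n - 1 and seq[q + 1] == "C":
                                        continue
                                    if abs(q - p) == spacing:
                                        motif = (p, q)
                                        break
                                if motif:
                                    break
                            if motif:
                                found.add((o_left, o_right, i_left, i_right, motif))
    return found


def brute_force_coloc_pairs(a_um: np.ndarray, b_um: np.ndarray, radius_nm: float):
    """O(n^2) all-pairs colocalization."""
    pairs = set()
    for i in range(a_um.shape[0]):
        for j in range(b_um.shape[0]):
            d = 0.0
            for k in range(a_um.shape[1]):
                d += (1000.0 * (a_um[i, k] - b_um[j, k])) ** 2
            if d ** 0.5 <= radius_nm:
                pairs.add((i, j))
    return pairs


def brute_force_matching(prev_xy, next_xy, max_dist):
    """Exhaustive min-total-distance matching with births/deaths allowed.

    Every subset of pairings with all edges < max_dist is scored as the sum
    of matched distances plus max_dist per unmatched detection; the global
    optimum's matched pair set is returned.
    """
    n, m = len(prev_xy), len(next_xy)
    best = (float("inf"), frozenset())
    idx_m = list(range(m))
    for r in range(min(n, m) + 1):
        for prev_sub in itertools.combinations(range(n), r):
            for next_perm in itertools.permutations(idx_m, r):
                cost = 0.0
                ok = True
                for p, q in zip(prev_sub, next_perm):
                    d = ((prev_xy[p][0] - next_xy[q][0]) ** 2 + (prev_xy[p][1] - next_xy[q][1]) ** 2) ** 0.5
                    if d >= max_dist:
                        ok = False
                        break
                    cost += d
                if not ok:
                    continue
                cost += max_dist * (n - r + m - r)
                if cost < best[0] - 1e-12:
                    best = (cost, frozenset(zip(prev_sub, next_perm)))
    return best[1]


def brute_force_parent_posterior(cands):
    """Exhaustive posterior over ordered (parent, bud) pairs.

    ``cands``: list of (id, area, overlap, nucleus) tuples.
    """
    tot = sum(c[2] for c in cands)
    raw = {}
    for p in cands:
        for q in cands:
            if p[0] == q[0]:
                continue
            w = p[1] / (p[1] + q[1])
            if tot > 0:
                w = w * (p[2] + q[2]) / tot
            if p[3]:
                w = w * 2.0
            raw[(p[0], q[0])] = w
    z = sum(raw.values())
    return {k: v / z for k, v in raw.items()}
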