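"""Independent brute-force oracles used by the test suite.

These are deliberately written from the model definitions, not from the
package's implementation: path enumeration for the profile-HMM forward
score, exhaustive edge enumeration for the centroid split, exhaustive
topology scoring for 4-taxon NJ, and a literal transcription of the
classification argmax formula.
"""

from __future__ import annotations

import math

AA = "ACDEFGHIKLMNPQRSTVWY"


def enumerate_forward_bits(ref, residues: str) -> float:
    """Sum over all state paths of the local profile HMM, in linear space.

    Architecture: N flank (background emission, self-loop) -> B -> uniform
    entry to any match state -> core transitions with per-match exit
    hazard 1/(M-k+1) -> E -> C flank; bit score against an i.i.d.
    background null of geometric length L-1.
    """
    x = [AA.index(c) if c in AA else 20 for c in residues]
    L = len(x)
    M = ref.M
    e0 = ref.null_ext_prob if ref.null_ext_prob is not None else L / (L + 1.0)
    e_n = ref.n_self_prob if ref.n_self_prob is not None else e0
    e_c = ref.c_self_prob if ref.c_self_prob is not None else e0
    ex = [1.0 / (M - k) for k in range(M)]
    bg = ref.background

    def emit_ratio(k: int, code: int) -> float:
        if code >= 20:
            return 1.0
        return ref.match_emissions[k][code] / bg[code]

    total = 0.0

    def finish(pos: int, w: float) -> None:
        nonlocal total
        n_right = L - pos
        total += w * (e_c**n_right) * (1.0 - e_c)

    def walk(pos: int, state: str, k: int, w: float) -> None:
        if w == 0.0:
            return
        if state == "M":
            if pos >= L:
                return
            w2 = w * emit_ratio(k, x[pos])
            finish(pos + 1, w2 * ex[k])
            if k < M - 1:
                rest = w2 * (1.0 - ex[k])
                walk(pos + 1, "M", k + 1, rest * ref.t_mm[k])
                walk(pos + 1, "I", k, rest * ref.t_mi[k])
                walk(pos + 1, "D", k + 1, rest * ref.t_md[k])
        elif state == "I":
            if pos >= L:
                return
            walk(pos + 1, "M", k + 1, w * ref.t_im[k])
            walk(pos + 1, "I", k, w * ref.t_ii[k])
        else:  # delete
            if k == M - 1:
                finish(pos, w)  # D_M -> E
                return
            walk(pos, "M", k + 1, w * ref.t_dm[k])
            walk(pos, "D", k + 1, w * ref.t_dd[k])

    for n_left in range(L):
        w0 = (e_n**n_left) * (1.0 - e_n) / M
        for k in range(M):
            walk(n_left, "M", k, w0)
    null = (e0 ** (L - 1)) * (1.0 - e0)
    return math.log2(total / null)


def exhaustive_centroid_splits(tree) -> list[tuple[int, frozenset, frozenset]]:
    """All proper bipartitions (imbalance, below, other) of a dendropy tree."""
    all_labels = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    splits = []
    for node in tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if not below or below == all_labels:
            continue
        other = all_labels - below
        splits.append((abs(len(below) - len(other)), below, other))
    return splits


def min_split_imbalance(tree) -> int:
    return min(s[0] for s in exhaustive_centroid_splits(tree))


def best_quartet_topology(ids, dist) -> frozenset:
    """Four-point-condition winner among the 3 unrooted quartet topologies.

    Returns the pair grouped together in the best topology.
    """
    a, b, c, d = ids
    sums = {
        frozenset((a, b)): dist[(a, b)] + dist[(c, d)],
        frozenset((a, c)): dist[(a, c)] + dist[(b, d)],
        frozenset((a, d)): dist[(a, d)] + dist[(b, c)],
    }
    return min(sorted(sums, key=lambda k: sorted(k)), key=lambda k: sums[k])


def brute_force_family(profile_scores, thresholds, scale):
    """Literal argmax_i max_j {BS(q, h_ij) : BS > scale*g_i} for one query.

    ``profile_scores``: {family_id: [bit scores of its profiles]}. An
    effective threshold of 0 accepts every score. Ties break to the
    lexicographically smallest family id. Returns (family or None, score).
    """
    best = None
    for fam in sorted(profile_scores):
        t = scale * thresholds.get(fam, 0.0)
        passing = [s for s in profile_scores[fam] if t <= 0 or s > t]
        if not passing:
            continue
        m = max(passing)
        if best is None or m > best[1]:
            best = (fam, m)
    return best if best is not None else (None, float("nan"))
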