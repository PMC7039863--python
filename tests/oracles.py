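"""Independent brute-force oracles used to validate the fast implementations.

These deliberately re-derive each quantity by exhaustive enumeration or
direct definition, sharing no code with the paths they check.
"""

from __future__ import annotations

import numpy as np

from sulfur_census.alphabet import AA_INDEX, AMBIG_INDEX


def enumerate_local_score(profile, query: str) -> float:
    """Exhaustive best local path score through a profile HMM.

    Enumerates every path that enters at some match state, traverses
    match/insert/delete states consuming query residues left to right, and
    exits after a match state. Intended for model length <= 4 and query
    length <= 4 only.
    """
    L = profile.length
    N = len(query)
    esc = np.log2(profile.match_emissions / profile.background[None, :])

    def em(k: int, i: int) -> float:
        ch = query[i].upper()
        if ch == "X" or AA_INDEX.get(ch) == AMBIG_INDEX:
            return 0.0
        return float(esc[k, AA_INDEX[ch]])

    if L > 1:
        lt = np.log2(profile.transitions)
    best = [float("-inf")]

    def go(state: str, k: int, i: int, score: float) -> None:
        # state just occupied at match position k, having consumed residues 0..i-1... i consumed
        if state == "M":
            best[0] = max(best[0], score)  # free exit after any match
        # transitions out of position k
        if state == "M":
            if i < N:  # M -> I_k
                if k <= L - 2:
                    go("I", k, i + 1, score + lt[k, 1] + 0.0)
            if k + 1 < L:
                if i < N:  # M -> M
                    go("M", k + 1, i + 1, score + lt[k, 0] + em(k + 1, i))
                go("D", k + 1, i, score + lt[k, 2])  # M -> D
        elif state == "I":
            if i < N:  # I -> I
                go("I", k, i + 1, score + lt[k, 4] + 0.0)
            if k + 1 < L and i < N:  # I -> M
                go("M", k + 1, i + 1, score + lt[k, 3] + em(k + 1, i))
        elif state == "D":
            if k + 1 < L:
                if i < N:  # D -> M
                    go("M", k + 1, i + 1, score + lt[k, 5] + em(k + 1, i))
                go("D", k + 1, i, score + lt[k, 6])  # D -> D
    # entry: start at any match state k0 consuming residue i0
    for k0 in range(L):
        for i0 in range(N):
            go("M", k0, i0 + 1, em(k0, i0))
    return best[0]


def lca_by_root_paths(tree, taxon_ids) -> str:
    """Lowest common ancestor via explicit root-path intersection."""
    paths = []
    for t in taxon_ids:
        path = []
        node = t
        while node is not None:
            path.append(node)
            node = tree.parent(node)
        paths.append(path)
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    # deepest member of the intersection = first along any root path
    for node in paths[0]:
        if node in common:
            return node
    raise AssertionError("root paths share no node")


def greedy_cluster_oracle(genes, matches) -> list[tuple[str, list[str]]]:
    """Greedy clustering from a precomputed all-pairs match matrix.

    ``matches`` maps frozenset({id_a, id_b}) -> bool. Genes are processed in
    decreasing length, ties by id; each joins the first existing cluster whose
    representative it matches, else founds a new one. The longest member is
    then chosen as representative.
    """
    order = sorted(genes, key=lambda g: (-g.nt_length, g.gene_id))
    clusters: list[list] = []
    for gene in order:
        for members in clusters:
            founder = members[0]
            if gene.gene_id == founder.gene_id or matches[frozenset((gene.gene_id, founder.gene_id))]:
                members.append(gene)
                break
        else:
            clusters.append([gene])
    out = []
    for members in clusters:
        rep = max(members, key=lambda g: (g.nt_length, g.gene_id))
        out.append((rep.gene_id, sorted(g.gene_id for g in members)))
    return out
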