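"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive results by brute force (per-base
scans, exhaustive path sums, textbook DP) so they share no code path with
the package implementation they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from numtsome.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=42, n_chromosomes=2, chromosome_lengths=(120_000, 120_000),
        n_insertions=8, n_pure_mt_contigs=1, n_partial_mt_contigs=2,
        partial_occupancy=(0.85, 0.5),
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def small_pipeline(small_genome):
    from numtsome.pipeline import detect, purge_assemble

    hsps = detect(small_genome)
    numts, kept, removed = purge_assemble(small_genome, hsps)
    return {"hsps": hsps, "numts": numts, "kept": kept, "removed": removed}


# ---------------------------------------------------------------------------
# Needleman-Wunsch (Gotoh affine) oracle

def nw_align(a: str, b: str, match=2, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Global affine-gap (Gotoh) alignment with backpointer traceback;
    returns (score, identity_percent, n_columns)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in a (consume b)
    PM = [[None] * (m + 1) for _ in range(n + 1)]
    PX = [[None] * (m + 1) for _ in range(n + 1)]
    PY = [[None] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * i
        PX[i][0] = "M" if i == 1 else "X"
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * j
        PY[0][j] = "M" if j == 1 else "Y"
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            cands = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            bi = max(range(3), key=lambda t: cands[t])
            M[i][j] = cands[bi] + s
            PM[i][j] = "MXY"[bi]
            xo, xe = M[i - 1][j] + gap_open + gap_extend, X[i - 1][j] + gap_extend
            X[i][j], PX[i][j] = (xo, "M") if xo >= xe else (xe, "X")
            yo, ye = M[i][j - 1] + gap_open + gap_extend, Y[i][j - 1] + gap_extend
            Y[i][j], PY[i][j] = (yo, "M") if yo >= ye else (ye, "Y")
    finals = (M[n][m], X[n][m], Y[n][m])
    state = "MXY"[max(range(3), key=lambda t: finals[t])]
    i, j = n, m
    matches = cols = 0
    while i > 0 or j > 0:
        cols += 1
        if state == "M":
            if a[i - 1] == b[j - 1]:
                matches += 1
            state = PM[i][j]
            i, j = i - 1, j - 1
        elif state == "X":
            state = PX[i][j]
            i -= 1
        else:
            state = PY[i][j]
            j -= 1
    return max(finals), 100.0 * matches / cols, cols


# ---------------------------------------------------------------------------
# brute-force merge-closure oracle

def brute_force_partition(hsps, repeats, max_gap=2000, bridge_cover=0.9):
    """Transitive closure of the pairwise merge rule via BFS on an explicit
    pair graph; returns the partition as a set of frozensets."""
    reps_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in repeats or []:
        reps_by_chrom.setdefault(r[0], []).append((int(r[1]), int(r[2])))

    def pair_ok(a, b):
        if a.chrom != b.chrom or a.strand != b.strand:
            return False
        lo, hi = (a, b) if a.g_start <= b.g_start else (b, a)
        g = hi.g_start - lo.g_end
        if g <= max_gap:
            return True
        gap_iv = (min(a.g_end, b.g_end), max(a.g_start, b.g_start))
        touching = [r for r in reps_by_chrom.get(a.chrom, [])
                    if min(r[1], gap_iv[1]) - max(r[0], gap_iv[0]) > 0]
        if len(touching) != 1:
            return False
        ov = min(touching[0][1], gap_iv[1]) - max(touching[0][0], gap_iv[0])
        return ov >= bridge_cover * (gap_iv[1] - gap_iv[0])

    n = len(hsps)
    seen = [False] * n
    parts = set()
    for s in range(n):
        if seen[s]:
            continue
        comp = {s}
        queue = [s]
        seen[s] = True
        while queue:
            u = queue.pop()
            for v in range(n):
                if not seen[v] and pair_ok(hsps[u], hsps[v]):
                    seen[v] = True
                    comp.add(v)
                    queue.append(v)
        parts.add(frozenset(
            (hsps[i].chrom, hsps[i].g_start, hsps[i].g_end, hsps[i].strand)
            for i in comp))
    return parts


def random_hsps(rng, n, chroms=("chr1", "chr2"), span=60_000):
    """Random HSP sets for merge-rule fuzzing, with gap sizes spanning the
    2-kb boundary."""
    from numtsome.hsp import HSP

    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(50, 3000))
        out.append(HSP(
            mt_start=int(rng.integers(0, 15000)),
            mt_end=int(rng.integers(0, 15000)) + 15001,
            chrom=chrom, g_start=start, g_end=start + length,
            strand="+" if rng.random() < 0.5 else "-",
            pct_identity=90.0, aln_len=length, mismatches=0, gap_opens=0,
            bitscore=100.0, evalue=1e-10))
    return out


def random_repeats(rng, n, chroms=("chr1", "chr2"), span=60_000):
    rows = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        s = int(rng.integers(0, span))
        rows.append((chrom, s, s + int(rng.integers(100, 4000)),
                     f"rep{i}", 0, "+"))
    return rows


# ---------------------------------------------------------------------------
# exhaustive forward-path oracle (no memoization: literally sums all paths)

def enumerate_forward(profile, seq: str) -> float:
    """P(seq | profile) as an explicit sum over every state path through
    the N / M / I / D / C machine.  Tractable for length <= ~4."""
    from numtsome import hmm as H

    k = profile.length
    em = profile.match_emissions
    bg = profile.insert_emissions
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    x = [idx[c] for c in seq.upper()]
    L = len(x)
    eta, out = H.FLANK_LOOP, 1 - H.FLANK_LOOP

    def from_state(state, j, i):
        # currently in (state, j) having emitted i bases (own emission done)
        if state == "C":
            total = out if i == L else 0.0
            if i < L:
                total += eta * bg[x[i]] * from_state("C", 0, i + 1)
            return total
        if state == "N":
            total = 0.0
            if i < L:
                total += eta * bg[x[i]] * from_state("N", 0, i + 1)
                total += out * H.ENTRY_M * em[0][x[i]] * from_state("M", 1, i + 1)
            total += out * H.ENTRY_D * from_state("D", 1, i)
            return total
        if state == "M":
            if j == k:
                return from_state("C", 0, i)
            total = 0.0
            if i < L:
                total += H.T_MM * em[j][x[i]] * from_state("M", j + 1, i + 1)
                total += H.T_MI * bg[x[i]] * from_state("I", j, i + 1)
            total += H.T_MD * from_state("D", j + 1, i)
            return total
        if state == "I":
            total = 0.0
            if i < L:
                total += H.T_II * bg[x[i]] * from_state("I", j, i + 1)
                total += H.T_IM * em[j][x[i]] * from_state("M", j + 1, i + 1)
            return total
        # D
        if j == k:
            return from_state("C", 0, i)
        total = H.T_DD * from_state("D", j + 1, i)
        if i < L:
            total += H.T_DM * em[j][x[i]] * from_state("M", j + 1, i + 1)
        return total

    return from_state("N", 0, 0)


# ---------------------------------------------------------------------------
# rank-formula Spearman oracle

def spearman_oracle(x, y):
    """Spearman rho from average ranks and the Pearson formula on ranks."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for t in range(i, j + 1):
                r[order[t]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


# ---------------------------------------------------------------------------
# tree helpers

def evolve_on_tree(tree, root_seq: str, kappa: float, rng):
    """Simulate sequences down a dendropy tree under K2P (branch length =
    substitutions/site); returns leaf label -> sequence."""
    from numtsome.simulate import mutate_k2p

    seqs = {}
    tree.seed_node.value = root_seq
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.value = mutate_k2p(node.parent_node.value,
                                    node.edge.length or 0.0, kappa, rng)
        if node.is_leaf():
            seqs[node.taxon.label] = node.value
    return seqs


def bipartition_oracle(tree, species_of):
    """Monophyly by explicit edge removal on a networkx copy of the tree."""
    import networkx as nx

    G = nx.Graph()
    names = {}
    for node in tree.preorder_node_iter():
        names[id(node)] = (node.taxon.label if node.taxon is not None
                           else f"int{id(node)}")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            G.add_edge(names[id(node.parent_node)], names[id(node)])
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    by_species = {}
    for leaf in leaves:
        sp = species_of.get(leaf)
        if sp:
            by_species.setdefault(sp, set()).add(leaf)
    out = {}
    for sp, members in by_species.items():
        if len(members) < 2:
            out[sp] = "not assessable"
            continue
        mono = False
        for u, v in list(G.edges):
            H = G.copy()
            H.remove_edge(u, v)
            comp = next(iter(nx.connected_components(H)))
            side = comp & leaves
            if side == members or (leaves - side) == members:
                mono = True
                break
        out[sp] = "monophyletic" if mono else "intermingled"
    return out
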