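"""NumtS phylogeny: K2P distances, neighbor joining, species clustering
patterns, and strict-clock node calibration.

Distances use the Kimura 2-parameter model, separating the proportion of
transition (P) and transversion (Q) differences per retained site:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Gap or N columns are removed pairwise before counting.  Trees are built
with the Saitou-Nei neighbor-joining criterion and held as dendropy
objects, so Newick I/O and tree comparison come for free.  A rooted tree
can be converted to a timetree by strict-clock scaling against one
calibrated node with an age window in Mya.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_VALID = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class K2PDistance:
    P: float          # transition proportion per retained site
    Q: float          # transversion proportion per retained site
    d: float          # K2P distance, substitutions/site
    n_sites: int      # retained (ungapped) columns

    @property
    def variance(self) -> float:
        """Large-sample sampling variance of d (delta method)."""
        a = 1.0 / (1.0 - 2 * self.P - self.Q)
        b = 0.5 * (a + 1.0 / (1.0 - 2 * self.Q))
        return (a * a * self.P + b * b * self.Q
                - (a * self.P + b * self.Q) ** 2) / self.n_sites


class SaturationError(ValueError):
    """Distance undefined: too many differences for the K2P correction."""


def k2p(seq_a: str, seq_b: str) -> K2PDistance:
    """Kimura 2-parameter distance between two aligned sequences with
    pairwise deletion of gap/N columns."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    ts = tv = n = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in _VALID or y not in _VALID:
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no retained columns after pairwise deletion")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2 * P - Q
    w2 = 1.0 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated: P={P:.3f}, Q={Q:.3f}")
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PDistance(P, Q, d, n)


def k2p_matrix(seqs: Mapping[str, str]) -> tuple[np.ndarray, list[str]]:
    """Pairwise K2P distance matrix over aligned sequences."""
    labels = list(seqs)
    n = len(labels)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = k2p(seqs[labels[i]], seqs[labels[j]]).d
    return D, labels


# ---------------------------------------------------------------------------
# neighbor joining

def nj(D: np.ndarray, labels: Sequence[str],
       taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Q-criterion ties break on the lexicographically smallest cluster label
    pair; negative branch lengths are clamped to zero with a warning.  The
    returned tree is unrooted with a trifurcating seed node (n >= 3).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(labels):
        raise ValueError("matrix/labels shape mismatch")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    if taxon_namespace is None:
        taxon_namespace = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = taxon_namespace.get_taxon(lab)
        nodes.append(nd)
    # each active cluster: (sort key = smallest member label, node)
    active = {i: (labels[i], nodes[i]) for i in range(n)}
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n) if i < j}

    def d(i, j):
        return dist[(i, j) if i < j else (j, i)]

    def clamp(x, where):
        if x < 0:
            warnings.warn(f"negative branch length {x:.4g} at {where} "
                          "clamped to 0")
            return 0.0
        return x

    next_id = n
    while len(active) > 3:
        ids = sorted(active)
        m = len(ids)
        r = {i: sum(d(i, j) for j in ids if j != i) for i in ids}
        best = None
        for i, j in itertools.combinations(ids, 2):
            q = (m - 2) * d(i, j) - r[i] - r[j]
            key = tuple(sorted((active[i][0], active[j][0])))
            if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]):
                best = (q, key, i, j)
        _, _, i, j = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        li = clamp(li, f"join({active[i][0]},{active[j][0]})")
        lj = clamp(lj, f"join({active[i][0]},{active[j][0]})")
        parent = dendropy.Node()
        ci, cj = active[i][1], active[j][1]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = li
        cj.edge.length = lj
        for kk in ids:
            if kk in (i, j):
                continue
            dist[(min(kk, next_id), max(kk, next_id))] = (
                0.5 * (d(i, kk) + d(j, kk) - d(i, j)))
        key = min(active[i][0], active[j][0])
        del active[i], active[j]
        active[next_id] = (key, parent)
        next_id += 1

    # final 3-star: v_i = (d_ij + d_ik - d_jk) / 2
    (i, j, kk) = sorted(active)
    root = tree.seed_node
    for a, b, c in ((i, j, kk), (j, i, kk), (kk, i, j)):
        v = clamp(0.5 * (d(a, b) + d(a, c) - d(b, c)), "final-join")
        node = active[a][1]
        root.add_child(node)
        node.edge.length = v
    tree.is_rooted = False
    return tree


def nj_from_seqs(seqs: Mapping[str, str]) -> dendropy.Tree:
    D, labels = k2p_matrix(seqs)
    return nj(D, labels)


# ---------------------------------------------------------------------------
# species clustering pattern

def species_pattern(tree: dendropy.Tree,
                    species_of: Mapping[str, str]) -> dict[str, str]:
    """Classify each species as monophyletic or intermingled on an unrooted
    tree: monophyletic iff some edge bipartition separates exactly its
    leaves from all others.  Single-leaf species are 'not assessable'.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    all_set = frozenset(leaves)
    by_species: dict[str, set[str]] = {}
    for leaf in leaves:
        sp = species_of.get(leaf)
        if sp is not None:
            by_species.setdefault(sp, set()).add(leaf)

    sides: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        sides.add(below)
        sides.add(all_set - below)

    out = {}
    for sp, members in sorted(by_species.items()):
        if len(members) < 2:
            out[sp] = "not assessable"
        elif frozenset(members) in sides:
            out[sp] = "monophyletic"
        else:
            out[sp] = "intermingled"
    return out


# ---------------------------------------------------------------------------
# strict-clock calibration

def _heights(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Node height = max branch-length distance to a descendant leaf."""
    h: dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            h[node] = 0.0
        else:
            h[node] = max(h[c] + max(c.edge.length or 0.0, 0.0)
                          for c in node.child_nodes())
    return h


def calibrate(tree: dendropy.Tree, calibration_leaves: Sequence[str],
              age_window: tuple[float, float] = (95.0, 105.0),
              root: str = "midpoint") -> dendropy.Tree:
    """Strict-clock timetree: scale node heights so the calibration node
    (MRCA of the given leaves) sits at the age-window midpoint (Mya).

    Each node gets annotations ``age`` (point estimate), ``age_lo`` and
    ``age_hi`` (window endpoints propagated proportionally).
    """
    tree = tree.clone(depth=1)
    if root == "midpoint" and not tree.is_rooted:
        # already-rooted input keeps its rooting
        tree.reroot_at_midpoint(update_bipartitions=True)
    tree.is_rooted = True
    leaf_labels = {nd.taxon.label for nd in tree.preorder_node_iter()
                   if nd.taxon is not None}
    wanted = set(calibration_leaves)
    if not wanted <= leaf_labels:
        raise ValueError("calibration leaves not all present in tree")
    if wanted == leaf_labels:
        mrca = tree.seed_node
    else:
        taxa = [t for t in tree.taxon_namespace if t.label in wanted]
        mrca = tree.mrca(taxa=taxa)
    if mrca is None:
        raise ValueError("calibration node not found")
    h = _heights(tree)
    h_cal = h[mrca]
    if h_cal <= 0:
        raise ValueError("calibration node has zero height")
    lo, hi = age_window
    mid = 0.5 * (lo + hi)
    for node in tree.preorder_node_iter():
        node.age = h[node] * mid / h_cal
        node.annotations["age"] = round(node.age, 6)
        node.annotations["age_lo"] = round(h[node] * lo / h_cal, 6)
        node.annotations["age_hi"] = round(h[node] * hi / h_cal, 6)
    return tree


def to_newick(tree: dendropy.Tree, ages: bool = False) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_annotations=not ages,
    ).strip()


def write_distance_matrix(path, D: np.ndarray, labels: Sequence[str]) -> None:
    """PHYLIP-style square distance matrix as TSV."""
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for lab, row in zip(labels, np.asarray(D)):
            fh.write(lab + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")
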