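"""Neighbor-joining trees, column-bootstrap supports, and monophyly checks.

The tree builder is the classical Saitou–Nei agglomeration with the
Studier–Keppler Q-criterion.  It is consistent on additive matrices: if the
input distances are exactly the path lengths of some tree, that tree (with
its branch lengths) is recovered.  All ties in the Q-matrix are broken by
the smallest (row, column) index pair in the current working order, so the
output is deterministic.

Bootstrap supports follow the standard column-resampling scheme: each
replicate resamples alignment columns with replacement, recomputes the
p-distance matrix and NJ tree, and each internal edge of the original tree
is annotated with the percentage of replicate trees containing the same
bipartition.  Trees are held in dendropy ``Tree`` objects; supports live in
internal node labels, as Newick convention expects.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .alignment_io import LabeledAlignment, SpecimenRecord
from .distances import DistanceMatrix, pdist_from_codes
from .errors import DegenerateDataError, IncompleteMatrixError, ValidationError

logger = logging.getLogger("barcodegap")


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _nj_clamp(li: float, lj: float) -> tuple[float, float]:
    # transfer a negative length to the sister branch so the joined pair's
    # path length is preserved; if both are negative nothing can be saved.
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li = max(0.0, li + lj)
        lj = 0.0
    return li, lj


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = False) -> dendropy.Tree:
    """Build the unrooted NJ tree of a complete distance matrix (n >= 3).

    Negative branch lengths arising from the NJ arithmetic are retained by
    default; with ``clamp_negative`` they are set to zero and the deficit is
    moved to the sister branch of the join.
    """
    if dm.n < 3:
        raise ValidationError(f"neighbor joining needs >= 3 tips, got {dm.n}")
    if not dm.is_complete():
        raise IncompleteMatrixError(
            "distance matrix has undefined (zero-overlap) entries"
        )

    tns = dendropy.TaxonNamespace([dendropy.Taxon(label=sid) for sid in dm.ids])
    nodes: list[dendropy.Node] = []
    for tax in tns:
        nd = dendropy.Node(taxon=tax)
        nodes.append(nd)

    D = dm.d.astype(np.float64).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # row-major argmin on the upper triangle = smallest (i, j) tie-break
        iu, ju = np.triu_indices(m, k=1)
        k = int(np.argmin(Q[iu, ju]))
        i, j = int(iu[k]), int(ju[k])

        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if clamp_negative:
            li, lj = _nj_clamp(li, lj)

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj

        newrow = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        D[i, :] = newrow
        D[:, i] = newrow
        D[i, i] = 0.0
        keep = [x for x in range(m) if x != j]
        D = D[np.ix_(keep, keep)]
        nodes[i] = parent
        del nodes[j]

    # resolve the final three around a central node (three-point formulas)
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    if clamp_negative:
        la, lb = _nj_clamp(la, lb)
        lb, lc = _nj_clamp(lb, lc)
        la, lc = _nj_clamp(la, lc)
    center = dendropy.Node()
    for nd, ln in ((a, la), (b, lb), (c, lc)):
        center.add_child(nd)
        nd.edge.length = ln

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------

def tip_labels(tree: dendropy.Tree) -> tuple[str, ...]:
    return tuple(leaf.taxon.label for leaf in tree.leaf_node_iter())


def bipartitions(tree: dendropy.Tree, include_trivial: bool = False):
    """Map each edge's split to its child node.

    A split is canonicalized as the frozenset of tip labels on the side NOT
    containing the reference tip (the lexicographically smallest label), so
    splits compare across trees regardless of rooting.  Trivial splits (one
    tip) are skipped unless requested.
    """
    all_tips = frozenset(tip_labels(tree))
    n = len(all_tips)
    ref = min(all_tips)
    out: dict[frozenset, dendropy.Node] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if ref in below:
            below = all_tips - below
        if not below or below == all_tips:
            continue
        if min(len(below), n - len(below)) < 2 and not include_trivial:
            continue
        out[below] = nd
    return out


def bipartition_set(tree: dendropy.Tree) -> frozenset:
    """The set of non-trivial splits of a tree (topology fingerprint)."""
    return frozenset(bipartitions(tree).keys())


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_supports(
    aln: LabeledAlignment,
    replicates: int = 1000,
    seed: int = 0,
    clamp_negative: bool = False,
    max_redraw_factor: int = 10,
) -> dendropy.Tree:
    """NJ tree of the full alignment with bootstrap percentages on internal edges.

    Each replicate resamples the alignment's columns with replacement
    (seeded), recomputes p-distances and the NJ tree; supports are the
    rounded percentage of replicates containing each original bipartition.
    Replicates whose resampled matrix has undefined entries are redrawn; more
    than ``max_redraw_factor * replicates`` redraws aborts.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    codes = aln.codes
    L = aln.L
    d, ov = pdist_from_codes(codes)
    base = neighbor_joining(DistanceMatrix(aln.ids, d, ov), clamp_negative)
    base_splits = bipartitions(base)

    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {s: 0 for s in base_splits}
    done = 0
    redraws = 0
    while done < replicates:
        cols = rng.integers(0, L, size=L)
        dr, ovr = pdist_from_codes(codes[:, cols])
        off = ~np.eye(len(aln.ids), dtype=bool)
        if np.isnan(dr[off]).any():
            redraws += 1
            if redraws > max_redraw_factor * replicates:
                raise DegenerateDataError(
                    f"exceeded {max_redraw_factor * replicates} bootstrap redraws; "
                    "too much missing data for column resampling"
                )
            continue
        rep_tree = neighbor_joining(DistanceMatrix(aln.ids, dr, ovr), clamp_negative)
        for s in bipartition_set(rep_tree):
            if s in counts:
                counts[s] += 1
        done += 1
    if redraws:
        logger.info("bootstrap: %d replicate(s) redrawn for undefined entries", redraws)

    for split, node in base_splits.items():
        pct = round(100.0 * counts[split] / replicates)
        node.label = str(int(pct))
        node.support = int(pct)
    return base


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree) -> str:
    """Serialize with branch lengths and supports as internal node labels."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_annotations=True,
    )
    return s.strip() + "\n"


def read_newick(text: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Monophyly
# ---------------------------------------------------------------------------

GROUP_ROW_LABEL = "<ingroup>"


def monophyly_report(
    tree: dendropy.Tree,
    records: Sequence[SpecimenRecord],
) -> pd.DataFrame:
    """Per-species monophyly and bootstrap support on a (support-annotated) tree.

    A species is monophyletic iff the split (its tips | everything else)
    exists in the tree; its support is that edge's annotation when present.
    Single-specimen species are monophyletic by convention with support NA.
    When outgroup records are present an extra ``<ingroup>`` row reports
    whether the ingroup as a whole is monophyletic with respect to the
    outgroups.
    """
    tips = set(tip_labels(tree))
    by_species: dict[str, set] = {}
    ingroup_tips: set = set()
    for r in records:
        if r.seq_id not in tips:
            continue
        by_species.setdefault(r.species, set()).add(r.seq_id)
        if r.role == "ingroup":
            ingroup_tips.add(r.seq_id)
    skipped = {r.species for r in records} - set(by_species)
    for sp in sorted(skipped):
        logger.warning("species %r has no tips in the tree; skipped", sp)

    all_tips = frozenset(tips)
    ref = min(all_tips)
    splits = bipartitions(tree, include_trivial=True)

    def canon(group: set) -> frozenset:
        g = frozenset(group)
        return (all_tips - g) if ref in g else g

    def check(group: set) -> tuple[bool, float]:
        if len(group) <= 1 or len(group) >= len(all_tips):
            return True, float("nan")
        node = splits.get(canon(group))
        if node is None:
            return False, float("nan")
        support = getattr(node, "support", None)
        if support is None and node.label not in (None, ""):
            try:
                support = float(node.label)
            except ValueError:
                support = None
        return True, float("nan") if support is None else float(support)

    rows = []
    for sp, group in by_species.items():
        mono, support = check(group)
        rows.append({
            "species": sp, "n_tips": len(group),
            "monophyletic": mono, "support": support,
        })
    if ingroup_tips and ingroup_tips != all_tips:
        mono, support = check(ingroup_tips)
        rows.append({
            "species": GROUP_ROW_LABEL, "n_tips": len(ingroup_tips),
            "monophyletic": mono, "support": support,
        })
    return pd.DataFrame(rows, columns=["species", "n_tips", "monophyletic", "support"])


def tree_path_lengths(tree: dendropy.Tree, ids: Iterable[str]) -> np.ndarray:
    """Patristic (path-length) matrix of the tree in the given tip order."""
    ids = list(ids)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.distance(taxa[ids[i]], taxa[ids[j]])
    return out
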