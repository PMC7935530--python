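"""Single-copy-gene phylogenetics: marker-family selection, p-distances,
neighbor joining, ecotype clade assignment and average nucleotide identity.

The tree stage is distance-based: pairwise p-distances (proportion of
differing sites over gap-free columns) feed a neighbor-joining agglomeration,
which reconstructs additive distance matrices exactly.  Ecotype labels are
transferred to query leaves from their nearest labeled reference leaf by
patristic distance.  ANI between two genomes is the mean identity of
reciprocal best-hit gene pairs above an identity floor, expressed in percent.

Trees are scikit-bio ``TreeNode`` objects, so Newick round-trips and patristic
distances come from the standard container.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .catalog import align_identity

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerSeq",
    "MarkerFamily",
    "select_marker_family",
    "align_to_anchor",
    "p_distance_matrix",
    "nj_tree",
    "assign_clade",
    "genome_ani",
]

GAP = "-"


@dataclass(frozen=True)
class MarkerSeq:
    seq_id: str
    sequence: str
    source: str = "catalog"   # e.g. reference genome, catalog, external gene set


@dataclass(frozen=True)
class MarkerFamily:
    """A single-copy gene family (COG-style) with its member sequences."""

    family_id: str
    members: tuple[MarkerSeq, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))


def select_marker_family(
    families: Sequence[MarkerFamily], min_len: int = 800
) -> MarkerFamily:
    """Pick the marker family with the most members longer than ``min_len`` bp
    (strict filter), returning it with short members dropped.  Ties break to
    the lexicographically smallest family id."""
    if not families:
        raise ValueError("no families given")
    filtered = [
        MarkerFamily(f.family_id, tuple(m for m in f.members if len(m.sequence) > min_len))
        for f in families
    ]
    best = min(filtered, key=lambda f: (-len(f.members), f.family_id))
    if not best.members:
        raise ValueError(f"no family retains members longer than {min_len} bp")
    return best


def align_to_anchor(seqs: Mapping[str, str], anchor_id: str) -> dict[str, str]:
    """Project sequences onto a chosen anchor's coordinates by global pairwise
    alignment, yielding equal-length gapped strings suitable for
    :func:`p_distance_matrix`.  Insertions relative to the anchor are dropped;
    deletions become gap characters.  A convenience for unaligned input; a
    proper multiple alignment is preferable when available."""
    from Bio import Align

    anchor = seqs[anchor_id]
    aligner = Align.PairwiseAligner(
        mode="global", match_score=1, mismatch_score=-1,
        open_gap_score=-2, extend_gap_score=-1,
    )
    out = {}
    for sid, seq in seqs.items():
        if sid == anchor_id:
            out[sid] = anchor
            continue
        aln = aligner.align(anchor, seq)[0]
        row_a, row_s = aln[0], aln[1]
        projected = [s for a, s in zip(row_a, row_s) if a != GAP]
        out[sid] = "".join(projected)
    logger.info("projected %d sequences onto anchor %r (%d columns)", len(seqs), anchor_id, len(anchor))
    return out


def p_distance_matrix(seqs: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise p-distances over equal-length (aligned) sequences.

    ``d(i, j)`` is the fraction of differing sites among columns where neither
    sequence has a gap; a pair with zero comparable columns is an error.
    """
    ids = list(seqs)
    if len(ids) < 3:
        raise ValueError("need at least 3 sequences")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be equal length (pre-aligned); see align_to_anchor")
    mat = np.array([np.frombuffer(seqs[i].encode(), dtype="S1") for i in ids])
    nongap = mat != GAP.encode()
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = nongap[i] & nongap[j]
            m = int(comparable.sum())
            if m == 0:
                raise ValueError(f"no comparable (gap-free) positions between {ids[i]!r} and {ids[j]!r}")
            d[i, j] = d[j, i] = int((mat[i] != mat[j])[comparable].sum()) / m
    return DistanceMatrix(d, ids)


def nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Neighbor joining on a symmetric, hollow distance matrix.

    Standard Saitou–Nei agglomeration; the returned tree is unrooted with a
    trifurcating root and binary internal nodes elsewhere.  Negative branch-
    length estimates are clamped to zero with the total deficit logged.
    """
    d = np.array(dist.data, dtype=float, copy=True)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if (d < 0).any():
        raise ValueError("distance matrix contains negative entries")
    if d.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [TreeNode(name=i) for i in dist.ids]
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)  # first minimum: smallest indices
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([np.hstack([d[np.ix_(keep, keep)], dnew[keep, None]]),
                       np.hstack([dnew[keep], [0.0]])])
        nodes = [nodes[k] for k in keep] + [parent]

    # final trifurcation: three-point closed form
    (d01, d02, d12) = (d[0, 1], d[0, 2], d[1, 2])
    lengths = ((d01 + d02 - d12) / 2, (d01 + d12 - d02) / 2, (d02 + d12 - d01) / 2)
    for node, L in zip(nodes, lengths):
        node.length = clamp(L)
    root = TreeNode(children=nodes)
    if deficit > 0:
        logger.info("clamped negative branch lengths; total deficit %.3g", deficit)
    return root


def assign_clade(
    query_ids: Sequence[str],
    refs: Mapping[str, str],
    tree: TreeNode,
) -> dict[str, str]:
    """Label each query leaf with the ecotype of its nearest labeled reference
    leaf by patristic distance.  Exact ties break toward the reference with
    the lexicographically smallest id."""
    if not refs:
        raise ValueError("no labeled references")
    tips = {t.name for t in tree.tips()}
    missing = (set(query_ids) | set(refs)) - tips
    if missing:
        raise ValueError(f"ids not in tree: {sorted(missing)}")
    dm = tree.tip_tip_distances()
    out = {}
    for q in query_ids:
        best = min(sorted(refs), key=lambda ref: dm[q, ref])
        out[q] = refs[best]
    return out


def genome_ani(
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    min_identity: float = 0.3,
) -> float:
    """Average nucleotide identity (percent) between two genomes given as gene
    lists, from reciprocal best-hit gene pairs at identity >= ``min_identity``.
    """
    if not genes_a or not genes_b:
        raise ValueError("both gene lists must be non-empty")
    ident = np.array([[align_identity(a, b)[0] for b in genes_b] for a in genes_a])
    best_a = ident.argmax(axis=1)
    best_b = ident.argmax(axis=0)
    kept = [
        ident[i, j]
        for i, j in enumerate(best_a)
        if best_b[j] == i and ident[i, j] >= min_identity
    ]
    if not kept:
        raise ValueError(
            f"no reciprocal best-hit gene pair reaches identity {min_identity}; "
            "the genomes may be unrelated at nucleotide level"
        )
    return float(np.mean(kept) * 100.0)
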