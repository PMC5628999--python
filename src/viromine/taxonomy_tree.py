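"""Whole-genome relatedness trees from translated-alignment scores.

Genome pairs are scored by summed six-frame translated local alignments
(:func:`viromine.align.translated_score`); the Dice coefficient

    dice(A, B) = 2 * S(A, B) / (S(A, A) + S(B, B))

turns shared translated score into a similarity in [0, 1], which is
transformed to the tree distance ``d = log10(1 + 9 * (1 - dice))`` — a
monotone map of [0, 1] onto [0, 1] that compresses the gap between
extreme values while keeping d(A, A) = 0 exactly.  Trees are built with
a canonical Saitou-Nei neighbour-joining implementation and written as
unrooted newick.  The same NJ engine serves marker-protein trees
(e.g. large-subunit terminase, a phylogenetic marker for tailed phages).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .align import local_align_protein, summarize_pair, translated_score

__all__ = [
    "DiceScore",
    "dice_matrix",
    "neighbor_joining",
    "marker_tree",
    "write_distance_tsv",
]


@dataclass
class DiceScore:
    a: str
    b: str
    s_ab: float
    s_aa: float
    s_bb: float

    @property
    def dice(self) -> float:
        denom = self.s_aa + self.s_bb
        if denom <= 0:
            return math.nan
        return min(max(2.0 * self.s_ab / denom, 0.0), 1.0)

    @property
    def dissimilarity(self) -> float:
        return 1.0 - self.dice

    @property
    def distance(self) -> float:
        return math.log10(1.0 + 9.0 * self.dissimilarity)


def dice_matrix(
    genomes: Mapping[str, str],
    word: int = 5,
    min_hsp_score: int = 50,
) -> tuple[list[str], np.ndarray]:
    """Log-scaled Dice dissimilarity matrix over a genome set.

    Requires at least three genomes; a genome whose self translated
    score is zero carries no scorable gene content and is an error.
    The off-diagonal is computed once per unordered pair and mirrored,
    so the matrix is exactly symmetric with a zero diagonal.
    """
    ids = sorted(genomes)
    if len(ids) < 3:
        raise ValueError("dice_matrix needs >= 3 genomes")
    self_scores = {}
    for g in ids:
        s = translated_score(genomes[g], genomes[g], word=word, min_hsp_score=min_hsp_score)
        if s <= 0:
            raise ValueError(f"genome {g} has zero self translated score")
        self_scores[g] = s
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s_ab = translated_score(genomes[ids[i]], genomes[ids[j]], word=word, min_hsp_score=min_hsp_score)
            score = DiceScore(ids[i], ids[j], s_ab, self_scores[ids[i]], self_scores[ids[j]])
            d[i, j] = d[j, i] = score.distance
    return ids, d


# ---------------------------------------------------------------------------
# Neighbour joining (Saitou-Nei)


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label: Optional[str] = None, children: Optional[list] = None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)


def _validate_matrix(ids: Sequence[str], d: np.ndarray) -> None:
    d = np.asarray(d, dtype=float)
    n = len(ids)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    if not np.isfinite(d).all():
        raise ValueError("distance matrix has non-finite entries")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix not symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix diagonal not zero")


def neighbor_joining(ids: Sequence[str], matrix: np.ndarray) -> str:
    """Canonical neighbour joining; returns an unrooted newick string.

    Pair selection minimises the Q criterion with ties broken by
    lexicographic pair order; branch lengths use the standard formulas
    with negative lengths clamped to zero and the deficit moved to the
    sister edge.
    """
    _validate_matrix(ids, matrix)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes: list[_Node] = [_Node(label=i) for i in ids]
    names: list[str] = list(ids)
    d = np.asarray(matrix, dtype=float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best: Optional[tuple[float, str, str, int, int]] = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key_pair = tuple(sorted((names[i], names[j])))
                cand = (q, key_pair[0], key_pair[1], i, j)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        _, _, _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        new_name = min(names[i], names[j])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d = np.pad(d[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        d[-1, :-1] = dnew[keep]
        d[:-1, -1] = dnew[keep]
        nodes = [nodes[x] for x in keep] + [new]
        names = [names[x] for x in keep] + [new_name]

    # final three taxa joined at the unrooted centre
    (a, b, c) = range(3)
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = _Node(
        children=[(nodes[a], max(la, 0.0)), (nodes[b], max(lb, 0.0)), (nodes[c], max(lc, 0.0))]
    )
    return _to_newick(root) + ";"


def _to_newick(node: _Node) -> str:
    if not node.children:
        return node.label
    parts = [f"{_to_newick(ch)}:{bl:.12g}" for ch, bl in node.children]
    return "(" + ",".join(parts) + ")"


def marker_tree(marker_proteins: Mapping[str, str]) -> str:
    """NJ tree over marker proteins (distance = 1 - alignment identity).

    Stands in for a maximum-likelihood marker phylogeny: pairwise
    protein identities come from the seed-and-extend protein aligner,
    with unalignable pairs set to the maximal distance 1.
    """
    ids = sorted(marker_proteins)
    if len(ids) < 3:
        raise ValueError("marker tree needs >= 3 proteins")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = marker_proteins[ids[i]], marker_proteins[ids[j]]
            hits = local_align_protein(a, b)
            if hits:
                summary = summarize_pair(hits, len(a), len(b))
                ident = summary.weighted_identity
            else:
                ident = 0.0
            d[i, j] = d[j, i] = 1.0 - ident
    return neighbor_joining(ids, d)


def write_distance_tsv(ids: Sequence[str], matrix: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(ids) + "\n")
        for i, name in enumerate(ids):
            fh.write(name + "\t" + "\t".join(f"{matrix[i, j]:.8g}" for j in range(len(ids))) + "\n")
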