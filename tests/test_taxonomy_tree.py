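"""Dice distances and neighbour joining."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from viromine.synthetic_data import CommunitySpec, SampleSpec, generate_genomes, _orf_cassette
from viromine.taxonomy_tree import DiceScore, dice_matrix, marker_tree, neighbor_joining


def _patristic(newick):
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda a, b: pdm.patristic_distance(taxa[a], taxa[b])


def test_three_taxon_closed_form():
    ids = ["A", "B", "C"]
    d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
    newick = neighbor_joining(ids, d)
    dist = _patristic(newick)
    # b_i = (d_ij + d_ik - d_jk) / 2: A=0, B=2, C=3
    assert dist("A", "B") == pytest.approx(2.0, abs=1e-9)
    assert dist("A", "C") == pytest.approx(3.0, abs=1e-9)
    assert dist("B", "C") == pytest.approx(5.0, abs=1e-9)


def test_additive_four_taxon_exact():
    ids = ["A", "B", "C", "D"]
    d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float)
    dist = _patristic(neighbor_joining(ids, d))
    for i in range(4):
        for j in range(i + 1, 4):
            assert dist(ids[i], ids[j]) == pytest.approx(d[i, j], abs=1e-9)


@settings(deadline=None, derandomize=True, max_examples=20)
@given(st.integers(0, 2**31 - 1))
def test_nj_consistent_on_random_additive_matrices(seed):
    """Random 5-taxon additive matrices are reproduced exactly (path check).

    Distances are hand-built on the caterpillar (A,B)-n1 -x- n2(C) -y-
    n3(D,E): the internal-node position along the spine determines every
    leaf-to-leaf path length.
    """
    rng = np.random.default_rng(seed)
    ids = ["A", "B", "C", "D", "E"]
    bl = dict(zip(ids, rng.uniform(0.1, 3.0, size=5)))
    x, y = rng.uniform(0.1, 3.0, size=2)
    spine = {"A": 0.0, "B": 0.0, "C": x, "D": x + y, "E": x + y}
    attach = {"A": "n1", "B": "n1", "C": "n2", "D": "n3", "E": "n3"}
    d = np.zeros((5, 5))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                spine_path = 0.0 if attach[a] == attach[b] else abs(spine[a] - spine[b])
                d[i, j] = d[j, i] = bl[a] + bl[b] + spine_path
    dist = _patristic(neighbor_joining(ids, d))
    for i in range(5):
        for j in range(i + 1, 5):
            assert dist(ids[i], ids[j]) == pytest.approx(d[i, j], abs=1e-9)


def test_nj_requires_three_taxa_and_valid_matrix():
    with pytest.raises(ValueError):
        neighbor_joining(["A", "B"], np.zeros((2, 2)))
    bad = np.array([[0, 1, 2], [1, 0, 3], [2, 99, 0]], dtype=float)
    with pytest.raises(ValueError):
        neighbor_joining(["A", "B", "C"], bad)


def test_dice_score_endpoints():
    s = DiceScore("A", "B", s_ab=0.0, s_aa=100.0, s_bb=100.0)
    assert s.dice == 0.0
    assert s.distance == pytest.approx(1.0)  # log10(10)
    t = DiceScore("A", "A", s_ab=100.0, s_aa=100.0, s_bb=100.0)
    assert t.dice == 1.0
    assert t.distance == 0.0


def test_dice_matrix_monotone_in_divergence():
    spec = CommunitySpec(
        n_genomes=4,
        seed=41,
        samples=[SampleSpec("A", 15, "ST1")],
        genome_length_range_bp=(10_000, 10_001),
        gc_range=(0.38, 0.42),
        divergence_plan=[(0, 1, 0.98), (0, 2, 0.90), (0, 3, 0.70)],
    )
    genomes, _ = generate_genomes(spec)
    ids, d = dice_matrix(genomes)
    row = d[ids.index("G000")]
    assert row[ids.index("G000")] == 0.0
    assert row[ids.index("G001")] < row[ids.index("G002")] < row[ids.index("G003")]
    assert np.allclose(d, d.T)


def test_dice_matrix_rejects_unscorable_genome():
    # a genome too short to carry any translated word has self score 0
    with pytest.raises(ValueError, match="C"):
        dice_matrix({"A": "ACGT" * 2000, "B": "ACGT" * 2000, "C": "ACGTACG"})


def test_newick_round_trip_preserves_lengths():
    import dendropy

    ids = ["A", "B", "C", "D"]
    d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float)
    newick = neighbor_joining(ids, d)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    rewritten = tree.as_string(schema="newick").strip()
    dist_a = _patristic(newick)
    dist_b = _patristic(rewritten)
    for i in range(4):
        for j in range(i + 1, 4):
            assert dist_a(ids[i], ids[j]) == pytest.approx(dist_b(ids[i], ids[j]), abs=1e-9)


def test_marker_tree_identical_and_families():
    rng = np.random.default_rng(5)
    fam1 = _orf_cassette(rng, 300)[1]
    fam2 = _orf_cassette(rng, 300)[1]
    star = marker_tree({"a": fam1, "b": fam1, "c": fam1})
    assert star.count(":0") >= 3  # all branch lengths zero

    aas = "ARNDCQEGHILKMFPSTWYV"

    def mutated(p, n):
        p = list(p)
        for i in rng.choice(len(p), n, replace=False):
            p[i] = aas[int(rng.integers(20))]
        return "".join(p)

    newick = marker_tree({"a1": fam1, "a2": mutated(fam1, 15), "b1": fam2, "b2": mutated(fam2, 15)})
    dist = _patristic(newick)
    assert dist("a1", "a2") < dist("a1", "b1")
    assert dist("b1", "b2") < dist("a2", "b2")
    with pytest.raises(ValueError):
        marker_tree({"a": fam1, "b": fam1})
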