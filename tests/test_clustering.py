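"""VC formation and greedy protein clustering."""

import numpy as np
import pytest

from viromine.clustering import build_vcs, cluster_proteins
from viromine.seqcore import ContigRecord
from viromine.synthetic_data import _orf_cassette, mutate_exact, random_genome


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(321)


def _partition(vcs):
    return {frozenset(v.member_contig_ids) for v in vcs}


def test_similar_pair_plus_singleton(rng):
    a = random_genome(rng, 10_000, 0.4)
    b = mutate_exact(a, 500, rng)  # 95% identity, full coverage
    c = random_genome(rng, 10_000, 0.45)
    contigs = [ContigRecord("A", a), ContigRecord("B", b), ContigRecord("C", c)]
    vcs = build_vcs(contigs)
    assert _partition(vcs) == {frozenset({"A", "B"}), frozenset({"C"})}
    multi = [v for v in vcs if not v.is_singleton]
    assert len(multi) == 1 and multi[0].representative in {"A", "B"}


def test_chain_joins_by_transitive_closure(rng):
    g = random_genome(rng, 20_000, 0.4)
    # A and C share no overlap but both overlap B
    a = g[:9_000]
    b = mutate_exact(g[6_000:15_000], 20, rng)
    c = g[12_000:20_000]
    vcs = build_vcs([ContigRecord(i, s) for i, s in [("A", a), ("B", b), ("C", c)]])
    assert _partition(vcs) == {frozenset({"A", "B", "C"})}


def test_partition_invariant_under_input_order(rng):
    g1 = random_genome(rng, 12_000, 0.4)
    g2 = random_genome(rng, 12_000, 0.45)
    contigs = [
        ContigRecord("x1", g1[:8_000]),
        ContigRecord("x2", mutate_exact(g1[4_000:], 30, rng)),
        ContigRecord("y1", g2),
    ]
    fwd = build_vcs(contigs)
    rev = build_vcs(contigs[::-1])
    assert _partition(fwd) == _partition(rev)
    assert [v.vc_id for v in fwd] == [v.vc_id for v in rev]


def test_raising_identity_refines_partition(rng):
    g = random_genome(rng, 10_000, 0.4)
    contigs = [
        ContigRecord("A", g),
        ContigRecord("B", mutate_exact(g, 700, rng)),  # ~93% identity
        ContigRecord("C", mutate_exact(g, 50, rng)),  # ~99.5% identity
    ]
    loose = _partition(build_vcs(contigs, identity_min=0.90))
    strict = _partition(build_vcs(contigs, identity_min=0.98))
    # every strict cluster nests inside one loose cluster
    for s in strict:
        assert any(s <= l for l in loose)
    assert len(strict) >= len(loose)


def test_empty_input_and_bad_thresholds():
    assert build_vcs([]) == []
    with pytest.raises(ValueError):
        build_vcs([ContigRecord("A", "ACGT" * 100)], identity_min=1.5)


def test_identical_proteins_single_cluster(rng):
    prot = _orf_cassette(rng, 200)[1]
    clusters = cluster_proteins({f"p{i}": prot for i in range(5)})
    assert len(clusters) == 1
    assert len(clusters[0].member_ids) == 5


def test_unrelated_families_split(rng):
    fam1 = _orf_cassette(rng, 250)[1]
    fam2 = _orf_cassette(rng, 250)[1]
    clusters = cluster_proteins({"a": fam1, "b": fam2})
    assert len(clusters) == 2


def test_protein_clustering_deterministic_and_rule_based(rng):
    aas = "ARNDCQEGHILKMFPSTWYV"
    fam = _orf_cassette(rng, 300)[1]

    def mutated(p, n):
        p = list(p)
        for i in rng.choice(len(p), n, replace=False):
            p[i] = aas[int(rng.integers(20))]
        return "".join(p)

    proteins = {
        "long": fam + "A" * 5,
        "close": mutated(fam, 60),  # ~80% identity, joins
        "far": mutated(fam, 200),  # ~33% identity, separate
    }
    first = cluster_proteins(proteins)
    second = cluster_proteins(dict(reversed(list(proteins.items()))))
    assert [sorted(c.member_ids) for c in first] == [sorted(c.member_ids) for c in second]
    by_member = {m: c.pc_id for c in first for m in c.member_ids}
    assert by_member["close"] == by_member["long"]
    assert by_member["far"] != by_member["long"]
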