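"""Host-evidence predicates and evidence combination."""

import numpy as np
import pytest

from viromine.host_predict import (
    Evidence,
    amg_flags,
    combine_evidence,
    crispr_match,
    majority_best_hit,
    trna_match,
)
from viromine.seqcore import ContigRecord, GeneCall, revcomp
from viromine.synthetic_data import _orf_cassette, mutate_exact, random_genome


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(99)


def test_trna_exact_match_both_strands(rng):
    trna = random_genome(rng, 72, 0.55)
    backbone = random_genome(rng, 5_000, 0.4)
    fwd = backbone[:2_000] + trna + backbone[2_000:]
    rev = backbone[:2_000] + revcomp(trna) + backbone[2_000:]
    db = [(trna, "SAR11")]
    assert trna_match(fwd, db).host_label == "SAR11"
    assert trna_match(rev, db).host_label == "SAR11"


def test_trna_one_mismatch_rejected(rng):
    trna = random_genome(rng, 72, 0.55)
    damaged = mutate_exact(trna, 1, rng)
    contig = random_genome(rng, 2_000, 0.4) + damaged + random_genome(rng, 2_000, 0.4)
    assert trna_match(contig, [(trna, "SAR11")]) is None


@pytest.mark.parametrize("n_mismatch,expected", [(0, True), (1, True), (2, False)])
def test_crispr_mismatch_threshold(rng, n_mismatch, expected):
    spacer = random_genome(rng, 32, 0.4)
    planted = mutate_exact(spacer, n_mismatch, rng)
    contig = random_genome(rng, 3_000, 0.4) + planted + random_genome(rng, 3_000, 0.4)
    ev = crispr_match(contig, [(spacer, "Cyanobacteria")])
    assert (ev is not None) == expected


def test_crispr_reverse_strand(rng):
    spacer = random_genome(rng, 32, 0.4)
    contig = random_genome(rng, 1_000, 0.4) + revcomp(spacer) + random_genome(rng, 1_000, 0.4)
    assert crispr_match(contig, [(spacer, "SAR116")]).host_label == "SAR116"


def _gene_fixture(rng, identities):
    """Contig with one planted gene per identity; reference carries a
    copy of each gene diverged to that identity."""
    genes = [_orf_cassette(rng, 120, gc=0.45)[0] for _ in identities]
    contig_seq = ""
    calls = []
    for dna in genes:
        start = len(contig_seq)
        contig_seq += dna + random_genome(rng, 100, 0.45)
        calls.append(GeneCall("c", start, start + len(dna), "+", 0, ""))
    return ContigRecord("c", contig_seq), calls, genes


def test_majority_best_hit_seven_of_ten(rng):
    contig, calls, genes = _gene_fixture(rng, range(10))
    ref_x = "".join(mutate_exact(g, round(0.12 * len(g)), rng) + random_genome(rng, 60, 0.45) for g in genes[:7])
    ref_y = "".join(mutate_exact(g, round(0.12 * len(g)), rng) + random_genome(rng, 60, 0.45) for g in genes[7:])
    ev = majority_best_hit(contig, calls, {"X": (ref_x, "H1"), "Y": (ref_y, "H2")})
    assert ev is not None and ev.host_label == "H1"


def test_majority_best_hit_even_split_gives_none(rng):
    contig, calls, genes = _gene_fixture(rng, range(10))
    ref_x = "".join(mutate_exact(g, round(0.1 * len(g)), rng) for g in genes[:5])
    ref_y = "".join(mutate_exact(g, round(0.1 * len(g)), rng) for g in genes[5:])
    ev = majority_best_hit(contig, calls, {"X": (ref_x, "H1"), "Y": (ref_y, "H2")})
    assert ev is None


def test_majority_best_hit_below_identity_threshold(rng):
    contig, calls, genes = _gene_fixture(rng, range(6))
    # ~70% identity only: below the >75% rule
    ref = "".join(mutate_exact(g, round(0.30 * len(g)), rng) for g in genes)
    assert majority_best_hit(contig, calls, {"X": (ref, "H1")}) is None


def test_majority_best_hit_no_genes():
    contig = ContigRecord("c", "ACGT" * 100)
    assert majority_best_hit(contig, [], {"X": ("ACGT" * 100, "H1")}) is None


def test_amg_flags():
    calls = [
        GeneCall("c", 0, 300, "+", 0, "", label="psbA"),
        GeneCall("c", 400, 700, "+", 0, "", label="psbD"),
        GeneCall("c", 800, 1100, "+", 0, "", label="hypothetical"),
    ]
    flags, ev = amg_flags(calls)
    assert flags == {"psbA", "psbD"}
    assert ev is None  # host evidence disabled by default
    flags, ev = amg_flags(calls, enable_host_evidence=True)
    assert ev.host_label == "Cyanobacteria"
    assert amg_flags([GeneCall("c", 0, 3, "+", 0, "")])[0] == set()


def test_precedence_trna_beats_amg():
    ev = {
        "c1": [Evidence("AMG", "H2"), Evidence("tRNA", "H1")],
    }
    calls = combine_evidence(ev)
    assert calls["c1"].host_label == "H1"
    assert not calls["c1"].ambiguous


def test_conflict_at_top_level_is_ambiguous():
    ev = {"c1": [Evidence("tRNA", "H1"), Evidence("CRISPR", "H2")]}
    calls = combine_evidence(ev)
    assert calls["c1"].host_label == "unassigned"
    assert calls["c1"].ambiguous


def test_cluster_neighbor_propagation():
    ev = {"labelled": [Evidence("tRNA", "H1")], "naked": []}
    calls = combine_evidence(ev, vc_partition={"labelled": "VC1", "naked": "VC1"})
    assert calls["naked"].host_label == "H1"
    assert calls["naked"].evidence[-1].kind == "cluster_neighbor"


def test_no_call_without_evidence():
    calls = combine_evidence({"c1": []})
    assert calls["c1"].host_label == "unassigned"
    assert calls["c1"].evidence == []
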