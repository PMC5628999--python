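"""The alignment engine against constructed cases and the SW oracle."""

import math

import numpy as np
import pytest

from viromine import align
from viromine.align import (
    AlignmentHit,
    AlignParams,
    GenomeIndex,
    call_snps,
    local_align_nt,
    local_align_protein,
    map_reads,
    summarize_pair,
    translated_score,
)
from viromine.seqcore import revcomp
from viromine.synthetic_data import mutate_exact, random_genome


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(1234)


def test_self_alignment_full_identity(rng):
    seq = random_genome(rng, 1000, 0.4)
    hits = local_align_nt(seq, seq)
    top = hits[0]
    assert top.identity == 1.0
    assert (top.q_start, top.q_end) == (0, 1000)
    assert (top.s_start, top.s_end) == (0, 1000)
    assert top.strand == "+"


def test_revcomp_subject_flips_strand_preserves_identity(rng):
    seq = random_genome(rng, 800, 0.45)
    hits = local_align_nt(seq, revcomp(seq))
    top = hits[0]
    assert top.strand == "-"
    assert top.identity == 1.0
    assert (top.q_start, top.q_end) == (0, 800)


def test_divergent_pair_identity_and_sw_score(rng):
    """5% planted substitutions: identity ~0.95 and score equal to the
    full Smith-Waterman optimum computed by an independent DP."""
    from skbio.alignment import pair_align

    for _ in range(5):
        n = int(rng.integers(1000, 2001))
        a = random_genome(rng, n, 0.4)
        b = mutate_exact(a, round(0.05 * n), rng)
        hits = local_align_nt(a, b)
        summary = summarize_pair(hits, n, n)
        assert 0.94 <= summary.weighted_identity <= 0.96
        sw = pair_align(a, b, mode="local", sub_score=(1.0, -2.0), gap_cost=(5.0, 2.0))
        assert max(h.score for h in hits) == pytest.approx(float(sw.score), rel=0.01)


def test_n_never_matches():
    a = "ACGT" * 30
    b = "ACGT" * 10 + "N" * 40 + "ACGT" * 10
    params = AlignParams(k=8, min_hit_score=5)
    hits = local_align_nt(a, b, params=params)
    for h in hits:
        assert h.identity <= 1.0
        # no hit may claim matches inside the N block
        assert h.matches <= 80


def _hit(qs, qe, ss, se, matches, columns):
    return AlignmentHit("q", "s", qs, qe, ss, se, "+", matches, columns, float(matches))


def test_summarize_pair_interval_union_hand_computed():
    # two hits covering [0,200) and [100,400) of a 1000-bp shorter query
    hits = [_hit(0, 200, 0, 200, 190, 200), _hit(100, 400, 500, 800, 285, 300)]
    s = summarize_pair(hits, 1000, 5000)
    assert s.coverage_shorter == pytest.approx(0.40)
    assert s.weighted_identity == pytest.approx((190 + 285) / 500)


def test_summarize_pair_single_hit_arithmetic():
    s = summarize_pair([_hit(0, 300, 0, 300, 285, 300)], 1000, 2000)
    assert s.coverage_shorter == pytest.approx(0.30)
    assert s.weighted_identity == pytest.approx(0.95)


def test_summarize_pair_empty():
    s = summarize_pair([], 1000, 1000)
    assert s.coverage_shorter == 0.0
    assert math.isnan(s.weighted_identity)


def test_translated_score_self_and_monotonicity(rng):
    a = random_genome(rng, 6000, 0.4)
    s_aa = translated_score(a, a)
    assert s_aa > 0
    b = mutate_exact(a, 600, rng)  # 10% divergence
    s_ab = translated_score(a, b)
    assert 0 < s_ab < s_aa
    # symmetry within tolerance
    s_ba = translated_score(b, a)
    assert abs(s_ab - s_ba) / max(s_ab, s_ba) <= 0.02


def test_translated_score_null_negligible(rng):
    """Unrelated random genomes: the null translated score is negligible
    relative to self (rare chance HSPs near the 50-score floor allowed)."""
    a = random_genome(rng, 30_000, 0.4)
    b = random_genome(rng, 30_000, 0.4)
    null = translated_score(a, b)
    assert null <= 0.002 * translated_score(a, a)


def test_translated_score_short_sequence_zero():
    assert translated_score("ATGATG", "ATGATG") == 0.0


def test_map_reads_exact_and_conservation(rng):
    genomes = {"GA": random_genome(rng, 20_000, 0.4), "GB": random_genome(rng, 20_000, 0.45)}
    reads = []
    for i in range(500):
        start = int(rng.integers(0, 20_000 - 100))
        reads.append((f"r{i}", genomes["GA"][start : start + 100]))
    counts = map_reads(reads, genomes, identity_threshold=0.99)
    assert counts["GA"] == 500
    assert counts["GB"] == 0
    assert sum(counts.values()) <= len(reads)


def test_map_reads_empty_genome_set():
    with pytest.raises(ValueError):
        GenomeIndex({})


def test_call_snps_identical_and_planted(rng):
    ref = random_genome(rng, 50_000, 0.4)
    assert call_snps(ref, ref) == []
    qry = mutate_exact(ref, 100, rng)
    snps = call_snps(ref, qry, reference_id="R", query_id="Q")
    assert abs(len(snps) - 100) <= 2
    for s in snps:
        assert s.ref_base != s.alt_base
        assert ref[s.position] == s.ref_base
        assert qry[s.position] == s.alt_base


def test_call_snps_specific_substitution():
    rng = np.random.default_rng(77)
    ref = random_genome(rng, 5_000, 0.4)
    pos = 1234
    old = ref[pos]
    new = {"A": "T", "C": "G", "G": "C", "T": "A"}[old]
    qry = ref[:pos] + new + ref[pos + 1 :]
    snps = call_snps(ref, qry)
    assert any(s.position == pos and s.ref_base == old and s.alt_base == new for s in snps)


def test_call_snps_unalignable_pair_errors(rng):
    a = random_genome(rng, 5_000, 0.35)
    b = random_genome(rng, 5_000, 0.45)
    with pytest.raises(ValueError, match="not alignable"):
        call_snps(a, b)


def test_strand_symmetry_property(rng):
    a = random_genome(rng, 1500, 0.4)
    b = mutate_exact(a, 30, rng)
    fwd = max(local_align_nt(a, b), key=lambda h: h.score)
    rev = max(local_align_nt(a, revcomp(b)), key=lambda h: h.score)
    assert fwd.strand == "+" and rev.strand == "-"
    assert fwd.identity == pytest.approx(rev.identity)
    assert fwd.score == pytest.approx(rev.score)


def test_protein_alignment_identity(rng):
    from viromine.synthetic_data import _orf_cassette

    prot = _orf_cassette(rng, 300)[1]
    hits = local_align_protein(prot, prot)
    assert hits[0].identity == 1.0
    assert hits[0].columns == len(prot)


def test_seed_length_floor():
    with pytest.raises(ValueError):
        AlignParams(k=5)


def test_hits_tsv_export(tmp_path, rng):
    a = random_genome(rng, 500, 0.4)
    hits = local_align_nt(a, a)
    out = tmp_path / "hits.tsv"
    align.hits_to_tsv(hits, out)
    lines = out.read_text().strip().splitlines()
    assert lines[0].startswith("qseqid\tsseqid")
    fields = lines[1].split("\t")
    assert fields[2] == "100.00"
    assert fields[4] == "1"  # 1-based export dialect
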