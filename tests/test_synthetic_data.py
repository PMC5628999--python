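"""The community generator: planted truth must match what was planted."""

import numpy as np
import pytest

from viromine import align
from viromine.seqcore import gc_content
from viromine.synthetic_data import (
    CommunitySpec,
    CompletePlan,
    DistributionTag,
    FragmentPlan,
    SampleSpec,
    generate_community,
    generate_genomes,
    shred_to_contigs,
    simulate_reads,
)

SAMPLES = [SampleSpec("A", 15, "ST1"), SampleSpec("B", 45, "ST1")]


def small_spec(seed, **kwargs):
    defaults = dict(
        n_genomes=2,
        seed=seed,
        samples=SAMPLES,
        genome_length_range_bp=(15_000, 20_000),
        gc_range=(0.30, 0.50),
    )
    defaults.update(kwargs)
    return CommunitySpec(**defaults)


def test_generation_is_deterministic():
    a, _ = generate_genomes(small_spec(42))
    b, _ = generate_genomes(small_spec(42))
    assert a == b


def test_planted_divergence_measured_by_alignment():
    spec = small_spec(7, divergence_plan=[(0, 1, 0.96)])
    genomes, truth = generate_genomes(spec)
    hits = align.local_align_nt(genomes["G000"], genomes["G001"])
    summary = align.summarize_pair(hits, len(genomes["G000"]), len(genomes["G001"]))
    assert 0.955 <= summary.weighted_identity <= 0.965
    assert truth.pairwise_identity[("G000", "G001")] == 0.96


def test_realized_gc_tracks_target():
    spec = small_spec(9, n_genomes=3, gc_range=(0.30, 0.3001), genome_length_range_bp=(30_000, 30_001))
    genomes, _ = generate_genomes(spec)
    for g in genomes.values():
        assert 0.28 <= gc_content(g) <= 0.32


def test_divergence_identity_bounds_rejected():
    with pytest.raises(ValueError):
        generate_genomes(small_spec(1, divergence_plan=[(0, 1, 1.2)]))
    with pytest.raises(ValueError):
        generate_genomes(small_spec(1, divergence_plan=[(0, 1, 0.4)]))


def test_complete_contig_has_exact_terminal_repeat():
    genomes, truth = generate_genomes(small_spec(11))
    rng = np.random.default_rng(0)
    out = shred_to_contigs(genomes, truth, [CompletePlan("G000", "A", repeat=40)], rng)
    contig = out["A"][0]
    L = len(genomes["G000"])
    assert contig.length_bp == L + 40
    assert contig.sequence[:40] == contig.sequence[-40:]


def test_fragments_overlap_at_mavg_mergeable_identity():
    genomes, truth = generate_genomes(small_spec(13))
    rng = np.random.default_rng(1)
    plan = [FragmentPlan("G000", ("A", "B"), n_fragments=3, overlap_range=(1000, 1001), mutation_rate=0.002)]
    out = shred_to_contigs(genomes, truth, plan, rng)
    frags = sorted(
        (c for s in out for c in out[s]),
        key=lambda c: truth.contig_sources[c.contig_id][1],
    )
    for a, b in zip(frags, frags[1:]):
        hits = align.local_align_nt(a.sequence, b.sequence)
        top = max(hits, key=lambda h: h.columns)
        assert top.columns >= 900
        assert top.identity >= 0.99


def test_wrap_fragment_relocatable_in_doubled_genome():
    genomes, truth = generate_genomes(small_spec(17))
    rng = np.random.default_rng(2)
    plan = [FragmentPlan("G000", ("A",), n_fragments=3, overlap_range=(500, 800), mutation_rate=0.0, circular=True)]
    out = shred_to_contigs(genomes, truth, plan, rng)
    doubled = genomes["G000"] * 2
    wrapped = 0
    for c in out["A"]:
        gid, start, end = truth.contig_sources[c.contig_id]
        assert doubled[start % len(genomes["G000"]) :][: end - start] == c.sequence or c.sequence in doubled
        assert c.sequence in doubled
        if end > len(genomes["G000"]):
            wrapped += 1
    assert wrapped >= 1


def test_fragment_longer_than_genome_rejected():
    genomes, truth = generate_genomes(small_spec(19))
    rng = np.random.default_rng(3)
    plan = [FragmentPlan("G000", ("A",), n_fragments=1, overlap_range=(30_000, 30_001))]
    with pytest.raises(ValueError):
        shred_to_contigs(genomes, truth, plan, rng)


def test_exact_reads_are_substrings_of_the_circle():
    genomes, _ = generate_genomes(small_spec(21, n_genomes=1))
    rng = np.random.default_rng(4)
    reads, counts = simulate_reads(genomes, {"G000": 1.0}, 100, 1.0, 200, rng)
    doubled = genomes["G000"] * 2
    from viromine.seqcore import revcomp

    for _, seq in reads:
        assert seq in doubled or revcomp(seq) in doubled
    assert counts["G000"] == 200


def test_read_apportionment_binomial_bound():
    spec = small_spec(23, genome_length_range_bp=(30_000, 30_001))
    genomes, _ = generate_genomes(spec)
    rng = np.random.default_rng(5)
    _, counts = simulate_reads(genomes, {g: 1.0 for g in genomes}, 100, 1.0, 10_000, rng)
    sigma = (10_000 * 0.5 * 0.5) ** 0.5
    for g in genomes:
        assert abs(counts[g] - 5_000) <= 3 * sigma


def test_read_simulation_errors():
    genomes, _ = generate_genomes(small_spec(25, n_genomes=1))
    rng = np.random.default_rng(6)
    with pytest.raises(ValueError):
        simulate_reads(genomes, {"G000": 1.0}, 100, 1.0, 0, rng)
    with pytest.raises(ValueError):
        simulate_reads(genomes, {"G000": 1.0}, 100, 0.5, 10, rng)
    with pytest.raises(ValueError):
        simulate_reads(genomes, {"G000": 1.0}, 73, 1.0, 10, rng)


def test_community_determinism_and_truth_sufficiency():
    spec = small_spec(27, planted_distribution=[DistributionTag(), DistributionTag("stenobathic", depths=(15.0,))])
    a = generate_community(spec)
    b = generate_community(spec)
    assert a.truth.genomes == b.truth.genomes
    assert a.reads_by_sample == b.reads_by_sample
    assert [(c.contig_id, c.sequence) for s in a.contigs_by_sample for c in a.contigs_by_sample[s]] == [
        (c.contig_id, c.sequence) for s in b.contigs_by_sample for c in b.contigs_by_sample[s]
    ]
    # truth names a source for every contig, a count for every sampled genome
    for s, contigs in a.contigs_by_sample.items():
        for c in contigs:
            gid, start, end = a.truth.contig_sources[c.contig_id]
            assert gid in a.truth.genomes
            assert end - start == c.length_bp
    assert set(a.truth.sample_gb) == {"A", "B"}


def test_inconsistent_planted_tags_rejected():
    with pytest.raises(ValueError):
        generate_genomes(
            small_spec(29, planted_distribution=[DistributionTag("stenobathic", depths=(999.0,)), DistributionTag()])
        )
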