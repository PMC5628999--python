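"""Screening rules and terminal-repeat completeness detection."""

import numpy as np
import pytest

from viromine.seqcore import ContigRecord, GeneCall, call_orfs, revcomp
from viromine.synthetic_data import _orf_cassette, random_genome
from viromine.viral_screen import detect_terminal_repeat, screen_contigs


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(55)


def _contig_with_cassettes(rng, length, labels, positions=None):
    seq = random_genome(rng, length, 0.42)
    annotations = {}
    positions = positions or np.linspace(0.1, 0.7, num=max(len(labels), 1)) * length
    for label, pos in zip(labels, positions):
        dna, prot = _orf_cassette(rng, 120)
        pos = int(pos)
        seq = seq[:pos] + dna + seq[pos + len(dna) :]
        annotations[prot] = label
    contig = ContigRecord("c", seq)
    return contig, annotations


def test_two_hallmarks_above_length_gate_is_viral(rng):
    contig, ann = _contig_with_cassettes(rng, 12_000, ["terminase", "major capsid protein"])
    calls = {"c": call_orfs(contig.sequence, contig_id="c")}
    [d] = screen_contigs([contig], calls, annotations=ann)
    assert d.verdict == "viral"
    assert d.hallmark_labels == {"terminase", "major capsid protein"}


def test_length_gate_blocks_short_contig_with_hallmarks(rng):
    labels = ["terminase", "portal protein", "tail protein", "major capsid protein"]
    contig, ann = _contig_with_cassettes(rng, 8_000, labels)
    calls = {"c": call_orfs(contig.sequence, contig_id="c")}
    [d] = screen_contigs([contig], calls, annotations=ann)
    assert d.passed_length is False
    assert d.verdict == "not_viral"


def test_synteny_rescues_contig_without_hallmarks(rng):
    seq = random_genome(rng, 9_000, 0.42)
    ref_proteins = []
    pos = 1000
    for _ in range(3):
        dna, prot = _orf_cassette(rng, 150)
        seq = seq[:pos] + dna + seq[pos + len(dna) :]
        ref_proteins.append(prot)
        pos += len(dna) + 400
    contig = ContigRecord("c", seq + random_genome(rng, 6_000, 0.42))
    calls = {"c": call_orfs(contig.sequence, contig_id="c")}
    [d] = screen_contigs([contig], calls, references={"ref_phage": ref_proteins})
    assert d.synteny_support == "ref_phage"
    assert d.verdict == "viral"


def test_contig_without_gene_calls_fails_quietly():
    contig = ContigRecord("bare", "ACGT" * 3000)
    [d] = screen_contigs([contig], {})
    assert d.verdict == "not_viral"
    assert d.hallmark_labels == set()


def test_screening_invariant_to_input_order(rng):
    contigs, anns = [], {}
    for i in range(4):
        c, a = _contig_with_cassettes(rng, 11_000, ["terminase", "tail protein"])
        c.contig_id = f"c{i}"
        contigs.append(c)
        anns.update(a)
    calls = {c.contig_id: call_orfs(c.sequence, contig_id=c.contig_id) for c in contigs}
    fwd = {d.contig_id: d.verdict for d in screen_contigs(contigs, calls, annotations=anns)}
    rev = {d.contig_id: d.verdict for d in screen_contigs(contigs[::-1], calls, annotations=anns)}
    assert fwd == rev


def test_terminal_repeat_planted_40(rng):
    g = random_genome(rng, 3_000, 0.4)
    res = detect_terminal_repeat(g + g[:40])
    assert res.is_complete
    assert res.repeat_length_nt == 40
    assert res.trimmed_length_bp == 3_000
    assert res.classification == "CGR"


def test_terminal_repeat_29_below_floor(rng):
    g = random_genome(rng, 3_000, 0.4)
    res = detect_terminal_repeat(g + g[:29])
    assert not res.is_complete
    assert res.classification == "fragment"


def test_terminal_repeat_reports_longest_vs_bruteforce(rng):
    # a 100-nt terminal repeat whose first 35 nt also recur: the detector
    # must report 100, as confirmed by a brute-force scan over all r
    g = random_genome(rng, 4_000, 0.4)
    seq = g + g[:100]
    brute = max(
        (r for r in range(30, 1001) if seq[:r] == seq[-r:]),
        default=0,
    )
    res = detect_terminal_repeat(seq)
    assert res.repeat_length_nt == brute == 100


def test_gf_classification_requires_explicit_map(rng):
    g = random_genome(rng, 3_000, 0.4)
    res = detect_terminal_repeat(ContigRecord("x", g), complete_by_synteny=["x"])
    assert not res.is_complete
    assert res.classification == "GF"
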