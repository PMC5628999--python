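"""Viral contig selection and complete-genome detection.

A contig is kept as putatively viral when it passes the length gate
(>= 10 kb) and either carries several hallmark virion genes (terminase,
portal protein, tail protein, major capsid protein) or is syntenic with
a reference phage genome.  Complete genomes are recognised by an
identical direct repeat (>= 30 nt) shared between the 5' and 3' termini,
the signature of a circularly permuted phage genome assembled past its
own origin (CGR).  Contigs deemed complete from gene order alone (GF)
require an explicit curator-supplied map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .align import ProteinAlignParams, local_align_protein
from .seqcore import ContigRecord, GeneCall

__all__ = [
    "ScreenDecision",
    "CompletenessResult",
    "screen_contigs",
    "detect_terminal_repeat",
    "screen_report",
    "HALLMARKS",
]

HALLMARKS = frozenset({"terminase", "portal protein", "tail protein", "major capsid protein"})


@dataclass
class ScreenDecision:
    contig_id: str
    passed_length: bool
    hallmark_labels: set[str] = field(default_factory=set)
    synteny_support: Optional[str] = None
    verdict: str = "not_viral"


@dataclass
class CompletenessResult:
    contig_id: str
    is_complete: bool
    repeat_length_nt: int
    trimmed_length_bp: int
    classification: str  # CGR / GF / fragment


def _label_genes(
    genes: Sequence[GeneCall],
    annotations: Optional[Mapping[str, str] | Callable[[str], Optional[str]]],
) -> None:
    """Assign functional labels to gene calls in place.

    ``annotations`` maps an exact protein string to a label, or is a
    callable returning a label (or None) for a protein.
    """
    if annotations is None:
        return
    get = annotations.get if isinstance(annotations, Mapping) else annotations
    for g in genes:
        label = get(g.protein)
        if label:
            g.label = label


def _synteny_support(
    genes: Sequence[GeneCall],
    references: Mapping[str, Sequence[str]],
    min_run: int = 3,
    params: ProteinAlignParams = ProteinAlignParams(),
) -> Optional[str]:
    """Reference genome backed by >= min_run consecutive collinear genes.

    Each gene's best protein hit across all reference genomes is taken;
    a reference supports the contig when at least ``min_run`` consecutive
    genes (by contig order) best-hit that reference with monotonic gene
    indices and a single query strand.
    """
    # keep the ordered subsequence of genes with any reference hit; ORF
    # calling emits overlapping spurious frames which carry no hit and
    # must not break an otherwise collinear run
    best_hits: list[tuple[str, int, str]] = []
    for g in sorted(genes, key=lambda x: x.start):
        best: Optional[tuple[float, str, int]] = None
        for ref_id in sorted(references):
            for idx, prot in enumerate(references[ref_id]):
                hits = local_align_protein(g.protein, prot, params=params)
                if hits and (best is None or hits[0].score > best[0]):
                    best = (hits[0].score, ref_id, idx)
        if best is not None:
            best_hits.append((best[1], best[2], g.strand))

    for start in range(len(best_hits) - min_run + 1):
        window = best_hits[start : start + min_run]
        if len({h[0] for h in window}) != 1 or len({h[2] for h in window}) != 1:
            continue
        idxs = [h[1] for h in window]
        increasing = all(b > a for a, b in zip(idxs, idxs[1:]))
        decreasing = all(b < a for a, b in zip(idxs, idxs[1:]))
        if increasing or decreasing:
            return window[0][0]
    return None


def screen_contigs(
    contigs: Sequence[ContigRecord],
    gene_calls: Mapping[str, Sequence[GeneCall]],
    annotations: Optional[Mapping[str, str] | Callable[[str], Optional[str]]] = None,
    references: Optional[Mapping[str, Sequence[str]]] = None,
    length_min: int = 10_000,
    min_hallmarks: int = 2,
) -> list[ScreenDecision]:
    """One screening decision per contig.

    A contig is ``viral`` when it passes the length gate and either
    carries at least ``min_hallmarks`` distinct hallmark labels or has
    synteny support from a reference genome.  A contig without gene
    calls simply fails (no error).
    """
    decisions = []
    for contig in contigs:
        genes = list(gene_calls.get(contig.contig_id, ()))
        _label_genes(genes, annotations)
        hallmarks = {g.label for g in genes if g.label in HALLMARKS}
        decision = ScreenDecision(
            contig_id=contig.contig_id,
            passed_length=contig.length_bp >= length_min,
            hallmark_labels=hallmarks,
        )
        if decision.passed_length and len(hallmarks) < min_hallmarks and references and genes:
            decision.synteny_support = _synteny_support(genes, references)
        if decision.passed_length and (
            len(hallmarks) >= min_hallmarks or decision.synteny_support is not None
        ):
            decision.verdict = "viral"
        decisions.append(decision)
    return decisions


def detect_terminal_repeat(
    contig: ContigRecord | str,
    min_repeat: int = 30,
    max_repeat: int = 1000,
    complete_by_synteny: Optional[Iterable[str]] = None,
) -> CompletenessResult:
    """Longest exact terminal direct repeat within [min_repeat, max_repeat].

    The repeat must be identical (no mismatches): the prefix of length r
    equals the suffix of length r.  A hit classifies the contig as CGR;
    otherwise the contig is GF when named in ``complete_by_synteny``,
    else a fragment.
    """
    if isinstance(contig, ContigRecord):
        cid, seq = contig.contig_id, contig.sequence
    else:
        cid, seq = "contig", contig
    limit = min(max_repeat, len(seq) // 2)
    repeat = 0
    for r in range(limit, min_repeat - 1, -1):
        if seq[:r] == seq[-r:]:
            repeat = r
            break
    if repeat:
        return CompletenessResult(cid, True, repeat, len(seq) - repeat, "CGR")
    cls = "GF" if complete_by_synteny and cid in set(complete_by_synteny) else "fragment"
    return CompletenessResult(cid, False, 0, len(seq), cls)


def screen_report(
    contigs: Sequence[ContigRecord],
    decisions: Sequence[ScreenDecision],
    completeness: Sequence[CompletenessResult],
    path: str | Path,
) -> None:
    """TSV report of screening verdicts and completeness classes."""
    by_id = {c.contig_id: c for c in contigs}
    comp = {c.contig_id: c for c in completeness}
    with open(path, "w") as fh:
        fh.write("contig_id\tlength_bp\tgc\tverdict\thallmarks\tclass\trepeat_nt\n")
        for d in decisions:
            c = by_id[d.contig_id]
            k = comp.get(d.contig_id)
            fh.write(
                "\t".join(
                    [
                        d.contig_id,
                        str(c.length_bp),
                        f"{c.gc_fraction:.4f}",
                        d.verdict,
                        ",".join(sorted(d.hallmark_labels)) or "-",
                        k.classification if k else "-",
                        str(k.repeat_length_nt) if k else "0",
                    ]
                )
                + "\n"
            )
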