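"""Sequence-based host assignment for viral contigs.

Evidence classes, strongest first:

* **tRNA** — an exact, full-length copy of a host tRNA gene inside the
  contig (phages carry host-derived tRNAs; an exact match pins the
  donor).
* **CRISPR** — a host CRISPR spacer matching the contig with at most
  one substitution (the protospacer record of a past infection).
* **best_hit** — a majority of the contig's genes give their best
  nucleotide hit (>75% identity over >50% of the gene) to the same
  labelled reference phage.
* **AMG** — auxiliary metabolic genes typical of one host group (e.g.
  photosystem genes psbA/psbD for cyanophages); weakest direct
  evidence, off by default for labelling.
* **cluster_neighbor** — label propagated from a labelled co-member of
  the same viral cluster.

tRNA and CRISPR rank equally; a disagreement at the highest populated
rank yields an explicit ``ambiguous`` call rather than a guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .align import AlignParams, SeqHandle, encode_nt, local_align_nt, summarize_pair
from .seqcore import ContigRecord, GeneCall, revcomp

__all__ = [
    "Evidence",
    "HostCall",
    "trna_match",
    "crispr_match",
    "majority_best_hit",
    "amg_flags",
    "combine_evidence",
    "DEFAULT_AMG_TABLE",
]

#: AMG label -> host group it points to
DEFAULT_AMG_TABLE = {
    "psbA": "Cyanobacteria",
    "psbD": "Cyanobacteria",
    "phytanoyl-CoA-dioxygenase": "Cyanobacteria",
    "2OG-Fe(II) oxygenase": "Cyanobacteria",
}

_PRECEDENCE = {"tRNA": 0, "CRISPR": 0, "best_hit": 1, "AMG": 2, "cluster_neighbor": 3}


@dataclass(frozen=True)
class Evidence:
    kind: str  # tRNA / CRISPR / AMG / best_hit / cluster_neighbor
    host_label: str
    detail: str = ""


@dataclass
class HostCall:
    contig_id: str
    host_label: str = "unassigned"
    evidence: list[Evidence] = field(default_factory=list)
    ambiguous: bool = False


def trna_match(
    contig: ContigRecord | str,
    host_trna_db: Sequence[tuple[str, str]],
) -> Optional[Evidence]:
    """Exact full-length host tRNA occurrence on either strand."""
    seq = contig.sequence if isinstance(contig, ContigRecord) else contig
    rc = revcomp(seq)
    for trna, host in host_trna_db:
        if trna in seq:
            return Evidence("tRNA", host, detail=f"exact tRNA match ({len(trna)} nt, + strand)")
        if trna in rc:
            return Evidence("tRNA", host, detail=f"exact tRNA match ({len(trna)} nt, - strand)")
    return None


def _mismatch_scan(contig_enc: np.ndarray, probe_enc: np.ndarray) -> int:
    """Minimum substitution count of the probe over all contig offsets."""
    m = len(probe_enc)
    if len(contig_enc) < m:
        return m
    windows = np.lib.stride_tricks.sliding_window_view(contig_enc, m)
    mism = (windows != probe_enc).sum(axis=1)
    return int(mism.min())


def crispr_match(
    contig: ContigRecord | str,
    spacer_db: Sequence[tuple[str, str]],
    max_mismatch: int = 1,
) -> Optional[Evidence]:
    """Spacer occurrence with <= max_mismatch substitutions, either strand."""
    seq = contig.sequence if isinstance(contig, ContigRecord) else contig
    enc = encode_nt(seq)
    enc_rc = encode_nt(revcomp(seq))
    for spacer, host in spacer_db:
        probe = encode_nt(spacer)
        best = min(_mismatch_scan(enc, probe), _mismatch_scan(enc_rc, probe))
        if best <= max_mismatch:
            return Evidence("CRISPR", host, detail=f"spacer match, {best} mismatch(es)")
    return None


def majority_best_hit(
    contig: ContigRecord,
    gene_calls: Sequence[GeneCall],
    references: Mapping[str, tuple[str, str]],
    identity_min: float = 0.75,
    coverage_min: float = 0.50,
    params: AlignParams = AlignParams(min_hit_score=30),
) -> Optional[Evidence]:
    """Majority-of-genes best nucleotide hit against labelled references.

    ``references`` maps reference genome id to (sequence, host label).
    Per gene, the best-scoring reference hit counts only when it exceeds
    both thresholds (identity strictly > identity_min over strictly >
    coverage_min of the gene).  Evidence requires a strict majority of
    the passing genes to agree on one host label.
    """
    if not gene_calls:
        return None
    handles = {rid: SeqHandle(rid, seq) for rid, (seq, _) in sorted(references.items())}
    votes: dict[str, int] = {}
    passing = 0
    for gene in sorted(gene_calls, key=lambda g: g.start):
        gene_seq = contig.sequence[gene.start : gene.end]
        best: Optional[tuple[float, str, float, float]] = None
        for rid in sorted(handles):
            hits = local_align_nt(gene_seq, handles[rid], params=params)
            if not hits:
                continue
            summary = summarize_pair(hits, len(gene_seq), len(handles[rid]))
            cov = sum(h.q_end - h.q_start for h in hits) / len(gene_seq)
            score = summary.summed_score
            if best is None or score > best[0]:
                best = (score, rid, summary.weighted_identity, min(cov, 1.0))
        if best is None:
            continue
        _, rid, ident, cov = best
        if ident > identity_min and cov > coverage_min:
            passing += 1
            label = references[rid][1]
            votes[label] = votes.get(label, 0) + 1
    if not passing:
        return None
    label, top = max(sorted(votes.items()), key=lambda kv: kv[1])
    if top * 2 > passing:
        return Evidence("best_hit", label, detail=f"{top}/{passing} passing genes agree")
    return None


def amg_flags(
    gene_calls: Sequence[GeneCall],
    amg_table: Mapping[str, str] = DEFAULT_AMG_TABLE,
    enable_host_evidence: bool = False,
) -> tuple[set[str], Optional[Evidence]]:
    """AMG labels present among the gene calls.

    Host-group evidence from AMGs alone (e.g. psbA -> Cyanobacteria) is
    only emitted when explicitly enabled; an AMG is weak evidence on its
    own.
    """
    flags = {g.label for g in gene_calls if g.label in amg_table}
    evidence = None
    if enable_host_evidence and flags:
        hosts = sorted({amg_table[f] for f in flags})
        if len(hosts) == 1:
            evidence = Evidence("AMG", hosts[0], detail=",".join(sorted(flags)))
    return flags, evidence


def combine_evidence(
    evidences: Mapping[str, Sequence[Evidence]],
    vc_partition: Optional[Mapping[str, str]] = None,
) -> dict[str, HostCall]:
    """Resolve per-contig evidence into host calls.

    Precedence: tRNA = CRISPR > best_hit > AMG > cluster_neighbor; a
    label conflict at the decisive precedence level marks the call
    ambiguous.  When a VC partition is given, unlabelled contigs inherit
    the (unique) label of labelled co-members as ``cluster_neighbor``
    evidence.
    """
    calls: dict[str, HostCall] = {}
    for cid in sorted(evidences):
        call = HostCall(contig_id=cid, evidence=sorted(evidences[cid], key=lambda e: (_PRECEDENCE[e.kind], e.kind)))
        for level in range(4):
            level_ev = [e for e in call.evidence if _PRECEDENCE[e.kind] == level]
            if not level_ev:
                continue
            labels = sorted({e.host_label for e in level_ev})
            if len(labels) == 1:
                call.host_label = labels[0]
            else:
                call.ambiguous = True
            break
        calls[cid] = call

    if vc_partition:
        by_vc: dict[str, list[str]] = {}
        for cid, vc in vc_partition.items():
            by_vc.setdefault(vc, []).append(cid)
        for vc, members in sorted(by_vc.items()):
            labels = sorted(
                {calls[c].host_label for c in members if c in calls and calls[c].host_label != "unassigned"}
            )
            if len(labels) != 1:
                continue
            for cid in members:
                if cid in calls and calls[cid].host_label == "unassigned" and not calls[cid].ambiguous:
                    calls[cid].host_label = labels[0]
                    calls[cid].evidence.append(
                        Evidence("cluster_neighbor", labels[0], detail=f"propagated within {vc}")
                    )
    return calls


def host_calls_to_tsv(calls: Mapping[str, HostCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\thost\tambiguous\tevidence\tdetails\n")
        for cid in sorted(calls):
            c = calls[cid]
            kinds = ",".join(e.kind for e in c.evidence) or "-"
            details = ";".join(f"{e.kind}:{e.host_label}({e.detail})" for e in c.evidence) or "-"
            fh.write(f"{cid}\t{c.host_label}\t{int(c.ambiguous)}\t{kinds}\t{details}\n")
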