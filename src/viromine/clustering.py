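"""Viral clusters (VCs) and CD-HIT-style protein clustering.

VCs approximate viral populations: contigs are nodes, an edge joins two
contigs whose pairwise alignment reaches >90% nucleotide identity over
>20% of the shorter sequence, and clusters are the connected components
of that graph (single linkage, the weakest assumption consistent with
pairwise cut-offs).  Protein clustering is greedy and length-ordered:
each protein joins the first cluster whose representative it matches at
>=60% identity over >=80% of the shorter sequence, else founds its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .align import (
    AlignParams,
    ProteinAlignParams,
    SeqHandle,
    local_align_nt,
    local_align_protein,
    summarize_pair,
)
from .seqcore import ContigRecord

__all__ = ["ViralCluster", "ProteinCluster", "build_vcs", "cluster_proteins", "vc_tables"]


@dataclass
class ViralCluster:
    vc_id: str
    member_contig_ids: frozenset[str]
    representative: str

    @property
    def is_singleton(self) -> bool:
        return len(self.member_contig_ids) == 1


@dataclass
class ProteinCluster:
    pc_id: str
    member_ids: list[str]
    representative: str


def pair_edge(
    a: ContigRecord | SeqHandle,
    b: ContigRecord | SeqHandle,
    identity_min: float,
    coverage_min: float,
    params: AlignParams,
) -> bool:
    """Does the contig pair pass the VC thresholds (strict >)?"""
    ha = a if isinstance(a, SeqHandle) else SeqHandle(a.contig_id, a.sequence)
    hb = b if isinstance(b, SeqHandle) else SeqHandle(b.contig_id, b.sequence)
    hits = local_align_nt(ha, hb, params=params)
    if not hits:
        return False
    summary = summarize_pair(hits, len(ha), len(hb))
    return summary.weighted_identity > identity_min and summary.coverage_shorter > coverage_min


def _candidate_pairs(handles: Sequence[SeqHandle], k: int) -> set[tuple[int, int]]:
    """Pairs sharing at least one exact k-mer (either strand)."""
    from collections import defaultdict

    owners: dict[int, set[int]] = defaultdict(set)
    for i, h in enumerate(handles):
        for rc in (False, True):
            codes, _ = h.codes(k, rc=rc)
            for c in set(codes.tolist()):
                owners[c].add(i)
    pairs: set[tuple[int, int]] = set()
    for members in owners.values():
        if len(members) > 1:
            ms = sorted(members)
            for x in range(len(ms)):
                for y in range(x + 1, len(ms)):
                    pairs.add((ms[x], ms[y]))
    return pairs


def build_vcs(
    contigs: Sequence[ContigRecord],
    identity_min: float = 0.90,
    coverage_min: float = 0.20,
    params: AlignParams = AlignParams(),
) -> list[ViralCluster]:
    """Cluster contigs into VCs by connected components of the edge graph.

    Cluster ids are assigned by descending size then representative id,
    so the output is a pure function of the input set regardless of
    input order.  The representative is the longest member (ties broken
    lexicographically).
    """
    if not (0 < identity_min <= 1 and 0 < coverage_min <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    if not contigs:
        return []
    ordered = sorted(contigs, key=lambda c: c.contig_id)
    handles = [SeqHandle(c.contig_id, c.sequence) for c in ordered]
    graph = nx.Graph()
    graph.add_nodes_from(h.seq_id for h in handles)
    for i, j in sorted(_candidate_pairs(handles, params.k)):
        if pair_edge(handles[i], handles[j], identity_min, coverage_min, params):
            graph.add_edge(handles[i].seq_id, handles[j].seq_id)
    lengths = {c.contig_id: c.length_bp for c in ordered}
    clusters = []
    for comp in nx.connected_components(graph):
        rep = max(sorted(comp), key=lambda cid: lengths[cid])
        clusters.append((comp, rep))
    clusters.sort(key=lambda cr: (-len(cr[0]), cr[1]))
    return [
        ViralCluster(vc_id=f"VC{i:04d}", member_contig_ids=frozenset(comp), representative=rep)
        for i, (comp, rep) in enumerate(clusters)
    ]


def cluster_proteins(
    proteins: Mapping[str, str],
    identity_min: float = 0.60,
    shorter_alignment_min: float = 0.80,
    params: ProteinAlignParams = ProteinAlignParams(),
) -> list[ProteinCluster]:
    """Greedy incremental protein clustering (longest first).

    A protein joins the first existing cluster whose representative it
    aligns to at >= identity_min over >= shorter_alignment_min of the
    shorter sequence; otherwise it founds a new cluster.  Determinism
    follows from the length-then-id ordering.
    """
    order = sorted(proteins, key=lambda pid: (-len(proteins[pid]), pid))
    clusters: list[ProteinCluster] = []
    for pid in order:
        seq = proteins[pid]
        placed = False
        for cl in clusters:
            rep = proteins[cl.representative]
            hits = local_align_protein(seq, rep, params=params)
            if not hits:
                continue
            summary = summarize_pair(hits, len(seq), len(rep))
            if (
                summary.weighted_identity >= identity_min
                and summary.coverage_shorter >= shorter_alignment_min
            ):
                cl.member_ids.append(pid)
                placed = True
                break
        if not placed:
            clusters.append(ProteinCluster(pc_id=f"PC{len(clusters):05d}", member_ids=[pid], representative=pid))
    return clusters


def vc_tables(clusters: Sequence[ViralCluster], contigs: Sequence[ContigRecord], outdir: str | Path) -> None:
    """Write contig->VC membership and per-VC summary TSVs."""
    outdir = Path(outdir)
    lengths = {c.contig_id: c.length_bp for c in contigs}
    with open(outdir / "vc_members.tsv", "w") as fh:
        fh.write("contig_id\tvc_id\n")
        for cl in clusters:
            for cid in sorted(cl.member_contig_ids):
                fh.write(f"{cid}\t{cl.vc_id}\n")
    with open(outdir / "vc_summary.tsv", "w") as fh:
        fh.write("vc_id\tsize\trepresentative\ttotal_bp\n")
        for cl in clusters:
            total = sum(lengths[c] for c in cl.member_contig_ids)
            fh.write(f"{cl.vc_id}\t{len(cl.member_contig_ids)}\t{cl.representative}\t{total}\n")
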