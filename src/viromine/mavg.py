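"""Metagenome-Assembled Viral Genomes (MAVGs).

Near-identical (>=99%) contigs of one phage population recur across
samples taken years and depths apart; merging their dovetail overlaps
extends partial assemblies into complete genomes.  This module builds an
overlap graph over screened contigs, lays out each connected component
greedily (seeded at the longest contig, best-supported overlap first),
takes a majority-base consensus and re-tests circularity on the merged
sequence.  Components whose overlaps imply inconsistent placements are
emitted unmerged with a conflict flag rather than forced together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .align import AlignParams, SeqHandle, local_align_nt
from .seqcore import ContigRecord, revcomp
from .viral_screen import detect_terminal_repeat

__all__ = ["MavgRecord", "Placement", "build_mavgs", "place_members"]

_NT = "ACGTN"


@dataclass
class Placement:
    contig_id: str
    sample_id: str
    start: int
    end: int
    strand: str
    identity: float


@dataclass
class MavgRecord:
    mavg_id: str
    member_contig_ids: list[str]
    sample_ids: list[str]
    consensus_sequence: str
    is_circular: bool
    trimmed_length_bp: int
    placements: list[Placement] = field(default_factory=list)
    conflict: bool = False

    @property
    def length_bp(self) -> int:
        return len(self.consensus_sequence)


@dataclass
class _Overlap:
    i: int
    j: int
    orientation: int  # +1 same strand, -1 opposite
    columns: int
    identity: float


def _dovetail(hit, len_q: int, len_s: int, overlap_min: int, identity_min: float, slack: int = 60) -> bool:
    """Is the hit an end-to-end (or containment) overlap?"""
    if hit.columns < overlap_min or hit.identity < identity_min:
        return False
    q_left = hit.q_start <= slack
    q_right = hit.q_end >= len_q - slack
    s_left = hit.s_start <= slack
    s_right = hit.s_end >= len_s - slack
    if hit.strand == "-":
        s_left, s_right = s_right, s_left
    # suffix(query)+prefix(subject), suffix(subject)+prefix(query), or containment
    return (q_right and s_left) or (s_right and q_left) or (q_left and q_right) or (s_left and s_right)


def _best_overlap(
    a: SeqHandle, b: SeqHandle, params: AlignParams, overlap_min: int, identity_min: float
) -> Optional[_Overlap]:
    hits = [
        h
        for h in local_align_nt(a, b, params=params)
        if _dovetail(h, len(a), len(b), overlap_min, identity_min)
    ]
    if not hits:
        return None
    best = max(hits, key=lambda h: (h.columns, h.identity))
    return _Overlap(0, 0, +1 if best.strand == "+" else -1, best.columns, best.identity)


def build_mavgs(
    contigs_by_sample: dict[str, Sequence[ContigRecord]] | Sequence[ContigRecord],
    overlap_min_bp: int = 500,
    identity_min: float = 0.99,
    cross_sample: bool = True,
    params: AlignParams = AlignParams(),
) -> list[MavgRecord]:
    """Merge >=identity_min overlapping contigs into consensus genomes.

    Requires every retained component to have >= 2 members from >= 2
    distinct samples (unless ``cross_sample`` is off).  Consensus bases
    are the per-column majority over the placed members, ties resolved
    in favour of the longest contributing contig.
    """
    if isinstance(contigs_by_sample, dict):
        contigs = [c for sample in sorted(contigs_by_sample) for c in contigs_by_sample[sample]]
    else:
        contigs = list(contigs_by_sample)
    contigs = sorted(contigs, key=lambda c: c.contig_id)
    handles = [SeqHandle(c.contig_id, c.sequence) for c in contigs]
    n = len(contigs)

    overlaps: list[_Overlap] = []
    for i in range(n):
        for j in range(i + 1, n):
            ov = _best_overlap(handles[i], handles[j], params, overlap_min_bp, identity_min)
            if ov is not None:
                ov.i, ov.j = i, j
                overlaps.append(ov)

    # connected components over overlap edges
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ov in overlaps:
        ri, rj = find(ov.i), find(ov.j)
        if ri != rj:
            parent[ri] = rj

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)

    records = []
    for root in sorted(comps, key=lambda r: min(contigs[i].contig_id for i in comps[r])):
        members = comps[root]
        if len(members) < 2:
            continue
        comp_edges = [ov for ov in overlaps if ov.i in members and ov.j in members]
        rec = _merge_component(contigs, handles, members, comp_edges, params, overlap_min_bp, identity_min)
        if rec is None:
            continue
        if cross_sample and len(set(rec.sample_ids)) < 2 and not rec.conflict:
            continue
        records.append(rec)
    records.sort(key=lambda r: (-len(r.consensus_sequence), r.member_contig_ids[0]))
    for i, rec in enumerate(records):
        rec.mavg_id = f"MAVG{i + 1}"
    return records


def _merge_component(
    contigs, handles, members, edges, params, overlap_min_bp, identity_min
) -> Optional[MavgRecord]:
    # orient members by BFS over edges, strongest overlap first
    edges = sorted(edges, key=lambda e: (-e.columns, contigs[e.i].contig_id, contigs[e.j].contig_id))
    seed = max(members, key=lambda i: (len(contigs[i].sequence), contigs[i].contig_id))
    ori: dict[int, int] = {seed: +1}
    conflict = False
    changed = True
    while changed:
        changed = False
        for e in edges:
            if e.i in ori and e.j not in ori:
                ori[e.j] = ori[e.i] * e.orientation
                changed = True
            elif e.j in ori and e.i not in ori:
                ori[e.i] = ori[e.j] * e.orientation
                changed = True
            elif e.i in ori and e.j in ori and ori[e.j] != ori[e.i] * e.orientation:
                conflict = True

    oriented: dict[int, SeqHandle] = {}
    for i in members:
        seq = contigs[i].sequence if ori[i] == +1 else revcomp(contigs[i].sequence)
        oriented[i] = SeqHandle(contigs[i].contig_id, seq)

    # offsets from plus-strand overlaps between oriented members
    offset: dict[int, int] = {seed: 0}
    placed = [seed]
    pending = set(members) - {seed}
    while pending:
        best: Optional[tuple[int, int, int, float]] = None  # columns, anchor, cand, diag
        for anchor in placed:
            for cand in sorted(pending):
                hits = [
                    h
                    for h in local_align_nt(oriented[anchor], oriented[cand], params=params)
                    if h.strand == "+"
                    and _dovetail(h, len(oriented[anchor]), len(oriented[cand]), overlap_min_bp, identity_min)
                ]
                if not hits:
                    continue
                top = max(hits, key=lambda h: (h.columns, h.identity))
                diag = top.q_start - top.s_start
                if best is None or top.columns > best[0]:
                    best = (top.columns, anchor, cand, diag)
        if best is None:
            conflict = True
            break
        _, anchor, cand, diag = best
        offset[cand] = offset[anchor] + diag
        placed.append(cand)
        pending.discard(cand)

    sample_ids = sorted({contigs[i].sample_id for i in members})
    member_ids = sorted(contigs[i].contig_id for i in members)
    if conflict:
        return MavgRecord("", member_ids, sample_ids, "", False, 0, conflict=True)

    # consistency audit: every dovetail edge must agree with the layout.
    # A fragment set tiling a full circle closes with one edge whose
    # implied offset differs from the layout by the genome length; that
    # discrepancy is circularity evidence, not a conflict.
    span = max(offset[i] + len(oriented[i]) for i in offset) - min(offset.values())
    discrepancies: list[int] = []
    for e in edges:
        if e.i in offset and e.j in offset:
            hits = [
                h
                for h in local_align_nt(oriented[e.i], oriented[e.j], params=params)
                if h.strand == "+" and h.columns >= overlap_min_bp and h.identity >= identity_min
            ]
            if hits:
                top = max(hits, key=lambda h: (h.columns, h.identity))
                implied = offset[e.i] + (top.q_start - top.s_start)
                delta = implied - offset[e.j]
                if abs(delta) > 100:
                    discrepancies.append(delta)
    wrap_period = 0
    if discrepancies:
        first = discrepancies[0]
        closure = all(abs(x - first) <= 150 for x in discrepancies) and abs(first) >= 0.5 * span
        if closure:
            wrap_period = abs(first)
        else:
            return MavgRecord("", member_ids, sample_ids, "", False, 0, conflict=True)

    consensus, placements = _consensus(contigs, oriented, ori, offset)
    comp = detect_terminal_repeat(consensus, min_repeat=30)
    is_circular = comp.is_complete
    trimmed = comp.trimmed_length_bp
    if not is_circular:
        wrap = _wrap_overlap(consensus, params, identity_min)
        if wrap:
            is_circular = True
            trimmed = len(consensus) - wrap
    if not is_circular and wrap_period:
        is_circular = True
        trimmed = wrap_period
    return MavgRecord("", member_ids, sample_ids, consensus, is_circular, trimmed, placements)


def _consensus(contigs, oriented, ori, offset):
    lo = min(offset[i] for i in offset)
    hi = max(offset[i] + len(oriented[i]) for i in offset)
    span = hi - lo
    counts = np.zeros((span, 4), dtype=np.int32)
    for i in offset:
        enc = oriented[i].enc
        o = offset[i] - lo
        real = enc < 4
        idx = np.nonzero(real)[0]
        counts[o + idx, enc[idx]] += 1
    total = counts.sum(axis=1)
    best = counts.argmax(axis=1)
    top = counts[np.arange(span), best]
    # tie columns: top count shared by another base
    tied = (counts == top[:, None]).sum(axis=1) > 1
    cons = best.astype(np.int8)
    cons[total == 0] = 4
    if tied.any():
        by_len = sorted(offset, key=lambda i: (-len(oriented[i]), oriented[i].seq_id))
        for col in np.nonzero(tied & (total > 0))[0].tolist():
            for i in by_len:
                o = offset[i] - lo
                if 0 <= col - o < len(oriented[i]) and oriented[i].enc[col - o] < 4:
                    if counts[col, oriented[i].enc[col - o]] == top[col]:
                        cons[col] = oriented[i].enc[col - o]
                        break
    consensus = "".join(_NT[b] for b in cons.tolist())
    placements = []
    for i in sorted(offset, key=lambda i: offset[i]):
        enc = oriented[i].enc
        o = offset[i] - lo
        seg = cons[o : o + len(enc)]
        ident = float(((seg == enc) & (enc < 4)).sum() / max(len(enc), 1))
        placements.append(
            Placement(
                contig_id=oriented[i].seq_id,
                sample_id=contigs[i].sample_id,
                start=o,
                end=o + len(enc),
                strand="+" if ori[i] == 1 else "-",
                identity=ident,
            )
        )
    return consensus, placements


def _wrap_overlap(consensus: str, params: AlignParams, identity_min: float, window: int = 5000, min_len: int = 30) -> int:
    """Length of a mismatch-tolerant dovetail between the consensus ends.

    The merged copies at the two ends of a circular reconstruction carry
    independent copy mutations, so the terminal repeat need not be exact;
    a high-identity suffix-prefix alignment still reveals circularity.
    Returns the overlap length in columns (0 when none).
    """
    w = min(window, len(consensus) // 2)
    if w < min_len:
        return 0
    suffix = consensus[-w:]
    prefix = consensus[:w]
    slack = 40
    best = 0
    for h in local_align_nt(suffix, prefix, params=params):
        if h.strand != "+" or h.identity < identity_min or h.columns < min_len:
            continue
        if h.q_end >= w - slack and h.s_start <= slack:
            best = max(best, h.columns)
    return best


def place_members(mavg: MavgRecord) -> list[Placement]:
    """Machine-readable member placements of a built MAVG."""
    return list(mavg.placements)


def placements_to_tsv(records: Sequence[MavgRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mavg_id\tcontig_id\tsample\tstart\tend\tstrand\tidentity\tcircular\tconflict\n")
        for rec in records:
            for p in rec.placements:
                fh.write(
                    f"{rec.mavg_id}\t{p.contig_id}\t{p.sample_id}\t{p.start}\t{p.end}\t"
                    f"{p.strand}\t{p.identity:.5f}\t{int(rec.is_circular)}\t{int(rec.conflict)}\n"
                )
            if rec.conflict:
                for cid in rec.member_contig_ids:
                    fh.write(f"{rec.mavg_id}\t{cid}\t-\t0\t0\t.\t0\t0\t1\n")
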