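"""Seed-and-extend alignment engine used by every comparison stage.

The engine finds exact k-mer seed matches between two sequences (both
strands for DNA), groups them by diagonal, and extends each seeded
diagonal into maximal scoring gap-free segments (Kadane-style maximal
subarray extraction).  Collinear segments on nearby diagonals are then
chained with affine gap costs.  Because the synthetic mutation model of
this package is substitution-only, the gap-free extension is exact: on
such data the best hit equals the full Smith-Waterman optimum, which is
asserted against an independent dynamic-programming oracle in the test
suite.

Identity is defined everywhere as matches / alignment columns, with gap
columns counting as non-matches.  ``N`` never matches anything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .seqcore import revcomp, translate

__all__ = [
    "AlignParams",
    "AlignmentHit",
    "PairwiseSummary",
    "SnpCall",
    "local_align_nt",
    "local_align_protein",
    "summarize_pair",
    "translated_score",
    "map_reads",
    "call_snps",
    "hits_to_tsv",
    "six_frame_translate",
]

# ---------------------------------------------------------------------------
# Parameters and result types


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for nucleotide seed-and-extend alignment.

    Defaults approximate megablast-like behaviour: +1/-2 match/mismatch,
    affine gaps -5 to open and -2 per position, 15-mer exact seeds.
    ``band`` bounds the diagonal shift bridged when chaining collinear
    segments (the only place gap penalties act on substitution-only data).
    """

    k: int = 15
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    min_hit_score: int = 40
    band: int = 16

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("seed length k must be >= 8")


@dataclass
class AlignmentHit:
    """One local alignment segment between a query and a subject.

    Coordinates are 0-based half-open; ``q_*`` are on the query forward
    strand, ``s_*`` on the subject forward strand, with ``strand`` giving
    the subject orientation.  ``columns`` includes gap columns.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    matches: int
    columns: int
    score: float
    #: gap-free constituent segments as (q_start, q_end, diag) on the
    #: strand-adjusted subject; used for SNP extraction
    segments: list[tuple[int, int, int]] = field(default_factory=list, repr=False)

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else math.nan


@dataclass
class PairwiseSummary:
    """Aggregate of all retained hits between one ordered sequence pair."""

    query_id: str
    subject_id: str
    weighted_identity: float
    coverage_shorter: float
    summed_score: float
    n_hits: int


@dataclass(frozen=True)
class SnpCall:
    reference_id: str
    position: int
    ref_base: str
    alt_base: str
    query_id: str


# ---------------------------------------------------------------------------
# Encoding helpers

_NT_LOOKUP = np.full(256, 4, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _NT_LOOKUP[ord(b)] = i

_AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_LOOKUP = np.full(256, _AA_ALPHABET.index("X"), dtype=np.int8)
for i, a in enumerate(_AA_ALPHABET):
    _AA_LOOKUP[ord(a)] = i

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_AA_SCORE = np.zeros((24, 24), dtype=np.int16)
for i, a in enumerate(_AA_ALPHABET):
    for j, b in enumerate(_AA_ALPHABET):
        _AA_SCORE[i, j] = int(_BLOSUM62[a, b])


def encode_nt(seq: str) -> np.ndarray:
    return _NT_LOOKUP[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_aa(seq: str) -> np.ndarray:
    return _AA_LOOKUP[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_codes(enc: np.ndarray, k: int, alphabet_size: int, invalid: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-windows and the positions of valid ones."""
    n = len(enc)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(enc, k)
    powers = alphabet_size ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = win.astype(np.int64) @ powers
    bad = np.zeros(len(win), dtype=bool)
    for sym in invalid:
        bad |= (win == sym).any(axis=1)
    pos = np.nonzero(~bad)[0]
    return codes[pos], pos


def nt_kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    return _window_codes(enc, k, 4, invalid=(4,))


def aa_kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    # exclude words containing stop or unknown residues
    return _window_codes(enc, k, 24, invalid=(_AA_ALPHABET.index("*"), _AA_ALPHABET.index("X")))


class KmerIndex:
    """Sorted-array index of k-mer codes for fast vectorised lookup."""

    def __init__(self, codes: np.ndarray, positions: np.ndarray):
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.positions = positions[order]

    def lookup(self, query_codes: np.ndarray, query_positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All (query_pos, index_pos) seed matches."""
        if len(query_codes) == 0 or len(self.codes) == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e
        lo = np.searchsorted(self.codes, query_codes, side="left")
        hi = np.searchsorted(self.codes, query_codes, side="right")
        counts = hi - lo
        nz = counts > 0
        if not nz.any():
            e = np.empty(0, dtype=np.int64)
            return e, e
        c = counts[nz]
        starts = lo[nz]
        ends = np.cumsum(c)
        total = int(ends[-1])
        ar = np.arange(total, dtype=np.int64)
        gather = ar - np.repeat(ends - c, c) + np.repeat(starts, c)
        return np.repeat(query_positions[nz], c), self.positions[gather]


# ---------------------------------------------------------------------------
# Maximal scoring segments on one diagonal


def max_scoring_segments(scores: np.ndarray, min_score: float) -> list[tuple[int, int, float]]:
    """Non-overlapping maximal scoring subarrays with score >= min_score.

    Returns (start, end, score) triples, found by repeated best-subarray
    extraction (best segment first, then recursion on both flanks).
    """
    out: list[tuple[int, int, float]] = []
    prefix = np.concatenate(([0.0], np.cumsum(scores, dtype=np.float64)))

    def recurse(lo: int, hi: int) -> None:
        if hi - lo <= 0:
            return
        p = prefix[lo : hi + 1]
        run_min = np.minimum.accumulate(p[:-1])
        gains = p[1:] - run_min
        e_rel = int(np.argmax(gains))
        best = float(gains[e_rel])
        if best < min_score:
            return
        b_rel = int(np.argmin(p[: e_rel + 1]))
        out.append((lo + b_rel, lo + e_rel + 1, best))
        recurse(lo, lo + b_rel)
        recurse(lo + e_rel + 1, hi)

    recurse(0, len(scores))
    out.sort()
    return out


@dataclass
class _Segment:
    diag: int
    q_start: int
    q_end: int
    matches: int
    score: float

    @property
    def s_start(self) -> int:
        return self.q_start - self.diag

    @property
    def s_end(self) -> int:
        return self.q_end - self.diag


def _diagonal_segments(
    qenc: np.ndarray,
    senc: np.ndarray,
    diagonals: np.ndarray,
    params: AlignParams,
) -> list[_Segment]:
    lq, ls = len(qenc), len(senc)
    segs: list[_Segment] = []
    for d in diagonals.tolist():
        q0 = max(0, d)
        q1 = min(lq, ls + d)
        if q1 - q0 < params.k:
            continue
        qs = qenc[q0:q1]
        ss = senc[q0 - d : q1 - d]
        match = (qs == ss) & (qs != 4) & (ss != 4)
        scores = np.where(match, float(params.match), float(params.mismatch))
        for b, e, sc in max_scoring_segments(scores, params.min_hit_score):
            segs.append(
                _Segment(
                    diag=d,
                    q_start=q0 + b,
                    q_end=q0 + e,
                    matches=int(match[b:e].sum()),
                    score=sc,
                )
            )
    return segs


def _chain_segments(segs: list[_Segment], params: AlignParams) -> list[list[_Segment]]:
    """Greedily chain collinear segments across nearby diagonals.

    Two segments chain when the later one starts after the earlier one on
    both sequences, the diagonal shift is within ``band`` and the affine
    gap penalty plus bridged-mismatch cost still improves on either
    segment alone.  Chains are returned as ordered segment lists.
    """
    segs = sorted(segs, key=lambda s: (s.q_start, s.q_end))
    chains: list[list[_Segment]] = []
    for seg in segs:
        attached = False
        for chain in chains:
            last = chain[-1]
            q_gap = seg.q_start - last.q_end
            s_gap = seg.s_start - last.s_end
            if q_gap < 0 or s_gap < 0:
                continue
            shift = abs(seg.diag - last.diag)
            if shift == 0 or shift > params.band:
                continue
            bridge = min(q_gap, s_gap)
            penalty = params.gap_open + params.gap_extend * shift + params.mismatch * bridge
            if seg.score + penalty > 0:
                chain.append(seg)
                attached = True
                break
        if not attached:
            chains.append([seg])
    return chains


def _hits_from_chains(
    chains: list[list[_Segment]],
    params: AlignParams,
    query_id: str,
    subject_id: str,
    strand: str,
    subject_len: int,
) -> list[AlignmentHit]:
    hits = []
    for chain in chains:
        q_start = chain[0].q_start
        q_end = chain[-1].q_end
        s_start = chain[0].s_start
        s_end = chain[-1].s_end
        matches = sum(s.matches for s in chain)
        score = sum(s.score for s in chain)
        columns = 0
        for i, seg in enumerate(chain):
            columns += seg.q_end - seg.q_start
            if i:
                prev = chain[i - 1]
                q_gap = seg.q_start - prev.q_end
                s_gap = seg.s_start - prev.s_end
                shift = abs(seg.diag - prev.diag)
                columns += max(q_gap, s_gap)
                score += params.gap_open + params.gap_extend * shift + params.mismatch * min(q_gap, s_gap)
        if score < params.min_hit_score:
            continue
        if strand == "+":
            sf_start, sf_end = s_start, s_end
        else:
            sf_start, sf_end = subject_len - s_end, subject_len - s_start
        hits.append(
            AlignmentHit(
                query_id=query_id,
                subject_id=subject_id,
                q_start=q_start,
                q_end=q_end,
                s_start=sf_start,
                s_end=sf_end,
                strand=strand,
                matches=matches,
                columns=columns,
                score=score,
                segments=[(s.q_start, s.q_end, s.diag) for s in chain],
            )
        )
    return hits


# ---------------------------------------------------------------------------
# Nucleotide alignment


class SeqHandle:
    """Pre-encoded sequence with cached k-mer machinery.

    Passing handles instead of strings lets all-vs-all stages reuse the
    encoding and index work across pairs.
    """

    def __init__(self, seq_id: str, sequence: str):
        self.seq_id = seq_id
        self.sequence = sequence
        self.enc = encode_nt(sequence)
        self._rc_enc: Optional[np.ndarray] = None
        self._codes: dict[tuple[int, bool], tuple[np.ndarray, np.ndarray]] = {}
        self._index: dict[int, KmerIndex] = {}

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def rc_enc(self) -> np.ndarray:
        if self._rc_enc is None:
            rc = self.enc[::-1].copy()
            real = rc < 4
            rc[real] = 3 - rc[real]
            self._rc_enc = rc
        return self._rc_enc

    def codes(self, k: int, rc: bool = False) -> tuple[np.ndarray, np.ndarray]:
        key = (k, rc)
        if key not in self._codes:
            enc = self.rc_enc if rc else self.enc
            self._codes[key] = nt_kmer_codes(enc, k)
        return self._codes[key]

    def index(self, k: int) -> KmerIndex:
        if k not in self._index:
            self._index[k] = KmerIndex(*self.codes(k))
        return self._index[k]


def _as_handle(seq: str | SeqHandle, seq_id: str) -> SeqHandle:
    if isinstance(seq, SeqHandle):
        return seq
    return SeqHandle(seq_id, seq)


def local_align_nt(
    query: str | SeqHandle,
    subject: str | SeqHandle,
    params: AlignParams = AlignParams(),
    query_id: str = "query",
    subject_id: str = "subject",
) -> list[AlignmentHit]:
    """Local nucleotide alignment of query against both subject strands."""
    q = _as_handle(query, query_id)
    s = _as_handle(subject, subject_id)
    sindex = s.index(params.k)
    hits: list[AlignmentHit] = []
    for strand, rc in (("+", False), ("-", True)):
        qcodes, qpos = q.codes(params.k, rc=rc)
        qp, sp = sindex.lookup(qcodes, qpos)
        if len(qp) == 0:
            continue
        # q positions are on the reverse complement of the query for "-";
        # align rc(query) against forward subject and convert afterwards
        diagonals = np.unique(qp - sp)
        qenc = q.rc_enc if rc else q.enc
        segs = _diagonal_segments(qenc, s.enc, diagonals, params)
        chains = _chain_segments(segs, params)
        strand_hits = _hits_from_chains(chains, params, q.seq_id, s.seq_id, strand, len(s))
        if rc:
            # coordinates computed on rc(query): flip back to query forward;
            # the strand label stays on the subject
            n = len(q)
            for h in strand_hits:
                h.q_start, h.q_end = n - h.q_end, n - h.q_start
                # subject coordinates were computed against the forward
                # subject already; s_start/s_end were flipped assuming the
                # subject was reversed, undo that
                h.s_start, h.s_end = len(s) - h.s_end, len(s) - h.s_start
        hits.extend(strand_hits)
    hits.sort(key=lambda h: (-h.score, h.q_start, h.s_start, h.strand))
    return hits


def summarize_pair(
    hits: Sequence[AlignmentHit],
    len_q: int,
    len_s: int,
    query_id: str = "query",
    subject_id: str = "subject",
) -> PairwiseSummary:
    """Aggregate identity / shorter-sequence coverage / summed score.

    Coverage is measured on the shorter sequence of the pair as the exact
    union of its aligned intervals.
    """
    if hits:
        query_id, subject_id = hits[0].query_id, hits[0].subject_id
    if not hits:
        return PairwiseSummary(query_id, subject_id, math.nan, 0.0, 0.0, 0)
    total_matches = sum(h.matches for h in hits)
    total_columns = sum(h.columns for h in hits)
    if len_q <= len_s:
        intervals = [(h.q_start, h.q_end) for h in hits]
        shorter = len_q
    else:
        intervals = [(h.s_start, h.s_end) for h in hits]
        shorter = len_s
    covered = _interval_union_length(intervals)
    return PairwiseSummary(
        query_id,
        subject_id,
        weighted_identity=total_matches / total_columns,
        coverage_shorter=covered / shorter if shorter else 0.0,
        summed_score=float(sum(h.score for h in hits)),
        n_hits=len(hits),
    )


def _interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    merged = 0
    last_end = None
    for start, end in sorted(intervals):
        if last_end is None or start > last_end:
            merged += end - start
            last_end = end
        elif end > last_end:
            merged += end - last_end
            last_end = end
    return merged


# ---------------------------------------------------------------------------
# Protein alignment and translated genome scoring


@dataclass(frozen=True)
class ProteinAlignParams:
    word: int = 4
    min_hsp_score: int = 30
    gap_open: int = -11
    gap_extend: int = -1
    band: int = 12


def local_align_protein(
    query: str,
    subject: str,
    params: ProteinAlignParams = ProteinAlignParams(),
    query_id: str = "query",
    subject_id: str = "subject",
) -> list[AlignmentHit]:
    """BLOSUM62 seed-and-extend local alignment of two protein sequences."""
    qenc = encode_aa(query)
    senc = encode_aa(subject)
    qcodes, qpos = aa_kmer_codes(qenc, params.word)
    index = KmerIndex(*aa_kmer_codes(senc, params.word))
    qp, sp = index.lookup(qcodes, qpos)
    if len(qp) == 0:
        return []
    diagonals = np.unique(qp - sp)
    segs = _protein_diagonal_segments(qenc, senc, diagonals, params)
    hits = []
    for seg in segs:
        hits.append(
            AlignmentHit(
                query_id=query_id,
                subject_id=subject_id,
                q_start=seg.q_start,
                q_end=seg.q_end,
                s_start=seg.s_start,
                s_end=seg.s_end,
                strand="+",
                matches=seg.matches,
                columns=seg.q_end - seg.q_start,
                score=seg.score,
                segments=[(seg.q_start, seg.q_end, seg.diag)],
            )
        )
    hits.sort(key=lambda h: (-h.score, h.q_start, h.s_start))
    return hits


def _protein_diagonal_segments(
    qenc: np.ndarray,
    senc: np.ndarray,
    diagonals: np.ndarray,
    params: ProteinAlignParams,
) -> list[_Segment]:
    lq, ls = len(qenc), len(senc)
    segs: list[_Segment] = []
    for d in diagonals.tolist():
        q0 = max(0, d)
        q1 = min(lq, ls + d)
        if q1 - q0 < params.word:
            continue
        qs = qenc[q0:q1]
        ss = senc[q0 - d : q1 - d]
        scores = _AA_SCORE[qs, ss].astype(np.float64)
        ident = qs == ss
        for b, e, sc in max_scoring_segments(scores, params.min_hsp_score):
            segs.append(
                _Segment(
                    diag=d,
                    q_start=q0 + b,
                    q_end=q0 + e,
                    matches=int(ident[b:e].sum()),
                    score=sc,
                )
            )
    return segs


def six_frame_translate(sequence: str) -> list[tuple[str, str]]:
    """All six conceptual translations as (frame_label, protein) pairs.

    Frame labels are ``+0 +1 +2 -0 -1 -2``; stops are kept as ``*``.
    """
    frames = []
    rc = revcomp(sequence)
    for i in range(3):
        frames.append((f"+{i}", translate(sequence[i:])))
    for i in range(3):
        frames.append((f"-{i}", translate(rc[i:])))
    return frames


def translated_score(
    genome_a: str,
    genome_b: str,
    word: int = 5,
    min_hsp_score: int = 50,
) -> float:
    """Summed translated-alignment score between two genomes.

    Both genomes are translated in six frames; every frame pair is
    searched with exact protein ``word``-mer seeds extended under
    BLOSUM62, HSPs below ``min_hsp_score`` are dropped and mutually
    overlapping HSPs within a frame pair are removed greedily (higher
    score kept) before summation.  This is the quantity the Dice
    coefficient of the genome taxonomy stage is built from.
    """
    if min(len(genome_a), len(genome_b)) < 3 * word:
        return 0.0
    params = ProteinAlignParams(word=word, min_hsp_score=min_hsp_score)
    frames_a = six_frame_translate(genome_a)
    frames_b = six_frame_translate(genome_b)
    enc_b: list[tuple[str, np.ndarray, KmerIndex]] = []
    for label, prot in frames_b:
        enc = encode_aa(prot)
        enc_b.append((label, enc, KmerIndex(*aa_kmer_codes(enc, word))))
    total = 0.0
    for label_a, prot_a in frames_a:
        enc_a = encode_aa(prot_a)
        codes_a, pos_a = aa_kmer_codes(enc_a, word)
        for label_b, enc, index in enc_b:
            qp, sp = index.lookup(codes_a, pos_a)
            if len(qp) == 0:
                continue
            diagonals = np.unique(qp - sp)
            segs = _protein_diagonal_segments(enc_a, enc, diagonals, params)
            total += _greedy_hsp_sum(segs)
    return total


def _greedy_hsp_sum(segs: list[_Segment]) -> float:
    """Sum segment scores after greedy removal of mutually overlapping ones."""
    kept: list[_Segment] = []
    for seg in sorted(segs, key=lambda s: (-s.score, s.q_start, s.diag)):
        clash = any(
            seg.q_start < other.q_end
            and other.q_start < seg.q_end
            and seg.s_start < other.s_end
            and other.s_start < seg.s_end
            for other in kept
        )
        if not clash:
            kept.append(seg)
    return float(sum(s.score for s in kept))


# ---------------------------------------------------------------------------
# Read recruitment


class GenomeIndex:
    """Joint k-mer index over a set of genomes for read mapping."""

    def __init__(self, genomes: dict[str, str], k: int = 15):
        if not genomes:
            raise ValueError("empty genome set")
        self.k = k
        self.ids = sorted(genomes)
        self.encs = {g: encode_nt(genomes[g]) for g in self.ids}
        self.lengths = {g: len(genomes[g]) for g in self.ids}
        parts = []
        offsets = []
        pos = 0
        spacer = np.full(k, 4, dtype=np.int8)
        for g in self.ids:
            offsets.append(pos)
            parts.append(self.encs[g])
            pos += len(self.encs[g])
            parts.append(spacer)
            pos += k
        cat = np.concatenate(parts)
        self.offsets = np.array(offsets, dtype=np.int64)
        codes, positions = nt_kmer_codes(cat, k)
        self.index = KmerIndex(codes, positions)

    def genome_of(self, cat_positions: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.offsets, cat_positions, side="right") - 1


def _best_window_qualifies(
    match: np.ndarray, read_len: int, identity_threshold: float, min_read_coverage: float
) -> bool:
    """Does any window covering >= min_read_coverage of the read reach
    the identity threshold?"""
    min_w = int(math.ceil(min_read_coverage * read_len - 1e-9))
    csum = np.concatenate(([0], np.cumsum(match)))
    n = len(match)
    for w in range(n, min_w - 1, -1):
        window_matches = csum[w:] - csum[:-w]
        if len(window_matches) and window_matches.max() >= identity_threshold * w - 1e-9:
            return True
    return False


def map_reads(
    reads: dict[str, str] | Sequence[tuple[str, str]],
    genomes: dict[str, str] | GenomeIndex,
    identity_threshold: float = 0.95,
    min_read_coverage: float = 0.9,
    k: int = 15,
    match: int = 1,
    mismatch: int = -2,
) -> dict[str, int]:
    """Best-hit read counting against a genome set.

    Each read is assigned to its single best-scoring genome (ties broken
    by lexicographic genome id) and counted when some alignment window
    covering at least ``min_read_coverage`` of the read reaches
    ``identity_threshold``.  The per-genome counts therefore never exceed
    the number of reads.
    """
    gindex = genomes if isinstance(genomes, GenomeIndex) else GenomeIndex(genomes, k=k)
    k = gindex.k
    counts = {g: 0 for g in gindex.ids}
    items = reads.items() if isinstance(reads, dict) else reads
    for read_id, seq in items:
        enc_f = encode_nt(seq)
        enc_r = enc_f[::-1].copy()
        real = enc_r < 4
        enc_r[real] = 3 - enc_r[real]
        best: Optional[tuple[float, str, np.ndarray]] = None
        for enc in (enc_f, enc_r):
            codes, qpos = nt_kmer_codes(enc, k)
            qp, cp = gindex.index.lookup(codes, qpos)
            if len(qp) == 0:
                continue
            gidx = gindex.genome_of(cp)
            spos = cp - gindex.offsets[gidx]
            for gi in np.unique(gidx):
                g = gindex.ids[int(gi)]
                mask = gidx == gi
                genc = gindex.encs[g]
                for d in np.unique(qp[mask] - spos[mask]).tolist():
                    q0 = max(0, d)
                    q1 = min(len(enc), len(genc) + d)
                    if q1 - q0 < k:
                        continue
                    qs = enc[q0:q1]
                    ss = genc[q0 - d : q1 - d]
                    m = (qs == ss) & (qs != 4) & (ss != 4)
                    score = float(np.where(m, match, mismatch).sum())
                    # local optimum on the diagonal
                    scores = np.where(m, float(match), float(mismatch))
                    segs = max_scoring_segments(scores, 1.0)
                    score = max((s[2] for s in segs), default=score)
                    full = np.zeros(len(enc), dtype=bool)
                    full[q0:q1] = m
                    cand = (score, g, full)
                    if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                        best = cand
        if best is None:
            continue
        _, g, full_match = best
        if _best_window_qualifies(full_match, len(seq), identity_threshold, min_read_coverage):
            counts[g] += 1
    return counts


# ---------------------------------------------------------------------------
# SNP listing

_NT = "ACGTN"


def call_snps(
    ref_genome: str | SeqHandle,
    query_genome: str | SeqHandle,
    params: AlignParams = AlignParams(),
    reference_id: str = "reference",
    query_id: str = "query",
) -> list[SnpCall]:
    """Substitution columns between two alignable genomes.

    The query is aligned to the reference; substitution columns inside
    plus-strand aligned blocks are reported on reference coordinates.
    Raises when the pair does not align over at least half of the shorter
    sequence.
    """
    ref = _as_handle(ref_genome, reference_id)
    qry = _as_handle(query_genome, query_id)
    hits = local_align_nt(qry, ref, params=params)
    summary = summarize_pair(hits, len(qry), len(ref))
    if summary.coverage_shorter < 0.5:
        raise ValueError(
            f"pair {qry.seq_id}/{ref.seq_id} not alignable: "
            f"coverage {summary.coverage_shorter:.3f} < 0.5"
        )
    snps: dict[int, SnpCall] = {}
    for hit in sorted(hits, key=lambda h: -h.score):
        if hit.strand != "+":
            continue
        for q0, q1, d in hit.segments:
            qs = qry.enc[q0:q1]
            ss = ref.enc[q0 - d : q1 - d]
            mism = np.nonzero((qs != ss) & (qs < 4) & (ss < 4))[0]
            for off in mism.tolist():
                pos = q0 - d + off
                if pos not in snps:
                    snps[pos] = SnpCall(
                        reference_id=ref.seq_id,
                        position=pos,
                        ref_base=_NT[ss[off]],
                        alt_base=_NT[qs[off]],
                        query_id=qry.seq_id,
                    )
    return [snps[p] for p in sorted(snps)]


def hits_to_tsv(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Export hits as BLAST outfmt-6-style TSV (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("qseqid\tsseqid\tpident\tlength\tqstart\tqend\tsstart\tsend\tscore\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{100 * h.identity:.2f}\t{h.columns}\t"
                f"{h.q_start + 1}\t{h.q_end}\t{h.s_start + 1}\t{h.s_end}\t{h.score:g}\n"
            )
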