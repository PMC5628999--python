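"""Synthetic viral communities with planted truth.

Every downstream stage of the pipeline is exercised on communities built
here: circular dsDNA phage genomes (30-200 kb, GC 18-55% by default),
depth- and station-structured abundances, per-sample contig sets with
>=99%-identical cross-sample genome copies and exact terminal repeats,
and reads at controlled per-base identity.  All outputs are
deterministic functions of the community specification and its seed.

The mutation model is substitution-only: planted divergence and read
error plant an exact number of substitutions, ``round(L * (1 -
identity))``, at uniform positions, so each copy's identity to its
source is controlled exactly rather than on average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .seqcore import ContigRecord, revcomp, translate

__all__ = [
    "SampleSpec",
    "DistributionTag",
    "CommunitySpec",
    "PlantedTruth",
    "CommunityData",
    "generate_genomes",
    "shred_to_contigs",
    "simulate_reads",
    "generate_community",
    "FragmentPlan",
    "CompletePlan",
]

HALLMARK_LABELS = ("terminase", "portal protein", "tail protein", "major capsid protein")
HOST_POOL = ("Cyanobacteria", "SAR11", "SAR116", "Actinomarina", "Euryarchaeota")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: codons free of in-frame stops, used to build planted gene cassettes
_SAFE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass(frozen=True)
class SampleSpec:
    """One sequenced sample: station, depth, filter fraction and size.

    ``reads_gb`` is the metagenome size in gigabases; the number of reads
    simulated for the sample is ``round(reads_gb * 1e9 / read_length)``.
    """

    sample_id: str
    depth_m: float
    station_id: str
    fraction: str = "free-living"
    reads_gb: float = 2e-4
    region: str = "origin"

    @property
    def photic(self) -> bool:
        return self.depth_m <= 200.0


@dataclass(frozen=True)
class DistributionTag:
    """Planted spatial behaviour of one genome.

    ``kind`` is one of ``stenobathic`` (present only at ``depths``, at
    most two contiguous sampled depths), ``eurybathic`` (present at every
    photic depth), ``endemic`` (present only at stations of the origin
    region), ``widespread`` (present at ``stations`` spanning more than
    one region) or ``uniform`` (no structure planted).
    """

    kind: str = "uniform"
    depths: tuple[float, ...] = ()
    stations: tuple[str, ...] = ()


@dataclass
class CommunitySpec:
    n_genomes: int
    samples: list[SampleSpec]
    seed: int
    genome_length_range_bp: tuple[int, int] = (30_000, 200_000)
    gc_range: tuple[float, float] = (0.18, 0.55)
    abundance_mu: float = 0.0
    abundance_sigma: float = 0.5
    read_length: int = 100
    read_identity: float = 0.98
    #: (parent_index, child_index, nucleotide identity) triples
    divergence_plan: list[tuple[int, int, float]] = field(default_factory=list)
    #: per-genome planted distribution, indexed like genomes
    planted_distribution: list[DistributionTag] = field(default_factory=list)
    hallmarks_per_genome: int = 4
    trna_fraction: float = 0.5
    spacer_fraction: float = 0.5

    def validate(self) -> None:
        lo, hi = self.genome_length_range_bp
        if not (0 < lo < hi):
            raise ValueError("degenerate genome length range")
        glo, ghi = self.gc_range
        if not (0 < glo < ghi < 1):
            raise ValueError("degenerate GC range")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        depths = {s.depth_m for s in self.samples}
        stations = {s.station_id for s in self.samples}
        for p, c, ident in self.divergence_plan:
            if not (0.5 <= ident <= 1.0):
                raise ValueError(f"divergence identity {ident} outside [0.5, 1]")
            if not (0 <= p < self.n_genomes and 0 <= c < self.n_genomes):
                raise ValueError("divergence plan indexes outside genome set")
        for tag in self.planted_distribution:
            if tag.kind == "stenobathic" and not set(tag.depths) <= depths:
                raise ValueError(f"stenobathic depths {tag.depths} not all sampled")
            if tag.kind in ("endemic", "widespread") and not set(tag.stations) <= stations:
                raise ValueError(f"planted stations {tag.stations} not all sampled")


@dataclass
class PlantedTruth:
    """Ground truth sufficient to score every pipeline stage."""

    genomes: dict[str, str] = field(default_factory=dict)
    gc_targets: dict[str, float] = field(default_factory=dict)
    host_labels: dict[str, str] = field(default_factory=dict)
    #: exact protein string -> functional label for planted cassettes
    gene_annotations: dict[str, str] = field(default_factory=dict)
    #: genome -> [(start, end, strand, label)]
    hallmark_intervals: dict[str, list[tuple[int, int, str, str]]] = field(default_factory=dict)
    #: genome -> (tRNA sequence, host label, position, strand)
    trna_inserts: dict[str, tuple[str, str, int, str]] = field(default_factory=dict)
    #: reference tRNA database [(sequence, host label)]
    trna_db: list[tuple[str, str]] = field(default_factory=list)
    #: CRISPR spacer database [(sequence, host label, source genome, position)]
    spacers: list[tuple[str, str, str, int]] = field(default_factory=list)
    #: (genome, sample) -> relative abundance
    abundance: dict[tuple[str, str], float] = field(default_factory=dict)
    #: contig -> (genome, start, end) on the doubled (circular) genome
    contig_sources: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    #: contig -> planted exact terminal repeat length (complete contigs)
    contig_repeats: dict[str, int] = field(default_factory=dict)
    #: (sample, genome) -> simulated read count
    read_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    sample_gb: dict[str, float] = field(default_factory=dict)
    #: (parent, child) -> planted nucleotide identity
    pairwise_identity: dict[tuple[str, str], float] = field(default_factory=dict)
    distribution: dict[str, DistributionTag] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genomes": self.genomes,
            "gc_targets": self.gc_targets,
            "host_labels": self.host_labels,
            "gene_annotations": self.gene_annotations,
            "hallmark_intervals": self.hallmark_intervals,
            "trna_inserts": self.trna_inserts,
            "trna_db": self.trna_db,
            "spacers": self.spacers,
            "abundance": {f"{g}\t{s}": v for (g, s), v in sorted(self.abundance.items())},
            "contig_sources": self.contig_sources,
            "contig_repeats": self.contig_repeats,
            "read_counts": {f"{s}\t{g}": v for (s, g), v in sorted(self.read_counts.items())},
            "sample_gb": self.sample_gb,
            "pairwise_identity": {f"{a}\t{b}": v for (a, b), v in sorted(self.pairwise_identity.items())},
            "distribution": {g: asdict(t) for g, t in sorted(self.distribution.items())},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class CommunityData:
    """Bundle returned by :func:`generate_community`."""

    spec: CommunitySpec
    genomes: dict[str, str]
    truth: PlantedTruth
    contigs_by_sample: dict[str, list[ContigRecord]]
    reads_by_sample: dict[str, list[tuple[str, str]]]


# ---------------------------------------------------------------------------
# Sequence-level helpers


def random_genome(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASES, size=length, p=p)
    return arr.tobytes().decode("ascii")


def mutate_exact(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Plant exactly ``n_subs`` substitutions at uniform distinct positions."""
    if n_subs == 0:
        return seq
    if n_subs > len(seq):
        raise ValueError("more substitutions than positions")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def mutate_rate(seq: str, rate: float, rng: np.random.Generator) -> str:
    return mutate_exact(seq, int(round(len(seq) * rate)), rng)


def _orf_cassette(rng: np.random.Generator, n_codons: int, gc: float = 0.5) -> tuple[str, str]:
    """A stop-free ORF of ``n_codons`` codons plus stop; returns (dna, protein).

    Codons are drawn with probability matching the genome's GC target so
    planted cassettes do not distort the realised GC.
    """
    w = np.array(
        [np.prod([gc / 2 if b in "GC" else (1 - gc) / 2 for b in codon]) for codon in _SAFE_CODONS]
    )
    body = "".join(rng.choice(_SAFE_CODONS, size=n_codons - 1, p=w / w.sum()))
    dna = "ATG" + body + "TAA"
    return dna, translate(dna[:-3])


def _overwrite(seq: str, pos: int, insert: str) -> str:
    return seq[:pos] + insert + seq[pos + len(insert) :]


# ---------------------------------------------------------------------------
# Genome generation


def generate_genomes(spec: CommunitySpec, rng: Optional[np.random.Generator] = None) -> tuple[dict[str, str], PlantedTruth]:
    """Generate the genome set and its planted truth.

    Genomes are random sequences at per-genome GC targets drawn from the
    spec's GC range.  Pairs named in the divergence plan are produced by
    copy-and-mutate to the target identity.  Each genome receives
    hallmark-gene cassettes; a seeded subset receives an exact host tRNA
    insert and contributes a CRISPR protospacer to the spacer database.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    truth = PlantedTruth()
    ids = [f"G{i:03d}" for i in range(spec.n_genomes)]
    children = {c for _, c, _ in spec.divergence_plan}
    lo, hi = spec.genome_length_range_bp

    # reference tRNA database: one 72-nt tRNA per host plus unused decoys
    for host in HOST_POOL:
        truth.trna_db.append((random_genome(rng, 72, 0.55), host))
    for i in range(3):
        truth.trna_db.append((random_genome(rng, 72, 0.55), f"decoy_{i}"))

    genomes: dict[str, str] = {}
    for i, gid in enumerate(ids):
        if i in children:
            continue
        length = int(rng.integers(lo, hi + 1))
        gc = float(rng.uniform(*spec.gc_range))
        truth.gc_targets[gid] = gc
        truth.host_labels[gid] = HOST_POOL[i % len(HOST_POOL)]
        g = random_genome(rng, length, gc)
        g = _plant_features(g, gid, spec, truth, rng)
        genomes[gid] = g

    for p, c, ident in spec.divergence_plan:
        parent, child = ids[p], ids[c]
        if parent not in genomes:
            raise ValueError("divergence plan child used as a parent before creation")
        seq = mutate_exact(genomes[parent], int(round(len(genomes[parent]) * (1 - ident))), rng)
        genomes[child] = seq
        truth.gc_targets[child] = truth.gc_targets[parent]
        truth.host_labels[child] = truth.host_labels[parent]
        truth.pairwise_identity[(parent, child)] = ident
        # record the child's own (mutated) cassette proteins
        for s, e, strand, label in truth.hallmark_intervals.get(parent, []):
            dna = seq[s:e] if strand == "+" else revcomp(seq[s:e])
            prot = translate(dna[:-3])
            if "*" not in prot:
                truth.gene_annotations[prot] = label
                truth.hallmark_intervals.setdefault(child, []).append((s, e, strand, label))

    truth.genomes = {g: genomes[g] for g in ids}
    for gid, tag in zip(ids, spec.planted_distribution):
        truth.distribution[gid] = tag
    return {g: genomes[g] for g in ids}, truth


def _plant_features(g: str, gid: str, spec: CommunitySpec, truth: PlantedTruth, rng: np.random.Generator) -> str:
    """Overwrite hallmark cassettes, an optional tRNA and record a spacer."""
    length = len(g)
    n_hall = min(spec.hallmarks_per_genome, len(HALLMARK_LABELS))
    slots = np.linspace(0.05, 0.75, num=max(n_hall, 1)) * length
    intervals = []
    for j in range(n_hall):
        label = HALLMARK_LABELS[j]
        n_codons = int(rng.integers(150, 250))
        dna, prot = _orf_cassette(rng, n_codons, gc=truth.gc_targets[gid])
        pos = int(slots[j]) + int(rng.integers(0, 200))
        strand = "+" if rng.random() < 0.5 else "-"
        insert = dna if strand == "+" else revcomp(dna)
        g = _overwrite(g, pos, insert)
        intervals.append((pos, pos + len(dna), strand, label))
        truth.gene_annotations[prot] = label
    truth.hallmark_intervals[gid] = intervals

    host = truth.host_labels[gid]
    if rng.random() < spec.trna_fraction:
        trna = truth.trna_db[HOST_POOL.index(host)][0]
        pos = int(rng.integers(int(0.8 * length), length - len(trna)))
        strand = "+" if rng.random() < 0.5 else "-"
        g = _overwrite(g, pos, trna if strand == "+" else revcomp(trna))
        truth.trna_inserts[gid] = (trna, host, pos, strand)

    if rng.random() < spec.spacer_fraction:
        spos = int(rng.integers(0, length - 32))
        truth.spacers.append((g[spos : spos + 32], host, gid, spos))
    return g


# ---------------------------------------------------------------------------
# Shredding genomes into per-sample contigs


@dataclass(frozen=True)
class FragmentPlan:
    """Shred one genome into overlapping fragments spread over samples.

    Fragment ``i`` is assigned to ``samples[i % len(samples)]``.  With
    ``circular`` the fragments tile the full circle and the last fragment
    wraps past the first one's start, so the merged reconstruction can
    re-detect circularity.
    """

    genome: str
    samples: tuple[str, ...]
    n_fragments: int = 3
    overlap_range: tuple[int, int] = (500, 1500)
    mutation_rate: float = 0.002
    circular: bool = True


@dataclass(frozen=True)
class CompletePlan:
    """Emit one full genome copy with an exact terminal repeat."""

    genome: str
    sample: str
    repeat: int = 40
    mutation_rate: float = 0.0


def shred_to_contigs(
    genomes: dict[str, str],
    truth: PlantedTruth,
    plan: Sequence[FragmentPlan | CompletePlan],
    rng: np.random.Generator,
) -> dict[str, list[ContigRecord]]:
    """Execute a shredding plan, updating truth with contig sources."""
    out: dict[str, list[ContigRecord]] = {}

    def emit(sample: str, cid: str, seq: str, gid: str, start: int, end: int) -> None:
        out.setdefault(sample, []).append(ContigRecord(cid, seq, sample_id=sample))
        truth.contig_sources[cid] = (gid, start, end)

    for item in plan:
        g = genomes[item.genome]
        length = len(g)
        if isinstance(item, CompletePlan):
            if item.repeat > length:
                raise ValueError("terminal repeat longer than genome")
            copy = mutate_rate(g, item.mutation_rate, rng) if item.mutation_rate else g
            seq = copy + copy[: item.repeat]
            cid = f"{item.genome}_{item.sample}_complete"
            emit(item.sample, cid, seq, item.genome, 0, length + item.repeat)
            truth.contig_repeats[cid] = item.repeat
            continue
        # tripled so a wrap fragment starting near the end never truncates
        doubled = g + g + g
        start0 = int(rng.integers(0, length))
        bounds = [start0 + int(round(i * length / item.n_fragments)) for i in range(item.n_fragments + 1)]
        for i in range(item.n_fragments):
            ov = int(rng.integers(*item.overlap_range))
            fstart = bounds[i]
            fend = bounds[i + 1] + ov
            if not item.circular and i == item.n_fragments - 1:
                fend = bounds[i + 1]
            if fend - fstart > length:
                raise ValueError("fragment longer than genome")
            frag = doubled[fstart : fend]
            frag = mutate_rate(frag, item.mutation_rate, rng)
            sample = item.samples[i % len(item.samples)]
            cid = f"{item.genome}_{sample}_f{i}"
            emit(sample, cid, frag, item.genome, fstart, fend)
    return out


# ---------------------------------------------------------------------------
# Read simulation


def simulate_reads(
    genomes: dict[str, str],
    abundance: dict[str, float],
    read_length: int,
    target_identity: float,
    total_reads: int,
    rng: np.random.Generator,
    sample_id: str = "S",
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Draw reads from circularised genomes at controlled identity.

    Reads are apportioned among genomes with probability proportional to
    ``abundance * length``; start positions are uniform on the circle and
    each read carries exactly ``round(read_length * (1 - target_identity))``
    substitutions.  Returns the reads and the per-genome truth counts.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if read_length not in (100, 150):
        raise ValueError("read_length must be 100 or 150")
    if not (0.8 <= target_identity <= 1.0):
        raise ValueError("target_identity outside [0.8, 1]")
    ids = sorted(g for g in genomes if abundance.get(g, 0.0) > 0)
    if not ids:
        raise ValueError("no genome with positive abundance")
    weights = np.array([abundance[g] * len(genomes[g]) for g in ids], dtype=float)
    counts = rng.multinomial(total_reads, weights / weights.sum())
    n_subs = int(round(read_length * (1 - target_identity)))
    reads: list[tuple[str, str]] = []
    truth_counts: dict[str, int] = {}
    serial = 0
    for g, n in zip(ids, counts):
        truth_counts[g] = int(n)
        doubled = genomes[g] + genomes[g]
        L = len(genomes[g])
        starts = rng.integers(0, L, size=n)
        flips = rng.random(n) < 0.5
        for s, flip in zip(starts.tolist(), flips.tolist()):
            seq = doubled[s : s + read_length]
            seq = mutate_exact(seq, n_subs, rng)
            if flip:
                seq = revcomp(seq)
            reads.append((f"{sample_id}_r{serial:07d}", seq))
            serial += 1
    return reads, truth_counts


# ---------------------------------------------------------------------------
# Whole-community orchestration


def _abundance_for(tag: DistributionTag, sample: SampleSpec, base: float) -> float:
    if tag.kind == "uniform":
        return base
    if tag.kind == "stenobathic":
        return base if sample.depth_m in tag.depths else 0.0
    if tag.kind == "eurybathic":
        return base if sample.photic else 0.0
    if tag.kind in ("endemic", "widespread"):
        return base if sample.station_id in tag.stations else 0.0
    raise ValueError(f"unknown distribution kind {tag.kind!r}")


def generate_community(spec: CommunitySpec) -> CommunityData:
    """Generate genomes, abundances, per-sample contigs and reads.

    Contigs: each genome is shredded into fragments spread across the
    samples where it is present; the most abundant genome of each sample
    additionally contributes a complete (terminal-repeat) contig.
    """
    rng = np.random.default_rng(spec.seed)
    genomes, truth = generate_genomes(spec, rng)
    ids = sorted(genomes)
    tags = {gid: truth.distribution.get(gid, DistributionTag()) for gid in ids}

    base = {
        (gid, s.sample_id): float(np.exp(rng.normal(spec.abundance_mu, spec.abundance_sigma)))
        for gid in ids
        for s in spec.samples
    }
    for gid in ids:
        for s in spec.samples:
            truth.abundance[(gid, s.sample_id)] = _abundance_for(tags[gid], s, base[(gid, s.sample_id)])

    plan: list[FragmentPlan | CompletePlan] = []
    for gid in ids:
        present = tuple(
            s.sample_id for s in spec.samples if truth.abundance[(gid, s.sample_id)] > 0
        )
        if not present:
            continue
        # fragments sized to clear the 10 kb screening gate, with ~30%
        # overlaps so fragments of one genome cluster into one VC
        length = len(genomes[gid])
        n_frag = max(2, min(len(present), length // 12_000))
        ov_lo = max(500, int(0.25 * length / n_frag))
        ov_hi = max(ov_lo + 100, int(0.35 * length / n_frag))
        plan.append(
            FragmentPlan(
                genome=gid, samples=present, n_fragments=n_frag, overlap_range=(ov_lo, ov_hi)
            )
        )
    for s in spec.samples:
        ranked = sorted(ids, key=lambda g: -truth.abundance[(g, s.sample_id)])
        if ranked and truth.abundance[(ranked[0], s.sample_id)] > 0:
            plan.append(CompletePlan(genome=ranked[0], sample=s.sample_id, repeat=40))
    contigs = shred_to_contigs(genomes, truth, plan, rng)

    reads: dict[str, list[tuple[str, str]]] = {}
    for s in spec.samples:
        n_reads = int(round(s.reads_gb * 1e9 / spec.read_length))
        ab = {gid: truth.abundance[(gid, s.sample_id)] for gid in ids}
        if not any(v > 0 for v in ab.values()):
            reads[s.sample_id] = []
            truth.sample_gb[s.sample_id] = n_reads * spec.read_length / 1e9
            continue
        sample_reads, counts = simulate_reads(
            genomes, ab, spec.read_length, spec.read_identity, n_reads, rng, sample_id=s.sample_id
        )
        reads[s.sample_id] = sample_reads
        for gid, c in counts.items():
            truth.read_counts[(s.sample_id, gid)] = c
        truth.sample_gb[s.sample_id] = n_reads * spec.read_length / 1e9
    return CommunityData(spec, genomes, truth, contigs, reads)
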