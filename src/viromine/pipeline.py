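"""End-to-end pipeline orchestration.

Stages run in the paper-shaped order: screen -> circularity -> viral
clusters -> MAVG merging -> recruitment -> distribution classification
-> genome taxonomy -> host calls.  Every stage reads and writes plain
text files under the output directory, and the run log records the
record counts surviving each filter.  With ``synthetic`` enabled the
demo community (12 genomes, 4 samples) is generated first, so a single
seed makes the whole run a pure function of the configuration.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import align, clustering, host_predict, mavg, recruitment, synthetic_data, taxonomy_tree, viral_screen
from .config import RunConfig
from .seqcore import call_orfs, gene_calls_to_tsv, write_fasta
from .synthetic_data import CommunitySpec, DistributionTag, SampleSpec

__all__ = ["demo_spec", "run_pipeline"]


def demo_spec(seed: int) -> CommunitySpec:
    """The 12-genome, 4-sample demonstration community."""
    samples = [
        SampleSpec("S01-15m", 15.0, "MED-A", reads_gb=2e-4, region="Mediterranean"),
        SampleSpec("S02-45m", 45.0, "MED-A", reads_gb=2e-4, region="Mediterranean"),
        SampleSpec("S03-75m", 75.0, "MED-B", reads_gb=2e-4, region="Mediterranean"),
        SampleSpec("S04-1000m", 1000.0, "MED-B", reads_gb=2e-4, region="Mediterranean"),
    ]
    tags = [DistributionTag()] * 8 + [
        DistributionTag("stenobathic", depths=(15.0,)),
        DistributionTag("stenobathic", depths=(45.0, 75.0)),
        DistributionTag("eurybathic"),
        DistributionTag("eurybathic"),
    ]
    return CommunitySpec(
        n_genomes=12,
        samples=samples,
        seed=seed,
        genome_length_range_bp=(20_000, 35_000),
        gc_range=(0.30, 0.50),
        read_identity=0.98,
        divergence_plan=[(0, 1, 0.96)],
        planted_distribution=tags,
    )


def _log(fh, message: str) -> None:
    fh.write(message + "\n")


def run_pipeline(config: RunConfig, outdir: str | Path, spec: Optional[CommunitySpec] = None) -> Path:
    """Run every stage, writing all artefacts under ``outdir``.

    With ``config.synthetic`` the community is generated from
    ``config.seed`` (or the given spec); otherwise ``config.input_dir``
    must point at a directory laid out like a simulate run.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    log = open(outdir / "log.txt", "w")
    _log(log, f"seed={config.seed}")

    if config.synthetic:
        community = synthetic_data.generate_community(spec or demo_spec(config.seed))
    else:
        if config.input_dir is None:
            raise FileNotFoundError("no input directory configured and synthetic mode off")
        community = _load_community(Path(config.input_dir), config)
    truth = community.truth
    sim_dir = outdir / "community"
    sim_dir.mkdir(exist_ok=True)
    write_fasta(sorted(truth.genomes.items()), sim_dir / "genomes.fasta")
    with open(sim_dir / "samples.tsv", "w") as fh:
        fh.write("sample_id\tdepth_m\tstation\tfraction\tregion\tgb\n")
        for s in community.spec.samples:
            fh.write(
                f"{s.sample_id}\t{s.depth_m:g}\t{s.station_id}\t{s.fraction}\t{s.region}\t"
                f"{truth.sample_gb.get(s.sample_id, s.reads_gb):.8g}\n"
            )
    for sample_id in sorted(community.contigs_by_sample):
        write_fasta(community.contigs_by_sample[sample_id], sim_dir / f"contigs_{sample_id}.fasta")
    for sample_id in sorted(community.reads_by_sample):
        write_fasta(community.reads_by_sample[sample_id], sim_dir / f"reads_{sample_id}.fasta")
    truth.to_json(sim_dir / "truth.json")

    contigs = [c for s in sorted(community.contigs_by_sample) for c in community.contigs_by_sample[s]]
    _log(log, f"contigs={len(contigs)}")

    # --- screening + circularity
    gene_calls = {c.contig_id: call_orfs(c.sequence, contig_id=c.contig_id) for c in contigs}
    all_calls = [g for c in contigs for g in gene_calls[c.contig_id]]
    gene_calls_to_tsv(all_calls, outdir / "gene_calls.tsv")
    decisions = viral_screen.screen_contigs(
        contigs,
        gene_calls,
        annotations=truth.gene_annotations,
        length_min=config.length_min,
        min_hallmarks=config.min_hallmarks,
    )
    completeness = [
        viral_screen.detect_terminal_repeat(c, min_repeat=config.repeat_min) for c in contigs
    ]
    viral_screen.screen_report(contigs, decisions, completeness, outdir / "screen.tsv")
    viral_ids = {d.contig_id for d in decisions if d.verdict == "viral"}
    viral_contigs = [c for c in contigs if c.contig_id in viral_ids]
    _log(log, f"viral_contigs={len(viral_contigs)}")
    _log(log, f"complete_CGR={sum(1 for c in completeness if c.is_complete)}")

    # --- viral clusters
    vcs = clustering.build_vcs(viral_contigs, config.vc_identity, config.vc_coverage)
    clustering.vc_tables(vcs, viral_contigs, outdir)
    _log(log, f"vcs={len(vcs)} singletons={sum(1 for v in vcs if v.is_singleton)}")

    # --- MAVGs
    mavgs = mavg.build_mavgs(
        {s: [c for c in community.contigs_by_sample[s] if c.contig_id in viral_ids] for s in community.contigs_by_sample},
        overlap_min_bp=config.mavg_overlap_min_bp,
        identity_min=config.mavg_identity,
    )
    merged = [m for m in mavgs if not m.conflict]
    write_fasta([(m.mavg_id, m.consensus_sequence) for m in merged], outdir / "mavgs.fasta")
    mavg.placements_to_tsv(mavgs, outdir / "mavg_placements.tsv")
    _log(log, f"mavgs={len(merged)} conflicts={sum(1 for m in mavgs if m.conflict)}")

    # --- recruitment at each identity threshold, against VC representatives
    rep_ids = sorted(v.representative for v in vcs)
    by_id = {c.contig_id: c for c in viral_contigs}
    targets = {rid: by_id[rid].sequence for rid in rep_ids}
    gindex = align.GenomeIndex(targets) if targets else None
    lengths = {rid: len(targets[rid]) for rid in targets}
    profiles = {}
    for threshold in config.recruit_identities:
        counts = {}
        for s in sorted(community.reads_by_sample):
            reads = community.reads_by_sample[s]
            sample_counts = (
                align.map_reads(reads, gindex, identity_threshold=threshold) if reads and gindex else {}
            )
            for rid, c in sample_counts.items():
                counts[(rid, s)] = c
        profile = recruitment.rpkg_profile(counts, lengths, truth.sample_gb, identity_threshold=threshold)
        profile.to_tsv(outdir / f"rpkg_{int(round(threshold * 100))}.tsv")
        profiles[threshold] = profile
        _log(log, f"rpkg@{threshold:g}: recruited_reads={sum(counts.values())}")

    # --- distribution classification on the loosest threshold profile
    loose = profiles[min(config.recruit_identities)]
    depth_order = sorted(((s.sample_id, s.depth_m) for s in community.spec.samples), key=lambda x: x[1])
    depth_calls = recruitment.classify_depth(loose, depth_order, floor=config.rpkg_floor)
    station_regions = {s.station_id: s.region for s in community.spec.samples}
    geo_calls = recruitment.classify_geo(
        loose,
        station_regions,
        origin_region=community.spec.samples[0].region,
        sample_stations={s.sample_id: s.station_id for s in community.spec.samples},
        floor=config.rpkg_floor,
    )
    with open(outdir / "distribution_calls.tsv", "w") as fh:
        fh.write("id\tdepth_class\tgeo_class\tdetected_samples\n")
        for rid in sorted(depth_calls):
            fh.write(
                f"{rid}\t{depth_calls[rid].depth_class}\t{geo_calls[rid].geo_class}\t"
                f"{','.join(depth_calls[rid].depth_samples) or '-'}\n"
            )

    # --- community comparison over samples (when any recruitment signal)
    if (loose.rpkg.values.sum(axis=0) > 0).all() and loose.rpkg.shape[1] >= 2:
        dm, upgma, coords, _ = recruitment.compare_samples(loose.rpkg)
        dm.to_csv(outdir / "sample_distances.tsv", sep="\t", float_format="%.6g")
        (outdir / "sample_upgma.nwk").write_text(upgma + "\n")
        coords.to_csv(outdir / "sample_pcoa.tsv", sep="\t", float_format="%.6g")

    # --- genome taxonomy over complete genomes (CGR + MAVG), padded with
    #     the longest representatives when fewer than four
    tree_seqs: dict[str, str] = {}
    for comp, contig in zip(completeness, contigs):
        if comp.is_complete and contig.contig_id in viral_ids:
            tree_seqs[contig.contig_id] = contig.sequence[: comp.trimmed_length_bp]
    for m in merged:
        tree_seqs[m.mavg_id] = m.consensus_sequence
    for rid in sorted(targets, key=lambda r: -lengths[r]):
        if len(tree_seqs) >= 4:
            break
        tree_seqs.setdefault(rid, targets[rid])
    if len(tree_seqs) >= 3:
        ids, dmat = taxonomy_tree.dice_matrix(tree_seqs)
        taxonomy_tree.write_distance_tsv(ids, dmat, outdir / "dice_distances.tsv")
        (outdir / "genome_tree.nwk").write_text(taxonomy_tree.neighbor_joining(ids, dmat) + "\n")
        _log(log, f"tree_taxa={len(ids)}")

    # --- host prediction
    rng = np.random.default_rng(config.seed + 9001)
    references = {}
    for gid in sorted(truth.genomes)[:3]:
        seq = synthetic_data.mutate_rate(truth.genomes[gid], 0.12, rng)
        references[f"REF_{gid}"] = (seq, truth.host_labels[gid])
    vc_of = {cid: v.vc_id for v in vcs for cid in v.member_contig_ids}
    evidences: dict[str, list[host_predict.Evidence]] = {}
    for c in viral_contigs:
        ev = []
        hit = host_predict.trna_match(c, truth.trna_db)
        if hit:
            ev.append(hit)
        hit = host_predict.crispr_match(c, [(s, h) for s, h, _, _ in truth.spacers])
        if hit:
            ev.append(hit)
        hit = host_predict.majority_best_hit(
            c,
            gene_calls[c.contig_id],
            references,
            identity_min=config.best_hit_identity,
            coverage_min=config.best_hit_coverage,
        )
        if hit:
            ev.append(hit)
        _, amg_ev = host_predict.amg_flags(gene_calls[c.contig_id])
        if amg_ev:
            ev.append(amg_ev)
        evidences[c.contig_id] = ev
    calls = host_predict.combine_evidence(evidences, vc_partition=vc_of)
    host_predict.host_calls_to_tsv(calls, outdir / "host_calls.tsv")
    _log(log, f"host_assigned={sum(1 for c in calls.values() if c.host_label != 'unassigned')}")

    log.close()
    return outdir


def _load_community(input_dir: Path, config: RunConfig):
    """Load a community from a directory laid out like a simulate run."""
    from .seqcore import read_fasta

    samples_tsv = input_dir / "samples.tsv"
    if not samples_tsv.exists():
        raise FileNotFoundError(f"missing input file: {samples_tsv}")
    table = pd.read_csv(samples_tsv, sep="\t")
    samples = [
        SampleSpec(r.sample_id, float(r.depth_m), r.station, r.fraction, float(r.gb), r.region)
        for r in table.itertuples()
    ]
    spec = CommunitySpec(n_genomes=0, samples=samples, seed=config.seed)
    truth = synthetic_data.PlantedTruth()
    contigs = {}
    reads = {}
    for s in samples:
        cpath = input_dir / f"contigs_{s.sample_id}.fasta"
        if not cpath.exists():
            raise FileNotFoundError(f"missing input file: {cpath}")
        contigs[s.sample_id] = read_fasta(cpath, sample_id=s.sample_id, depth_m=s.depth_m, station_id=s.station_id)
        rpath = input_dir / f"reads_{s.sample_id}.fasta"
        reads[s.sample_id] = (
            [(r.contig_id, r.sequence) for r in read_fasta(rpath)] if rpath.exists() else []
        )
        truth.sample_gb[s.sample_id] = s.reads_gb
    gpath = input_dir / "genomes.fasta"
    genomes = {r.contig_id: r.sequence for r in read_fasta(gpath)} if gpath.exists() else {}
    truth.genomes = genomes
    return synthetic_data.CommunityData(spec, genomes, truth, contigs, reads)
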