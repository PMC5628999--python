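"""RPKG recruitment profiles and distribution classification.

RPKG — reads recruited per kilobase of genome per gigabase of
metagenome — normalises recruited read counts so abundances are
comparable across genomes and across samples:

    RPKG = count / (genome_length_bp / 1000) / metagenome_gb

A genome or viral cluster is *detected* in a sample when its RPKG
strictly exceeds the detection floor (10 RPKG by default).  Depth
classification follows the water-column reading of the detections:
restricted to at most two contiguous sampled depths -> stenobathic;
detected at every photic depth -> eurybathic; anything in between ->
intermediate.  Geographic classification contrasts endemic genomes
(detected only at stations of their region of origin) with widespread
ones (detected at two or more stations including at least one outside
the origin region).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "RecruitmentProfile",
    "DistributionCall",
    "rpkg_profile",
    "classify_depth",
    "classify_geo",
    "compare_samples",
]


@dataclass
class RecruitmentProfile:
    """Genome/VC x sample RPKG matrix at a stated identity threshold."""

    rpkg: pd.DataFrame  # rows: genome/VC ids, columns: sample ids
    identity_threshold: float
    sample_gb: dict[str, float]

    def to_tsv(self, path: str | Path) -> None:
        self.rpkg.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class DistributionCall:
    id: str
    depth_class: str = "undetected"  # stenobathic / eurybathic / intermediate / undetected
    geo_class: str = "undetected"  # endemic / widespread / undetected
    depth_samples: list[str] = field(default_factory=list)
    geo_stations: list[str] = field(default_factory=list)


def rpkg_profile(
    read_counts: Mapping[tuple[str, str], int] | pd.DataFrame,
    genome_lengths: Mapping[str, int],
    sample_gbs: Mapping[str, float],
    identity_threshold: float = 0.95,
) -> RecruitmentProfile:
    """Exact RPKG from read counts; no pseudocounts.

    ``read_counts`` maps (genome_id, sample_id) to a count, or is a
    genome x sample DataFrame.  Zero genome length or zero metagenome
    size is an error.
    """
    for g, L in genome_lengths.items():
        if L <= 0:
            raise ValueError(f"genome {g} has non-positive length")
    for s, gb in sample_gbs.items():
        if gb <= 0:
            raise ValueError(f"sample {s} has non-positive metagenome size")
    if isinstance(read_counts, pd.DataFrame):
        counts = read_counts
    else:
        genomes = sorted(genome_lengths)
        samples = sorted(sample_gbs)
        counts = pd.DataFrame(0, index=genomes, columns=samples, dtype=float)
        for (g, s), c in read_counts.items():
            counts.loc[g, s] = c
    kb = pd.Series({g: genome_lengths[g] / 1000.0 for g in counts.index})
    gb = pd.Series({s: sample_gbs[s] for s in counts.columns})
    rpkg = counts.div(kb, axis=0).div(gb, axis=1)
    return RecruitmentProfile(rpkg=rpkg, identity_threshold=identity_threshold, sample_gb=dict(sample_gbs))


def classify_depth(
    profile: RecruitmentProfile,
    depth_ordered_samples: Sequence[tuple[str, float]],
    photic_samples: Optional[Sequence[str]] = None,
    floor: float = 10.0,
    photic_max_depth: float = 200.0,
) -> dict[str, DistributionCall]:
    """Depth-distribution call per profile row.

    ``depth_ordered_samples`` is the (sample_id, depth_m) profile in
    strictly increasing depth order; the photic subset defaults to
    samples at <= ``photic_max_depth`` m.
    """
    depths = [d for _, d in depth_ordered_samples]
    if any(b < a for a, b in zip(depths, depths[1:])):
        raise ValueError("samples must be ordered by increasing depth")
    order = [s for s, _ in depth_ordered_samples]
    if photic_samples is None:
        photic_samples = [s for s, d in depth_ordered_samples if d <= photic_max_depth]
    photic = [s for s in order if s in set(photic_samples)]
    calls = {}
    for gid, row in profile.rpkg.iterrows():
        detected = [s for s in order if s in row.index and row[s] > floor]
        call = DistributionCall(id=gid, depth_samples=detected)
        if not detected:
            call.depth_class = "undetected"
        elif set(photic) and set(photic) <= set(detected):
            call.depth_class = "eurybathic"
        else:
            idx = [order.index(s) for s in detected]
            contiguous = max(idx) - min(idx) == len(idx) - 1
            if len(detected) <= 2 and contiguous:
                call.depth_class = "stenobathic"
            else:
                call.depth_class = "intermediate"
        calls[gid] = call
    return calls


def classify_geo(
    profile: RecruitmentProfile,
    station_regions: Mapping[str, str],
    origin_region: str,
    sample_stations: Mapping[str, str],
    floor: float = 10.0,
    min_stations: int = 2,
) -> dict[str, DistributionCall]:
    """Geographic-distribution call per profile row.

    A genome is widespread when detected at >= ``min_stations`` stations
    including at least one outside the origin region, endemic when every
    detection lies inside the origin region, undetected otherwise.
    """
    for sample, station in sample_stations.items():
        if station not in station_regions:
            raise ValueError(f"sample {sample} maps to unknown station/region {station!r}")
    calls = {}
    for gid, row in profile.rpkg.iterrows():
        stations = sorted(
            {
                sample_stations[s]
                for s in row.index
                if s in sample_stations and row[s] > floor
            }
        )
        call = DistributionCall(id=gid, geo_stations=stations)
        outside = [st for st in stations if station_regions[st] != origin_region]
        if not stations:
            call.geo_class = "undetected"
        elif len(stations) >= min_stations and outside:
            call.geo_class = "widespread"
        elif not outside:
            call.geo_class = "endemic"
        else:
            call.geo_class = "undetected"
        calls[gid] = call
    return calls


def _linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(link)

    def rec(node, parent_dist) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return rec(tree, tree.dist) + ";"


def compare_samples(
    abundance: pd.DataFrame,
    method: str = "bray_curtis",
) -> tuple[pd.DataFrame, str, pd.DataFrame, np.ndarray]:
    """Bray-Curtis distances, UPGMA tree and PCoA over samples.

    ``abundance`` has genomes/VCs as rows and samples as columns
    (non-negative RPKG or counts).  Returns (distance matrix, UPGMA
    newick, PCoA coordinates, eigenvalues); PCoA axes are ordered by
    decreasing eigenvalue.
    """
    if method != "bray_curtis":
        raise ValueError(f"unsupported method {method!r}")
    if (abundance.values < 0).any():
        raise ValueError("abundances must be non-negative")
    zero = [c for c in abundance.columns if abundance[c].sum() == 0]
    if zero:
        raise ValueError(f"all-zero sample(s): {', '.join(map(str, zero))}")
    data = abundance.T.values.astype(float)
    condensed = pdist(data, metric="braycurtis")
    labels = list(abundance.columns)
    dm = pd.DataFrame(squareform(condensed), index=labels, columns=labels)
    newick = _linkage_to_newick(hierarchy.average(condensed), labels)

    # classical multidimensional scaling of the squared distances
    d2 = dm.values**2
    n = len(labels)
    centering = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * centering @ d2 @ centering
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    pos = eigval > 1e-12
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    coords_df = pd.DataFrame(coords, index=labels, columns=axes)
    return dm, newick, coords_df, eigval
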