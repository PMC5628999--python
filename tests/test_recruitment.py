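"""RPKG arithmetic, distribution calls, sample comparison."""

import numpy as np
import pandas as pd
import pytest

from viromine.recruitment import (
    RecruitmentProfile,
    classify_depth,
    classify_geo,
    compare_samples,
    rpkg_profile,
)


def test_rpkg_formula_example():
    profile = rpkg_profile({("G", "S"): 100}, {"G": 10_000}, {"S": 2.0})
    assert profile.rpkg.loc["G", "S"] == pytest.approx(5.0)


def test_rpkg_zero_count_and_errors():
    profile = rpkg_profile({}, {"G": 10_000}, {"S": 2.0})
    assert profile.rpkg.loc["G", "S"] == 0.0
    with pytest.raises(ValueError):
        rpkg_profile({}, {"G": 0}, {"S": 2.0})
    with pytest.raises(ValueError):
        rpkg_profile({}, {"G": 10_000}, {"S": 0.0})


def test_rpkg_linearity():
    base = rpkg_profile({("G", "S"): 120}, {"G": 30_000}, {"S": 1.5}).rpkg.loc["G", "S"]
    assert rpkg_profile({("G", "S"): 240}, {"G": 30_000}, {"S": 1.5}).rpkg.loc["G", "S"] == pytest.approx(2 * base)
    assert rpkg_profile({("G", "S"): 120}, {"G": 60_000}, {"S": 1.5}).rpkg.loc["G", "S"] == pytest.approx(base / 2)
    assert rpkg_profile({("G", "S"): 120}, {"G": 30_000}, {"S": 3.0}).rpkg.loc["G", "S"] == pytest.approx(base / 2)


DEPTHS = [("d15", 15.0), ("d30", 30.0), ("d45", 45.0), ("d60", 60.0), ("d75", 75.0), ("d90", 90.0)]


def _profile(rows):
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[s for s, _ in DEPTHS])
    return RecruitmentProfile(df, 0.95, {s: 1.0 for s, _ in DEPTHS})


def test_depth_classes():
    profile = _profile(
        {
            "adjacent_75_90": [0, 0, 0, 0, 50, 60],
            "all_photic": [20, 30, 40, 25, 50, 60],
            "disjoint_15_75": [30, 0, 0, 0, 40, 0],
            "nothing": [0, 0, 0, 0, 0, 0],
            "at_floor": [10.0, 0, 0, 0, 0, 0],  # strictly-greater rule
        }
    )
    calls = classify_depth(profile, DEPTHS)
    assert calls["adjacent_75_90"].depth_class == "stenobathic"
    assert calls["all_photic"].depth_class == "eurybathic"
    assert calls["disjoint_15_75"].depth_class == "intermediate"
    assert calls["nothing"].depth_class == "undetected"
    assert calls["at_floor"].depth_class == "undetected"


def test_depth_requires_ordered_samples():
    profile = _profile({"g": [0, 0, 0, 0, 0, 60]})
    with pytest.raises(ValueError):
        classify_depth(profile, list(reversed(DEPTHS)))


def test_geo_classes():
    samples = ["sM1", "sM2", "sA1"]
    df = pd.DataFrame(
        {
            "sM1": {"endemic_g": 50.0, "wide_g": 40.0, "none_g": 0.0},
            "sM2": {"endemic_g": 30.0, "wide_g": 0.0, "none_g": 0.0},
            "sA1": {"endemic_g": 0.0, "wide_g": 80.0, "none_g": 0.0},
        }
    )
    profile = RecruitmentProfile(df, 0.95, {s: 1.0 for s in samples})
    regions = {"M1": "Med", "M2": "Med", "A1": "Atl"}
    stations = {"sM1": "M1", "sM2": "M2", "sA1": "A1"}
    calls = classify_geo(profile, regions, "Med", stations)
    assert calls["endemic_g"].geo_class == "endemic"
    assert calls["wide_g"].geo_class == "widespread"
    assert calls["none_g"].geo_class == "undetected"


def test_geo_unknown_region_errors():
    df = pd.DataFrame({"s1": {"g": 50.0}})
    profile = RecruitmentProfile(df, 0.95, {"s1": 1.0})
    with pytest.raises(ValueError):
        classify_geo(profile, {}, "Med", {"s1": "mystery"})


def test_compare_samples_identical_and_disjoint():
    df = pd.DataFrame({"s1": [1.0, 0.0], "s2": [1.0, 0.0], "s3": [0.0, 1.0]})
    dm, newick, coords, eig = compare_samples(df)
    assert dm.loc["s1", "s2"] == pytest.approx(0.0)
    assert dm.loc["s1", "s3"] == pytest.approx(1.0)
    assert np.allclose(coords.loc["s1"], coords.loc["s2"])
    assert newick.endswith(";")


def test_compare_samples_recovers_planted_groups():
    rng = np.random.default_rng(3)
    group1 = {f"a{i}": rng.uniform(40, 60, size=8) for i in range(3)}
    group2 = {f"b{i}": np.concatenate([rng.uniform(0, 2, size=4), rng.uniform(40, 60, size=4)]) for i in range(3)}
    df = pd.DataFrame({**group1, **group2})
    dm, newick, coords, eig = compare_samples(df)
    # first PCoA axis separates the groups
    a_coord = coords.loc[[f"a{i}" for i in range(3)], "PC1"]
    b_coord = coords.loc[[f"b{i}" for i in range(3)], "PC1"]
    assert a_coord.max() < b_coord.min() or b_coord.max() < a_coord.min()
    # UPGMA splits them: every a is closer to all a's than to any b
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    within = pdm.patristic_distance(taxa["a0"], taxa["a1"])
    across = pdm.patristic_distance(taxa["a0"], taxa["b0"])
    assert within < across


def test_compare_samples_eigenvalue_sum_matches_variance():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(rng.uniform(0, 10, size=(6, 5)), columns=list("abcde"))
    dm, _, coords, eig = compare_samples(df)
    d2 = dm.values**2
    n = d2.shape[0]
    total_centred = -0.5 * ((np.eye(n) - 1 / n) @ d2 @ (np.eye(n) - 1 / n)).trace()
    assert abs(eig.sum() - total_centred) <= 1e-8


def test_compare_samples_all_zero_sample_named():
    df = pd.DataFrame({"good": [1.0, 2.0], "empty": [0.0, 0.0]})
    with pytest.raises(ValueError, match="empty"):
        compare_samples(df)
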