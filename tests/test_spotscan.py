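import numpy as np
import pandas as pd
import pytest

from xomap.iocore import GenomeAnnotation
from xomap import spotscan
from tests.conftest import SMALL_CHROMS, synthetic_crossover_set


@pytest.fixture(scope="module")
def ann():
    return GenomeAnnotation(dict(SMALL_CHROMS))


def test_uniform_cooccurrence_probability_published_value():
    p = spotscan.uniform_cooccurrence_probability(6, 5_000, 463_000_000)
    assert p == pytest.approx(1.6e-30, rel=0.05)


def test_hotspots_planted_spikes_recovered(ann):
    """10x intensity spikes at known 5-kb windows are recovered with
    recall > 90% and false-discovery proportion <= 1.5 x nominal."""
    rng = np.random.default_rng(0)
    spikes = [("chr1", 1_000_000), ("chr1", 2_000_000), ("chr2", 500_000),
              ("chr2", 1_500_000), ("chr2", 2_500_000)]
    pos, chroms = [], []
    for c, s in spikes:
        for _ in range(30):
            pos.append(int(rng.uniform(s, s + 5_000)))
            chroms.append(c)
    n_bg = 1000
    for _ in range(n_bg):
        c = "chr1" if rng.random() < 0.5 else "chr2"
        chroms.append(c)
        pos.append(int(rng.uniform(1, SMALL_CHROMS[c])))
    ev = pd.DataFrame({
        "family": "f", "offspring": "o1", "parent": "maternal",
        "sex": "F", "ecotype": "marine", "chrom": chroms,
        "left": pos, "right": np.asarray(pos) + 2})
    from xomap.iocore import CrossoverSet
    xs = CrossoverSet(ev)
    res = spotscan.detect_hotspots(xs, ann, n_perm=150, seed=1)
    hs = res["hotspots"]
    recovered = 0
    for c, s in spikes:
        hit = hs[(hs["chrom"] == c) & (hs["start"] < s + 5_000)
                 & (hs["end"] > s)]
        recovered += int(len(hit) > 0)
    assert recovered / len(spikes) > 0.9
    false = 0
    for _, r in hs.iterrows():
        near = any(c == r["chrom"] and r["start"] < s + 5_000 and r["end"] > s
                   for c, s in spikes)
        false += int(not near)
    assert false / max(len(hs), 1) <= 1.5 * 0.05 + 1e-9


def test_hotspots_null_finds_nothing_stable(ann):
    xs = synthetic_crossover_set(np.random.default_rng(2), n_events=500)
    res = spotscan.detect_hotspots(xs, ann, n_perm=150, seed=3)
    # on uniform data no count threshold reaches FDR < 0.05
    assert len(res["hotspots"]) == 0 or res["k_threshold"] is None or \
        len(res["hotspots"]) <= 0.001 * len(res["windows"])


def test_log2fc_pseudocount_value():
    """Counts (8, 0) with pseudocount 0.1 give log2(8.1/0.1) = 6.34."""
    fc = np.log2((8 + 0.1) / (0 + 0.1))
    assert fc == pytest.approx(6.34, abs=0.005)


def test_log2fc_antisymmetry_and_symmetry():
    a, b, pc = 3, 3, 0.1
    assert np.log2((a + pc) / (b + pc)) == 0.0
    a, b = 7, 2
    assert np.log2((a + pc) / (b + pc)) == -np.log2((b + pc) / (a + pc))


def test_ecotype_divergent_hotspots_planted(ann):
    """Windows where one ecotype has many crossovers and another none are
    flagged; shuffled labels produce few flags."""
    rng = np.random.default_rng(4)
    sets = {}
    for eco in ("marine", "freshwater", "hybrid"):
        xs = synthetic_crossover_set(rng, n_events=600, ecotype=eco)
        sets[eco] = xs
    # plant a marine-only cluster
    ev = sets["marine"].events.copy()
    extra = pd.DataFrame({
        "family": "f", "offspring": "o1", "parent": "maternal", "sex": "F",
        "ecotype": "marine", "chrom": "chr1",
        "left": rng.integers(1_000_000, 1_004_000, 25),
        "right": rng.integers(1_000_000, 1_004_000, 25) + 4000})
    from xomap.iocore import CrossoverSet, XO_COLUMNS
    sets["marine"] = CrossoverSet(
        pd.concat([ev[XO_COLUMNS], extra], ignore_index=True))
    res = spotscan.ecotype_divergent_hotspots(
        sets, ann, downsample=None, n_shuffle=150, seed=5)
    mf = res[("freshwater", "marine")]
    reg = mf["regions"]
    assert len(reg) >= 1
    assert ((reg["chrom"] == "chr1") & (reg["start"] < 1_005_000)
            & (reg["end"] > 1_000_000)).any()


def test_coldspot_min_length_arithmetic():
    """10,000 crossovers on a 400-Mb genome: expected-5 gap length is
    5 x 400e6 / 10,000 = 200 kb."""
    ann = GenomeAnnotation({"chr1": 400_000_000})
    rng = np.random.default_rng(6)
    xs = synthetic_crossover_set(rng, n_events=10_000,
                                 chroms={"chr1": 400_000_000})
    res = spotscan.detect_coldspots({"all": xs}, ann)
    assert res["pools"]["all"]["min_length"] == pytest.approx(200_000)


def test_coldspot_counts_match_gap_simulation(ann):
    """The number of detected coldspots on uniform data is consistent with
    the empirical distribution of long uniform gaps."""
    rng = np.random.default_rng(7)
    n_obs = []
    for rep in range(10):
        xs = synthetic_crossover_set(np.random.default_rng(100 + rep),
                                     n_events=300)
        res = spotscan.detect_coldspots({"all": xs}, ann)
        n_obs.append(len(res["pools"]["all"]["coldspots"]))
    # oracle: direct simulation of uniform gaps
    G = ann.genome_length
    lam = 300 / G
    min_len = 5 / lam
    n_null = []
    for rep in range(200):
        tot = 0
        for L in ann.chrom_lengths.values():
            k = np.sort(rng.uniform(0, L, int(300 * L / G)))
            gaps = np.diff(np.concatenate([[0], k, [L]]))
            tot += int((gaps >= min_len).sum())
        n_null.append(tot)
    assert (np.mean(n_null) - 3 * np.std(n_null)
            <= np.mean(n_obs) <= np.mean(n_null) + 3 * np.std(n_null))


def test_coldspot_identical_pools_wilcoxon_not_extreme(ann):
    xs1 = synthetic_crossover_set(np.random.default_rng(8), n_events=400)
    xs2 = synthetic_crossover_set(np.random.default_rng(9), n_events=400)
    res = spotscan.detect_coldspots({"a": xs1, "b": xs2}, ann)
    if len(res["size_tests"]):
        assert res["size_tests"]["p"].iloc[0] > 0.001


def test_feature_association_whole_genome_feature(ann):
    xs = synthetic_crossover_set(np.random.default_rng(10), n_events=200)
    ann2 = GenomeAnnotation(dict(SMALL_CHROMS))
    ann2.add_intervals("all", pd.DataFrame(
        [{"chrom": c, "start": 0, "end": L} for c, L in SMALL_CHROMS.items()]))
    res = spotscan.feature_association(xs, ann2, n_shuffle=50, seed=11)
    assert res["observed"].iloc[0] == 1.0
    assert res["p"].iloc[0] == 1.0


def test_feature_association_planted_extreme_p(ann):
    rng = np.random.default_rng(12)
    pos = rng.integers(100_000, 2_900_000, 100)
    xs = synthetic_crossover_set(rng, n_events=100,
                                 chroms={"chr1": 3_000_000}, positions=pos)
    feats = pd.DataFrame({"chrom": "chr1", "start": pos - 50, "end": pos + 50})
    ann2 = GenomeAnnotation({"chr1": 3_000_000})
    ann2.add_intervals("planted", feats.sort_values("start"))
    n = 100
    res = spotscan.feature_association(xs, ann2, max_dist=100, n_shuffle=n,
                                       seed=13)
    assert res["p"].iloc[0] == pytest.approx(1 / (n + 1))


def test_feature_association_random_matches_null(ann):
    rng = np.random.default_rng(14)
    xs = synthetic_crossover_set(rng, n_events=400)
    feats = pd.DataFrame({"chrom": "chr1",
                          "start": np.sort(rng.integers(0, 2_900_000, 30)),
                          "end": 0})
    feats["end"] = feats["start"] + 1000
    ann2 = GenomeAnnotation(dict(SMALL_CHROMS))
    ann2.add_intervals("rand", feats)
    res = spotscan.feature_association(xs, ann2, n_shuffle=150, seed=15)
    assert abs(res["observed"].iloc[0] - res["null_mean"].iloc[0]) \
        <= 4 * max(res["null_sd"].iloc[0], 1e-3)


def test_peak_proximity_exact_and_constructed(ann):
    rng = np.random.default_rng(16)
    pos = np.asarray(sorted(rng.integers(100_000, 2_900_000, 200)))
    xs = synthetic_crossover_set(rng, n_events=200,
                                 chroms={"chr1": 3_000_000}, positions=pos)
    mids = xs.events["midpoint"].to_numpy()
    # peaks placed at 40% of crossover midpoints
    k = 80
    peaks = pd.DataFrame({"chrom": "chr1", "start": mids[:k] - 1,
                          "end": mids[:k] + 1})
    far = pd.DataFrame({"chrom": "chr2",
                        "start": rng.integers(0, 2_900_000, 120)})
    far["end"] = far["start"] + 2
    res = spotscan.peak_proximity(pd.concat([peaks, far], ignore_index=True),
                                  xs, max_dist=100)
    assert res["fraction_within"] == pytest.approx(0.40, abs=0.01)
    assert res["distances"][:k].max() <= 1
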