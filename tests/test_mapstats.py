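import itertools

import numpy as np
import pandas as pd
import pytest

from xomap.iocore import GenomeAnnotation
from xomap import mapstats as ms
from xomap.synthdata import SimFamilySpec, simulate_meiosis
from tests.conftest import SMALL_CHROMS, synthetic_crossover_set


@pytest.fixture(scope="module")
def ann():
    return GenomeAnnotation(dict(SMALL_CHROMS))


@pytest.fixture(scope="module")
def uni_set():
    return synthetic_crossover_set(np.random.default_rng(0), n_events=2000,
                                   n_offspring=50)


def test_map_length_arithmetic_from_totals():
    """Published totals reproduce the map lengths, heterochiasmy ratio and
    minimum-chiasmata estimates."""
    s = ms.map_summary_from_totals(31_809, 18_039, 1_669)
    assert round(s["mean_maternal"], 2) == 19.06
    assert round(s["mean_paternal"], 2) == 10.81
    assert round(s["map_cM_maternal"]) == 1906
    assert round(s["map_cM_paternal"]) == 1081
    assert round(s["map_cM_sex_averaged"]) == 1493
    assert round(s["heterochiasmy_ratio"], 2) == 1.76
    assert round(s["min_chiasmata_paternal"], 2) == 21.62
    assert round(s["min_chiasmata_maternal"], 2) == 38.12


def test_per_gamete_counts_include_zero_gametes(uni_set):
    pg = ms.per_gamete_counts(uni_set)
    assert pg["total_gametes"] == uni_set.n_gametes
    assert pg["per_gamete"]["count"].sum() == len(uni_set)
    # sex-averaged identity holds exactly
    assert pg["sex_averaged_cM"] == pytest.approx(
        100.0 * len(uni_set) / uni_set.n_gametes)


def test_chromosomes_with_crossover_bounds(uni_set, ann):
    rec = ms.chromosomes_with_crossover(uni_set, ann)
    per = rec["per_gamete"]["n_rec_chrom"]
    assert per.min() >= 0 and per.max() <= len(SMALL_CHROMS)


def test_periphery_uniform_is_thirty_percent(uni_set, ann):
    frac = ms.periphery_fraction(uni_set, ann, by_sex=False)
    n = len(uni_set)
    assert abs(frac - 0.30) < 3 * np.sqrt(0.3 * 0.7 / n)


def test_periphery_all_terminal(ann):
    rng = np.random.default_rng(1)
    pos = [int(0.05 * 3_000_000)] * 50
    xs = synthetic_crossover_set(rng, n_events=50, positions=pos)
    assert ms.periphery_fraction(xs, ann, by_sex=False) == 1.0


@pytest.mark.parametrize("counts,expected", [
    ([5, 5, 5, 5], 0.0),
    ([0] * 9 + [10], 0.9),          # all mass in 1 of 10 bins: 1 - 1/n
])
def test_gini_known_values(counts, expected):
    assert ms.gini_coefficient(np.array(counts)) == pytest.approx(expected)


def test_gini_matches_mean_absolute_difference():
    x = np.array([0, 0, 1, 3], dtype=float)
    brute = sum(abs(a - b) for a, b in itertools.product(x, x)) \
        / (2 * len(x) ** 2 * x.mean())
    assert ms.gini_coefficient(x) == pytest.approx(brute)


def test_gini_invariant_to_relabeling():
    rng = np.random.default_rng(2)
    x = rng.poisson(3, 50).astype(float)
    assert ms.gini_coefficient(x) == pytest.approx(
        ms.gini_coefficient(rng.permutation(x)))


def test_gini_single_bin():
    assert ms.gini_coefficient(np.array([7.0])) == 0.0


def test_windowed_rates_conservation(uni_set, ann):
    wt = ms.windowed_rates(uni_set, ann, window=500_000, step=500_000)
    total = wt.groupby(["family", "parent"])["count"].sum()
    ev_total = uni_set.events.groupby(["family", "parent"]).size()
    for k in ev_total.index:
        assert total[k] == ev_total[k]


def test_windowed_rate_units(ann):
    """One crossover among 93 gametes in a window = 100/93 = 1.075 cM."""
    rng = np.random.default_rng(3)
    xs = synthetic_crossover_set(rng, n_events=1, n_offspring=93,
                                 positions=[250_000])
    # force the event to be maternal so gametes=93 for that parent
    wt = ms.windowed_rates(xs, ann, window=500_000, step=500_000)
    hot = wt[wt["count"] == 1]
    assert len(hot) == 1
    assert hot["cM"].iloc[0] == pytest.approx(100 / 93)


def test_concentration_two_route(uni_set, ann):
    """The 80/35-style statistic equals a direct quantile computation on the
    sorted cumulative window counts."""
    window = 100_000
    frac = ms.concentration_fraction(uni_set, ann, mass=0.8, window=window)
    counts = []
    for chrom, L in ann.chrom_lengths.items():
        edges = np.arange(0, L + window, window)
        h, _ = np.histogram(
            uni_set.events.loc[uni_set.events["chrom"] == chrom, "midpoint"],
            bins=edges)
        counts.append(h)
    x = np.sort(np.concatenate(counts))[::-1]
    cum = np.cumsum(x) / x.sum()
    expected = (np.argmax(cum >= 0.8) + 1) / len(x)
    assert frac == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Interference
# ---------------------------------------------------------------------------

def _meiosis_set(nu_f, nu_m, n_gam=400, seed=0):
    spec = SimFamilySpec(chrom_lengths={"chr1": 20_000_000},
                         maternal_mean_xo=4.0, paternal_mean_xo=4.0,
                         interference_nu_f=nu_f, interference_nu_m=nu_m,
                         periphery_fraction_f=0.30, periphery_fraction_m=0.30)
    rng = np.random.default_rng(seed)
    rows = []
    from xomap.iocore import CrossoverSet, MATERNAL, PATERNAL
    gametes = []
    for i in range(n_gam):
        for parent, sex in ((MATERNAL, "F"), (PATERNAL, "M")):
            off = f"off{i:04d}"
            gametes.append({"family": "f", "offspring": off, "parent": parent,
                            "sex": sex, "ecotype": "marine"})
            bp, _ = simulate_meiosis(spec, sex, "chr1", rng)
            for x in bp:
                rows.append({"family": "f", "offspring": off, "parent": parent,
                             "sex": sex, "ecotype": "marine", "chrom": "chr1",
                             "left": int(x), "right": int(x) + 2})
    return CrossoverSet(pd.DataFrame(rows), gametes=pd.DataFrame(gametes))


def test_interference_detected_with_strong_shape():
    xs = _meiosis_set(nu_f=10.0, nu_m=10.0, n_gam=500)
    ann = GenomeAnnotation({"chr1": 20_000_000})
    res = ms.interference_test(xs, ann, n_null=200, seed=1)
    assert res["defined"] and res["p"] < 0.05


def test_interference_null_not_rejected():
    xs = _meiosis_set(nu_f=1.0, nu_m=1.0, n_gam=400, seed=2)
    ann = GenomeAnnotation({"chr1": 20_000_000})
    res = ms.interference_test(xs, ann, n_null=200, seed=3)
    assert res["p"] > 0.05


def test_interference_sex_ordering():
    """Stronger male interference gives larger mean inter-crossover distance
    and smaller CV in males than females."""
    xs = _meiosis_set(nu_f=1.0, nu_m=12.0, n_gam=500, seed=4)
    ann = GenomeAnnotation({"chr1": 20_000_000})
    f = ms.interference_test(xs, ann, n_null=10, seed=5, sex="F")
    m = ms.interference_test(xs, ann, n_null=10, seed=6, sex="M")
    assert m["mean_distance"] > f["mean_distance"]
    assert m["cv_distance"] < f["cv_distance"]


def test_interference_undefined_without_multi_crossover_gametes(ann):
    from xomap.iocore import CrossoverSet
    ev = pd.DataFrame([
        {"family": "f", "offspring": f"o{i}", "parent": "maternal",
         "sex": "F", "ecotype": "marine", "chrom": "chr1",
         "left": 1000 * (i + 1), "right": 1000 * (i + 1) + 10}
        for i in range(10)])
    res = ms.interference_test(CrossoverSet(ev), ann, n_null=10, seed=8)
    assert res["defined"] is False
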