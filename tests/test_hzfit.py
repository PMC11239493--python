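import itertools

import numpy as np
import pandas as pd
import pytest

from xomap import hzfit as hz
from xomap.iocore import XomapError
from xomap.synthdata import SimCohortSpec, simulate_cohort


ALL_GENOTYPES = list(itertools.product(["MM", "FF", "FM"], repeat=5))


def test_score_dp_equals_bruteforce_all_243():
    mx = 0
    for g in ALL_GENOTYPES:
        a = hz.min_crossover_score(g)
        assert a == hz.min_crossover_score_bruteforce(g)
        mx = max(mx, a)
    assert mx == 8   # the published maximum for five loci


@pytest.mark.parametrize("g,expected", [
    (["FM"] * 5, 0),
    (["MM", "FF", "MM", "FF", "MM"], 8),
    (["MM", "FM", "FF"], 2),
    (["MM", "missing", "MM"], 0),
    (["MM"], 0),                       # <2 informative loci
    (["MM", "missing", "FF"], 2),
])
def test_score_known_values(g, expected):
    assert hz.min_crossover_score(g) == expected


def test_score_invariances():
    flip = {"MM": "FF", "FF": "MM", "FM": "FM"}
    for g in ALL_GENOTYPES[::7]:
        s = hz.min_crossover_score(g)
        assert hz.min_crossover_score(list(g)[::-1]) == s
        assert hz.min_crossover_score([flip[x] for x in g]) == s


def test_residual_length_centres_dates():
    df = pd.DataFrame({
        "date": ["a"] * 3 + ["b"] * 3,
        "length_mm": [10.0, 12.0, 14.0, 30.0, 31.0, 35.0]})
    r = hz.residual_length(df)
    assert r[:3].sum() == pytest.approx(0.0)
    assert r[3:].sum() == pytest.approx(0.0)
    assert r.iloc[0] == pytest.approx(-2.0)
    assert r.iloc[5] == pytest.approx(3.0)


def test_residual_orthogonal_to_date():
    spec = SimCohortSpec(n_fry=100, n_juvenile=100)
    c = simulate_cohort(spec, np.random.default_rng(0))
    r = hz.residual_length(c)
    for _, sub in pd.concat([c, r], axis=1).groupby("date"):
        assert sub["residual_length"].sum() == pytest.approx(0.0, abs=1e-8)


def test_size_vs_score_recovers_penalty():
    """A cohort simulated with 0.5 mm penalty per event yields slope
    ~ -0.5."""
    spec = SimCohortSpec(size_penalty=0.5, viability_per_event=1.0,
                         n_fry=400, n_juvenile=400, size_sd=1.0)
    c = simulate_cohort(spec, np.random.default_rng(1))
    res = hz.size_vs_score(c)
    assert res["defined"]
    assert res["slope"] == pytest.approx(-0.5, abs=2.5 * res["se"])
    assert res["p"] < 0.01


def test_size_vs_score_null():
    spec = SimCohortSpec(size_penalty=0.0, viability_per_event=1.0,
                         n_fry=200, n_juvenile=200)
    c = simulate_cohort(spec, np.random.default_rng(2))
    res = hz.size_vs_score(c)
    assert abs(res["slope"]) < 3 * res["se"] + 0.2


def test_size_vs_score_constant_flagged():
    spec = SimCohortSpec(recombinant_fraction=0.0, n_fry=30, n_juvenile=30)
    c = simulate_cohort(spec, np.random.default_rng(3))
    res = hz.size_vs_score(c)
    assert res["defined"] is False


def test_epistasis_detects_mismatch_penalty():
    """A penalty applied only to mismatched two-locus genotypes produces an
    interaction and a negative mismatched-vs-matched contrast."""
    rng = np.random.default_rng(4)
    n = 500
    g1 = rng.choice(["MM", "FF"], n)
    g2 = rng.choice(["MM", "FF"], n)
    length = 30 + rng.normal(0, 1, n) - 3.0 * (g1 != g2)
    c = pd.DataFrame({"id": range(n), "date": "d1", "stage": "fry",
                      "length_mm": length,
                      "chr4_100": g1, "chr4_200": g2})
    res = hz.epistasis_scan(c, pairs=[("chr4_100", "chr4_200")])
    r = res.iloc[0]
    assert not r["degenerate"]
    assert r["p_interaction"] < 0.01
    assert r["mismatched_minus_matched"] < -2.0
    assert r["contrast_t"] < 0 and r["contrast_p"] < 0.01


def test_epistasis_additive_only_calibrated():
    rng = np.random.default_rng(5)
    hits = 0
    reps = 30
    for _ in range(reps):
        n = 200
        g1 = rng.choice(["MM", "FF", "FM"], n)
        g2 = rng.choice(["MM", "FF", "FM"], n)
        length = 30 + (g1 == "MM") * 1.0 + (g2 == "FF") * 0.5 \
            + rng.normal(0, 1, n)
        c = pd.DataFrame({"id": range(n), "date": "d1", "stage": "fry",
                          "length_mm": length,
                          "chr4_1": g1, "chr4_2": g2})
        res = hz.epistasis_scan(c, pairs=[("chr4_1", "chr4_2")])
        hits += int(res.iloc[0]["p_interaction"] < 0.05)
    assert hits / reps < 0.15


def test_epistasis_degenerate_flagged():
    c = pd.DataFrame({"id": range(20), "date": "d1", "stage": "fry",
                      "length_mm": 30.0,
                      "chr4_1": ["MM"] * 20, "chr4_2": ["MM"] * 20})
    res = hz.epistasis_scan(c, pairs=[("chr4_1", "chr4_2")])
    assert bool(res.iloc[0]["degenerate"])


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def test_ld_complete_coupling():
    g = ["MM"] * 10 + ["FF"] * 10
    res = hz.ld_r2_em(g, g)
    assert res["r2"] == pytest.approx(1.0)


def test_ld_independent_loci_near_zero():
    rng = np.random.default_rng(6)
    n = 2000
    g1 = rng.choice(["MM", "FM", "FF"], n, p=[0.25, 0.5, 0.25])
    g2 = rng.choice(["MM", "FM", "FF"], n, p=[0.25, 0.5, 0.25])
    res = hz.ld_r2_em(g1, g2)
    assert res["r2"] < 0.01


def test_ld_em_matches_counting_on_unambiguous_data():
    """Without double heterozygotes the EM estimate equals direct haplotype
    counting."""
    rng = np.random.default_rng(7)
    haps = [(1, 1), (1, 0), (0, 1), (0, 0)]
    p = np.array([0.4, 0.1, 0.2, 0.3])
    n = 200
    while True:
        h1 = rng.choice(4, n, p=p)
        h2 = rng.choice(4, n, p=p)
        a1 = np.array([haps[i][0] for i in h1]) + \
            np.array([haps[i][0] for i in h2])
        a2 = np.array([haps[i][1] for i in h1]) + \
            np.array([haps[i][1] for i in h2])
        keep = ~((a1 == 1) & (a2 == 1))
        if keep.sum() >= 50:
            break
    code = {2: "MM", 1: "FM", 0: "FF"}
    g1 = [code[x] for x in a1[keep]]
    g2 = [code[x] for x in a2[keep]]
    res = hz.ld_r2_em(g1, g2)
    # direct counting oracle on the phased haplotypes
    hcnt = np.zeros(4)
    for arr in (h1[keep], h2[keep]):
        for i in arr:
            hcnt[i] += 1
    hf = hcnt / hcnt.sum()
    pA = hf[0] + hf[1]
    pB = hf[0] + hf[2]
    D = hf[0] - pA * pB
    r2 = D ** 2 / (pA * (1 - pA) * pB * (1 - pB))
    assert res["r2"] == pytest.approx(r2, abs=1e-6)


def test_ld_monomorphic_flagged():
    res = hz.ld_r2_em(["MM"] * 20, ["MM"] * 10 + ["FF"] * 10)
    assert res["defined"] is False


def test_ld_allele_relabeling_invariance():
    rng = np.random.default_rng(8)
    g1 = rng.choice(["MM", "FM", "FF"], 100)
    g2 = rng.choice(["MM", "FM", "FF"], 100)
    flip = {"MM": "FF", "FF": "MM", "FM": "FM"}
    a = hz.ld_r2_em(g1, g2)
    b = hz.ld_r2_em([flip[x] for x in g1], g2)
    assert a["r2"] == pytest.approx(b["r2"], abs=1e-6)


# ---------------------------------------------------------------------------
# Temporal comparison
# ---------------------------------------------------------------------------

def test_temporal_thinning_direction():
    """Viability < 1 per event lowers the juvenile mean score and increases
    adjacent-pair LD."""
    spec = SimCohortSpec(viability_per_event=0.5, n_fry=400, n_juvenile=400,
                         recombinant_fraction=0.25)
    c = simulate_cohort(spec, np.random.default_rng(9))
    res = hz.temporal_comparison(c)
    assert res["mean_juvenile"] < res["mean_fry"]
    assert res["t"] > 0 and res["p"] < 0.05
    adj = [res["delta_r2"].iloc[i, i + 1] for i in range(4)]
    assert np.nanmean(adj) > 0


def test_temporal_identical_stages_null():
    rng = np.random.default_rng(10)
    spec = SimCohortSpec(viability_per_event=1.0, n_fry=200, n_juvenile=200)
    c = simulate_cohort(spec, rng)
    res = hz.temporal_comparison(c)
    assert abs(res["t"]) < 3.5


def test_temporal_one_stage_fatal():
    spec = SimCohortSpec(n_fry=30, n_juvenile=30)
    c = simulate_cohort(spec, np.random.default_rng(11))
    with pytest.raises(XomapError):
        hz.temporal_comparison(c[c["stage"] == "fry"])
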