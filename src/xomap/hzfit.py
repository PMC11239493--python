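"""Hybrid-zone fitness analysis.

Each fish carries genotypes at five linked marine/freshwater-divergent loci
on one chromosome, coded MM / FF / FM (or missing).  The minimum-crossover
score is the smallest number of crossover events, over all phase
assignments, needed to explain the multi-locus genotype: marine (MMMMM),
freshwater (FFFFF) and F1 hybrids score 0; the maximum for five loci is 8.

Fitness proxies: residual standard length (length centred on its sampling-
date mean) regressed on the score and on two-locus genotype combinations;
temporal change in mean score and in two-locus LD (R^2 from unphased
genotypes via EM) between fry and juvenile stages.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .iocore import XomapError, log

GENO_STATES = ("MM", "FF", "FM")


# ---------------------------------------------------------------------------
# Minimum-crossover score
# ---------------------------------------------------------------------------

_ALLELES = {"MM": [("M", "M")], "FF": [("F", "F")],
            "FM": [("M", "F"), ("F", "M")],
            "missing": [(a, b) for a in "MF" for b in "MF"]}


def min_crossover_score(genotypes) -> int:
    """Minimum number of crossovers explaining a multi-locus genotype.

    ``genotypes``: sequence of 'MM' / 'FF' / 'FM' / 'missing' in locus
    order.  Dynamic programme over the (hap1 allele, hap2 allele) phase
    state at each locus; missing loci are free wildcards (conservative
    lower bound).  Fewer than two informative loci score 0.
    """
    g = [x if x in _ALLELES else "missing" for x in genotypes]
    informative = [x for x in g if x != "missing"]
    if len(informative) < 2:
        log.debug("min_crossover_score: <2 informative loci; score 0")
        return 0
    states = _ALLELES[g[0]]
    best = {s: 0 for s in states}
    for geno in g[1:]:
        nxt = {}
        for s2 in _ALLELES[geno]:
            cost = min(best[s1] + (s1[0] != s2[0]) + (s1[1] != s2[1])
                       for s1 in best)
            nxt[s2] = cost
        best = nxt
    return int(min(best.values()))


def min_crossover_score_bruteforce(genotypes) -> int:
    """Exhaustive-enumeration oracle for :func:`min_crossover_score`."""
    g = [x if x in _ALLELES else "missing" for x in genotypes]
    if len([x for x in g if x != "missing"]) < 2:
        return 0
    best = None
    for combo in itertools.product(*[_ALLELES[x] for x in g]):
        h1 = [c[0] for c in combo]
        h2 = [c[1] for c in combo]
        cost = sum(a != b for a, b in zip(h1, h1[1:])) \
            + sum(a != b for a, b in zip(h2, h2[1:]))
        best = cost if best is None else min(best, cost)
    return int(best)


# ---------------------------------------------------------------------------
# Cohort preparation and length models
# ---------------------------------------------------------------------------

def locus_columns(cohort: pd.DataFrame) -> list[str]:
    return [c for c in cohort.columns if c.startswith("chr") and "_" in c]


def add_scores(cohort: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Attach the minimum-crossover score.

    Missing locus genotypes are free wildcards (conservative lower bound);
    with ``strict=True`` individuals with any missing locus are dropped
    instead."""
    cols = locus_columns(cohort)
    out = cohort.copy()
    if strict:
        out = out.dropna(subset=cols).reset_index(drop=True)
    out["min_crossover"] = [
        min_crossover_score([r[c] if pd.notna(r[c]) else "missing"
                             for c in cols])
        for _, r in out.iterrows()]
    return out


def residual_length(cohort: pd.DataFrame) -> pd.Series:
    """Length minus sampling-date mean (OLS on the date factor)."""
    out = np.empty(len(cohort))
    for date, sub in cohort.groupby("date"):
        if len(sub) == 1:
            out[cohort.index.get_indexer(sub.index)] = 0.0
            log.info("residual_length: singleton date %s -> residual 0", date)
        else:
            out[cohort.index.get_indexer(sub.index)] = (
                sub["length_mm"] - sub["length_mm"].mean())
    return pd.Series(out, index=cohort.index, name="residual_length")


def size_vs_score(cohort: pd.DataFrame) -> dict:
    """OLS of residual standard length on the minimum-crossover score, plus
    companion models adding each single-locus genotype as a main effect and
    as an interaction."""
    d = add_scores(cohort)
    d["residual_length"] = residual_length(d)
    if d["min_crossover"].nunique() < 2:
        return {"defined": False, "reason": "constant score"}
    base = smf.ols("residual_length ~ min_crossover", data=d).fit()
    an = base.f_test("min_crossover = 0")
    res = {"defined": True, "fit": base,
           "slope": float(base.params["min_crossover"]),
           "se": float(base.bse["min_crossover"]),
           "F": float(an.fvalue), "p": float(an.pvalue),
           "df_resid": int(base.df_resid)}
    companions = {}
    for c in locus_columns(d):
        if d[c].nunique() < 2:
            continue
        main = smf.ols(f"residual_length ~ min_crossover + C({c})", data=d).fit()
        inter = smf.ols(f"residual_length ~ min_crossover * C({c})", data=d).fit()
        companions[c] = {
            "score_p_with_main": float(main.pvalues["min_crossover"]),
            "score_slope_with_main": float(main.params["min_crossover"]),
            "interaction_p": float(inter.compare_f_test(main)[1]),
        }
    res["companions"] = companions
    return res


# ---------------------------------------------------------------------------
# Two-locus epistasis
# ---------------------------------------------------------------------------

def epistasis_scan(cohort: pd.DataFrame,
                   pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Two-locus genotype interaction ANOVA on residual length with post hoc
    contrasts of mismatched vs matched genotype combinations."""
    d = cohort.copy()
    d["residual_length"] = residual_length(d)
    cols = locus_columns(d)
    pairs = pairs or list(itertools.combinations(cols, 2))
    rows = []
    for a, b in pairs:
        sub = d.dropna(subset=[a, b])
        if sub[a].nunique() < 2 or sub[b].nunique() < 2:
            rows.append({"locus_a": a, "locus_b": b, "degenerate": True})
            continue
        add = smf.ols(f"residual_length ~ C({a}) + C({b})", data=sub).fit()
        full = smf.ols(f"residual_length ~ C({a}) * C({b})", data=sub).fit()
        Fint, pint, _ = full.compare_f_test(add)
        matched = sub[((sub[a] == "MM") & (sub[b] == "MM"))
                      | ((sub[a] == "FF") & (sub[b] == "FF"))]
        mism = sub[((sub[a] == "MM") & (sub[b] == "FF"))
                   | ((sub[a] == "FF") & (sub[b] == "MM"))
                   | ((sub[a] == "FM") ^ (sub[b] == "FM"))]
        contrast = np.nan
        cp = np.nan
        if len(matched) > 1 and len(mism) > 1:
            t = stats.ttest_ind(mism["residual_length"],
                                matched["residual_length"], equal_var=False)
            contrast, cp = float(t.statistic), float(t.pvalue)
        rows.append({"locus_a": a, "locus_b": b, "degenerate": False,
                     "F_interaction": float(Fint), "p_interaction": float(pint),
                     "mismatched_minus_matched":
                         float(mism["residual_length"].mean()
                               - matched["residual_length"].mean())
                         if len(matched) and len(mism) else np.nan,
                     "contrast_t": contrast, "contrast_p": cp})
    out = pd.DataFrame(rows)
    if "contrast_p" in out:
        ok = out["contrast_p"].notna()
        out.loc[ok, "contrast_p_bh"] = _bh(out.loc[ok, "contrast_p"].to_numpy())
    return out


def _bh(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Two-locus LD via EM
# ---------------------------------------------------------------------------

def ld_r2_em(g1, g2, tol: float = 1e-8, max_iter: int = 1000) -> dict:
    """D, D' and R^2 between two loci from unphased MM/FF/FM genotypes.

    EM resolves double-heterozygote phase ambiguity into maximum-likelihood
    haplotype frequencies.  The 'M' allele is the reference allele at both
    loci.
    """
    d1 = pd.Series(g1).map({"MM": 2, "FM": 1, "FF": 0})
    d2 = pd.Series(g2).map({"MM": 2, "FM": 1, "FF": 0})
    ok = d1.notna() & d2.notna()
    x = d1[ok].to_numpy(int)
    y = d2[ok].to_numpy(int)
    n = len(x)
    if n < 10:
        raise XomapError("ld_r2_em needs >= 10 individuals")
    pM1 = x.mean() / 2
    pM2 = y.mean() / 2
    if pM1 in (0.0, 1.0) or pM2 in (0.0, 1.0):
        return {"defined": False, "reason": "monomorphic locus"}
    # haplotypes: 0 = MM, 1 = MF, 2 = FM, 3 = FF (locus1 allele, locus2 allele)
    h = np.array([pM1 * pM2, pM1 * (1 - pM2), (1 - pM1) * pM2,
                  (1 - pM1) * (1 - pM2)])
    dh = (x == 1) & (y == 1)
    n_dh = int(dh.sum())

    def hap_idx(a1: int, a2: int) -> int:
        # haplotype order in h: MM=0, MF=1, FM=2, FF=3 (1 = M allele)
        return (0 if a1 else 2) + (0 if a2 else 1)

    # phase is unique for every genotype pair except the double het
    base = np.zeros(4)
    for xi, yi in zip(x[~dh], y[~dh]):
        a1 = [1, 1] if xi == 2 else [0, 0] if xi == 0 else [1, 0]
        a2 = [1, 1] if yi == 2 else [0, 0] if yi == 0 else [1, 0]
        base[hap_idx(a1[0], a2[0])] += 1
        base[hap_idx(a1[1], a2[1])] += 1
    for _ in range(max_iter):
        # E: split double hets between coupling (MM/FF) and repulsion (MF/FM)
        pc = h[0] * h[3]
        pr = h[1] * h[2]
        w = pc / (pc + pr) if (pc + pr) > 0 else 0.5
        cnt = base.copy()
        cnt[0] += n_dh * w
        cnt[3] += n_dh * w
        cnt[1] += n_dh * (1 - w)
        cnt[2] += n_dh * (1 - w)
        new = cnt / cnt.sum()
        if np.max(np.abs(new - h)) < tol:
            h = new
            break
        h = new
    pA = h[0] + h[1]   # M at locus 1
    pB = h[0] + h[2]   # M at locus 2
    D = h[0] - pA * pB
    dmax = min(pA * (1 - pB), (1 - pA) * pB) if D > 0 else \
        min(pA * pB, (1 - pA) * (1 - pB))
    r2 = D ** 2 / (pA * (1 - pA) * pB * (1 - pB))
    return {"defined": True, "D": float(D),
            "Dprime": float(D / dmax) if dmax > 0 else np.nan,
            "r2": float(r2), "hap_freqs": h, "n": n}


# ---------------------------------------------------------------------------
# Temporal comparison
# ---------------------------------------------------------------------------

def temporal_comparison(cohort: pd.DataFrame) -> dict:
    """Welch t-test of fry vs juvenile mean minimum-crossover score, plus
    pairwise R^2 matrices per stage and their difference."""
    d = add_scores(cohort)
    stages = {s: sub for s, sub in d.groupby("stage")}
    if "fry" not in stages or "juvenile" not in stages:
        raise XomapError("both fry and juvenile stages required")
    fry = stages["fry"]["min_crossover"]
    juv = stages["juvenile"]["min_crossover"]
    t = stats.ttest_ind(fry, juv, equal_var=False)
    cols = locus_columns(d)
    mats = {}
    for s in ("fry", "juvenile"):
        m = pd.DataFrame(np.nan, index=cols, columns=cols)
        for a, b in itertools.combinations(cols, 2):
            try:
                r = ld_r2_em(stages[s][a], stages[s][b])
            except XomapError:
                continue
            if r.get("defined"):
                m.loc[a, b] = m.loc[b, a] = r["r2"]
        mats[s] = m
    delta = mats["juvenile"] - mats["fry"]
    return {"mean_fry": float(fry.mean()), "mean_juvenile": float(juv.mean()),
            "t": float(t.statistic), "p": float(t.pvalue),
            "df": float(t.df), "r2_fry": mats["fry"],
            "r2_juvenile": mats["juvenile"], "delta_r2": delta}
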