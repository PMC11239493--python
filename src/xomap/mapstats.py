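"""Recombination-map summaries.

Per-gamete crossover counts, genetic map lengths, heterochiasmy, recombinant
chromosomes per gamete, periphery bias, crossover interference, Gini
heterogeneity of the genomic crossover distribution, and windowed rates.

Throughout, the location of a crossover is its interval midpoint.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .iocore import CrossoverSet, GenomeAnnotation, XomapError

IND_KEY = ["family", "parent", "sex", "ecotype"]


# ---------------------------------------------------------------------------
# Per-gamete counts and map lengths
# ---------------------------------------------------------------------------

def map_summary_from_totals(total_maternal: int, total_paternal: int,
                            n_gametes_per_sex: int) -> dict:
    """Map-length arithmetic from crossover totals.

    Mean per gamete, map length (cM = 100 x mean), sex-averaged map length,
    female/male ratio (heterochiasmy strength) and the minimum-chiasmata
    estimate (2 x per-gamete mean: each chiasma reaches a given gamete with
    probability 1/2)."""
    mean_f = total_maternal / n_gametes_per_sex
    mean_m = total_paternal / n_gametes_per_sex
    return {
        "mean_maternal": mean_f, "mean_paternal": mean_m,
        "map_cM_maternal": 100.0 * mean_f, "map_cM_paternal": 100.0 * mean_m,
        "map_cM_sex_averaged": 100.0 * (total_maternal + total_paternal)
        / (2 * n_gametes_per_sex),
        "heterochiasmy_ratio": mean_f / mean_m,
        "min_chiasmata_maternal": 2.0 * mean_f,
        "min_chiasmata_paternal": 2.0 * mean_m,
    }


def per_gamete_counts(xoset: CrossoverSet) -> dict:
    """Per-gamete counts, per-parent-sex means, map lengths and minimum
    chiasmata estimates.

    Map length in cM = 100 x mean crossovers per gamete; the sex-averaged
    map length uses all meiotic products jointly.  The minimum chiasmata
    estimate doubles the per-gamete mean (each chiasma is transmitted to a
    given gamete with probability 1/2).
    """
    if xoset.n_gametes == 0:
        raise XomapError("crossover set has no gametes")
    counts = xoset.counts_per_gamete()
    by_sex = counts.groupby("sex")["count"]
    summary = pd.DataFrame({
        "n_gametes": by_sex.size(),
        "total": by_sex.sum(),
        "mean": by_sex.mean(),
        "sem": by_sex.sem(),
    })
    summary["map_cM"] = 100.0 * summary["mean"]
    summary["min_chiasmata"] = 2.0 * summary["mean"]
    sex_avg = 100.0 * counts["count"].sum() / len(counts)
    return {"per_gamete": counts, "per_sex": summary,
            "sex_averaged_cM": float(sex_avg),
            "total_crossovers": int(counts["count"].sum()),
            "total_gametes": int(len(counts))}


def chromosomes_with_crossover(xoset: CrossoverSet,
                               annotation: GenomeAnnotation) -> dict:
    """Per-gamete count of chromosomes carrying >= 1 crossover."""
    n_chrom = len(annotation.chrom_lengths)
    key = ["family", "offspring", "parent"]
    ev = xoset.events
    rec = ev.groupby(key)["chrom"].nunique().rename("n_rec_chrom")
    per = xoset.gametes.set_index(key).join(rec).fillna({"n_rec_chrom": 0})
    per["n_rec_chrom"] = per["n_rec_chrom"].astype(int)
    per = per.reset_index()
    by_sex = per.groupby("sex")["n_rec_chrom"].agg(["mean", "sem", "size"])
    by_sex["fraction"] = by_sex["mean"] / n_chrom
    return {"per_gamete": per, "per_sex": by_sex, "n_chrom": n_chrom}


# ---------------------------------------------------------------------------
# Periphery bias
# ---------------------------------------------------------------------------

def periphery_fraction(xoset: CrossoverSet, annotation: GenomeAnnotation,
                       terminal: float = 0.15,
                       gap_mask: pd.DataFrame | None = None,
                       by_sex: bool = True):
    """Fraction of crossover midpoints in the terminal ``terminal`` of their
    chromosome (both ends).  Events overlapping a scaffold-gap mask (BED)
    are excluded when a mask is given."""
    ev = xoset.events
    if gap_mask is not None and len(gap_mask):
        from .iocore import points_in_intervals
        drop = np.zeros(len(ev), dtype=bool)
        for col in ("left", "right"):
            drop |= points_in_intervals(ev["chrom"].to_numpy(),
                                        ev[col].to_numpy(), gap_mask)
        ev = ev[~drop]
    L = ev["chrom"].map(annotation.chrom_lengths).to_numpy(dtype=float)
    m = ev["midpoint"].to_numpy(dtype=float)
    in_term = (m <= terminal * L) | (m >= (1 - terminal) * L)
    if not by_sex:
        return float(in_term.mean()) if len(ev) else float("nan")
    out = (pd.DataFrame({"sex": ev["sex"].to_numpy(), "t": in_term})
           .groupby("sex")["t"].agg(["mean", "size"]))
    out.columns = ["fraction", "n"]
    return out


# ---------------------------------------------------------------------------
# Interference
# ---------------------------------------------------------------------------

def _inter_distances(ev: pd.DataFrame) -> np.ndarray:
    d = []
    for _, sub in ev.groupby(["family", "offspring", "parent", "chrom"]):
        if len(sub) >= 2:
            m = np.sort(sub["midpoint"].to_numpy())
            d.append(np.diff(m))
    return np.concatenate(d) if d else np.array([])


def interference_test(xoset: CrossoverSet, annotation: GenomeAnnotation,
                      n_null: int = 1000, seed: int = 0,
                      sex: str | None = None) -> dict:
    """Compare observed inter-crossover distances to a null in which the same
    per-gamete crossover counts are re-placed independently from the pooled
    marginal crossover density (conditioning on counts isolates positional
    interference from count variation).

    Returns KS statistic, empirical p, and mean/CV of distances.
    """
    rng = np.random.default_rng(seed)
    ev = xoset.events if sex is None else xoset.events[xoset.events["sex"] == sex]
    obs = _inter_distances(ev)
    if len(obs) == 0:
        return {"defined": False}
    pooled = {c: sub["midpoint"].to_numpy(dtype=float)
              for c, sub in ev.groupby("chrom")}
    gamete_counts = (ev.groupby(["family", "offspring", "parent", "chrom"])
                     .size())

    def one_null():
        d = []
        for (fam, off, par, chrom), k in gamete_counts.items():
            if k >= 2:
                pts = np.sort(rng.choice(pooled[chrom], size=k, replace=True))
                d.append(np.diff(pts))
        return np.concatenate(d) if d else np.array([])

    null_sets = [one_null() for _ in range(n_null)]
    reference = np.concatenate(null_sets)
    d_obs = stats.ks_2samp(obs, reference).statistic
    d_null = np.array([stats.ks_2samp(s, reference).statistic
                       for s in null_sets])
    p = (1 + np.sum(d_null >= d_obs)) / (1 + n_null)
    return {"defined": True, "ks_D": float(d_obs), "p": float(p),
            "mean_distance": float(obs.mean()),
            "cv_distance": float(obs.std(ddof=1) / obs.mean())
            if len(obs) > 1 else float("nan"),
            "n_distances": int(len(obs))}


# ---------------------------------------------------------------------------
# Gini heterogeneity
# ---------------------------------------------------------------------------

def gini_coefficient(counts: np.ndarray) -> float:
    """Gini coefficient of per-bin crossover counts (Lorenz-curve form)."""
    x = np.sort(np.asarray(counts, dtype=float))
    n = len(x)
    if n <= 1 or x.sum() == 0:
        return 0.0
    # equivalent to sum |xi - xj| / (2 n^2 mean)
    i = np.arange(1, n + 1)
    return float((2 * np.sum(i * x) / (n * x.sum())) - (n + 1) / n)


def gini(xoset: CrossoverSet, annotation: GenomeAnnotation,
         bin_sizes=(100_000, 500_000, 1_000_000)) -> pd.Series:
    """Gini coefficient of the pooled crossover distribution per bin size."""
    if len(xoset) == 0:
        raise XomapError("gini requires at least one crossover")
    out = {}
    ev = xoset.events
    for b in bin_sizes:
        counts = []
        for chrom, L in annotation.chrom_lengths.items():
            edges = np.arange(0, L + b, b)
            m = ev.loc[ev["chrom"] == chrom, "midpoint"].to_numpy()
            h, _ = np.histogram(m, bins=edges)
            counts.append(h)
        out[b] = gini_coefficient(np.concatenate(counts))
    return pd.Series(out, name="gini")


# ---------------------------------------------------------------------------
# Windowed rates
# ---------------------------------------------------------------------------

def windowed_rates(xoset: CrossoverSet, annotation: GenomeAnnotation,
                   window: int = 500_000, step: int | None = None) -> pd.DataFrame:
    """Per-individual crossover counts and rates in (sliding) windows.

    One individual = one parent of one family.  Rate in cM = 100 x count /
    gametes of that parent; cM/Mb divides by window size.  ``step`` defaults
    to window/2; ``step == window`` gives a non-overlapping tiling.
    """
    step = step or max(window // 2, 1)
    gam = xoset.gametes.groupby(IND_KEY).size().rename("n_gametes").reset_index()
    ev = xoset.events
    rows = []
    for chrom, L in annotation.chrom_lengths.items():
        starts = np.arange(0, max(L - window, 0) + step, step)
        if len(starts) == 0 or (L <= window):
            starts = np.array([0])
        ends = np.minimum(starts + window, L)
        sub = ev[ev["chrom"] == chrom]
        for _, ind in gam.iterrows():
            m = sub[(sub["family"] == ind["family"])
                    & (sub["parent"] == ind["parent"])]["midpoint"].to_numpy()
            m.sort()
            lo = np.searchsorted(m, starts, side="right")   # midpoint > start
            hi = np.searchsorted(m, ends, side="right")     # midpoint <= end
            cnt = hi - lo
            for s, e, c in zip(starts, ends, cnt):
                rows.append({
                    "chrom": chrom, "start": int(s), "end": int(e),
                    "family": ind["family"], "parent": ind["parent"],
                    "sex": ind["sex"], "ecotype": ind["ecotype"],
                    "count": int(c),
                    "cM": 100.0 * c / ind["n_gametes"],
                })
    wt = pd.DataFrame(rows)
    if len(wt):
        wt["cM_per_Mb"] = wt["cM"] / ((wt["end"] - wt["start"]) / 1e6)
    return wt


def concentration_fraction(xoset: CrossoverSet, annotation: GenomeAnnotation,
                           mass: float = 0.8, window: int = 100_000) -> float:
    """Smallest genome fraction whose windows hold ``mass`` of all
    crossovers (the '80% of crossovers in <35% of the genome' statistic)."""
    counts = []
    ev = xoset.events
    for chrom, L in annotation.chrom_lengths.items():
        edges = np.arange(0, L + window, window)
        h, _ = np.histogram(ev.loc[ev["chrom"] == chrom, "midpoint"], bins=edges)
        counts.append(h)
    x = np.sort(np.concatenate(counts))[::-1]
    if x.sum() == 0:
        return float("nan")
    cum = np.cumsum(x) / x.sum()
    k = int(np.searchsorted(cum, mass) + 1)
    return k / len(x)
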