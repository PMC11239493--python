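"""Hotspot / coldspot detection and feature-association statistics.

Hotspots are genome-tiling 5-kb windows whose crossover-midpoint counts
exceed what per-chromosome uniform shuffles produce at 5% FDR.  Ecotype-
divergent hotspots follow an MA-style test: ecotype sets are down-sampled to
equal size, per-window log2 fold changes (pseudocount 0.1) are compared with
count-conditional 2.5% quantile envelopes from random splits, and windows
must also carry at least six crossovers among the compared fish.  Coldspots
are maximal zero-crossover runs long enough to expect at least five
crossovers under a pool-specific uniform intensity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .iocore import CrossoverSet, GenomeAnnotation, XomapError, log


def uniform_cooccurrence_probability(k: int, window: float, G: float) -> float:
    """Probability that k independent uniformly placed crossovers fall within
    one given window of a genome of length G: (window/G)**k."""
    return float((window / G) ** k)


# ---------------------------------------------------------------------------
# Pooled hotspot detection
# ---------------------------------------------------------------------------

def _window_counts(midpoints: dict, annotation: GenomeAnnotation,
                   window: int) -> pd.DataFrame:
    rows = []
    for chrom, L in annotation.chrom_lengths.items():
        edges = np.arange(0, L + window, window)
        m = midpoints.get(chrom, np.array([]))
        h, _ = np.histogram(m, bins=edges)
        rows.append(pd.DataFrame({"chrom": chrom,
                                  "start": edges[:-1].astype(int),
                                  "end": np.minimum(edges[1:], L).astype(int),
                                  "count": h}))
    return pd.concat(rows, ignore_index=True)


def _merge_adjacent(df: pd.DataFrame) -> pd.DataFrame:
    """Merge adjacent/overlapping flagged windows into regions."""
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "count"])
    out = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom"):
        cur = None
        for _, r in sub.iterrows():
            if cur is not None and r["start"] <= cur["end"]:
                cur["end"] = max(cur["end"], r["end"])
                cur["count"] += r["count"]
            else:
                if cur is not None:
                    out.append(cur)
                cur = {"chrom": chrom, "start": int(r["start"]),
                       "end": int(r["end"]), "count": int(r["count"])}
        out.append(cur)
    return pd.DataFrame(out)


def detect_hotspots(xoset: CrossoverSet, annotation: GenomeAnnotation,
                    window: int = 5000, fdr: float = 0.05,
                    n_perm: int = 200, seed: int = 0) -> dict:
    """Pooled hotspot detection with permutation FDR.

    The null relocates every crossover midpoint uniformly within its
    chromosome; per count threshold k, FDR(k) = mean null windows >= k /
    observed windows >= k.  Hotspots are windows at the smallest k with
    FDR < ``fdr``; adjacent hot windows are merged.
    """
    if n_perm < 100:
        log.warning("detect_hotspots: n_perm=%d gives unstable FDR", n_perm)
    rng = np.random.default_rng(seed)
    ev = xoset.events
    mids = {c: s["midpoint"].to_numpy(dtype=float)
            for c, s in ev.groupby("chrom")}
    obs = _window_counts(mids, annotation, window)
    kmax = int(obs["count"].max()) if len(obs) else 0
    if kmax == 0:
        return {"windows": obs, "hotspots": _merge_adjacent(obs.iloc[0:0]),
                "k_threshold": None, "fdr_table": pd.DataFrame()}
    obs_tail = np.array([(obs["count"] >= k).sum()
                         for k in range(1, kmax + 1)], dtype=float)
    null_tail = np.zeros(kmax)
    for _ in range(n_perm):
        sh = {c: rng.uniform(0, annotation.chrom_lengths[c], size=len(m))
              for c, m in mids.items()}
        nc = _window_counts(sh, annotation, window)["count"].to_numpy()
        for k in range(1, kmax + 1):
            null_tail[k - 1] += (nc >= k).sum()
    null_tail /= n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_k = np.where(obs_tail > 0, null_tail / obs_tail, np.nan)
    fdr_table = pd.DataFrame({"k": np.arange(1, kmax + 1),
                              "obs_windows": obs_tail.astype(int),
                              "null_windows": null_tail, "fdr": fdr_k})
    passing = fdr_table[(fdr_table["fdr"] < fdr)
                        & (fdr_table["obs_windows"] > 0)]
    if len(passing) == 0:
        return {"windows": obs, "hotspots": _merge_adjacent(obs.iloc[0:0]),
                "k_threshold": None, "fdr_table": fdr_table}
    k_thr = int(passing["k"].min())
    hot = obs[obs["count"] >= k_thr]
    merged = _merge_adjacent(hot)

    genome_rate = len(ev) / annotation.genome_length
    folds, flank_folds = [], []
    for _, r in merged.iterrows():
        m = mids.get(r["chrom"], np.array([]))
        width = r["end"] - r["start"]
        inside = ((m > r["start"]) & (m <= r["end"])).sum()
        flank = (((m > r["start"] - 50_000) & (m <= r["start"]))
                 | ((m > r["end"]) & (m <= r["end"] + 50_000))).sum()
        rate_in = inside / width
        rate_flank = flank / 100_000
        folds.append(rate_in / genome_rate if genome_rate else np.nan)
        flank_folds.append(rate_in / rate_flank if rate_flank else np.inf)
    merged = merged.assign(fold_vs_genome=folds, fold_vs_flank=flank_folds)
    return {"windows": obs, "hotspots": merged, "k_threshold": k_thr,
            "fdr_table": fdr_table}


# ---------------------------------------------------------------------------
# Ecotype-divergent hotspots
# ---------------------------------------------------------------------------

def _counts_near(mids_sorted: np.ndarray, centers: np.ndarray,
                 half: float) -> np.ndarray:
    lo = np.searchsorted(mids_sorted, centers - half, side="left")
    hi = np.searchsorted(mids_sorted, centers + half, side="right")
    return hi - lo


def ecotype_divergent_hotspots(sets_by_ecotype: dict, annotation,
                               window: int = 5000, pseudocount: float = 0.1,
                               downsample: int | None = 9463,
                               n_shuffle: int = 1000, min_total: int = 6,
                               max_interval: float = 10_000.0,
                               seed: int = 0) -> dict:
    """Pairwise ecotype comparison of fine-scale crossover counts.

    Each ecotype's midpoints (crossover intervals <= ``max_interval`` only)
    are down-sampled to equal size; counts within ``window``/2 of every
    pooled midpoint are compared via log2((a+pc)/(b+pc)) against
    count-conditional 2.5% quantile envelopes of random splits.
    """
    rng = np.random.default_rng(seed)
    half = window / 2.0
    mids = {}
    for eco, xs in sets_by_ecotype.items():
        ev = xs.events
        ev = ev[(ev["right"] - ev["left"]) <= max_interval]
        mids[eco] = {c: np.sort(s["midpoint"].to_numpy(dtype=float))
                     for c, s in ev.groupby("chrom")}, ev
    target = min(len(ev) for _, ev in mids.values())
    if downsample is not None:
        if target < downsample:
            log.info("ecotype_divergent_hotspots: downsample target lowered "
                     "to %d", target)
        else:
            target = downsample
    ds_mids = {}
    for eco, (_, ev) in mids.items():
        take = rng.choice(len(ev), size=target, replace=False)
        sub = ev.iloc[take]
        ds_mids[eco] = {c: np.sort(s["midpoint"].to_numpy(dtype=float))
                        for c, s in sub.groupby("chrom")}

    ecos = sorted(ds_mids)
    results = {}
    for i in range(len(ecos)):
        for j in range(i + 1, len(ecos)):
            a, b = ecos[i], ecos[j]
            chroms = sorted(set(ds_mids[a]) | set(ds_mids[b]))
            rows = []
            for c in chroms:
                ma = ds_mids[a].get(c, np.array([]))
                mb = ds_mids[b].get(c, np.array([]))
                centers = np.unique(np.concatenate([ma, mb]))
                ca = _counts_near(ma, centers, half)
                cb = _counts_near(mb, centers, half)
                rows.append(pd.DataFrame({
                    "chrom": c, "center": centers, "a": ca, "b": cb}))
            tab = pd.concat(rows, ignore_index=True)
            tab["log2fc"] = np.log2((tab["a"] + pseudocount)
                                    / (tab["b"] + pseudocount))
            tab["mean_count"] = (tab["a"] + tab["b"]) / 2.0

            # null: random splits of the combined set
            pool = {c: np.sort(np.concatenate([ds_mids[a].get(c, []),
                                               ds_mids[b].get(c, [])]))
                    for c in chroms}
            null_fc, null_mean = [], []
            for _ in range(n_shuffle):
                fc_parts, mean_parts = [], []
                for c in chroms:
                    pts = pool[c]
                    lab = rng.random(len(pts)) < 0.5
                    pa, pb = np.sort(pts[lab]), np.sort(pts[~lab])
                    centers = pts
                    ca = _counts_near(pa, centers, half)
                    cb = _counts_near(pb, centers, half)
                    fc_parts.append(np.log2((ca + pseudocount)
                                            / (cb + pseudocount)))
                    mean_parts.append((ca + cb) / 2.0)
                null_fc.append(np.concatenate(fc_parts))
                null_mean.append(np.concatenate(mean_parts))
            nfc = np.concatenate(null_fc)
            nmean = np.concatenate(null_mean)

            # count-conditional envelopes (bins with >= 10 null windows)
            bins = np.unique(np.quantile(nmean, np.linspace(0, 1, 21)))
            which = np.clip(np.digitize(tab["mean_count"], bins) - 1,
                            0, len(bins) - 2)
            nwhich = np.clip(np.digitize(nmean, bins) - 1, 0, len(bins) - 2)
            lo_env = np.full(len(bins) - 1, -np.inf)
            hi_env = np.full(len(bins) - 1, np.inf)
            for k in range(len(bins) - 1):
                vals = nfc[nwhich == k]
                if len(vals) >= 10:
                    lo_env[k] = np.quantile(vals, 0.025)
                    hi_env[k] = np.quantile(vals, 0.975)
            tab["outside_envelope"] = ((tab["log2fc"] < lo_env[which])
                                       | (tab["log2fc"] > hi_env[which]))
            tab["total"] = tab["a"] + tab["b"]
            tab["divergent"] = tab["outside_envelope"] & (tab["total"] >= min_total)
            flagged = tab[tab["divergent"]]
            win = pd.DataFrame({
                "chrom": flagged["chrom"],
                "start": (flagged["center"] - half).clip(lower=0).astype(int),
                "end": (flagged["center"] + half).astype(int),
                "count": flagged["total"].astype(int)})
            results[(a, b)] = {"table": tab, "regions": _merge_adjacent(win)}
    return results


# ---------------------------------------------------------------------------
# Coldspots
# ---------------------------------------------------------------------------

def detect_coldspots(pools: dict, annotation: GenomeAnnotation,
                     min_expected: float = 5.0) -> dict:
    """Coldspots per pool (e.g. ecotype x sex): maximal zero-crossover runs
    expected to hold >= ``min_expected`` crossovers under the pool's uniform
    intensity.  Also Wilcoxon rank-sum tests between pools on lengths."""
    G = annotation.genome_length
    out = {}
    for name, xs in pools.items():
        n = len(xs)
        if n == 0:
            raise XomapError(f"pool {name!r} has no crossovers")
        lam = n / G
        min_len = min_expected / lam
        rows = []
        for chrom, L in annotation.chrom_lengths.items():
            m = np.sort(xs.events.loc[xs.events["chrom"] == chrom,
                                      "midpoint"].to_numpy(dtype=float))
            edges = np.concatenate([[0.0], m, [float(L)]])
            gaps = np.diff(edges)
            starts = edges[:-1]
            for s, g in zip(starts, gaps):
                if g >= min_len:
                    rows.append({"chrom": chrom, "start": int(s),
                                 "end": int(s + g), "length": int(g),
                                 "expected": g * lam, "pool": name})
        out[name] = {"coldspots": pd.DataFrame(
            rows, columns=["chrom", "start", "end", "length",
                           "expected", "pool"]),
            "min_length": float(min_len), "lambda": lam}
    names = sorted(out)
    tests = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = out[names[i]]["coldspots"]["length"]
            b = out[names[j]]["coldspots"]["length"]
            if len(a) and len(b):
                w = stats.ranksums(a, b)
                tests.append({"pool_a": names[i], "pool_b": names[j],
                              "stat": w.statistic, "p": w.pvalue,
                              "median_a": float(np.median(a)),
                              "median_b": float(np.median(b))})
    return {"pools": out, "size_tests": pd.DataFrame(tests)}


# ---------------------------------------------------------------------------
# Feature association and peak proximity
# ---------------------------------------------------------------------------

def feature_association(xoset: CrossoverSet, annotation: GenomeAnnotation,
                        feature_sets: list[str] | None = None,
                        max_dist: float = 2000.0, n_shuffle: int = 1000,
                        seed: int = 0) -> pd.DataFrame:
    """Observed proportion of crossover midpoints within ``max_dist`` of each
    feature set versus within-chromosome uniform shuffles (per-chromosome
    counts preserved).  Empirical p = (1 + #null >= obs) / (1 + n)."""
    rng = np.random.default_rng(seed)
    feature_sets = feature_sets or list(annotation.intervals)
    ev = xoset.events
    mids = {c: s["midpoint"].to_numpy(dtype=float)
            for c, s in ev.groupby("chrom")}
    rows = []
    for name in feature_sets:
        feat = annotation.intervals.get(name)
        if feat is None or len(feat) == 0:
            log.warning("feature_association: empty feature set %r skipped", name)
            continue
        fsort = {c: (s["start"].to_numpy(dtype=float),
                     s["end"].to_numpy(dtype=float))
                 for c, s in feat.groupby("chrom")}

        def prop(points: dict) -> float:
            hit = tot = 0
            for c, m in points.items():
                tot += len(m)
                if c not in fsort:
                    continue
                st, en = fsort[c]
                idx = np.searchsorted(st, m, side="right") - 1
                d_in = np.where((idx >= 0) & (m <= en[np.clip(idx, 0, None)]),
                                0.0, np.inf)
                nxt = np.clip(np.searchsorted(st, m, side="right"),
                              0, len(st) - 1)
                d_next = np.abs(st[nxt] - m)
                prv = np.clip(idx, 0, len(st) - 1)
                d_prev = np.abs(m - en[prv])
                d = np.minimum(d_in, np.minimum(d_next, d_prev))
                hit += (d <= max_dist).sum()
            return hit / tot if tot else float("nan")

        obs = prop(mids)
        null = np.empty(n_shuffle)
        for t in range(n_shuffle):
            sh = {c: rng.uniform(0, annotation.chrom_lengths[c], len(m))
                  for c, m in mids.items()}
            null[t] = prop(sh)
        p = (1 + np.sum(null >= obs)) / (1 + n_shuffle)
        stars = "***" if p <= 0.001 else "**" if p <= 0.01 else \
            "*" if p <= 0.05 else ""
        rows.append({"feature": name, "observed": obs,
                     "null_mean": float(null.mean()),
                     "null_sd": float(null.std(ddof=1)),
                     "p": float(p), "stars": stars})
    return pd.DataFrame(rows)


def peak_proximity(peaks: pd.DataFrame, xoset: CrossoverSet,
                   max_dist: float = 5000.0) -> dict:
    """For each peak (BED), distance from its midpoint to the nearest
    crossover midpoint; reports the fraction within ``max_dist``."""
    ev = xoset.events
    mids = {c: np.sort(s["midpoint"].to_numpy(dtype=float))
            for c, s in ev.groupby("chrom")}
    dists = []
    for _, r in peaks.iterrows():
        center = (r["start"] + r["end"]) / 2.0
        m = mids.get(r["chrom"])
        if m is None or len(m) == 0:
            dists.append(np.inf)
            continue
        i = np.searchsorted(m, center)
        cand = []
        if i > 0:
            cand.append(abs(center - m[i - 1]))
        if i < len(m):
            cand.append(abs(m[i] - center))
        dists.append(min(cand))
    dists = np.asarray(dists)
    finite = dists[np.isfinite(dists)]
    hist = np.histogram(finite, bins=np.arange(0, 50_001, 2_500))
    return {"distances": dists,
            "fraction_within": float(np.mean(dists <= max_dist)),
            "histogram": pd.DataFrame({"bin_start": hist[1][:-1],
                                       "bin_end": hist[1][1:],
                                       "n_peaks": hist[0]})}
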