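"""Read-based marine/freshwater ancestry and adaptive-locus profiles.

Per-site ancestry is the fraction of reads carrying the marine allele
(optionally pseudocounted).  Genome-wide ancestry feeds a quadratic
admixture-recombination regression; rescaled adaptive-locus profiles compare
recombination and heterozygous-SNP density across loci grouped by local
ancestry class (hom-marine / hom-freshwater / het).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .iocore import CrossoverSet, XomapError, log


def site_ancestry(r_marine, r_fresh, alpha: float = 0.5):
    """P(marine) per site from marine/freshwater allele read counts:
    (rM + alpha) / (rM + rF + 2 alpha).  With alpha = 0, zero-coverage sites
    return NaN (skipped)."""
    rM = np.asarray(r_marine, dtype=float)
    rF = np.asarray(r_fresh, dtype=float)
    if (rM < 0).any() or (rF < 0).any():
        raise XomapError("negative read counts")
    denom = rM + rF + 2 * alpha
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (rM + alpha) / denom
    return p if p.ndim else float(p)


def locus_ancestry_class(p_marine_mean: float, hom_threshold: float = 0.75):
    """Diploid ancestry class from mean P(marine) over a locus."""
    if p_marine_mean >= hom_threshold:
        return "hom_marine"
    if p_marine_mean <= 1 - hom_threshold:
        return "hom_freshwater"
    return "het"


# ---------------------------------------------------------------------------
# Admixture-recombination regression
# ---------------------------------------------------------------------------

def admixture_recombination_regression(df: pd.DataFrame) -> dict:
    """Quadratic regression of recombination rate on genome-wide ancestry.

    ``df`` columns: ``ancestry`` (genome-wide P(marine)), ``rate``,
    ``sex``.  Fits rate ~ ancestry^2 + ancestry + sex and F-tests the
    squared term (full vs linear model).
    """
    if len(df) < 10:
        raise XomapError("need at least 10 individuals")
    d = df.copy()
    d["ancestry2"] = d["ancestry"] ** 2
    full = smf.ols("rate ~ ancestry2 + ancestry + C(sex)", data=d).fit()
    if np.linalg.cond(full.model.exog) > 1e10:
        raise XomapError(
            f"collinear design (cond={np.linalg.cond(full.model.exog):.3g})")
    reduced = smf.ols("rate ~ ancestry + C(sex)", data=d).fit()
    ftest = full.compare_f_test(reduced)
    return {"fit": full, "beta_quadratic": float(full.params["ancestry2"]),
            "beta_linear": float(full.params["ancestry"]),
            "F": float(ftest[0]), "p": float(ftest[1])}


def island_contrast(xoset: CrossoverSet, islands: pd.DataFrame,
                    genome_length: int) -> pd.DataFrame:
    """Per sex, fold difference of per-bp crossover rate outside vs inside
    adaptive islands (BED intervals)."""
    from .iocore import points_in_intervals
    ev = xoset.events
    inside = points_in_intervals(ev["chrom"].to_numpy(),
                                 ev["midpoint"].to_numpy(), islands)
    island_bp = int((islands["end"] - islands["start"]).sum())
    outside_bp = genome_length - island_bp
    if outside_bp <= 0:
        raise XomapError("islands cover the whole genome; contrast undefined")
    rows = []
    for sex, sub in ev.groupby("sex"):
        sel = inside[ev["sex"].to_numpy() == sex]
        n_in, n_out = int(sel.sum()), int((~sel).sum())
        rate_in = n_in / island_bp
        rate_out = n_out / outside_bp
        fold = rate_out / rate_in if rate_in > 0 else np.inf
        rows.append({"sex": sex, "n_inside": n_in, "n_outside": n_out,
                     "rate_inside": rate_in, "rate_outside": rate_out,
                     "fold_outside_over_inside": fold,
                     "infinite": rate_in == 0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rescaled adaptive-locus profiles
# ---------------------------------------------------------------------------

def rescaled_locus_profiles(xoset: CrossoverSet, loci: pd.DataFrame,
                            locus_classes: pd.DataFrame | None = None,
                            het_sites: pd.DataFrame | None = None,
                            flank: float = 1.0, n_bins: int = 50,
                            n_flank_bins: int = 25) -> dict:
    """Mean +/- s.e. crossover density across loci rescaled to unit width.

    Each locus is mapped to [0, 1]; flanks of ``flank`` locus-widths map to
    [-flank, 0) and (1, 1+flank].  Profiles are averaged over loci (and over
    each locus's orientation flip, making them invariant to strand).

    ``locus_classes``: optional columns (chrom, start, end, class) grouping
    loci by diploid ancestry class.  ``het_sites``: optional per-individual
    heterozygous site positions (chrom, pos) for a heterozygosity profile.
    """
    edges = np.concatenate([
        np.linspace(-flank, 0, n_flank_bins + 1)[:-1],
        np.linspace(0, 1, n_bins + 1)[:-1],
        np.linspace(1, 1 + flank, n_flank_bins + 1),
    ])
    centers = (edges[:-1] + edges[1:]) / 2

    def profile_for(points_by_chrom: dict, loci: pd.DataFrame):
        per_locus = []
        for _, r in loci.iterrows():
            width = r["end"] - r["start"]
            if width < 2:
                log.info("locus %s:%s-%s too short; excluded",
                         r["chrom"], r["start"], r["end"])
                continue
            pts = points_by_chrom.get(r["chrom"], np.array([]))
            rel = (pts - r["start"]) / width
            sel = rel[(rel >= -flank) & (rel <= 1 + flank)]
            h, _ = np.histogram(sel, bins=edges)
            h = h.astype(float) / width    # density per bp, per locus
            h_flip = h[::-1]               # orientation-flip averaging
            per_locus.append((h + h_flip) / 2.0)
        if not per_locus:
            return np.full(len(centers), np.nan), np.full(len(centers), np.nan), 0
        mat = np.vstack(per_locus)
        mean = mat.mean(axis=0)
        se = (mat.std(axis=0, ddof=1) / np.sqrt(len(mat))
              if len(mat) > 1 else np.full(len(centers), np.nan))
        return mean, se, len(mat)

    mids = {c: s["midpoint"].to_numpy(dtype=float)
            for c, s in xoset.events.groupby("chrom")}
    out = {"bin_center": centers}
    groups = {"all": loci}
    if locus_classes is not None:
        for cls, sub in locus_classes.groupby("class"):
            groups[cls] = sub
    results = {}
    for name, sub_loci in groups.items():
        mean, se, n = profile_for(mids, sub_loci)
        results[name] = {"recomb_mean": mean, "recomb_se": se, "n_loci": n}
        if het_sites is not None:
            hpts = {c: s["pos"].to_numpy(dtype=float)
                    for c, s in het_sites.groupby("chrom")}
            hmean, hse, _ = profile_for(hpts, sub_loci)
            results[name]["het_mean"] = hmean * 100.0   # per 100 bp
            results[name]["het_se"] = hse * 100.0
    out["groups"] = results
    return out
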