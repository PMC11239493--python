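"""Crossover calling from phased haplotype tracks.

A crossover is a *long switch*: a change of parental-haplotype label where
the maximal same-label run on each side spans more than ``min_span`` bp and
contains at least ``min_snps`` SNPs.  Short label flips (genotyping error or
gene conversion) are absorbed into their flanking runs.  Post-filters remove
family-recurrent boundaries (parental phasing error), events from
low-coverage offspring, low-resolution intervals, and correct the
triplet signature left by regions whose sample orientation is inverted
relative to the reference assembly.

Filter order is fixed: switches -> recurrent -> quality -> inversions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .famphase import FamilyTracks
from .iocore import CrossoverSet, MATERNAL, PATERNAL, XomapError, log

CAND_COLS = ["family", "offspring", "parent", "chrom", "left", "right",
             "left_snps", "left_span", "right_snps", "right_span",
             "left_terminal", "right_terminal"]


@dataclass
class CallParams:
    min_span: float = 50_000.0       # bp span required on either side
    min_snps: int = 50               # SNPs required on either side
    recurrent_fraction: float = 0.5  # family-recurrence removal threshold
    min_coverage: float = 2.0        # offspring sequencing coverage
    max_resolution: float = 1e6      # interval size unless no informative SNPs
    inversion_span: float = 2e6      # first-to-third triplet distance
    inversion_same_loc: float = 10_000.0
    inversion_min_offspring: int = 2


# ---------------------------------------------------------------------------
# Long-switch calling
# ---------------------------------------------------------------------------

def _runs(labels: np.ndarray) -> list[list]:
    """Maximal constant-label runs as [label, start_idx, end_idx] (inclusive)."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append([int(labels[start]), start, i - 1])
            start = i
    return out


def _run_support(run, positions) -> tuple[int, float]:
    _, a, b = run
    return b - a + 1, float(positions[b] - positions[a])


def _passes(run, positions, min_span, min_snps, terminal=False) -> bool:
    n, span = _run_support(run, positions)
    if terminal:
        # span rule waived at chromosome termini (flank truncated by the end)
        return n >= min_snps
    return span > min_span and n >= min_snps


def call_switches(positions: np.ndarray, labels: np.ndarray,
                  min_span: float = 50_000.0,
                  min_snps: int = 50) -> list[dict]:
    """Call long switches on one offspring x parent x chromosome track.

    ``positions``/``labels`` must be the non-missing labelled SNPs in
    position order.  Returns a list of candidate dicts with the boundary SNP
    pair and flank supports.
    """
    if len(positions) == 0:
        return []
    runs = _runs(labels)
    # absorb short flips: interior runs failing support whose flanks agree
    changed = True
    while changed and len(runs) >= 3:
        changed = False
        fails = [i for i in range(1, len(runs) - 1)
                 if not _passes(runs[i], positions, min_span, min_snps)
                 and runs[i - 1][0] == runs[i + 1][0]]
        if fails:
            i = min(fails, key=lambda k: runs[k][2] - runs[k][1])
            merged = [runs[i - 1][0], runs[i - 1][1], runs[i + 1][2]]
            runs[i - 1:i + 2] = [merged]
            changed = True
    out = []
    for i in range(len(runs) - 1):
        left, right = runs[i], runs[i + 1]
        lt = i == 0
        rt = i + 1 == len(runs) - 1
        if not _passes(left, positions, min_span, min_snps, terminal=lt):
            continue
        if not _passes(right, positions, min_span, min_snps, terminal=rt):
            continue
        ln, ls = _run_support(left, positions)
        rn, rs = _run_support(right, positions)
        out.append({
            "left": int(positions[left[2]]),
            "right": int(positions[right[1]]),
            "left_snps": ln, "left_span": ls,
            "right_snps": rn, "right_span": rs,
            "left_terminal": lt, "right_terminal": rt,
        })
    return out


def call_family_switches(tracks: FamilyTracks,
                         params: CallParams | None = None) -> pd.DataFrame:
    """Candidate switches for every offspring/parent/chromosome of a family."""
    params = params or CallParams()
    rows = []
    for (chrom, parent), pc in tracks.chromosomes.items():
        for off in pc.offspring:
            pos, lab = pc.track(off)
            for cand in call_switches(pos, lab, params.min_span,
                                      params.min_snps):
                cand.update(family=tracks.family, offspring=off,
                            parent=parent, chrom=chrom)
                rows.append(cand)
    if not rows:
        return pd.DataFrame(columns=CAND_COLS)
    return pd.DataFrame(rows)[CAND_COLS].sort_values(
        ["offspring", "parent", "chrom", "left"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Post-filters
# ---------------------------------------------------------------------------

def filter_family_recurrent(cands: pd.DataFrame, n_offspring: int,
                            threshold: float = 0.5):
    """Remove candidates sharing identical boundary SNPs in >= threshold of
    the family's offspring (parental phasing error signature)."""
    if len(cands) == 0:
        return cands, 0
    key = ["parent", "chrom", "left", "right"]
    rec = cands.groupby(key)["offspring"].nunique()
    bad_keys = set(rec[rec >= threshold * n_offspring].index)
    if not bad_keys:
        return cands, 0
    mask = [tuple(r) in bad_keys for r in cands[key].itertuples(index=False)]
    mask = np.asarray(mask)
    return cands[~mask].reset_index(drop=True), int(mask.sum())


def filter_low_quality(cands: pd.DataFrame, coverage: pd.Series,
                       tracks: FamilyTracks,
                       max_resolution: float = 1e6,
                       min_coverage: float = 2.0):
    """Remove events of offspring with coverage < min_coverage and events
    with resolution > max_resolution unless their interval contains zero
    retained informative SNPs (kept, flagged low_res)."""
    if len(cands) == 0:
        return cands.assign(low_res=pd.Series(dtype=bool)), {"coverage": 0,
                                                             "resolution": 0}
    for off in cands["offspring"].unique():
        if off not in coverage.index:
            raise XomapError(f"no coverage entry for offspring {off!r}")
    cov_bad = cands["offspring"].map(coverage) < min_coverage
    res = cands["right"] - cands["left"]
    big = res > max_resolution
    no_inf = np.zeros(len(cands), dtype=bool)
    for i in np.where(big & ~cov_bad)[0]:
        r = cands.iloc[i]
        pc = tracks.get(r["chrom"], r["parent"])
        if pc is None:
            continue
        inside = (pc.positions > r["left"]) & (pc.positions < r["right"])
        no_inf[i] = not inside.any()
    drop = cov_bad | (big & ~no_inf)
    out = cands[~drop.to_numpy() if hasattr(drop, "to_numpy") else ~drop]
    out = out.reset_index(drop=True)
    out["low_res"] = ((out["right"] - out["left"]) > max_resolution)
    removed = {"coverage": int(cov_bad.sum()),
               "resolution": int((big & ~no_inf & ~cov_bad).sum())}
    return out, removed


def correct_inversion_triplets(cands: pd.DataFrame,
                               params: CallParams | None = None):
    """Detect and correct inversion triplets.

    Three consecutive crossovers of one gamete whose first and third
    midpoints lie within ``inversion_span``, recurring at the same genomic
    location (boundaries within ``inversion_same_loc``) in at least
    ``inversion_min_offspring`` offspring, mark a region whose sample
    orientation is inverted versus the reference: the first and third events
    are dropped and the second is reflected through the inversion interval
    (new = inv_start + inv_end - old, bounds reordered).

    Returns (corrected candidates, inversion report DataFrame).
    """
    params = params or CallParams()
    if len(cands) == 0:
        return cands, pd.DataFrame(
            columns=["chrom", "inv_start", "inv_end", "n_offspring"])
    cands = cands.reset_index(drop=True)
    mid = (cands["left"] + cands["right"]) // 2
    triplets = []      # (chrom, first_mid, third_mid, offspring, idx1, idx2, idx3)
    for (off, parent, chrom), sub in cands.groupby(
            ["offspring", "parent", "chrom"]):
        sub = sub.sort_values("left")
        idx = sub.index.to_numpy()
        i = 0
        while i + 2 <= len(idx) - 1:
            i1, i2, i3 = idx[i], idx[i + 1], idx[i + 2]
            if mid[i3] - mid[i1] < params.inversion_span:
                triplets.append((chrom, int(mid[i1]), int(mid[i3]),
                                 off, i1, i2, i3))
                i += 3      # overlapping triplets resolved left-to-right
            else:
                i += 1
    if not triplets:
        return cands, pd.DataFrame(
            columns=["chrom", "inv_start", "inv_end", "n_offspring"])

    # cluster triplets by location
    tdf = pd.DataFrame(triplets, columns=["chrom", "m1", "m3", "offspring",
                                          "i1", "i2", "i3"])
    drop_idx, fixes, report = [], [], []
    for chrom, sub in tdf.groupby("chrom"):
        sub = sub.sort_values("m1").reset_index(drop=True)
        used = np.zeros(len(sub), dtype=bool)
        for a in range(len(sub)):
            if used[a]:
                continue
            grp = [a]
            for b in range(a + 1, len(sub)):
                if used[b]:
                    continue
                if (abs(sub.loc[b, "m1"] - sub.loc[a, "m1"])
                        <= params.inversion_same_loc and
                        abs(sub.loc[b, "m3"] - sub.loc[a, "m3"])
                        <= params.inversion_same_loc):
                    grp.append(b)
            n_off = sub.loc[grp, "offspring"].nunique()
            if n_off < params.inversion_min_offspring:
                continue
            used[grp] = True
            inv_start = float(sub.loc[grp, "m1"].median())
            inv_end = float(sub.loc[grp, "m3"].median())
            report.append({"chrom": chrom, "inv_start": int(inv_start),
                           "inv_end": int(inv_end), "n_offspring": int(n_off)})
            for g in grp:
                drop_idx += [sub.loc[g, "i1"], sub.loc[g, "i3"]]
                fixes.append((sub.loc[g, "i2"], inv_start, inv_end))
    out = cands.copy()
    for i2, a, b in fixes:
        old_l, old_r = out.loc[i2, "left"], out.loc[i2, "right"]
        nl, nr = a + b - old_r, a + b - old_l
        out.loc[i2, "left"], out.loc[i2, "right"] = int(min(nl, nr)), int(max(nl, nr))
    out = out.drop(index=drop_idx).reset_index(drop=True)
    return out, pd.DataFrame(report, columns=["chrom", "inv_start",
                                              "inv_end", "n_offspring"])


# ---------------------------------------------------------------------------
# Full pipeline for one family
# ---------------------------------------------------------------------------

def call_crossovers(tracks: FamilyTracks, meta: dict,
                    coverage: pd.Series,
                    params: CallParams | None = None):
    """Run the full calling pipeline on one family's tracks.

    ``meta`` maps parent-of-origin to (sex, ecotype), e.g.
    ``{"maternal": ("F", "marine"), "paternal": ("M", "marine")}``.

    Returns ``(CrossoverSet, audit dict, inversion report)``.
    """
    params = params or CallParams()
    cands = call_family_switches(tracks, params)
    audit = {"switches": len(cands)}
    n_off = len(tracks.offspring)
    cands, n_rec = filter_family_recurrent(cands, n_off,
                                           params.recurrent_fraction)
    audit["recurrent_removed"] = n_rec
    cands, rem = filter_low_quality(cands, coverage, tracks,
                                    params.max_resolution, params.min_coverage)
    audit.update({f"lowqual_{k}": v for k, v in rem.items()})
    cands, inv_report = correct_inversion_triplets(cands, params)
    audit["inversion_triplet_removed"] = 2 * sum(
        inv_report["n_offspring"]) if len(inv_report) else 0
    audit["final"] = len(cands)

    ev = cands.copy()
    ev["sex"] = ev["parent"].map(lambda p: meta[p][0])
    ev["ecotype"] = ev["parent"].map(lambda p: meta[p][1])
    gametes = pd.DataFrame(
        [{"family": tracks.family, "offspring": o, "parent": p,
          "sex": meta[p][0], "ecotype": meta[p][1]}
         for o in tracks.offspring for p in (MATERNAL, PATERNAL)])
    cols = ["family", "offspring", "parent", "sex", "ecotype",
            "chrom", "left", "right"]
    xoset = CrossoverSet(ev[cols] if len(ev) else pd.DataFrame(columns=cols),
                         gametes=gametes,
                         provenance=[f"{k}={v}" for k, v in audit.items()])
    log.info("call_crossovers %s: %s", tracks.family, audit)
    return xoset, audit, inv_report
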