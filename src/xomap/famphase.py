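"""Family-based SNP filtering and co-segregation phasing.

Each nuclear family is phased per parent and per chromosome.  SNPs that are
heterozygous in exactly one parent are informative for that parent; the
transmitted allele in each offspring is obtained by Mendelian subtraction of
the homozygous parent's obligatory contribution.  Offspring then partition
the informative parent's two alleles into its two haplotypes; a greedy chain
walk orients successive SNPs to maximise co-segregation agreement with the
running consensus of the previous ``window`` phased SNPs.  Global haplotype
labels per chromosome are arbitrary (defined up to a flip).

A second pass removes problem SNPs (isolated double-flank disagreements in
many offspring, a proxy for high genotyping-error probability, and SNPs
phased to one haplotype in more than 75% of offspring, a transmission-
distortion proxy) and rephases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iocore import FamilyDataset, MATERNAL, PATERNAL, log

AF_CENTERS = (0.25, 0.5, 0.75)


@dataclass
class PhaseParams:
    af_tolerance: float = 0.06        # distance to nearest Mendelian AF centre
    coverage_band: float = 0.5        # site mean depth within +/-50% of family mean
    allele_balance: float = 0.30      # parental het read-balance deviation
    window: int = 20                  # chain-consensus window
    error_min_offspring: int = 20     # double-flank disagreement rule
    distortion_fraction: float = 0.75 # one-haplotype fraction rule


@dataclass
class PhasedChromosome:
    """Haplotype labels for one parent on one chromosome.

    ``labels``: (n_snps, n_offspring) int8, values 1/2, 0 = missing.
    """

    chrom: str
    parent: str
    positions: np.ndarray
    labels: np.ndarray
    offspring: list[str]

    def track(self, offspring: str):
        """(positions, labels) for one offspring, missing labels dropped."""
        j = self.offspring.index(offspring)
        lab = self.labels[:, j]
        keep = lab != 0
        return self.positions[keep], lab[keep]


@dataclass
class FamilyTracks:
    family: str
    offspring: list[str]
    chromosomes: dict = field(default_factory=dict)  # (chrom, parent) -> PhasedChromosome
    filter_counts: dict = field(default_factory=dict)

    def get(self, chrom: str, parent: str) -> PhasedChromosome | None:
        return self.chromosomes.get((chrom, parent))


# ---------------------------------------------------------------------------
# SNP filtering
# ---------------------------------------------------------------------------

def filter_snps(ds: FamilyDataset, params: PhaseParams | None = None):
    """Select informative SNPs per chromosome.

    Returns ``(informative, counts)`` where ``informative`` maps chromosome
    to a DataFrame (idx, pos, parent) and ``counts`` tallies rejections by
    reason (conservation: retained + rejected = input).
    """
    params = params or PhaseParams()
    im = ds.sample_index(ds.mother)
    if_ = ds.sample_index(ds.father)
    fam_cov = ds.mean_coverage().mean()
    out = {}
    counts = {"input": 0, "retained": 0, "not_single_het": 0,
              "allele_freq": 0, "coverage": 0, "allele_balance": 0}
    for chrom in ds.chroms:
        G = ds.genotypes[chrom]
        R = ds.ad_ref[chrom].astype(float)
        A = ds.ad_alt[chrom].astype(float)
        n = G.shape[0]
        counts["input"] += n
        mo_het = G[:, im] == 1
        fa_het = G[:, if_] == 1
        single = mo_het ^ fa_het
        counts["not_single_het"] += int((~single).sum())

        ok = np.isfinite(G).all(axis=1) if G.dtype.kind == "f" else np.ones(n, bool)
        valid = G >= 0
        af = np.where(valid, G, 0).sum(axis=1) / np.maximum(
            2 * valid.sum(axis=1), 1)
        near = np.min(np.abs(af[:, None] - np.array(AF_CENTERS)[None, :]), axis=1)
        af_ok = near <= params.af_tolerance
        counts["allele_freq"] += int((single & ~af_ok).sum())

        dp = R + A
        site_cov = dp.mean(axis=1)
        cov_ok = np.abs(site_cov - fam_cov) <= params.coverage_band * fam_cov
        counts["coverage"] += int((single & af_ok & ~cov_ok).sum())

        ip = np.where(mo_het, im, if_)
        ra = R[np.arange(n), ip]
        aa = A[np.arange(n), ip]
        tot = np.maximum(ra + aa, 1)
        bal_ok = np.abs(aa / tot - 0.5) < params.allele_balance
        counts["allele_balance"] += int((single & af_ok & cov_ok & ~bal_ok).sum())

        keep = single & af_ok & cov_ok & bal_ok & ok
        counts["retained"] += int(keep.sum())
        idx = np.where(keep)[0]
        if len(idx) == 0:
            log.warning("filter_snps: no informative SNPs retained on %s (%s)",
                        chrom, ds.family)
        out[chrom] = pd.DataFrame({
            "idx": idx,
            "pos": ds.positions[chrom][idx],
            "parent": np.where(mo_het[idx], "mother", "father"),
        })
    return out, counts


# ---------------------------------------------------------------------------
# Transmitted alleles
# ---------------------------------------------------------------------------

def transmitted_matrix(ds: FamilyDataset, chrom: str, info: pd.DataFrame,
                       parent: str) -> tuple[np.ndarray, np.ndarray]:
    """Transmitted-allele matrix of the informative parent.

    Returns ``(positions, T)`` with T of shape (n_snps, n_offspring) holding
    the transmitted allele (0/1) of the informative parent, or -1 when the
    offspring genotype is missing or Mendelian-inconsistent.
    """
    which = "mother" if parent == MATERNAL else "father"
    sub = info[info["parent"] == which]
    idx = sub["idx"].to_numpy()
    pos = sub["pos"].to_numpy()
    G = ds.genotypes[chrom]
    other = ds.sample_index(ds.father if which == "mother" else ds.mother)
    off_idx = [ds.sample_index(o) for o in ds.offspring]
    g_off = G[np.ix_(idx, off_idx)].astype(np.int16)
    hom = (G[idx, other] // 2).astype(np.int16)       # 0 or 1 allele contributed
    T = g_off - hom[:, None]
    bad = (T < 0) | (T > 1) | (g_off < 0)
    T[bad] = -1
    return pos, T.astype(np.int8)


def infer_transmitted_allele(parent_gt: int, other_gt: int,
                             offspring_gt: int) -> int:
    """Single-site Mendelian subtraction (scalar convenience wrapper).

    ``parent_gt`` must be 1 (het); ``other_gt`` in {0, 2}.  Returns the
    transmitted allele of the informative parent, or -1 if the offspring
    genotype is missing or Mendelian-inconsistent.
    """
    if offspring_gt < 0:
        return -1
    t = offspring_gt - other_gt // 2
    return t if t in (0, 1) else -1


# ---------------------------------------------------------------------------
# Greedy chain phasing
# ---------------------------------------------------------------------------

def phase_parent(positions: np.ndarray, T: np.ndarray,
                 window: int = 20) -> np.ndarray:
    """Orient each SNP against the consensus of the previous ``window``
    phased SNPs; return label matrix (1/2, 0 = missing).

    Ties (equal agreement both ways) keep the orientation implying fewer
    label switches relative to the immediately preceding SNP.
    """
    n, m = T.shape
    if n == 0:
        return np.zeros((0, m), dtype=np.int8)
    if m < 10:
        log.warning("phase_parent: only %d offspring; phasing is best-effort", m)
    lab = np.zeros((n, m), dtype=np.int8)     # oriented allele + 1
    orient = np.zeros(n, dtype=np.int8)
    first = T[0]
    lab[0] = np.where(first >= 0, first + 1, 0)
    n_ties = 0
    for i in range(1, n):
        lo = max(0, i - window)
        win = lab[lo:i]                        # (w, m)
        ones = (win == 2).sum(axis=0).astype(np.int32)
        zeros = (win == 1).sum(axis=0).astype(np.int32)
        cons = np.where(ones > zeros, 1, np.where(zeros > ones, 0, -1))
        t = T[i]
        ok = (t >= 0) & (cons >= 0)
        agree_fwd = int(np.sum(ok & (t == cons)))
        agree_rev = int(np.sum(ok & ((1 - t) == cons)))
        if agree_fwd > agree_rev:
            o = 0
        elif agree_rev > agree_fwd:
            o = 1
        else:
            n_ties += 1
            prev = lab[i - 1]
            ok2 = (t >= 0) & (prev > 0)
            sw_fwd = int(np.sum(ok2 & (t + 1 != prev)))
            sw_rev = int(np.sum(ok2 & (2 - t != prev)))
            o = 0 if sw_fwd <= sw_rev else 1
        orient[i] = o
        ti = np.where(t >= 0, (t ^ o) + 1, 0)
        lab[i] = ti
    if n_ties:
        log.debug("phase_parent: %d orientation ties broken by switch count",
                  n_ties)
    return lab


# ---------------------------------------------------------------------------
# Problem-SNP filter
# ---------------------------------------------------------------------------

def problem_snp_mask(labels: np.ndarray, params: PhaseParams) -> np.ndarray:
    """True where a SNP should be removed.

    (a) its label disagrees with both flanking neighbours in
        >= error_min_offspring offspring (isolated-flip error proxy);
    (b) it is assigned to one haplotype in > distortion_fraction of
        offspring (transmission-distortion proxy).
    """
    n, m = labels.shape
    bad = np.zeros(n, dtype=bool)
    if n >= 3:
        a, b, c = labels[:-2], labels[1:-1], labels[2:]
        obs = (a > 0) & (b > 0) & (c > 0)
        flip = obs & (b != a) & (b != c)
        bad[1:-1] |= flip.sum(axis=1) >= params.error_min_offspring
    n1 = (labels == 1).sum(axis=1)
    n2 = (labels == 2).sum(axis=1)
    tot = np.maximum(n1 + n2, 1)
    frac = np.maximum(n1, n2) / tot
    bad |= (frac > params.distortion_fraction) & ((n1 + n2) > 0)
    return bad


def phase_family(ds: FamilyDataset,
                 params: PhaseParams | None = None) -> FamilyTracks:
    """Full two-pass phasing of one family: SNP QC, chain phasing,
    problem-SNP removal, rephasing."""
    params = params or PhaseParams()
    info, counts = filter_snps(ds, params)
    tracks = FamilyTracks(ds.family, ds.offspring, filter_counts=dict(counts))
    n_problem = 0
    for chrom in ds.chroms:
        for parent in (MATERNAL, PATERNAL):
            pos, T = transmitted_matrix(ds, chrom, info[chrom], parent)
            if len(pos) < 2:
                continue
            lab = phase_parent(pos, T, params.window)
            bad = problem_snp_mask(lab, params)
            n_problem += int(bad.sum())
            if bad.any():
                pos, T = pos[~bad], T[~bad]
                lab = phase_parent(pos, T, params.window)
            tracks.chromosomes[(chrom, parent)] = PhasedChromosome(
                chrom, parent, pos, lab, ds.offspring)
    tracks.filter_counts["problem_snps_removed"] = n_problem
    return tracks


# ---------------------------------------------------------------------------
# Track I/O
# ---------------------------------------------------------------------------

def write_tracks(tracks: FamilyTracks, path) -> None:
    """Long-format TSV: family, chrom, parent, pos, offspring, label."""
    frames = []
    for (chrom, parent), pc in tracks.chromosomes.items():
        n, m = pc.labels.shape
        df = pd.DataFrame({
            "family": tracks.family,
            "chrom": chrom,
            "parent": parent,
            "pos": np.repeat(pc.positions, m),
            "offspring": np.tile(pc.offspring, n),
            "label": pc.labels.ravel(),
        })
        frames.append(df[df["label"] > 0])
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_tracks(path) -> FamilyTracks:
    df = pd.read_csv(path, sep="\t")
    family = str(df["family"].iloc[0])
    offspring = sorted(df["offspring"].unique())
    tracks = FamilyTracks(family, offspring)
    for (chrom, parent), sub in df.groupby(["chrom", "parent"]):
        pos = np.sort(sub["pos"].unique())
        lab = np.zeros((len(pos), len(offspring)), dtype=np.int8)
        pidx = {p: i for i, p in enumerate(pos)}
        oidx = {o: j for j, o in enumerate(offspring)}
        for p, o, l in zip(sub["pos"], sub["offspring"], sub["label"]):
            lab[pidx[p], oidx[o]] = l
        tracks.chromosomes[(chrom, parent)] = PhasedChromosome(
            chrom, parent, pos.astype(np.int64), lab, offspring)
    return tracks
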