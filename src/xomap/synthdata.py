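"""Synthetic nuclear families, annotations and hybrid-zone cohorts.

The generator reproduces the statistical structure the downstream analyses
assume: female-biased crossover counts (defaults 19.06 maternal / 10.81
paternal per gamete over 21 chromosomes), crossover interference (stationary
gamma renewal along the genetic map, stronger in males), periphery-biased
crossover placement (defaults: 70% of male and 47% of female crossover mass
in the terminal 15% of the chromosome), genotyping error, short
gene-conversion-like haplotype blips, optional inversion polymorphisms
(regions whose sample orientation is reversed relative to the reference),
ecotype-divergent adaptive loci with heterozygosity-dependent local crossover
suppression, and a hybrid-zone cohort with genotype-dependent growth and
survival.

Ground truth (true crossover positions, true haplotype labels, injected
artefact sites) is always returned/written so recovery tests read it rather
than re-deriving it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iocore import (CrossoverSet, FamilyDataset, GenomeAnnotation, MATERNAL,
                     PATERNAL, XomapError, log)

# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


def _default_chroms() -> dict[str, int]:
    # 21 chromosomes totalling ~462 Mb, matching the stickleback karyotype
    return {f"chr{i}": 22_000_000 for i in range(1, 22)}


@dataclass
class SimFamilySpec:
    """Parameters of one simulated nuclear family."""

    family: str = "fam1"
    mother_ecotype: str = "marine"
    father_ecotype: str = "marine"
    n_offspring: int = 93
    chrom_lengths: dict[str, int] = field(default_factory=_default_chroms)
    snp_density: float = 1.25e-3          # SNPs per bp (all categories)
    p_maternal_informative: float = 0.4   # mother het, father hom
    p_paternal_informative: float = 0.4
    p_both_het: float = 0.1
    maternal_mean_xo: float = 19.06       # per gamete, genome-wide
    paternal_mean_xo: float = 10.81
    interference_nu_f: float = 3.0        # gamma renewal shape, females
    interference_nu_m: float = 6.0
    obligate_chiasma: bool = False
    periphery_fraction_f: float = 0.47    # crossover mass in terminal 15%
    periphery_fraction_m: float = 0.70
    terminal_fraction: float = 0.15
    genotype_error_rate: float = 0.002
    blip_rate: float = 0.2                # blips per gamete-chromosome
    blip_tract_bp: tuple = (50, 2000)
    distorted_site_rate: float = 0.0      # sites with non-Mendelian AF ~0.9
    systematic_error_rate: float = 0.0    # sites mislabelled in many offspring
    offspring_coverage: tuple = (10.0, 3.0)   # mean, sd
    parent_coverage: float = 40.0
    read_error: float = 0.01
    adaptive_loci: pd.DataFrame | None = None   # BED-style chrom/start/end
    divergent_snp_density: float = 5e-3   # extra divergent SNPs inside loci
    het_suppression_k: float = 0.0713     # acceptance = exp(-k * het/kb)
    inversions: pd.DataFrame | None = None  # chrom/start/end (sample-inverted)

    def __post_init__(self):
        if self.n_offspring < 1:
            raise XomapError("n_offspring must be >= 1")
        for f in (self.periphery_fraction_f, self.periphery_fraction_m):
            if not 0.0 <= f <= 1.0:
                raise XomapError("periphery fractions must lie in [0, 1]")
        for r in (self.snp_density, self.genotype_error_rate, self.blip_rate,
                  self.maternal_mean_xo, self.paternal_mean_xo):
            if r < 0:
                raise XomapError("rates must be non-negative")

    def annotation(self) -> GenomeAnnotation:
        ann = GenomeAnnotation(dict(self.chrom_lengths))
        if self.adaptive_loci is not None:
            ann.add_intervals("adaptive_loci", self.adaptive_loci)
        if self.inversions is not None:
            ann.add_intervals("inversions", self.inversions)
        return ann


@dataclass
class SimCohortSpec:
    """Hybrid-zone cohort: 5 linked adaptive loci, growth and survival."""

    n_fry: int = 150
    n_juvenile: int = 150
    fry_dates: tuple = ("2003-07-01", "2003-08-01")
    juvenile_dates: tuple = ("2003-09-15", "2003-10-15")
    locus_positions: tuple = (12_812_500, 13_940_000, 22_210_000,
                              26_300_000, 26_350_000)
    chrom: str = "chrIV"
    p_marine_hap: float = 0.5
    recombinant_fraction: float = 0.15    # per-interval switch prob per hap
    size_baseline: dict | None = None     # per-date mean length (mm)
    size_penalty: float = 0.5             # mm per min-crossover event
    size_sd: float = 2.0
    viability_per_event: float = 0.8      # survival multiplier per event

    def __post_init__(self):
        if len(self.fry_dates) == 0 or len(self.juvenile_dates) == 0:
            raise XomapError("cohort needs at least one fry and one juvenile date")
        if not all(a < b for a, b in zip(self.locus_positions,
                                         self.locus_positions[1:])):
            raise XomapError("locus positions must be strictly increasing")
        if not 0 <= self.recombinant_fraction <= 1:
            raise XomapError("recombinant_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Crossover placement machinery
# ---------------------------------------------------------------------------

def _periphery_cdf_params(target: float, terminal: float) -> float:
    """Weight of the terminal bump in the uniform+terminal mixture such that
    the total mass in the two terminal segments equals ``target``."""
    t = 2 * terminal
    if target <= t:
        return 0.0
    return (target - t) / (1.0 - t)


def _periphery_ppf(u: np.ndarray, L: float, target: float,
                   terminal: float) -> np.ndarray:
    """Inverse CDF of the periphery-biased placement density on [0, L]."""
    c = _periphery_cdf_params(target, terminal)
    t = terminal
    # piecewise-uniform mixture: weight c spread over the two terminal
    # segments, weight 1-c genome-uniform; terminal mass is max(target, 2t)
    m_end = c + (1 - c) * 2 * t
    m1 = m_end / 2
    out = np.empty_like(u, dtype=float)
    lo = u < m1
    hi = u > 1 - m1
    mid = ~(lo | hi)
    out[lo] = u[lo] / m1 * (t * L)
    out[hi] = L - (1 - u[hi]) / m1 * (t * L)
    span = (1 - 2 * t) * L
    out[mid] = t * L + (u[mid] - m1) / (1 - 2 * m1) * span
    return out


def _gamma_renewal_points(rate_length: float, nu: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Stationary gamma-renewal event positions on [0, rate_length] where the
    mean inter-event distance is 1.  Burn-in from the left gives stationarity."""
    if rate_length <= 0:
        return np.array([])
    burn = 10.0 + 5.0 / max(nu, 0.2)
    x = -burn
    pts = []
    while x < rate_length:
        x += rng.gamma(nu, 1.0 / nu)
        if 0 <= x < rate_length:
            pts.append(x)
    return np.asarray(pts)


def simulate_meiosis(spec: SimFamilySpec, sex: str, chrom: str,
                     rng: np.random.Generator,
                     het_intervals: pd.DataFrame | None = None,
                     het_density_per_kb: float = 0.0):
    """Simulate one meiosis on one chromosome; return the crossover
    breakpoints (bp, float) of a single sampled gamete and the starting
    haplotype (1 or 2).

    In obligate-chiasma mode exactly one chiasma forms per bivalent between
    one of the four non-sister chromatid pairs chosen uniformly; one of the
    four chromatids is transmitted, so half of gametes carry the crossover.
    In count mode chiasmata follow a stationary gamma renewal process along
    the map-scaled axis (shape ``nu`` controls interference) and each chiasma
    involves the transmitted chromatid with probability 1/2.

    ``het_intervals`` (BED-style) with ``het_density_per_kb`` > 0 applies
    heterozygosity-dependent suppression: a chiasma proposed inside a
    divergent interval is accepted with probability exp(-k * density).
    """
    if chrom not in spec.chrom_lengths:
        raise XomapError(f"chromosome {chrom!r} absent from spec")
    L = spec.chrom_lengths[chrom]
    genome = sum(spec.chrom_lengths.values())
    mean_total = spec.maternal_mean_xo if sex == "F" else spec.paternal_mean_xo
    nu = spec.interference_nu_f if sex == "F" else spec.interference_nu_m
    target = (spec.periphery_fraction_f if sex == "F"
              else spec.periphery_fraction_m)
    mu_gamete = mean_total * L / genome   # expected gamete crossovers here

    if spec.obligate_chiasma:
        u = rng.random(1)
        pos = _periphery_ppf(u, float(L), target, spec.terminal_fraction)
        # chromatids: homolog 1 = {0,1}, homolog 2 = {2,3}; chiasma joins one
        # chromatid of each, chosen uniformly among the 4 pairs
        a = rng.integers(0, 2)
        b = 2 + rng.integers(0, 2)
        transmitted = rng.integers(0, 4)
        keep = transmitted in (a, b)
        bp = pos if keep else np.array([])
    else:
        # chiasma count on the bivalent has mean 2*mu_gamete; renewal on the
        # CDF-transformed axis so the marginal density is periphery-biased
        map_len = 2.0 * mu_gamete
        pts = _gamma_renewal_points(map_len, nu, rng)
        keep = rng.random(len(pts)) < 0.5    # 2-of-4 chromatid thinning
        pts = pts[keep]
        u = pts / map_len if map_len > 0 else pts
        bp = _periphery_ppf(u, float(L), target, spec.terminal_fraction)

    bp = np.sort(np.atleast_1d(np.asarray(bp, dtype=float)))
    if het_intervals is not None and het_density_per_kb > 0 and len(bp):
        acc = np.exp(-spec.het_suppression_k * het_density_per_kb)
        sub = het_intervals[het_intervals["chrom"] == chrom]
        inside = np.zeros(len(bp), dtype=bool)
        for _, r in sub.iterrows():
            inside |= (bp >= r["start"]) & (bp < r["end"])
        drop = inside & (rng.random(len(bp)) >= acc)
        bp = bp[~drop]
    start_hap = int(rng.integers(1, 3))
    return bp, start_hap


def _labels_from_breakpoints(positions: np.ndarray, bp: np.ndarray,
                             start_hap: int) -> np.ndarray:
    """Haplotype label (1/2) at each SNP position given switch breakpoints."""
    n_switch = np.searchsorted(bp, positions, side="left")
    return np.where(n_switch % 2 == 0, start_hap, 3 - start_hap).astype(np.int8)


# ---------------------------------------------------------------------------
# Family simulation
# ---------------------------------------------------------------------------

def _site_categories(n: int, spec: SimFamilySpec, rng) -> np.ndarray:
    """0 = maternal-informative, 1 = paternal-informative, 2 = both het,
    3 = uninformative."""
    p = np.array([spec.p_maternal_informative, spec.p_paternal_informative,
                  spec.p_both_het, 0.0])
    p[3] = max(0.0, 1.0 - p[:3].sum())
    return rng.choice(4, size=n, p=p / p.sum())


def _parent_hap_ecotypes(ecotype: str) -> tuple[str, str]:
    if ecotype == "hybrid":
        return ("marine", "freshwater")
    return (ecotype, ecotype)


def simulate_family(spec: SimFamilySpec, rng: np.random.Generator):
    """Simulate one nuclear family.

    Returns ``(dataset, truth)`` where ``truth`` holds per-offspring true
    crossover breakpoints, true haplotype-label tracks at informative SNPs,
    and the positions of injected artefact sites.
    """
    samples = ["mother", "father"] + [f"off{i + 1:03d}"
                                      for i in range(spec.n_offspring)]
    n_off = spec.n_offspring
    cov_mean, cov_sd = spec.offspring_coverage
    off_cov = np.clip(rng.normal(cov_mean, cov_sd, n_off), 0.5, None)
    coverages = np.concatenate([[spec.parent_coverage] * 2, off_cov])

    positions, genotypes, ad_ref, ad_alt = {}, {}, {}, {}
    truth = {
        "crossovers": [],           # rows: offspring, parent, chrom, pos
        "tracks": {},               # (offspring, parent, chrom) -> (pos, label)
        "distorted_sites": [],
        "systematic_error_sites": [],
        "blips": [],
    }
    m_eco = _parent_hap_ecotypes(spec.mother_ecotype)
    f_eco = _parent_hap_ecotypes(spec.father_ecotype)
    mother_het_int, father_het_int = None, None
    if spec.adaptive_loci is not None:
        if m_eco[0] != m_eco[1]:
            mother_het_int = spec.adaptive_loci
        if f_eco[0] != f_eco[1]:
            father_het_int = spec.adaptive_loci
    het_dens_kb = spec.divergent_snp_density * 1000.0

    for chrom, L in spec.chrom_lengths.items():
        n_bg = rng.poisson(spec.snp_density * L)
        pos = rng.integers(1, L + 1, size=n_bg)
        cat = _site_categories(n_bg, spec, rng)
        divergent = np.zeros(n_bg, dtype=bool)
        if spec.adaptive_loci is not None:
            loci = spec.adaptive_loci[spec.adaptive_loci["chrom"] == chrom]
            extra_pos, extra_cat = [], []
            for _, r in loci.iterrows():
                n_x = rng.poisson(spec.divergent_snp_density * (r["end"] - r["start"]))
                extra_pos.append(rng.integers(r["start"] + 1, r["end"] + 1, n_x))
            if extra_pos:
                extra_pos = np.concatenate(extra_pos)
                pos = np.concatenate([pos, extra_pos])
                cat = np.concatenate([cat, np.full(len(extra_pos), 4)])
                divergent = np.concatenate(
                    [divergent, np.ones(len(extra_pos), dtype=bool)])
        pos, uniq = np.unique(pos, return_index=True)
        cat, divergent = cat[uniq], divergent[uniq]
        n = len(pos)

        # Parental haplotype alleles (0/1); hap arrays shape (n, 2)
        mo = np.zeros((n, 2), dtype=np.int8)
        fa = np.zeros((n, 2), dtype=np.int8)
        for arr, haps_eco, het_here in (
                (mo, m_eco, cat == 0), (fa, f_eco, cat == 1)):
            # informative parent: heterozygous; order randomised
            flip = rng.random(n) < 0.5
            arr[het_here & flip, 0] = 1
            arr[het_here & ~flip, 1] = 1
        both = cat == 2
        for arr in (mo, fa):
            flip = rng.random(n) < 0.5
            arr[both & flip, 0] = 1
            arr[both & ~flip, 1] = 1
        # homozygous states for the non-informative parent
        hom_alt_mo = (cat == 1) & (rng.random(n) < 0.5)
        hom_alt_fa = (cat == 0) & (rng.random(n) < 0.5)
        mo[hom_alt_mo] = 1
        fa[hom_alt_fa] = 1
        # divergent sites: allele 1 marks the marine haplotype
        for arr, eco in ((mo, m_eco), (fa, f_eco)):
            for h in (0, 1):
                arr[divergent, h] = 1 if eco[h] == "marine" else 0

        inv = None
        if spec.inversions is not None:
            iv = spec.inversions[spec.inversions["chrom"] == chrom]
            inv = list(zip(iv["start"], iv["end"])) if len(iv) else None

        G = np.zeros((n, 2 + n_off), dtype=np.int8)
        G[:, 0] = mo.sum(axis=1)
        G[:, 1] = fa.sum(axis=1)
        mat_inf = pos[cat == 0]
        pat_inf = pos[cat == 1]

        for j in range(n_off):
            off = samples[2 + j]
            alleles = np.zeros(n, dtype=np.int8)
            for parent, arr, sex, het_int, inf_pos in (
                    (MATERNAL, mo, "F", mother_het_int, mat_inf),
                    (PATERNAL, fa, "M", father_het_int, pat_inf)):
                bp, start = simulate_meiosis(
                    spec, sex, chrom, rng,
                    het_intervals=het_int,
                    het_density_per_kb=het_dens_kb if het_int is not None else 0.0)
                labels = _labels_from_breakpoints(pos, bp, start)
                # gene-conversion-like blips: short label flips
                n_blip = rng.poisson(spec.blip_rate)
                for _ in range(n_blip):
                    b0 = rng.integers(1, L + 1)
                    b1 = b0 + rng.integers(spec.blip_tract_bp[0],
                                           spec.blip_tract_bp[1] + 1)
                    flip = (pos >= b0) & (pos < b1)
                    labels[flip] = 3 - labels[flip]
                    truth["blips"].append((off, parent, chrom, int(b0), int(b1)))
                # inversion: reference order of labels reversed inside region
                if inv is not None:
                    for a, b in inv:
                        m = (pos > a) & (pos <= b)
                        labels[m] = labels[m][::-1]
                alleles = alleles + arr[np.arange(n), labels - 1]
                for x in bp:
                    truth["crossovers"].append(
                        {"family": spec.family, "offspring": off,
                         "parent": parent, "chrom": chrom, "pos": float(x)})
                mask = np.isin(pos, inf_pos)
                truth["tracks"][(off, parent, chrom)] = (
                    pos[mask].copy(), labels[mask].copy())
            G[:, 2 + j] = alleles

        # injected artefacts, with truth labels
        if spec.distorted_site_rate > 0:
            bad = rng.random(n) < spec.distorted_site_rate
            bad &= (cat == 0) | (cat == 1)
            for i in np.where(bad)[0]:
                # push family allele frequency to ~0.9, far from 0.25/0.5/0.75
                G[i, 2:] = 1 + (rng.random(n_off) < 0.95).astype(np.int8)
                truth["distorted_sites"].append((chrom, int(pos[i])))
        if spec.systematic_error_rate > 0:
            bad = rng.random(n) < spec.systematic_error_rate
            bad &= (cat == 0) | (cat == 1)
            for i in np.where(bad)[0]:
                hit = rng.random(n_off) < 0.3
                G[i, 2:][hit] = rng.integers(0, 3, hit.sum())
                truth["systematic_error_sites"].append((chrom, int(pos[i])))
        if spec.genotype_error_rate > 0:
            err = rng.random((n, n_off)) < spec.genotype_error_rate
            shift = rng.integers(1, 3, size=(n, n_off)).astype(np.int8)
            G[:, 2:] = np.where(err, (G[:, 2:] + shift) % 3, G[:, 2:])

        # read depths
        dp = rng.poisson(np.broadcast_to(coverages, (n, len(samples))))
        p_alt = np.select(
            [G == 0, G == 1, G == 2],
            [spec.read_error, 0.5, 1 - spec.read_error], default=0.5)
        alt = rng.binomial(dp, p_alt).astype(np.int32)
        ref = (dp - alt).astype(np.int32)

        positions[chrom] = pos.astype(np.int64)
        genotypes[chrom] = G
        ad_ref[chrom] = ref
        ad_alt[chrom] = alt
        if (cat <= 1).sum() == 0:
            log.warning("no informative SNPs simulated on %s", chrom)

    meta = {"mother": {"role": "mother", "sex": "F",
                       "ecotype": spec.mother_ecotype},
            "father": {"role": "father", "sex": "M",
                       "ecotype": spec.father_ecotype}}
    for s in samples[2:]:
        meta[s] = {"role": "offspring", "sex": "U", "ecotype": "offspring"}
    ds = FamilyDataset(spec.family, samples, "mother", "father",
                       positions, genotypes, ad_ref, ad_alt, meta)
    truth["coverage"] = pd.Series(coverages, index=samples)
    return ds, truth


def true_crossover_set(spec: SimFamilySpec, truth: dict) -> CrossoverSet:
    """Ground-truth crossovers as a CrossoverSet (point intervals, 1 bp)."""
    rows = []
    for r in truth["crossovers"]:
        sex = "F" if r["parent"] == MATERNAL else "M"
        eco = spec.mother_ecotype if sex == "F" else spec.father_ecotype
        left = max(1, int(np.floor(r["pos"])))
        rows.append({"family": r["family"], "offspring": r["offspring"],
                     "parent": r["parent"], "sex": sex, "ecotype": eco,
                     "chrom": r["chrom"], "left": left, "right": left + 1})
    gametes = []
    for off in [f"off{i + 1:03d}" for i in range(spec.n_offspring)]:
        for parent, sex, eco in ((MATERNAL, "F", spec.mother_ecotype),
                                 (PATERNAL, "M", spec.father_ecotype)):
            gametes.append({"family": spec.family, "offspring": off,
                            "parent": parent, "sex": sex, "ecotype": eco})
    ev = pd.DataFrame(rows, columns=XO_TRUTH_COLS) if rows else \
        pd.DataFrame(columns=XO_TRUTH_COLS)
    return CrossoverSet(ev, gametes=pd.DataFrame(gametes))


XO_TRUTH_COLS = ["family", "offspring", "parent", "sex", "ecotype",
                 "chrom", "left", "right"]


# ---------------------------------------------------------------------------
# Obligate-chiasma summaries (used by the minimum-recombination argument)
# ---------------------------------------------------------------------------

def obligate_chiasma_counts(n_meioses: int, n_chrom: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Crossover count per chromosome per sampled gamete under the obligate
    single-chiasma model: one chiasma per bivalent between one of the four
    non-sister chromatid pairs (uniform), one of four chromatids transmitted.

    Returns an (n_meioses, n_chrom) 0/1 array.
    """
    a = rng.integers(0, 2, size=(n_meioses, n_chrom))       # chromatid of hom 1
    b = 2 + rng.integers(0, 2, size=(n_meioses, n_chrom))   # chromatid of hom 2
    t = rng.integers(0, 4, size=(n_meioses, n_chrom))       # transmitted
    return ((t == a) | (t == b)).astype(np.int8)


# ---------------------------------------------------------------------------
# VCF writing (plain text, VCF 4.2)
# ---------------------------------------------------------------------------

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_family_vcf(ds: FamilyDataset, path) -> None:
    """Write the family as an uncompressed VCF 4.2 with GT and AD."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, L in sorted((c, 0) for c in ds.chroms):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ds.samples) + "\n")
        for chrom in ds.chroms:
            pos = ds.positions[chrom]
            G = ds.genotypes[chrom]
            R = ds.ad_ref[chrom]
            A = ds.ad_alt[chrom]
            for i in range(len(pos)):
                cells = [f"{_GT_STR[int(g)]}:{r},{a}"
                         for g, r, a in zip(G[i], R[i], A[i])]
                fh.write(f"{chrom}\t{pos[i]}\t.\tA\tG\t.\tPASS\t.\tGT:AD\t"
                         + "\t".join(cells) + "\n")


def family_pedigree(ds: FamilyDataset) -> pd.DataFrame:
    rows = []
    for s in ds.samples:
        m = ds.meta.get(s, {})
        rows.append({"sample": s, "family": ds.family,
                     "role": m.get("role", "offspring"),
                     "sex": m.get("sex", "U"),
                     "ecotype": m.get("ecotype", "unknown")})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hybrid-zone cohort
# ---------------------------------------------------------------------------

def _draw_haplotype(n_loci: int, p_marine: float, rf: float, rng) -> np.ndarray:
    """One 5-locus haplotype: Markov chain with per-interval switch prob rf.
    1 = marine allele (M), 0 = freshwater allele (F)."""
    h = np.empty(n_loci, dtype=np.int8)
    h[0] = rng.random() < p_marine
    for i in range(1, n_loci):
        h[i] = (1 - h[i - 1]) if rng.random() < rf else h[i - 1]
    return h


def _genotype_codes(h1: np.ndarray, h2: np.ndarray) -> list[str]:
    out = []
    for a, b in zip(h1, h2):
        if a == 1 and b == 1:
            out.append("MM")
        elif a == 0 and b == 0:
            out.append("FF")
        else:
            out.append("FM")
    return out


def simulate_cohort(spec: SimCohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Simulate a hybrid-zone cohort table.

    Body size = date baseline - penalty x (min-crossover score) + noise.
    Survival from fry to juvenile stage is thinned with probability
    ``viability_per_event ** score``.
    """
    from .hzfit import min_crossover_score

    L = len(spec.locus_positions)
    dates = list(spec.fry_dates) + list(spec.juvenile_dates)
    baseline = spec.size_baseline or {}
    default_base = {d: 25.0 + 5.0 * i for i, d in enumerate(dates)}
    rows = []
    idv = 0

    def make_individual(date, stage):
        nonlocal idv
        h1 = _draw_haplotype(L, spec.p_marine_hap, spec.recombinant_fraction, rng)
        h2 = _draw_haplotype(L, spec.p_marine_hap, spec.recombinant_fraction, rng)
        g = _genotype_codes(h1, h2)
        score = min_crossover_score(g)
        if stage == "juvenile" and rng.random() > spec.viability_per_event ** score:
            return None
        base = baseline.get(date, default_base[date])
        length = base - spec.size_penalty * score + rng.normal(0, spec.size_sd)
        idv += 1
        row = {"id": f"hz{idv:04d}", "date": date, "stage": stage,
               "length_mm": round(float(max(length, 1.0)), 2),
               "true_score": score}
        for k, p in enumerate(spec.locus_positions):
            row[f"{spec.chrom}_{p}"] = g[k]
        return row

    for stage, n, ds_ in (("fry", spec.n_fry, spec.fry_dates),
                          ("juvenile", spec.n_juvenile, spec.juvenile_dates)):
        made = 0
        while made < n:
            date = ds_[made % len(ds_)]
            row = make_individual(date, stage)
            if row is not None:
                rows.append(row)
                made += 1
    return pd.DataFrame(rows)
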