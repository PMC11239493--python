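"""Forward Wright-Fisher simulation of three linked loci in a
marine-freshwater metapopulation.

Demes are arranged linearly (default FW1 - MAR - FW2) and exchange migrants
with adjacent demes at rate m.  Each locus carries a marine (M = 0) or
freshwater (F = 1) allele; selection is multiplicative across loci with the
locally favoured allele at advantage (1, 1+hs, 1+s).  Gametes recombine at
sex-specific fractions r_F / r_M — the transmitting sex is drawn per gamete,
so heterochiasmy changes the variance but not the mean recombination rate —
and recombination in an interval is suppressed by factor (1 - sigma) when
the parent is heterozygous with the interval's flanking divergent alleles in
coupling phase (an MMM/FFF-type diplotype).

Scenario bundles:
1 heterochiasmy + coupling suppression; 2 heterochiasmy only;
3 neither (r_F = r_M); 5 male recombination suppressed (r_M = 0, r_F as in
scenario 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .iocore import XomapError, log

N_LOCI = 3
HAPLOTYPES = np.array([[(i >> k) & 1 for k in range(N_LOCI - 1, -1, -1)]
                       for i in range(2 ** N_LOCI)])   # 8 x 3, allele 1 = F


@dataclass
class SimConfig:
    deme_types: tuple = ("freshwater", "marine", "freshwater")
    N: int = 1000
    m: float = 0.01
    s: float = 0.1
    h: float = 0.5
    r_mean: float = 0.01            # sex-averaged per-interval recombination
    heterochiasmy: bool = True      # r_F = 2 r_mean, r_M = 0
    sigma: float = 0.8              # coupling-heterozygote suppression
    male_suppressed: bool = False   # scenario 5: r_M = 0, r_F = r_mean
    generations: int = 300
    record_every: int = 10
    init: str = "divergent"         # FW1 = FFF, others = MMM
    init_freq: float = 1.0          # freshwater-haplotype frequency in FW1

    def __post_init__(self):
        for v, name in ((self.m, "m"), (self.sigma, "sigma"),
                        (self.h, "h")):
            if not 0 <= v <= 1:
                raise XomapError(f"{name} must lie in [0, 1]")
        if self.N < 2:
            raise XomapError("N must be >= 2")

    @property
    def r_sex(self) -> tuple[float, float]:
        """(r_F, r_M) per interval."""
        if self.male_suppressed:
            return (self.r_mean, 0.0)
        if self.heterochiasmy:
            return (2 * self.r_mean, 0.0)
        return (self.r_mean, self.r_mean)


SCENARIOS = {
    1: dict(heterochiasmy=True, sigma=0.8, male_suppressed=False),
    2: dict(heterochiasmy=True, sigma=0.0, male_suppressed=False),
    3: dict(heterochiasmy=False, sigma=0.0, male_suppressed=False),
    5: dict(heterochiasmy=False, sigma=0.0, male_suppressed=True),
}


def scenario_config(scenario: int, **overrides) -> SimConfig:
    if scenario not in SCENARIOS:
        raise XomapError(f"unknown scenario {scenario}; defined: 1, 2, 3, 5")
    kw = dict(SCENARIOS[scenario])
    kw.update(overrides)
    return SimConfig(**kw)


# ---------------------------------------------------------------------------
# Gamete production
# ---------------------------------------------------------------------------

def _gamete_table(r1: float, r2: float) -> np.ndarray:
    """P(gamete haplotype | diplotype) for all 64 ordered diplotypes.

    Returns array (8, 8, 8): [hap_i, hap_j, gamete].  The gamete starts on
    either homolog with probability 1/2 and switches at interval k with
    probability r_k, independently.
    """
    out = np.zeros((8, 8, 8))
    for i in range(8):
        for j in range(8):
            for c1 in (0, 1):
                for c2 in (0, 1):
                    p = (r1 if c1 else 1 - r1) * (r2 if c2 else 1 - r2)
                    for start in (0, 1):
                        strand = [start, start ^ c1, start ^ c1 ^ c2]
                        alleles = tuple(
                            HAPLOTYPES[i][k] if strand[k] == 0
                            else HAPLOTYPES[j][k] for k in range(3))
                        g = alleles[0] * 4 + alleles[1] * 2 + alleles[2]
                        out[i, j, g] += 0.5 * p
    return out


def _coupling_het(i: int, j: int, interval: int) -> bool:
    """Is the diplotype (i, j) heterozygous with divergent alleles in
    coupling phase at the flanking loci of ``interval`` (0 or 1)?

    Coupling: one homolog carries both freshwater alleles, the other both
    marine, at the interval's two flanking loci.
    """
    a, b = HAPLOTYPES[i][interval:interval + 2], HAPLOTYPES[j][interval:interval + 2]
    return (tuple(a), tuple(b)) in (((1, 1), (0, 0)), ((0, 0), (1, 1)))


class _GameteKernel:
    """Pre-computed gamete distributions for all suppression patterns."""

    def __init__(self, config: SimConfig):
        r_f, r_m = config.r_sex
        self.tables = {}
        for sex, r in (("F", r_f), ("M", r_m)):
            tabs = {}
            for s1 in (False, True):
                for s2 in (False, True):
                    r1 = r * (1 - config.sigma) if s1 else r
                    r2 = r * (1 - config.sigma) if s2 else r
                    tabs[(s1, s2)] = _gamete_table(r1, r2)
            self.tables[sex] = tabs
        self.supp = np.zeros((8, 8, 2), dtype=bool)
        for i in range(8):
            for j in range(8):
                for k in (0, 1):
                    self.supp[i, j, k] = _coupling_het(i, j, k)

    def gamete_dist(self, diplo_freq: np.ndarray) -> np.ndarray:
        """Gamete haplotype distribution given ordered-diplotype frequencies
        (8x8).  Sex of the transmitting parent is drawn per gamete (1/2)."""
        out = np.zeros(8)
        for sex in ("F", "M"):
            tabs = self.tables[sex]
            for s1 in (False, True):
                for s2 in (False, True):
                    mask = (self.supp[:, :, 0] == s1) & (self.supp[:, :, 1] == s2)
                    w = diplo_freq * mask
                    if w.any():
                        out += 0.5 * np.einsum("ij,ijg->g", w, tabs[(s1, s2)])
        return out


# ---------------------------------------------------------------------------
# Life cycle
# ---------------------------------------------------------------------------

def _fitness_matrix(config: SimConfig, deme_type: str) -> np.ndarray:
    """Multiplicative diploid fitness (8x8) for a deme."""
    favored = 1 if deme_type == "freshwater" else 0   # allele value favoured
    w = np.ones((8, 8))
    for i in range(8):
        for j in range(8):
            for k in range(N_LOCI):
                n_fav = int(HAPLOTYPES[i][k] == favored) \
                    + int(HAPLOTYPES[j][k] == favored)
                w[i, j] *= (1.0, 1.0 + config.h * config.s,
                            1.0 + config.s)[n_fav]
    return w


def step_generation(freqs: np.ndarray, config: SimConfig,
                    kernel: _GameteKernel, fitness: list[np.ndarray],
                    rng: np.random.Generator,
                    deterministic: bool = False) -> np.ndarray:
    """One generation: migration -> selection -> recombination -> sampling.

    ``freqs``: (n_demes, 8) haplotype frequencies.  With
    ``deterministic=True`` the multinomial sampling step is skipped
    (infinite-N recursion, used as an oracle)."""
    n_demes = len(freqs)
    # migration between adjacent demes
    mig = freqs.copy()
    for d in range(n_demes):
        inflow = np.zeros(8)
        n_nb = 0
        for nb in (d - 1, d + 1):
            if 0 <= nb < n_demes:
                inflow += freqs[nb]
                n_nb += 1
        mig[d] = (1 - config.m * n_nb) * freqs[d] + config.m * inflow
    out = np.empty_like(freqs)
    for d in range(n_demes):
        h = mig[d]
        diplo = np.outer(h, h) * fitness[d]
        tot = diplo.sum()
        if tot <= 0:
            out[d] = h
            continue
        diplo /= tot
        g = kernel.gamete_dist(diplo)
        g = np.clip(g, 0, None)
        g /= g.sum()
        if deterministic:
            out[d] = g
        else:
            out[d] = rng.multinomial(2 * config.N, g) / (2 * config.N)
    return out


def initial_state(config: SimConfig) -> np.ndarray:
    """Starting haplotype frequencies.

    ``init='divergent'``: the freshwater haplotype FFF is present only in
    the first deme at ``init_freq`` (spread must pass the hybrid zone);
    ``init='standing'``: every deme starts with FFF at ``init_freq``
    (standing variation; each deme then fixes its favoured alleles)."""
    n = len(config.deme_types)
    freqs = np.zeros((n, 8))
    FFF = 7
    MMM = 0
    for d, t in enumerate(config.deme_types):
        if config.init == "standing" or (d == 0 and t == "freshwater"):
            freqs[d, FFF] = config.init_freq
            freqs[d, MMM] = 1 - config.init_freq
        else:
            freqs[d, MMM] = 1.0
    return freqs


def run(config: SimConfig, seed: int = 0,
        deterministic: bool = False) -> dict:
    """Run one replicate; returns trajectories and summary statistics."""
    rng = np.random.default_rng(seed)
    kernel = _GameteKernel(config)
    fitness = [_fitness_matrix(config, t) for t in config.deme_types]
    freqs = initial_state(config)
    records = []
    spread_time = None
    for gen in range(config.generations + 1):
        p_fresh = freqs @ HAPLOTYPES    # (n_demes, 3) freshwater-allele freq
        if gen % config.record_every == 0 or gen == config.generations:
            for d in range(len(freqs)):
                records.append({"generation": gen, "deme": d,
                                "deme_type": config.deme_types[d],
                                **{f"p_fresh_L{k + 1}": p_fresh[d, k]
                                   for k in range(3)}})
        last_fw = len(freqs) - 1
        if (spread_time is None
                and config.deme_types[last_fw] == "freshwater"
                and p_fresh[last_fw].mean() >= 0.5):
            spread_time = gen
        if gen < config.generations:
            freqs = step_generation(freqs, config, kernel, fitness, rng,
                                    deterministic)
    traj = pd.DataFrame(records)
    stats_ = divergence_stats(traj, config)
    return {"trajectory": traj, "final_freqs": freqs,
            "spread_time": spread_time,
            "established": spread_time is not None,
            "divergence": stats_}


def divergence_stats(traj: pd.DataFrame, config: SimConfig) -> dict:
    """Marine-freshwater allele-frequency divergence and F_ST at the final
    recorded generation (mean over loci)."""
    last = traj[traj["generation"] == traj["generation"].max()]
    pcols = [f"p_fresh_L{k + 1}" for k in range(3)]
    fw = last[last["deme_type"] == "freshwater"][pcols].mean()
    mar = last[last["deme_type"] == "marine"][pcols].mean()
    div = float(np.abs(fw - mar).mean())
    p = last[pcols].to_numpy()
    pbar = p.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(pbar * (1 - pbar) > 0,
                       p.var(axis=0) / (pbar * (1 - pbar)), 0.0)
    return {"divergence": div, "fst": float(np.nanmean(fst))}


def run_scenarios(scenarios=(1, 2, 3, 5), replicates: int = 50,
                  seed: int = 0, **overrides) -> dict:
    """Run scenario bundles and compare them.

    Returns per-replicate summaries and pairwise contrasts (1 vs 3, 1 vs 2,
    5 vs 3) on end-point divergence and spread time (one-sided
    Mann-Whitney)."""
    rows = []
    for sc in scenarios:
        cfg = scenario_config(sc, **overrides)
        for rep in range(replicates):
            res = run(cfg, seed=seed + 7919 * sc + rep)
            rows.append({"scenario": sc, "replicate": rep,
                         "divergence": res["divergence"]["divergence"],
                         "fst": res["divergence"]["fst"],
                         "established": res["established"],
                         "spread_time": res["spread_time"]})
    table = pd.DataFrame(rows)
    contrasts = []
    for a, b in ((1, 3), (1, 2), (5, 3)):
        if a not in scenarios or b not in scenarios:
            continue
        da = table.loc[table["scenario"] == a, "divergence"]
        db = table.loc[table["scenario"] == b, "divergence"]
        u = stats.mannwhitneyu(da, db, alternative="greater")
        contrasts.append({"a": a, "b": b,
                          "mean_div_a": float(da.mean()),
                          "mean_div_b": float(db.mean()),
                          "p_div_greater": float(u.pvalue)})
    return {"replicates": table, "contrasts": pd.DataFrame(contrasts)}
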