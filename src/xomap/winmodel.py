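"""Window-level linear models of sex and ecotype effects on recombination.

For every genomic window the per-individual recombination rate (cM) is
modelled by two-factor OLS (sex, ecotype, interaction).  Model selection is
by AIC over the marginality-respecting candidate set {1, sex, ecotype,
sex + ecotype, sex * ecotype} — the set a backward elimination from the full
model can reach.  Significance is a pooled permutation FDR: crossover
midpoints are relocated uniformly within chromosomes, rates recomputed, and
the observed overall F of the selected model compared with the pooled null F
distribution.

Hybrid dominance: in windows with an ecotype effect, the deviation of the
hybrid mean rate from the parental midpoint, raw and scaled by half the
parental difference (0 additive, +1 high-parent dominant, -1 low-parent
dominant, beyond +/-1 over/underdominant).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .iocore import CrossoverSet, GenomeAnnotation, log

MODELS = {
    "1": [],
    "sex": ["sex"],
    "ecotype": ["ecotype"],
    "sex+ecotype": ["sex", "ecotype"],
    "sex*ecotype": ["sex", "ecotype", "sex:ecotype"],
}


# ---------------------------------------------------------------------------
# Rate matrices
# ---------------------------------------------------------------------------

def _individuals(xoset: CrossoverSet) -> pd.DataFrame:
    gam = (xoset.gametes.groupby(["family", "parent", "sex", "ecotype"])
           .size().rename("n_gametes").reset_index())
    gam["ind"] = gam["family"] + ":" + gam["parent"]
    return gam


def _window_edges(annotation: GenomeAnnotation, window: int):
    out = {}
    for chrom, L in annotation.chrom_lengths.items():
        edges = np.arange(0, L + window, window, dtype=float)
        out[chrom] = edges
    return out


def rate_matrix(events: pd.DataFrame, individuals: pd.DataFrame,
                annotation: GenomeAnnotation, window: int):
    """(windows meta DataFrame, rate matrix [windows x individuals] in cM)."""
    edges = _window_edges(annotation, window)
    metas = []
    for chrom, e in edges.items():
        metas.append(pd.DataFrame({
            "chrom": chrom, "start": e[:-1].astype(int),
            "end": np.minimum(e[1:], annotation.chrom_lengths[chrom]).astype(int)}))
    meta = pd.concat(metas, ignore_index=True)
    Y = np.zeros((len(meta), len(individuals)))
    offsets = {}
    off = 0
    for chrom, e in edges.items():
        offsets[chrom] = off
        off += len(e) - 1
    grouped = dict(list(events.groupby(["family", "parent"]))) if len(events) else {}
    for j, ind in individuals.iterrows():
        sub = grouped.get((ind["family"], ind["parent"]))
        if sub is None:
            continue
        for chrom, s in sub.groupby("chrom"):
            h, _ = np.histogram(s["midpoint"].to_numpy(dtype=float),
                                bins=edges[chrom])
            o = offsets[chrom]
            Y[o:o + len(h), j] += h
    Y = 100.0 * Y / individuals["n_gametes"].to_numpy()[None, :]
    return meta, Y


# ---------------------------------------------------------------------------
# Vectorized OLS machinery
# ---------------------------------------------------------------------------

def _design(individuals: pd.DataFrame, model: str) -> np.ndarray:
    n = len(individuals)
    cols = [np.ones(n)]
    sex_d = pd.get_dummies(individuals["sex"], drop_first=True).to_numpy(float)
    eco_d = pd.get_dummies(individuals["ecotype"], drop_first=True).to_numpy(float)
    terms = MODELS[model]
    if "sex" in terms:
        cols.append(sex_d)
    if "ecotype" in terms:
        cols.append(eco_d)
    if "sex:ecotype" in terms:
        inter = np.einsum("ni,nj->nij", sex_d, eco_d).reshape(n, -1)
        cols.append(inter)
    X = np.column_stack(cols)
    # drop collinear columns (empty cells)
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(r).max())
    return X[:, keep]


def _rss(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    q, _ = np.linalg.qr(X)
    proj = Y @ q
    rss = (Y ** 2).sum(axis=1) - (proj ** 2).sum(axis=1)
    return np.maximum(rss, 0.0), X.shape[1]


def select_models(Y: np.ndarray, individuals: pd.DataFrame):
    """AIC-selected model per window over the marginality-respecting set.

    Returns (model name array, overall F vs intercept, per-model RSS dict).
    """
    n = Y.shape[1]
    rss = {}
    p = {}
    for name in MODELS:
        X = _design(individuals, name)
        rss[name], p[name] = _rss(Y, X)
    names = list(MODELS)
    aic = np.stack([n * np.log(np.maximum(rss[m], 1e-300) / n) + 2 * (p[m] + 1)
                    for m in names])
    best = np.argmin(aic, axis=0)
    chosen = np.array(names, dtype=object)[best]
    # overall F of the chosen model vs intercept
    F = np.zeros(len(chosen))
    for i, m in enumerate(chosen):
        if m == "1":
            continue
        df1 = p[m] - 1
        df2 = n - p[m]
        num = (rss["1"][i] - rss[m][i]) / max(df1, 1)
        den = rss[m][i] / max(df2, 1)
        F[i] = num / den if den > 0 else np.inf
    return chosen, F, rss, p


# ---------------------------------------------------------------------------
# Fitting with permutation FDR
# ---------------------------------------------------------------------------

def fit_window_models(xoset: CrossoverSet, annotation: GenomeAnnotation,
                      window: int = 500_000, n_perm: int = 2000,
                      fdr: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Fit per-window sex/ecotype models with pooled permutation FDR.

    Windows with all-zero rates are excluded.  Returns one row per retained
    window with the selected model, overall F, empirical FDR, and effect
    sizes (differences of group means, cM).
    """
    rng = np.random.default_rng(seed)
    individuals = _individuals(xoset)
    meta, Y = rate_matrix(xoset.events, individuals, annotation, window)
    nz = Y.sum(axis=1) > 0
    meta, Y = meta[nz].reset_index(drop=True), Y[nz]
    if len(meta) == 0:
        return pd.DataFrame()
    chosen, F, rss, p = select_models(Y, individuals)

    # permutation null: uniform relocation of midpoints within chromosomes
    ev = xoset.events
    null_F = []
    for _ in range(n_perm):
        sh = ev.copy()
        L = sh["chrom"].map(annotation.chrom_lengths).to_numpy(dtype=float)
        sh["midpoint"] = rng.uniform(0, L)
        _, Yn = rate_matrix(sh, individuals, annotation, window)
        Yn = Yn[nz]
        _, Fn, _, _ = select_models(Yn, individuals)
        null_F.append(Fn)
    null_F = np.concatenate(null_F) if null_F else np.array([0.0])

    obs_sorted = np.sort(F)
    null_sorted = np.sort(null_F)
    fdr_vals = np.empty(len(F))
    for i, f in enumerate(F):
        n_obs_ge = len(F) - np.searchsorted(obs_sorted, f, side="left")
        n_null_ge = (len(null_sorted)
                     - np.searchsorted(null_sorted, f, side="left")) / max(n_perm, 1)
        fdr_vals[i] = min(n_null_ge / max(n_obs_ge, 1), 1.0) if f > 0 else 1.0

    eff = effect_sizes(Y, individuals)
    out = meta.copy()
    out["model"] = chosen
    out["F"] = F
    out["fdr"] = fdr_vals
    out["significant"] = (out["fdr"] < fdr) & (out["model"] != "1")
    for c in eff.columns:
        out[c] = eff[c].to_numpy()
    out["window_bp"] = out["end"] - out["start"]
    return out


def effect_sizes(Y: np.ndarray, individuals: pd.DataFrame) -> pd.DataFrame:
    """Signed differences of group-mean rates per window (cM)."""
    sex = individuals["sex"].to_numpy()
    eco = individuals["ecotype"].to_numpy()
    out = {}
    f, m = Y[:, sex == "F"], Y[:, sex == "M"]
    if f.shape[1] and m.shape[1]:
        out["sex_effect"] = f.mean(axis=1) - m.mean(axis=1)
    mar, fre = Y[:, eco == "marine"], Y[:, eco == "freshwater"]
    if mar.shape[1] and fre.shape[1]:
        out["ecotype_effect"] = mar.mean(axis=1) - fre.mean(axis=1)
        for s in ("F", "M"):
            a = Y[:, (eco == "marine") & (sex == s)]
            b = Y[:, (eco == "freshwater") & (sex == s)]
            if a.shape[1] and b.shape[1]:
                out[f"ecotype_effect_{s}"] = a.mean(axis=1) - b.mean(axis=1)
    return pd.DataFrame(out)


def genome_fraction_by_term(results: pd.DataFrame,
                            annotation: GenomeAnnotation) -> pd.Series:
    """Fraction of the genome in significant windows, per retained model."""
    G = annotation.genome_length
    sig = results[results["significant"]]
    return sig.groupby("model")["window_bp"].sum() / G


# ---------------------------------------------------------------------------
# Hybrid dominance / additivity
# ---------------------------------------------------------------------------

def dominance(xoset: CrossoverSet, annotation: GenomeAnnotation,
              sig_windows: pd.DataFrame,
              scales=(5_000, 50_000, 500_000),
              by_sex: bool = False) -> pd.DataFrame:
    """Hybrid deviation from the parental midpoint in ecotype-significant
    windows, at several sub-window scales.

    ratio = (hybrid - midparent) / (0.5 * |high - low|); 0 = additive,
    +1 = high-parent dominant, -1 = low-parent dominant.
    """
    individuals = _individuals(xoset)
    ev = xoset.events
    records = []
    strata = ["F", "M"] if by_sex else [None]
    for scale in scales:
        for _, w in sig_windows.iterrows():
            edges = np.arange(w["start"], w["end"] + scale, scale, dtype=float)
            edges[-1] = min(edges[-1], w["end"])
            sub = ev[(ev["chrom"] == w["chrom"])
                     & (ev["midpoint"] > w["start"])
                     & (ev["midpoint"] <= w["end"])]
            for s in strata:
                inds = individuals if s is None else \
                    individuals[individuals["sex"] == s]
                rates = {}
                for eco in ("marine", "freshwater", "hybrid"):
                    ig = inds[inds["ecotype"] == eco]
                    if len(ig) == 0:
                        rates[eco] = None
                        continue
                    mat = np.zeros((len(edges) - 1, len(ig)))
                    for j, (_, ind) in enumerate(ig.iterrows()):
                        m = sub[(sub["family"] == ind["family"])
                                & (sub["parent"] == ind["parent"])]
                        h, _ = np.histogram(m["midpoint"], bins=edges)
                        mat[:, j] = 100.0 * h / ind["n_gametes"]
                    rates[eco] = mat.mean(axis=1)
                if any(rates[e] is None for e in rates):
                    continue
                high = np.maximum(rates["marine"], rates["freshwater"])
                low = np.minimum(rates["marine"], rates["freshwater"])
                mid = (high + low) / 2.0
                dev = rates["hybrid"] - mid
                half = 0.5 * (high - low)
                for k in range(len(dev)):
                    undef = half[k] == 0
                    records.append({
                        "chrom": w["chrom"],
                        "start": int(edges[k]), "end": int(edges[k + 1]),
                        "scale": scale, "sex": s or "both",
                        "parent_high": high[k], "parent_low": low[k],
                        "hybrid": rates["hybrid"][k],
                        "deviation": dev[k],
                        "ratio": np.nan if undef else dev[k] / half[k],
                        "undefined": bool(undef),
                    })
    df = pd.DataFrame(records)
    if len(df) == 0:
        log.warning("dominance: no comparable windows")
    return df


def dominance_summary(records: pd.DataFrame) -> pd.DataFrame:
    ok = records[~records["undefined"]]
    return (ok.groupby(["scale", "sex"])["ratio"]
            .agg(["median", "mean", lambda r: float((r < 0).mean())])
            .rename(columns={"<lambda_0>": "mass_below_zero"}))
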