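"""Core containers, coordinate conventions and file I/O.

Conventions
-----------
* SNP positions are 1-based (as in VCF) everywhere inside the package.
* A crossover is an interval ``(left, right]`` in bp between the last SNP of
  the first parental haplotype and the first SNP of the second.
* Annotation interval sets (genes, peaks, adaptive loci, ...) are stored in
  BED convention: 0-based half-open.  Conversion happens only at the point
  of comparison (`points_in_intervals`) and at BED export/import.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("xomap")

MATERNAL = "maternal"
PATERNAL = "paternal"

XO_COLUMNS = [
    "family", "offspring", "parent", "sex", "ecotype", "chrom", "left", "right",
]


class XomapError(RuntimeError):
    """Fatal, user-facing error (bad input, inconsistent files)."""


# ---------------------------------------------------------------------------
# Genotype container
# ---------------------------------------------------------------------------

@dataclass
class FamilyDataset:
    """Genotypes and per-allele depths for one nuclear family.

    Arrays are keyed by chromosome; rows are SNPs in strictly increasing
    1-based position order, columns are family members in ``samples`` order.
    Genotypes are alt-allele dosages (0, 1, 2) with -1 for missing.
    """

    family: str
    samples: list[str]
    mother: str
    father: str
    positions: dict[str, np.ndarray]
    genotypes: dict[str, np.ndarray]
    ad_ref: dict[str, np.ndarray]
    ad_alt: dict[str, np.ndarray]
    meta: dict[str, dict] = field(default_factory=dict)
    n_multiallelic_skipped: int = 0

    @property
    def offspring(self) -> list[str]:
        return [s for s in self.samples if s not in (self.mother, self.father)]

    @property
    def chroms(self) -> list[str]:
        return list(self.positions)

    def n_sites(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.positions[chrom])
        return sum(len(p) for p in self.positions.values())

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise XomapError(f"sample {name!r} not present in family {self.family}")

    def mean_coverage(self) -> pd.Series:
        """Mean total read depth per sample across all retained sites."""
        tot = np.zeros(len(self.samples), dtype=float)
        n = 0
        for chrom in self.chroms:
            tot += (self.ad_ref[chrom] + self.ad_alt[chrom]).sum(axis=0)
            n += len(self.positions[chrom])
        return pd.Series(tot / max(n, 1), index=self.samples)


def read_genotypes(path, pedigree: pd.DataFrame) -> FamilyDataset:
    """Read a family VCF into a :class:`FamilyDataset`.

    Parameters
    ----------
    path
        VCF 4.x file with GT and AD for every family member.
    pedigree
        Table with columns ``sample``, ``role`` (mother/father/offspring),
        ``family`` and optionally ``sex``/``ecotype``.  Exactly one mother
        and one father are required.

    Multiallelic records are skipped (counted), indels are skipped.
    """
    from cyvcf2 import VCF

    mothers = pedigree.loc[pedigree["role"] == "mother", "sample"].tolist()
    fathers = pedigree.loc[pedigree["role"] == "father", "sample"].tolist()
    if len(mothers) != 1 or len(fathers) != 1:
        raise XomapError("pedigree must name exactly one mother and one father")
    family = str(pedigree["family"].iloc[0]) if "family" in pedigree else "fam"

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    for s in pedigree["sample"]:
        if s not in samples:
            raise XomapError(f"sample {s!r} from pedigree missing in VCF {path}")

    pos: dict[str, list] = {}
    gts: dict[str, list] = {}
    adr: dict[str, list] = {}
    ada: dict[str, list] = {}
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        if not var.is_snp:
            continue
        c = var.CHROM
        g = np.asarray(var.gt_types, dtype=np.int8)  # 0,1,2 and 3=unknown
        g[g == 3] = -1
        ad = var.format("AD")
        if ad is None:
            r = np.zeros(len(samples), dtype=np.int32)
            a = np.zeros(len(samples), dtype=np.int32)
        else:
            ad = np.asarray(ad, dtype=np.int32)
            ad[ad < 0] = 0
            r, a = ad[:, 0], ad[:, 1]
        pos.setdefault(c, []).append(var.POS)
        gts.setdefault(c, []).append(g)
        adr.setdefault(c, []).append(r)
        ada.setdefault(c, []).append(a)
    if n_multi:
        log.info("read_genotypes: skipped %d multiallelic records", n_multi)

    meta = {}
    for _, row in pedigree.iterrows():
        meta[row["sample"]] = {
            "role": row["role"],
            "sex": row.get("sex", "F" if row["role"] == "mother" else "M"),
            "ecotype": row.get("ecotype", "unknown"),
        }
    ds = FamilyDataset(
        family=family,
        samples=samples,
        mother=mothers[0],
        father=fathers[0],
        positions={c: np.asarray(v, dtype=np.int64) for c, v in pos.items()},
        genotypes={c: np.vstack(v) for c, v in gts.items()},
        ad_ref={c: np.vstack(v) for c, v in adr.items()},
        ad_alt={c: np.vstack(v) for c, v in ada.items()},
        meta=meta,
        n_multiallelic_skipped=n_multi,
    )
    for c, p in ds.positions.items():
        if len(p) > 1 and not np.all(np.diff(p) > 0):
            raise XomapError(f"VCF positions not strictly increasing on {c}")
    return ds


# ---------------------------------------------------------------------------
# Genome annotation
# ---------------------------------------------------------------------------

@dataclass
class GenomeAnnotation:
    """Chromosome lengths plus named interval sets (BED convention)."""

    chrom_lengths: dict[str, int]
    centromeres: dict[str, int] = field(default_factory=dict)
    intervals: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self):
        if sum(self.chrom_lengths.values()) <= 0:
            raise XomapError("total genome length must be positive")
        for name, df in self.intervals.items():
            self.intervals[name] = self._validate(name, df)

    def _validate(self, name: str, df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        for _, r in df.iterrows():
            L = self.chrom_lengths.get(r["chrom"])
            if L is None:
                raise XomapError(f"interval set {name!r}: unknown chromosome {r['chrom']!r}")
            if not (0 <= r["start"] < r["end"] <= L):
                raise XomapError(
                    f"interval set {name!r}: bad interval {r['chrom']}:{r['start']}-{r['end']}")
        return df.sort_values(["chrom", "start"]).reset_index(drop=True)

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def add_intervals(self, name: str, df: pd.DataFrame) -> None:
        self.intervals[name] = self._validate(name, df)

    def add_intervals_from_bed(self, name: str, path) -> None:
        self.add_intervals(name, read_bed(path))


def read_bed(path) -> pd.DataFrame:
    """Read BED3+ into a DataFrame (chrom, start, end[, name, score, strand])."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"], df["length"].astype(int)))


def points_in_intervals(chroms: np.ndarray, pos: np.ndarray,
                        intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask: is each 1-based point inside any BED interval."""
    out = np.zeros(len(pos), dtype=bool)
    for chrom, sub in intervals.groupby("chrom"):
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        p = pos[sel]
        # 1-based point m is inside [start, end) 0-based iff start < m <= end
        idx = np.searchsorted(starts, p, side="left") - 1
        ok = (idx >= 0) & (p <= ends[np.clip(idx, 0, None)])
        out[sel] = ok
    return out


# ---------------------------------------------------------------------------
# Crossovers
# ---------------------------------------------------------------------------

@dataclass
class CrossoverSet:
    """A set of crossover events plus the gamete roster they came from.

    ``events`` columns: family, offspring, parent, sex, ecotype, chrom,
    left, right (1-based SNP positions; the crossover lies in (left, right]).
    ``gametes`` lists every meiotic product (offspring x parent-of-origin)
    so that zero-crossover gametes contribute to per-gamete means.
    """

    events: pd.DataFrame
    gametes: pd.DataFrame | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        ev = self.events
        missing = [c for c in XO_COLUMNS if c not in ev.columns]
        if missing:
            raise XomapError(f"CrossoverSet missing columns {missing}")
        if len(ev) and not (ev["left"] < ev["right"]).all():
            raise XomapError("crossover intervals must satisfy left < right")
        ev = ev.copy()
        ev["resolution"] = ev["right"] - ev["left"]
        ev["midpoint"] = (ev["left"] + ev["right"]) // 2
        self.events = ev.reset_index(drop=True)
        if self.gametes is None:
            self.gametes = (
                ev[["family", "offspring", "parent", "sex", "ecotype"]]
                .drop_duplicates().reset_index(drop=True)
            )

    def __len__(self) -> int:
        return len(self.events)

    @property
    def n_gametes(self) -> int:
        return len(self.gametes)

    def subset(self, mask, note: str | None = None) -> "CrossoverSet":
        sub = CrossoverSet(self.events.loc[mask, XO_COLUMNS],
                           gametes=self.gametes,
                           provenance=list(self.provenance))
        if note:
            sub.provenance.append(note)
        return sub

    def counts_per_gamete(self) -> pd.DataFrame:
        """One row per gamete with its crossover count (zeros included)."""
        key = ["family", "offspring", "parent"]
        counts = self.events.groupby(key).size().rename("count")
        out = self.gametes.set_index(key).join(counts).fillna({"count": 0})
        out["count"] = out["count"].astype(int)
        return out.reset_index()


def write_crossovers(xoset: CrossoverSet, path) -> None:
    """Write crossovers as sorted BED6: (chrom, left-1, right, offspring:parent,
    resolution, '.')."""
    if len(xoset) == 0:
        raise XomapError("refusing to write an empty crossover set")
    ev = xoset.events.sort_values(["chrom", "left", "right"])
    with open(path, "w") as fh:
        for _, r in ev.iterrows():
            name = f"{r['family']}|{r['offspring']}|{r['parent']}|{r['sex']}|{r['ecotype']}"
            fh.write(f"{r['chrom']}\t{r['left'] - 1}\t{r['right']}\t{name}"
                     f"\t{r['resolution']}\t.\n")


def read_crossovers(path, gametes: pd.DataFrame | None = None) -> CrossoverSet:
    """Read a BED file written by :func:`write_crossovers`."""
    df = read_bed(path)
    parts = df["name"].str.split("|", expand=True)
    ev = pd.DataFrame({
        "family": parts[0], "offspring": parts[1], "parent": parts[2],
        "sex": parts[3], "ecotype": parts[4],
        "chrom": df["chrom"], "left": df["start"] + 1, "right": df["end"],
    })
    return CrossoverSet(ev, gametes=gametes)


def write_gametes(gametes: pd.DataFrame, path) -> None:
    gametes.to_csv(path, sep="\t", index=False)


def read_gametes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise XomapError("config file must contain a mapping at top level")
    return cfg
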