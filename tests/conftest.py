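import numpy as np
import pandas as pd
import pytest

from xomap.famphase import phase_family
from xomap.iocore import MATERNAL, PATERNAL, CrossoverSet
from xomap.synthdata import SimFamilySpec, simulate_family, true_crossover_set
from xomap.xocall import call_crossovers

SMALL_CHROMS = {"chr1": 3_000_000, "chr2": 3_000_000}


def small_spec(**kw) -> SimFamilySpec:
    base = dict(chrom_lengths=dict(SMALL_CHROMS), n_offspring=30,
                snp_density=2e-3, maternal_mean_xo=2.0, paternal_mean_xo=1.2,
                genotype_error_rate=0.0, blip_rate=0.0)
    base.update(kw)
    return SimFamilySpec(**base)


@pytest.fixture(scope="session")
def clean_family():
    """Noise-free family: no genotyping error, no blips, no inversions."""
    spec = small_spec()
    ds, truth = simulate_family(spec, np.random.default_rng(11))
    return spec, ds, truth


@pytest.fixture(scope="session")
def clean_tracks(clean_family):
    _, ds, _ = clean_family
    return phase_family(ds)


@pytest.fixture(scope="session")
def clean_calls(clean_family, clean_tracks):
    spec, ds, truth = clean_family
    meta = {MATERNAL: ("F", "marine"), PATERNAL: ("M", "marine")}
    xoset, audit, inv = call_crossovers(clean_tracks, meta, truth["coverage"])
    return xoset, audit, true_crossover_set(spec, truth), truth["coverage"]


def synthetic_crossover_set(rng, n_events=400, chroms=SMALL_CHROMS,
                            n_offspring=20, sexes=("F", "M"),
                            ecotype="marine", family="fam1",
                            positions=None) -> CrossoverSet:
    """Uniformly placed crossovers assigned to random gametes (test helper)."""
    chrom_names = list(chroms)
    rows = []
    for i in range(n_events):
        c = chrom_names[rng.integers(len(chrom_names))]
        pos = (positions[i] if positions is not None
               else int(rng.integers(1, chroms[c] - 1)))
        parent = MATERNAL if rng.random() < 0.5 else PATERNAL
        rows.append({
            "family": family,
            "offspring": f"off{rng.integers(n_offspring) + 1:03d}",
            "parent": parent,
            "sex": "F" if parent == MATERNAL else "M",
            "ecotype": ecotype, "chrom": c,
            "left": pos, "right": pos + 2,
        })
    gametes = pd.DataFrame(
        [{"family": family, "offspring": f"off{i + 1:03d}", "parent": p,
          "sex": "F" if p == MATERNAL else "M", "ecotype": ecotype}
         for i in range(n_offspring) for p in (MATERNAL, PATERNAL)])
    return CrossoverSet(pd.DataFrame(rows), gametes=gametes)
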