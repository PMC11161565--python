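import numpy as np
import pytest

from radtrace.model import AlleleCall, GenotypeTable, PopulationMap, SiteRecord


def make_sites(n, per_locus=1, with_coords=True):
    sites = []
    for j in range(n):
        locus = f"L{j // per_locus:04d}"
        col = j % per_locus
        kw = {"chrom": locus, "pos": col + 1} if with_coords else {}
        sites.append(SiteRecord(site_id=f"s{j}", locus_id=locus, column=col, **kw))
    return sites


def random_table(rng, n_ind=10, n_sites=20, per_locus=2, miss=0.1, prefix="I"):
    """Random pseudo-diploid table for oracle tests."""
    inds = [f"{prefix}{i}" for i in range(n_ind)]
    sites = make_sites(n_sites, per_locus=per_locus)
    a = rng.integers(0, 4, size=(n_ind, n_sites), dtype=np.int8)
    b = rng.integers(0, 4, size=(n_ind, n_sites), dtype=np.int8)
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    gone = rng.random((n_ind, n_sites)) < miss
    lo[gone] = -1
    hi[gone] = -1
    return GenotypeTable(inds, sites, lo, hi)


def table_from_strings(genotypes, per_locus=1):
    """Build a table from {'ind': ['A/T', './.', 'G/G', ...]} strings."""
    inds = list(genotypes)
    n_sites = len(next(iter(genotypes.values())))
    sites = make_sites(n_sites, per_locus=per_locus)
    calls = {}
    for ind, row in genotypes.items():
        for j, g in enumerate(row):
            if g in ("./.", "."):
                continue
            a, b = g.split("/")
            calls[(ind, f"s{j}")] = AlleleCall.of(a, b)
    return GenotypeTable.from_calls(inds, sites, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def worked_toy():
    """Ancestors A/B and derived D from the worked tracing example."""
    table = table_from_strings({
        "a1": ["A/A", "C/T", "G/G"],
        "b1": ["A/A", "C/C", "G/A"],
        "D": ["A/A", "T/C", "G/G"],
    })
    pops = PopulationMap({
        "a1": ("A", "ancestral"),
        "b1": ("B", "ancestral"),
        "D": ("Dpop", "derived"),
    })
    return table, pops
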