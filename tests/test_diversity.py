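import numpy as np
import pytest

from radtrace.diversity import filter_sites, individual_hexp, population_diversity
from radtrace.model import AlleleCall, FilterConfig, PopulationMap
from radtrace.simulate import DerivedPopConfig, SimulationConfig, simulate_dataset
from .conftest import random_table, table_from_strings


def brute_filter(table, pops, cfg):
    """Independent site-by-site re-evaluation of the filter rules."""
    kept = []
    for j, site in enumerate(table.sites):
        ok = True
        if cfg.scope == "overall" or pops is None:
            typed = sum(1 for i in range(table.n_individuals) if table.a_lo[i, j] >= 0)
            ok &= typed / table.n_individuals >= cfg.r
        else:
            for pop in pops.populations():
                rows = [table.individual_index(x) for x in pops.members(pop)]
                if not rows:
                    continue
                typed = sum(1 for i in rows if table.a_lo[i, j] >= 0)
                ok &= typed / len(rows) >= cfg.r
        # overall MAF from allele copies
        copies = []
        for i in range(table.n_individuals):
            lo, hi = table.a_lo[i, j], table.a_hi[i, j]
            if lo >= 0:
                copies += [int(lo), int(hi)]
        if copies:
            from collections import Counter
            top = Counter(copies).most_common(1)[0][1]
            maf = 1 - top / len(copies)
        else:
            maf = 0.0
        ok &= maf >= cfg.min_maf or cfg.min_maf == 0
        if ok:
            kept.append(site.site_id)
    return kept


class TestFilterSites:
    def test_identity_when_disabled(self, rng):
        t = random_table(rng, 8, 12)
        cfg = FilterConfig(r=0.0, min_maf=0.0)
        assert filter_sites(t, None, cfg) == t

    def test_r_threshold(self):
        # site typed in 4 of 10 individuals, R=0.5 -> dropped
        geno = {f"i{k}": ["A/T" if k < 4 else "./."] for k in range(10)}
        t = table_from_strings(geno)
        out = filter_sites(t, None, FilterConfig(r=0.5))
        assert out.n_sites == 0
        out2 = filter_sites(t, None, FilterConfig(r=0.4))
        assert out2.n_sites == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_ind=10, n_sites=20, miss=0.3)
        pops = PopulationMap({
            ind: (f"P{k % 3}", "ancestral") for k, ind in enumerate(t.individuals)
        })
        cfg = FilterConfig(
            r=float(rng.choice([0.3, 0.5, 0.8])),
            min_maf=float(rng.choice([0.0, 0.05, 0.2])),
            scope=str(rng.choice(["overall", "per_population"])),
        )
        got = [s.site_id for s in filter_sites(t, pops, cfg).sites]
        assert got == brute_filter(t, pops, cfg)

    def test_one_snp_per_locus(self, rng):
        t = random_table(rng, n_ind=12, n_sites=30, per_locus=3, miss=0.0)
        cfg = FilterConfig(r=0.0, min_maf=0.0, one_snp_per_locus=True, seed=7)
        out = filter_sites(t, None, cfg)
        loci = [s.locus_id for s in out.sites]
        assert len(loci) == len(set(loci)) == 10
        # deterministic under the same seed
        again = filter_sites(t, None, cfg)
        assert [s.site_id for s in again.sites] == [s.site_id for s in out.sites]


class TestPopulationDiversity:
    def test_worked_example(self):
        # two diploids A/T and A/A: p_A = 0.75, Hexp = 0.375, Hobs = 0.5, FIS = -1/3
        t = table_from_strings({"i1": ["A/T"], "i2": ["A/A"]})
        pm = PopulationMap({"i1": ("P", "ancestral"), "i2": ("P", "ancestral")})
        (rec,) = population_diversity(t, pm)
        assert rec.hobs == pytest.approx(0.5)
        assert rec.hexp == pytest.approx(0.375)
        assert rec.fis == pytest.approx(-1.0 / 3.0)

    def test_monomorphic(self):
        t = table_from_strings({"i1": ["A/A"], "i2": ["A/A"]})
        pm = PopulationMap({"i1": ("P", "ancestral"), "i2": ("P", "ancestral")})
        (rec,) = population_diversity(t, pm)
        assert rec.hobs == 0.0 and rec.hexp == 0.0
        assert np.isnan(rec.fis)

    def test_empty_population(self):
        t = table_from_strings({"i1": ["A/T"]})
        pm = PopulationMap({"i1": ("P", "ancestral"), "ghost": ("Q", "ancestral")})
        recs = {r.population: r for r in population_diversity(t, pm)}
        assert recs["Q"].n == 0 and np.isnan(recs["Q"].hexp)

    def test_pa_brute_force(self, rng):
        t = random_table(rng, n_ind=9, n_sites=5, miss=0.2)
        pm = PopulationMap({ind: (f"P{k % 3}", "ancestral")
                            for k, ind in enumerate(t.individuals)})
        recs = {r.population: r for r in population_diversity(t, pm)}
        # brute-force allele presence set difference
        present = {}
        for pop in pm.populations():
            s = set()
            for ind in pm.members(pop):
                for site in t.sites:
                    c = t.call(ind, site.site_id)
                    if not c.missing:
                        s |= {(site.site_id, a) for a in c.alleles}
            present[pop] = s
        for pop in pm.populations():
            others = set().union(*(present[o] for o in present if o != pop))
            assert recs[pop].pa == len(present[pop] - others)

    def test_bounds_invariant(self, rng):
        t = random_table(rng, n_ind=15, n_sites=40, miss=0.25)
        pm = PopulationMap({ind: (f"P{k % 2}", "ancestral")
                            for k, ind in enumerate(t.individuals)})
        for rec in population_diversity(t, pm):
            assert 0.0 <= rec.hobs <= 1.0
            assert 0.0 <= rec.hexp <= 1.0
            assert rec.pa >= 0
            if rec.n_per_locus_mean > 0:
                assert rec.pa_per_n == pytest.approx(rec.pa / rec.n_per_locus_mean)

    def test_fis_method_option(self):
        t = table_from_strings({"i1": ["A/T", "C/C"], "i2": ["A/A", "C/G"]})
        pm = PopulationMap({"i1": ("P", "ancestral"), "i2": ("P", "ancestral")})
        a = population_diversity(t, pm, fis_method="mean_of_ratios")[0].fis
        b = population_diversity(t, pm, fis_method="ratio_of_means")[0].fis
        assert a == pytest.approx(-1.0 / 3.0)
        assert b == pytest.approx(-1.0 / 3.0)  # symmetric toy: both -1/3


class TestFisSimulationProperties:
    def test_random_mating_fis_near_zero(self):
        vals = []
        for seed in range(10):
            cfg = SimulationConfig(
                n_ancestors=2, n_loci=1000, sites_per_locus=2, seed=seed,
                private_rates=[0.0, 0.0], ancestral_sample_sizes=[30, 30],
                dirichlet_alpha=3.0, emit_sequences=False)
            ds = simulate_dataset(cfg)
            recs = population_diversity(ds.table, ds.popmap)
            vals += [r.fis for r in recs]
        assert abs(float(np.mean(vals))) < 0.05

    def test_clonal_fis_differs_from_sexual(self):
        cfg = SimulationConfig(
            n_ancestors=2, n_loci=500, sites_per_locus=2, seed=4,
            private_rates=[0.0, 0.0], ancestral_sample_sizes=[10, 10],
            derived_populations=[
                DerivedPopConfig("Sex", 15, (0.3, 0.3, 0.4)),
                DerivedPopConfig("Apo", 15, (0.3, 0.3, 0.4), clonal=True,
                                 clone_mutation_rate=0.0005, n_clone_groups=1),
            ],
            dirichlet_alpha=3.0, emit_sequences=False)
        ds = simulate_dataset(cfg)
        recs = {r.population: r for r in population_diversity(ds.table, ds.popmap)}
        # one clone group: every polymorphic site is a repeated founder het,
        # so site-level FIS sits near -1, well below the sexual population
        assert recs["Apo"].fis < recs["Sex"].fis - 0.15
        assert recs["Apo"].fis < -0.9


class TestIndividualHexp:
    def test_all_het_upper_bound(self):
        t = table_from_strings({"i1": ["A/T", "C/G", "A/C"]})
        (d,) = individual_hexp(t)
        assert d.hexp_ind == pytest.approx(0.5)
        assert d.n_variant_sites == 3

    def test_all_hom_zero(self):
        t = table_from_strings({"i1": ["A/A", "C/C"]})
        (d,) = individual_hexp(t)
        assert d.hexp_ind == 0.0

    def test_three_of_eight(self):
        row = ["A/T", "C/G", "A/C"] + ["A/A"] * 5
        t = table_from_strings({"i1": row})
        (d,) = individual_hexp(t)
        assert d.hexp_ind == pytest.approx(0.1875)  # 0.5 * 3/8

    def test_no_sites_is_nan(self):
        t = table_from_strings({"i1": ["./.", "./."], "i2": ["A/T", "A/A"]})
        recs = {d.individual: d for d in individual_hexp(t)}
        assert recs["i1"].n_variant_sites == 0
        assert np.isnan(recs["i1"].hexp_ind)

    def test_filter_applied_relative_to_cohort(self):
        t = table_from_strings({
            "i1": ["A/T", "A/T"],
            "i2": ["./.", "A/A"],
            "i3": ["./.", "A/A"],
        })
        recs = {d.individual: d for d in
                individual_hexp(t, FilterConfig(r=0.7, min_maf=0.0))}
        # site s0 typed in 1/3 < 0.7 -> dropped for everyone
        assert recs["i1"].n_variant_sites == 1
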