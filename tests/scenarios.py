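"""Shared simulation scenarios for the acceptance criteria.

Used by tests/test_acceptance.py and scripts/acceptance.py so both exercise
exactly the same configurations.
"""

import numpy as np

from radtrace.affinity import affinity, build_pseudoreference
from radtrace.diversity import individual_hexp
from radtrace.geo import distance_to_borderline, hexp_distance_regression
from radtrace.privates import attribute_extinct, build_catalog, trace
from radtrace.simulate import (
    DerivedPopConfig,
    GeoConfig,
    SimulationConfig,
    simulate_dataset,
)

ANC3 = ["A1", "A2", "A3"]


def introgression_recovery(seed):
    """K=3, L=2000, pi=0.05, 40 derived individuals with donor weight in
    {0, 0.05, 0.1, 0.2}; returns (spearman rho, w=0 props, w=0.2 props)."""
    wvals = [0.0, 0.05, 0.1, 0.2]
    pops = [DerivedPopConfig(f"D{j}", 10, (w, 0.0, 0.0, 1.0 - w))
            for j, w in enumerate(wvals)]
    cfg = SimulationConfig(
        n_ancestors=3, n_loci=2000, sites_per_locus=2, seed=seed,
        private_rates=[0.05] * 3, ancestral_sample_sizes=[12] * 3,
        derived_populations=pops, missing_rate_range=(0.0, 0.0),
        dirichlet_alpha=3.0, emit_sequences=False)
    ds = simulate_dataset(cfg)
    catalog = build_catalog(ds.table, ds.popmap, ANC3)
    targets = [i for i in ds.table.individuals if ds.popmap.role(i) == "derived"]
    tm = trace(ds.table, catalog, targets, ds.popmap)
    from radtrace.simulate import truth_introgression_rank
    rho = truth_introgression_rank(ds.truth, tm, "A1")
    p0 = [tm.proportion(i, "A1") for i in targets if i.startswith("D0")]
    p20 = [tm.proportion(i, "A1") for i in targets if i.startswith("D3")]
    return rho, np.array(p0), np.array(p20)


def _ghost_config(seed, include_extinct):
    if include_extinct:
        wp = (0.0, 0.0, 0.5, 0.25, 0.25)
        wd = (0.1, 0.0, 0.0, 0.15, 0.75)
    else:
        wp = (0.0, 0.0, 0.5, 0.5)
        wd = (0.1, 0.0, 0.0, 0.9)
    return SimulationConfig(
        n_ancestors=3, n_loci=2000, sites_per_locus=1, seed=seed,
        private_rates=[0.05] * 3,
        include_extinct=include_extinct,
        extinct_private_rate=0.08 if include_extinct else 0.0,
        ancestral_sample_sizes=[15] * 3,
        derived_populations=[
            DerivedPopConfig("Proxy", 14, wp, role="proxy_polyploid"),
            DerivedPopConfig("D", 20, wd)],
        missing_rate_range=(0.0, 0.1), dirichlet_alpha=3.0,
        emit_sequences=False)


def ghost_recall(seed):
    """Recall of injected ghost privates that reached the proxy population."""
    ds = simulate_dataset(_ghost_config(seed, include_extinct=True))
    ghost = attribute_extinct(ds.table, ds.popmap, "Proxy", ANC3)
    injected = ds.truth.private_sets["E"]
    rows = [ds.table.individual_index(i) for i in ds.popmap.members("Proxy")]
    pres = ds.table.presence(rows=rows)
    reached = {(sid, al) for sid, al in injected
               if pres[ds.table.site_index(sid), "ACGT".index(al)]}
    recall = len(ghost & reached) / len(reached) if reached else float("nan")
    return recall, len(reached), len(ghost)


def ghost_null(seed):
    """Attributed-set size with the ghost off, plus an expected upper bound
    on sampling-dropout false positives computed from the truth frequencies."""
    ds = simulate_dataset(_ghost_config(seed, include_extinct=False))
    ghost = attribute_extinct(ds.table, ds.popmap, "Proxy", ANC3)
    freqs = ds.truth.taxon_frequencies  # (taxa incl base, sites, 4)
    wp = np.array([0.0, 0.0, 0.5, 0.5])
    n_proxy = len(ds.popmap.members("Proxy"))
    n_anc = [len(ds.popmap.members(a)) for a in ANC3]
    p_mix = np.tensordot(wp, freqs, axes=(0, 0))  # (sites, 4)
    p_in_proxy = 1.0 - (1.0 - p_mix) ** (4 * n_proxy)  # upper bound (collapse drops some)
    p_absent_all = np.ones_like(p_mix)
    for k in range(3):
        p_absent_all *= (1.0 - freqs[k]) ** (2 * n_anc[k])
    expected_fp = float((p_in_proxy * p_absent_all).sum())
    return len(ghost), expected_fp


def normalization_r(seed, n_ind=1500):
    """Correlation(proportion, n_variant_sites) at constant w, missingness
    in [0.1, 0.6]."""
    cfg = SimulationConfig(
        n_ancestors=3, n_loci=1000, sites_per_locus=2, seed=seed,
        private_rates=[0.05] * 3, ancestral_sample_sizes=[12] * 3,
        derived_populations=[DerivedPopConfig("D", n_ind, (0.1, 0.0, 0.0, 0.9))],
        missing_rate_range=(0.1, 0.6), dirichlet_alpha=3.0,
        emit_sequences=False)
    ds = simulate_dataset(cfg)
    catalog = build_catalog(ds.table, ds.popmap, ANC3)
    targets = ds.popmap.members("D")
    tm = trace(ds.table, catalog, targets, ds.popmap)
    props = tm.proportions("A1")
    n = np.array([tm.n_variant_sites[i] for i in targets])
    return float(np.corrcoef(props, n)[0, 1])


def affinity_replicates(seed, n_reps=20):
    """Donor-vs-plain centered affinity over seeded replicates; returns
    (wins, spearman rhos of centered affinity vs traced proportion)."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    wins = 0
    rhos = []
    for rep_seed in rep_seeds:
        cfg = SimulationConfig(
            n_ancestors=3, n_loci=500, sites_per_locus=4, seed=int(rep_seed),
            private_rates=[0.10] * 3, ancestral_sample_sizes=[10] * 3,
            derived_populations=[
                DerivedPopConfig("Intro", 10, (0.25, 0.0, 0.0, 0.75)),
                DerivedPopConfig("Plain", 10, (0.0, 0.0, 0.0, 1.0))],
            missing_rate_range=(0.0, 0.05), dirichlet_alpha=3.0,
            locus_length=40)
        ds = simulate_dataset(cfg)
        refs = [build_pseudoreference(ds.sequences, ds.popmap, a) for a in ANC3]
        targets = [i for i in ds.table.individuals if ds.popmap.role(i) == "derived"]
        aff = affinity(ds.sequences, refs, targets, max_mismatch=1)
        intro = np.mean([aff.centered(i, "A1") for i in targets if i.startswith("Intro")])
        plain = np.mean([aff.centered(i, "A1") for i in targets if i.startswith("Plain")])
        wins += int(intro > plain)
        catalog = build_catalog(ds.table, ds.popmap, ANC3)
        tm = trace(ds.table, catalog, targets, ds.popmap)
        pa = [tm.proportion(i, "A1") for i in targets]
        ca = [aff.centered(i, "A1") for i in targets]
        rhos.append(float(stats.spearmanr(ca, pa).statistic))
    return wins, rhos


def regression_recovery(seed):
    """Imposed negative Hexp gradient + coverage confound; returns
    (generating slope, naive result, residual result)."""
    geo = GeoConfig(hexp_thin_per_km=0.0006, coverage_het_effect=1.5,
                    coverage_distance_coupling=0.25,
                    default_distance_km=(5.0, 300.0))
    cfg = SimulationConfig(
        n_ancestors=2, n_loci=2000, sites_per_locus=1, seed=seed,
        private_rates=[0.0, 0.0], ancestral_sample_sizes=[5, 5],
        derived_populations=[DerivedPopConfig("Sex", 150, (0.1, 0.1, 0.8))],
        missing_rate_range=(0.1, 0.42), geo=geo, dirichlet_alpha=3.0,
        emit_sequences=False)
    ds = simulate_dataset(cfg)
    div = [d for d in individual_hexp(ds.table)
           if ds.popmap.role(d.individual) == "derived"]
    dists = distance_to_borderline(ds.coordinates, ds.borderline)
    naive = hexp_distance_regression(div, dists, mode="naive", min_sites=0)
    resid = hexp_distance_regression(div, dists, mode="residual", min_sites=0)
    return ds.truth.geo_generating_slope, naive, resid
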