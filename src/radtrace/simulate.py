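"""Seeded synthetic-data generator with ground truth.

Generative model (drift-free frequency sampling — the downstream statistics
depend only on allele-sharing patterns, not on a coalescent):

1. Per locus, an ancestral base sequence; at each variant site, two base
   alleles with per-taxon frequencies drawn from a symmetric Dirichlet.
   With probability ``pi_k`` a taxon-unique third allele (frequency in
   [0.2, 0.8]) replaces one base allele in taxon ``k`` only; injected
   private alleles are pairwise disjoint across taxa by construction.
2. Ancestral diploids draw 2 allele copies from their taxon's frequencies.
3. Derived tetraploids draw 4 copies; each copy's source taxon is drawn per
   locus from the individual's ancestry weights (over the ancestors plus a
   neutral base pool). The pseudo-diploid collapse keeps the <=2 most
   frequent distinct alleles among the 4 copies (ties broken by a seeded
   uniform pick).
4. Clonal populations copy one founder genotype per clone group with
   per-site alteration probability ``epsilon``.
5. Each call goes missing with a per-individual probability drawn from
   ``missing_rate_range``; optional couplings convert heterozygous calls to
   homozygous ones as a function of distance (an imposed Hexp gradient) and
   of the missing rate (the coverage confound the residual regression is
   meant to remove).
6. Locus sequences are the base sequence with each individual's majority
   allele substituted at variant columns (N where the call is missing).
7. Coordinates place sexual derived populations on a distance gradient from
   a straight borderline.

An extinct ancestor ("ghost") is simulated like any taxon but emits no
diploid samples; it reaches the output only through derived/proxy
populations whose weight vectors give it mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .model import (
    MISSING,
    NUCLEOTIDES,
    ConfigError,
    GenotypeTable,
    LocusSequenceSet,
    PopulationMap,
    SiteRecord,
)
from .privates import TraceMatrix

KM_PER_DEG_LAT = 111.19492664455873  # 6371 km * pi / 180


@dataclass
class GeoConfig:
    borderline_lat: float = 47.0
    borderline_lon: Tuple[float, float] = (8.0, 18.0)
    n_border_points: int = 501
    default_distance_km: Tuple[float, float] = (5.0, 200.0)
    hexp_thin_per_km: float = 0.0       # g: het->hom thinning per km of distance
    coverage_het_effect: float = 0.0    # k: het->hom thinning per unit missing rate
    coverage_distance_coupling: float = 0.0  # alpha: far individuals miss less


@dataclass
class DerivedPopConfig:
    label: str
    n_individuals: int
    ancestry_weights: Tuple[float, ...]
    clonal: bool = False
    clone_mutation_rate: float = 0.0
    n_clone_groups: int = 1
    role: str = "derived"  # or "proxy_polyploid"
    distance_range_km: Optional[Tuple[float, float]] = None
    per_individual_weights: Optional[Sequence[Sequence[float]]] = None


@dataclass
class SimulationConfig:
    n_ancestors: int
    n_loci: int
    seed: int
    sites_per_locus: int = 1
    private_rates: Optional[Sequence[float]] = None  # per extant ancestor
    ancestral_sample_sizes: Optional[Sequence[int]] = None
    derived_populations: List[DerivedPopConfig] = field(default_factory=list)
    include_extinct: bool = False
    extinct_private_rate: float = 0.0
    missing_rate_range: Tuple[float, float] = (0.0, 0.0)
    geo: GeoConfig = field(default_factory=GeoConfig)
    dirichlet_alpha: float = 0.8
    locus_length: int = 50
    ancestor_labels: Optional[Sequence[str]] = None
    extinct_label: str = "E"
    emit_sequences: bool = True

    def __post_init__(self) -> None:
        if self.n_ancestors < 2:
            raise ConfigError("need K >= 2 ancestral taxa")
        if self.private_rates is None:
            self.private_rates = [0.05] * self.n_ancestors
        if len(self.private_rates) != self.n_ancestors:
            raise ConfigError("private_rates must have one entry per extant ancestor")
        for p in list(self.private_rates) + [self.extinct_private_rate]:
            if not 0.0 <= p <= 0.5:
                raise ConfigError(f"private rate {p} outside [0, 0.5]")
        if self.ancestral_sample_sizes is None:
            self.ancestral_sample_sizes = [10] * self.n_ancestors
        if len(self.ancestral_sample_sizes) != self.n_ancestors:
            raise ConfigError("ancestral_sample_sizes must match n_ancestors")
        if self.ancestor_labels is None:
            self.ancestor_labels = [f"A{k + 1}" for k in range(self.n_ancestors)]
        lo, hi = self.missing_rate_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ConfigError("missing_rate_range must satisfy 0 <= lo <= hi <= 1")
        n_taxa = self.n_ancestors + (1 if self.include_extinct else 0) + 1
        for pop in self.derived_populations:
            if not 0.0 <= pop.clone_mutation_rate <= 0.01:
                raise ConfigError(f"clone_mutation_rate {pop.clone_mutation_rate} outside [0, 0.01]")
            if pop.role not in ("derived", "proxy_polyploid"):
                raise ConfigError(f"bad role {pop.role!r} for {pop.label}")
            vectors = pop.per_individual_weights or [pop.ancestry_weights]
            for w in vectors:
                w = np.asarray(w, dtype=float)
                if w.shape != (n_taxa,):
                    raise ConfigError(
                        f"{pop.label}: weights must have length {n_taxa} "
                        f"(extant ancestors{', extinct' if self.include_extinct else ''}, base pool)"
                    )
                if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
                    raise ConfigError(f"{pop.label}: weights must be non-negative and sum to 1")
            if pop.per_individual_weights is not None and \
                    len(pop.per_individual_weights) != pop.n_individuals:
                raise ConfigError(f"{pop.label}: need one weight vector per individual")

    @property
    def taxa_order(self) -> List[str]:
        taxa = list(self.ancestor_labels)
        if self.include_extinct:
            taxa.append(self.extinct_label)
        return taxa + ["base"]


@dataclass
class SyntheticTruth:
    taxa_order: List[str]
    ancestry_weights: Dict[str, Tuple[float, ...]]
    clone_group: Dict[str, Optional[str]]
    missing_rate: Dict[str, float]
    private_sets: Dict[str, Set[Tuple[str, str]]]
    taxon_frequencies: np.ndarray  # (n_taxa, n_sites, 4)
    distances_km: Dict[str, float]
    geo_generating_slope: Optional[float] = None
    mean_prethin_het: Optional[float] = None


@dataclass
class SimulatedDataset:
    table: GenotypeTable
    sequences: LocusSequenceSet
    popmap: PopulationMap
    coordinates: List[Tuple[str, float, float]]
    borderline: List[Tuple[float, float]]
    truth: SyntheticTruth


# ---------------------------------------------------------------------------

def _draw_copies(rng, cum, src_sites, n_sites):
    """Allele codes for each copy: src_sites (ploidy, n_sites) taxon indices."""
    ploidy = src_sites.shape[0]
    u = rng.random((ploidy, n_sites))
    cf = cum[src_sites, np.arange(n_sites)[None, :], :]
    return (u[:, :, None] > cf).sum(axis=-1).astype(np.int8)


def _collapse(rng, copies, n_sites):
    """Pseudo-diploid collapse + majority consensus with seeded tie-breaks.

    Returns (a_lo, a_hi, consensus) allele-code arrays of length n_sites.
    """
    counts = np.zeros((n_sites, 4), dtype=np.int16)
    cols = np.arange(n_sites)
    for c in range(copies.shape[0]):
        np.add.at(counts, (cols, copies[c]), 1)
    jitter = counts + rng.random(counts.shape) * 0.5
    order = np.argsort(-jitter, axis=1, kind="stable")
    top1 = order[:, 0]
    top2 = order[:, 1]
    has2 = counts[cols, top2] > 0
    a = top1
    b = np.where(has2, top2, top1)
    a_lo = np.minimum(a, b).astype(np.int8)
    a_hi = np.maximum(a, b).astype(np.int8)
    return a_lo, a_hi, top1.astype(np.int8)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    K = config.n_ancestors
    L, spl = config.n_loci, config.sites_per_locus
    n_sites = L * spl
    taxa = config.taxa_order          # extant..., [extinct,] base
    n_taxa = len(taxa)
    base_idx = n_taxa - 1

    # --- loci, base sequences, variant columns ---------------------------
    base_seq_codes = rng.integers(0, 4, size=(L, config.locus_length), dtype=np.int8)
    var_cols = np.stack([
        rng.choice(config.locus_length, size=spl, replace=False) for _ in range(L)
    ])  # (L, spl)
    sites: List[SiteRecord] = []
    for l in range(L):
        locus_id = f"L{l:05d}"
        for s in range(spl):
            col = int(var_cols[l, s])
            sites.append(SiteRecord(
                site_id=f"{locus_id}_{col}", locus_id=locus_id, column=col,
                chrom=locus_id, pos=col + 1,
            ))
    site_locus = np.repeat(np.arange(L), spl)
    site_col = var_cols.reshape(-1)

    ref_codes = base_seq_codes[site_locus, site_col]
    alt_codes = (ref_codes + rng.integers(1, 4, size=n_sites)) % 4

    # --- per-taxon allele frequencies -------------------------------------
    freqs = np.zeros((n_taxa, n_sites, 4))
    p_ref = rng.dirichlet([config.dirichlet_alpha] * 2, size=(n_taxa, n_sites))[:, :, 0]
    rows = np.arange(n_sites)
    for t in range(n_taxa):
        freqs[t, rows, ref_codes] += p_ref[t]
        freqs[t, rows, alt_codes] += 1.0 - p_ref[t]

    # --- private-allele injection (disjoint across taxa) -------------------
    private_sets: Dict[str, Set[Tuple[str, str]]] = {t: set() for t in taxa}
    rates = list(config.private_rates) + (
        [config.extinct_private_rate] if config.include_extinct else []
    )
    used_private: Dict[int, Set[int]] = {}
    for t, rate in enumerate(rates):  # extant then extinct; never the base pool
        if rate <= 0:
            continue
        chosen = np.nonzero(rng.random(n_sites) < rate)[0]
        for j in chosen:
            taken = used_private.setdefault(int(j), set())
            avail = [c for c in range(4)
                     if c not in (ref_codes[j], alt_codes[j]) and c not in taken]
            if not avail:
                continue
            priv = avail[rng.integers(len(avail))]
            taken.add(priv)
            q = rng.uniform(0.2, 0.8)
            # replace one of the taxon's two base alleles with the private one
            drop = ref_codes[j] if rng.random() < 0.5 else alt_codes[j]
            keep = alt_codes[j] if drop == ref_codes[j] else ref_codes[j]
            f = np.zeros(4)
            f[keep] = 1.0 - q
            f[priv] = q
            freqs[t, j] = f
            private_sets[taxa[t]].add((sites[j].site_id, NUCLEOTIDES[priv]))
    cum = np.cumsum(freqs, axis=2)
    cum[:, :, -1] = 1.0  # guard against fp drift

    # --- roster ------------------------------------------------------------
    individuals: List[str] = []
    assignment: Dict[str, Tuple[str, str]] = {}
    ind_taxon: Dict[str, int] = {}        # ancestral individuals
    ind_pop: Dict[str, DerivedPopConfig] = {}
    weights_by_ind: Dict[str, Tuple[float, ...]] = {}
    clone_group: Dict[str, Optional[str]] = {}
    for t, label in enumerate(config.ancestor_labels):
        onehot = tuple(1.0 if j == t else 0.0 for j in range(n_taxa))
        for i in range(config.ancestral_sample_sizes[t]):
            ind = f"{label}_{i:03d}"
            individuals.append(ind)
            assignment[ind] = (label, "ancestral")
            ind_taxon[ind] = t
            weights_by_ind[ind] = onehot
            clone_group[ind] = None
    for pop in config.derived_populations:
        for i in range(pop.n_individuals):
            ind = f"{pop.label}_{i:03d}"
            individuals.append(ind)
            assignment[ind] = (pop.label, pop.role)
            ind_pop[ind] = pop
            w = (pop.per_individual_weights[i]
                 if pop.per_individual_weights is not None else pop.ancestry_weights)
            weights_by_ind[ind] = tuple(float(x) for x in w)
            clone_group[ind] = None
    popmap = PopulationMap(assignment)
    n_ind = len(individuals)

    # --- geography ----------------------------------------------------------
    geo = config.geo
    lon_lo, lon_hi = geo.borderline_lon
    borderline = [(geo.borderline_lat, float(lon))
                  for lon in np.linspace(lon_lo, lon_hi, geo.n_border_points)]
    distances: Dict[str, float] = {}
    coordinates: List[Tuple[str, float, float]] = []
    for t, label in enumerate(config.ancestor_labels):
        lat0 = geo.borderline_lat + 3.0 + t * 0.5
        for ind in popmap.members(label):
            lat = lat0 + rng.normal(0, 0.05)
            lon = rng.uniform(lon_lo, lon_hi)
            coordinates.append((ind, float(lat), float(lon)))
    for pop in config.derived_populations:
        d_lo, d_hi = pop.distance_range_km or geo.default_distance_km
        south = pop.clonal or pop.role == "proxy_polyploid"
        for ind in popmap.members(pop.label):
            d = float(rng.uniform(d_lo, d_hi))
            distances[ind] = d
            sign = -1.0 if south else 1.0
            lat = geo.borderline_lat + sign * d / KM_PER_DEG_LAT
            lon = float(rng.uniform(lon_lo + 0.3, lon_hi - 0.3))
            coordinates.append((ind, lat, lon))

    # --- per-individual missing rates (optionally coupled to distance) -----
    m_lo, m_hi = config.missing_rate_range
    alpha = geo.coverage_distance_coupling
    grad_inds = [i for i in individuals
                 if i in ind_pop and not ind_pop[i].clonal and ind_pop[i].role == "derived"]
    if grad_inds:
        dvals = np.array([distances[i] for i in grad_inds])
        d_span = dvals.max() - dvals.min()
    missing_rate: Dict[str, float] = {}
    for ind in individuals:
        u = rng.uniform(0.0, 1.0)
        if alpha > 0 and ind in distances and ind in grad_inds and d_span > 0:
            d_norm = (distances[ind] - dvals.min()) / d_span
            mix = np.clip(alpha * (1.0 - d_norm) + (1.0 - alpha) * u, 0.0, 1.0)
        else:
            mix = u
        missing_rate[ind] = float(m_lo + (m_hi - m_lo) * mix)

    # --- genotypes ----------------------------------------------------------
    a_lo = np.full((n_ind, n_sites), MISSING, dtype=np.int8)
    a_hi = np.full((n_ind, n_sites), MISSING, dtype=np.int8)
    cons = np.zeros((n_ind, n_sites), dtype=np.int8)

    def draw_derived(w: Sequence[float]):
        src_loci = rng.choice(n_taxa, size=(4, L), p=np.asarray(w, dtype=float))
        src_sites = np.repeat(src_loci, spl, axis=1)
        copies = _draw_copies(rng, cum, src_sites, n_sites)
        return _collapse(rng, copies, n_sites)

    founders: Dict[Tuple[str, int], Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for idx, ind in enumerate(individuals):
        if ind in ind_taxon:  # ancestral diploid
            t = ind_taxon[ind]
            src_sites = np.full((2, n_sites), t, dtype=np.int64)
            copies = _draw_copies(rng, cum, src_sites, n_sites)
            lo, hi, c1 = _collapse(rng, copies, n_sites)
        else:
            pop = ind_pop[ind]
            if pop.clonal:
                within = int(ind.rsplit("_", 1)[1])
                g = within % max(pop.n_clone_groups, 1)  # deterministic group cycling
                key = (pop.label, g)
                if key not in founders:
                    founders[key] = draw_derived(weights_by_ind[ind])
                lo, hi, c1 = (arr.copy() for arr in founders[key])
                clone_group[ind] = f"{pop.label}.g{g}"
                eps = pop.clone_mutation_rate
                if eps > 0:
                    alter = np.nonzero(rng.random(n_sites) < eps)[0]
                    if alter.size:
                        src = rng.choice(n_taxa, size=(4, alter.size),
                                         p=np.asarray(weights_by_ind[ind], dtype=float))
                        u = rng.random((4, alter.size))
                        cf = cum[src, alter[None, :], :]
                        cps = (u[:, :, None] > cf).sum(axis=-1).astype(np.int8)
                        nlo, nhi, nc = _collapse(rng, cps, alter.size)
                        lo[alter], hi[alter], c1[alter] = nlo, nhi, nc
            else:
                lo, hi, c1 = draw_derived(weights_by_ind[ind])
        a_lo[idx], a_hi[idx], cons[idx] = lo, hi, c1

    # --- Hexp gradient + coverage-driven het loss ---------------------------
    geo_slope = mean_prethin = None
    het = (a_lo >= 0) & (a_lo != a_hi)
    if (geo.hexp_thin_per_km > 0 or geo.coverage_het_effect > 0):
        if geo.hexp_thin_per_km > 0 and grad_inds:
            prethin = np.array([
                het[individuals.index(i)].mean() for i in grad_inds
            ])
            mean_prethin = float(prethin.mean())
            geo_slope = -0.5 * mean_prethin * geo.hexp_thin_per_km
        for idx, ind in enumerate(individuals):
            q = 0.0
            if geo.hexp_thin_per_km > 0 and ind in grad_inds:
                q += geo.hexp_thin_per_km * distances[ind]
            if geo.coverage_het_effect > 0 and ind in ind_pop:
                q += geo.coverage_het_effect * missing_rate[ind]
            q = min(q, 0.95)
            if q <= 0:
                continue
            hj = np.nonzero(het[idx])[0]
            thin = hj[rng.random(hj.size) < q]
            keep_hi = rng.random(thin.size) < 0.5
            kept = np.where(keep_hi, a_hi[idx, thin], a_lo[idx, thin])
            a_lo[idx, thin] = kept
            a_hi[idx, thin] = kept
            cons[idx, thin] = kept

    # --- missingness ---------------------------------------------------------
    for idx, ind in enumerate(individuals):
        m = missing_rate[ind]
        if m > 0:
            gone = rng.random(n_sites) < m
            a_lo[idx, gone] = MISSING
            a_hi[idx, gone] = MISSING

    table = GenotypeTable(individuals, sites, a_lo, a_hi)

    # --- locus sequences ------------------------------------------------------
    seqs = LocusSequenceSet()
    if config.emit_sequences:
        bases = np.array(list("ACGT"), dtype="U1")
        miss = a_lo < 0
        for idx, ind in enumerate(individuals):
            chars = bases[base_seq_codes]  # (L, locus_length) fresh view per ind
            chars = chars.copy()
            sub = bases[cons[idx]]
            sub = np.where(miss[idx], "N", sub)
            chars[site_locus, site_col] = sub
            locus_missing = miss[idx].reshape(L, spl).all(axis=1)
            for l in np.nonzero(~locus_missing)[0]:
                seqs.add(f"L{l:05d}", ind, "".join(chars[l]))

    truth = SyntheticTruth(
        taxa_order=taxa,
        ancestry_weights=weights_by_ind,
        clone_group=clone_group,
        missing_rate=missing_rate,
        private_sets=private_sets,
        taxon_frequencies=freqs,
        distances_km=distances,
        geo_generating_slope=geo_slope,
        mean_prethin_het=mean_prethin,
    )
    # injected private sets must be pairwise disjoint across taxa
    seen: Set[Tuple[str, str]] = set()
    for s in private_sets.values():
        assert not (s & seen), "private-allele injection produced overlapping sets"
        seen |= s
    return SimulatedDataset(table, seqs, popmap, coordinates, borderline, truth)


# ---------------------------------------------------------------------------

def truth_introgression_rank(
    truth: SyntheticTruth, trace_matrix: TraceMatrix, ancestor: str
) -> float:
    """Spearman correlation between true ancestry weight for ``ancestor``
    and the traced private-allele proportion, across the traced individuals.

    Returns NaN when all weights are identical (correlation undefined).
    """
    inds = trace_matrix.individuals
    if len(inds) < 3:
        raise ValueError("need >=3 traced individuals for a rank correlation")
    t = truth.taxa_order.index(ancestor)
    w = np.array([truth.ancestry_weights[i][t] for i in inds])
    if np.allclose(w, w[0]):
        return float("nan")
    props = trace_matrix.proportions(ancestor)
    rho = stats.spearmanr(w, props).statistic
    return float(rho)


# ---------------------------------------------------------------------------

def write_truth(truth: SyntheticTruth, ind_path, pa_path) -> None:
    """Ground truth as two TSVs (per-individual and injected privates)."""
    with open(ind_path, "w") as fh:
        fh.write("individual\tancestry_weights\tclone_group\tmissing_rate\tdistance_km\n")
        for ind, w in truth.ancestry_weights.items():
            cg = truth.clone_group.get(ind) or "NA"
            d = truth.distances_km.get(ind)
            ds = "NA" if d is None else f"{d:.3f}"
            fh.write(f"{ind}\t{','.join(f'{x:g}' for x in w)}\t{cg}\t"
                     f"{truth.missing_rate[ind]:.4f}\t{ds}\n")
    with open(pa_path, "w") as fh:
        fh.write("taxon\tsite_id\tallele\n")
        for taxon, pairs in truth.private_sets.items():
            for site_id, allele in sorted(pairs):
                fh.write(f"{taxon}\t{site_id}\t{allele}\n")
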