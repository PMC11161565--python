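"""Site filtering and population / per-individual diversity statistics.

Conventions (fixed for reproducibility):

* Hexp is the plain ``1 - sum(p^2)`` without small-sample correction; allele
  frequencies come from pseudo-diploid calls, each non-missing call
  contributing two allele draws (homozygote 2 copies, heterozygote 1+1).
* FIS defaults to the mean over sites with Hexp > 0 of
  ``(Hexp - Hobs) / Hexp`` ("mean of ratios"); a "ratio of means" variant
  (``1 - mean(Hobs)/mean(Hexp)``) is available via ``fis_method``.
* PA counts (site, allele) pairs present in a population and absent from
  every other population in the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .model import FilterConfig, GenotypeTable, PopulationMap

logger = logging.getLogger(__name__)


@dataclass
class DiversityRecord:
    population: str
    n: int
    n_per_locus_mean: float
    n_per_locus_sd: float
    hobs: float
    hobs_sd: float
    hexp: float
    hexp_sd: float
    fis: float
    fis_sd: float
    pa: int
    pa_per_n: float


@dataclass
class IndividualDiversity:
    individual: str
    n_variant_sites: int
    hexp_ind: float


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_sites(
    table: GenotypeTable,
    pops: Optional[PopulationMap],
    cfg: FilterConfig,
) -> GenotypeTable:
    """Apply the R / min-maf / one-SNP-per-locus filters.

    A site is retained iff (a) the proportion of non-missing individuals is
    >= R — overall, or within every population when ``scope`` is
    ``per_population``; (b) the overall minor-allele frequency (1 minus the
    major-allele frequency, over all allele copies) is >= ``min_maf``; and
    (c) when ``one_snp_per_locus`` is set, it is the seeded-random pick among
    the surviving sites of its locus.
    """
    n_ind, n_sites = table.n_individuals, table.n_sites
    if n_sites == 0:
        return table
    nonmiss = ~table.missing_mask()

    if cfg.scope == "overall" or pops is None:
        keep_r = nonmiss.sum(axis=0) / n_ind >= cfg.r
    else:
        keep_r = np.ones(n_sites, dtype=bool)
        for pop in pops.populations():
            rows = [table.individual_index(i) for i in pops.members(pop)
                    if i in table._ind_index]
            if not rows:
                continue
            keep_r &= nonmiss[rows].sum(axis=0) / len(rows) >= cfg.r

    counts = table.allele_counts()
    tot = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        major = np.where(tot > 0, counts.max(axis=1) / np.maximum(tot, 1), 0.0)
    maf = np.where(tot > 0, 1.0 - major, 0.0)
    keep_maf = maf >= cfg.min_maf if cfg.min_maf > 0 else np.ones(n_sites, dtype=bool)

    keep = keep_r & keep_maf

    if cfg.one_snp_per_locus:
        rng = np.random.default_rng(cfg.seed)
        by_locus: Dict[str, List[int]] = {}
        for j in np.nonzero(keep)[0]:
            by_locus.setdefault(table.sites[j].locus_id, []).append(int(j))
        chosen = np.zeros(n_sites, dtype=bool)
        for locus in sorted(by_locus):
            js = by_locus[locus]
            chosen[js[rng.integers(len(js))]] = True
        keep = chosen

    out = table.subset_sites(keep)
    if out.n_sites == 0:
        logger.warning("filter_sites: no sites survive (R=%s, min_maf=%s)", cfg.r, cfg.min_maf)
    return out


# ---------------------------------------------------------------------------
# Population statistics
# ---------------------------------------------------------------------------

def population_diversity(
    table: GenotypeTable,
    pops: PopulationMap,
    fis_method: str = "mean_of_ratios",
) -> List[DiversityRecord]:
    """Per-population diversity record (one Table-2-style row each).

    Expects an already-filtered table. Populations are taken from the
    popmap; individuals absent from the table are ignored.
    """
    if fis_method not in ("mean_of_ratios", "ratio_of_means"):
        raise ValueError(f"unknown fis_method {fis_method!r}")
    pop_rows = {
        pop: [table.individual_index(i) for i in pops.members(pop)
              if i in table._ind_index]
        for pop in pops.populations()
    }
    presence = {p: table.presence(rows=r) for p, r in pop_rows.items() if r}
    locus_ids = np.array([s.locus_id for s in table.sites])
    loci = list(dict.fromkeys(locus_ids))
    locus_cols = {l: np.nonzero(locus_ids == l)[0] for l in loci}

    records: List[DiversityRecord] = []
    for pop, rows in pop_rows.items():
        if not rows:
            records.append(DiversityRecord(pop, 0, *([float("nan")] * 8), 0, float("nan")))
            continue
        lo = table.a_lo[rows]
        hi = table.a_hi[rows]
        nonmiss = lo >= 0
        het = nonmiss & (lo != hi)

        n_typed = nonmiss.sum(axis=0)  # per site
        counts = table.allele_counts(rows=rows)
        tot = counts.sum(axis=1)
        informative = tot > 0

        with np.errstate(invalid="ignore", divide="ignore"):
            hobs_site = np.where(informative, het.sum(axis=0) / np.maximum(n_typed, 1), np.nan)
            freqs = counts / np.maximum(tot, 1)[:, None]
            hexp_site = np.where(informative, 1.0 - (freqs**2).sum(axis=1), np.nan)

        if informative.any():
            hobs = float(np.nanmean(hobs_site))
            hobs_sd = float(np.nanstd(hobs_site))
            hexp = float(np.nanmean(hexp_site))
            hexp_sd = float(np.nanstd(hexp_site))
            poly = informative & (hexp_site > 0)
            if poly.any():
                fis_site = (hexp_site[poly] - hobs_site[poly]) / hexp_site[poly]
                if fis_method == "mean_of_ratios":
                    fis = float(np.mean(fis_site))
                else:
                    fis = float(1.0 - np.mean(hobs_site[poly]) / np.mean(hexp_site[poly]))
                fis_sd = float(np.std(fis_site))
            else:
                fis = fis_sd = float("nan")
        else:
            hobs = hobs_sd = hexp = hexp_sd = fis = fis_sd = float("nan")

        # private alleles against all other populations in the run
        others = [p for p in presence if p != pop]
        if pop in presence:
            own = presence[pop]
            other_any = np.zeros_like(own)
            for o in others:
                other_any |= presence[o]
            pa = int((own & ~other_any).sum())
        else:
            pa = 0

        # mean individuals genotyped per locus
        per_locus = np.array([
            (nonmiss[:, cols].any(axis=1)).sum() for cols in locus_cols.values()
        ]) if loci else np.array([0])
        npl_mean = float(per_locus.mean()) if len(per_locus) else float("nan")
        npl_sd = float(per_locus.std()) if len(per_locus) else float("nan")
        pa_per_n = pa / npl_mean if npl_mean > 0 else float("nan")

        records.append(DiversityRecord(
            pop, len(rows), npl_mean, npl_sd, hobs, hobs_sd, hexp, hexp_sd,
            fis, fis_sd, pa, pa_per_n,
        ))
    return records


# ---------------------------------------------------------------------------
# Per-individual expected heterozygosity
# ---------------------------------------------------------------------------

def individual_hexp(
    table: GenotypeTable,
    cfg: Optional[FilterConfig] = None,
) -> List[IndividualDiversity]:
    """Per-individual Hexp from each individual's own genotype.

    A heterozygous site contributes ``1 - (0.5^2 + 0.5^2) = 0.5``, a
    homozygous site 0; the value is the mean over the individual's
    non-missing sites after filtering (R relative to the full cohort).
    """
    if cfg is not None:
        table = filter_sites(table, None, cfg)
    nonmiss = ~table.missing_mask()
    het = table.het_mask()
    out: List[IndividualDiversity] = []
    for i, ind in enumerate(table.individuals):
        n = int(nonmiss[i].sum())
        if n == 0:
            logger.warning("individual_hexp: %s has no non-missing sites", ind)
            out.append(IndividualDiversity(ind, 0, float("nan")))
        else:
            out.append(IndividualDiversity(ind, n, 0.5 * float(het[i].sum() / n)))
    return out
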