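"""Private-allele catalogues and tracing through derived individuals.

An allele is *private* to an ancestral taxon when it occurs in at least one
non-missing call of that taxon and in no non-missing call of any other taxon
in the privacy universe (the listed ancestral taxa; derived and proxy
populations never veto privacy). Alleles carried by a proxy polyploid
population but absent from every extant ancestor are attributed to an
extinct (ghost) ancestor.

Tracing counts, per derived individual and ancestor, the catalogue
(site, allele) pairs whose allele appears in the individual's call at that
site — once per pair, dosage being unknowable from pseudo-diploid calls —
and normalizes by the individual's number of non-missing variant sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .model import NUCLEOTIDES, GenotypeTable, PopulationMap, RadtraceError

PairSet = Set[Tuple[str, str]]


@dataclass
class PrivateAlleleCatalog:
    """taxon label -> set of (site_id, allele); provenance per taxon."""

    entries: Dict[str, PairSet] = field(default_factory=dict)
    provenance: Dict[str, str] = field(default_factory=dict)

    def add_taxon(self, taxon: str, pairs: PairSet, provenance: str = "extant") -> None:
        if provenance not in ("extant", "extinct_attributed"):
            raise ValueError(f"unknown provenance {provenance!r}")
        self.entries[taxon] = set(pairs)
        self.provenance[taxon] = provenance

    def taxa(self) -> List[str]:
        return list(self.entries.keys())

    def total(self) -> int:
        return sum(len(v) for v in self.entries.values())


@dataclass
class TraceMatrix:
    individuals: List[str]
    ancestors: List[str]
    raw: Dict[Tuple[str, str], int]
    n_variant_sites: Dict[str, int]

    def raw_count(self, individual: str, ancestor: str) -> int:
        return self.raw[(individual, ancestor)]

    def proportion(self, individual: str, ancestor: str) -> float:
        n = self.n_variant_sites[individual]
        if n == 0:
            return float("nan")
        return self.raw[(individual, ancestor)] / n

    def proportions(self, ancestor: str) -> np.ndarray:
        return np.array([self.proportion(i, ancestor) for i in self.individuals])


@dataclass
class BoxplotStats:
    q1: float
    q2: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    mild_outliers: List[float]
    severe_outliers: List[float]
    n: int


@dataclass
class BoxplotSummary:
    """(population, ancestor) -> BoxplotStats."""

    cells: Dict[Tuple[str, str], BoxplotStats] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Catalogue construction
# ---------------------------------------------------------------------------

def _taxon_presence(
    table: GenotypeTable, pops: PopulationMap, taxa: Sequence[str]
) -> Dict[str, np.ndarray]:
    out = {}
    for taxon in taxa:
        members = [i for i in pops.members(taxon) if i in table._ind_index]
        if not members:
            raise RadtraceError(f"taxon {taxon!r} has no genotyped individuals in the table")
        rows = [table.individual_index(i) for i in members]
        out[taxon] = table.presence(rows=rows)
    return out


def _pairs_from_mask(table: GenotypeTable, mask: np.ndarray) -> PairSet:
    jj, aa = np.nonzero(mask)
    return {(table.sites[j].site_id, NUCLEOTIDES[a]) for j, a in zip(jj, aa)}


def build_catalog(
    table: GenotypeTable,
    pops: PopulationMap,
    ancestors: Sequence[str],
    strict: bool = False,
) -> PrivateAlleleCatalog:
    """Per-ancestor private (site, allele) pairs.

    ``strict=True`` skips sites where any listed ancestor is entirely
    missing; the default optimistic mode lets such sites still yield
    privates for the taxa that are typed there.
    """
    unknown = [a for a in ancestors if a not in pops.populations()]
    if unknown:
        raise RadtraceError(f"ancestor labels not in popmap: {unknown}")
    presence = _taxon_presence(table, pops, ancestors)

    typed_everywhere = None
    if strict:
        typed_everywhere = np.ones(table.n_sites, dtype=bool)
        for taxon in ancestors:
            typed_everywhere &= presence[taxon].any(axis=1)

    catalog = PrivateAlleleCatalog()
    for taxon in ancestors:
        own = presence[taxon]
        other_any = np.zeros_like(own)
        for o in ancestors:
            if o != taxon:
                other_any |= presence[o]
        mask = own & ~other_any
        if strict:
            mask &= typed_everywhere[:, None]
        catalog.add_taxon(taxon, _pairs_from_mask(table, mask), "extant")
    return catalog


def attribute_extinct(
    table: GenotypeTable,
    pops: PopulationMap,
    proxy_pop: str,
    extant_ancestors: Sequence[str],
    label: str = "extinct",
) -> PairSet:
    """(site, allele) pairs present in the proxy polyploid population and
    absent from every extant ancestor: attributed to a ghost ancestor."""
    if proxy_pop not in pops.populations():
        raise RadtraceError(f"proxy population {proxy_pop!r} not in popmap")
    roles = {pops.role(i) for i in pops.members(proxy_pop)}
    if roles != {"proxy_polyploid"}:
        raise RadtraceError(f"population {proxy_pop!r} must have role proxy_polyploid")
    presence = _taxon_presence(table, pops, list(extant_ancestors) + [proxy_pop])
    extant_any = np.zeros((table.n_sites, 4), dtype=bool)
    for taxon in extant_ancestors:
        extant_any |= presence[taxon]
    mask = presence[proxy_pop] & ~extant_any
    return _pairs_from_mask(table, mask)


def extend_catalog_with_extinct(
    catalog: PrivateAlleleCatalog,
    pairs: PairSet,
    label: str = "extinct",
) -> PrivateAlleleCatalog:
    catalog.add_taxon(label, pairs, "extinct_attributed")
    return catalog


# ---------------------------------------------------------------------------
# Tracing
# ---------------------------------------------------------------------------

def trace(
    table: GenotypeTable,
    catalog: PrivateAlleleCatalog,
    targets: Sequence[str],
    pops: Optional[PopulationMap] = None,
) -> TraceMatrix:
    """Count catalogue alleles carried by each target individual.

    ``n_variant_sites`` is the target's number of non-missing sites in the
    (already filtered) table — the per-individual denominator that removes
    coverage and missing-data effects.
    """
    if pops is not None:
        bad = [t for t in targets if pops.role(t) == "ancestral"]
        if bad:
            raise RadtraceError(
                f"targets {bad[:5]} are ancestral; tracing them would contaminate privacy logic"
            )
    ancestors = catalog.taxa()
    # pair sets -> boolean (n_sites, 4) masks for vectorized counting
    masks = {}
    for taxon in ancestors:
        m = np.zeros((table.n_sites, 4), dtype=bool)
        for site_id, allele in catalog.entries[taxon]:
            if site_id in table._site_index:
                m[table.site_index(site_id), "ACGT".index(allele)] = True
        masks[taxon] = m

    raw: Dict[Tuple[str, str], int] = {}
    n_sites: Dict[str, int] = {}
    for ind in targets:
        i = table.individual_index(ind)
        pres = np.zeros((table.n_sites, 4), dtype=bool)
        lo, hi = table.a_lo[i], table.a_hi[i]
        ok = lo >= 0
        jj = np.nonzero(ok)[0]
        pres[jj, lo[jj]] = True
        pres[jj, hi[jj]] = True
        n_sites[ind] = int(ok.sum())
        for taxon in ancestors:
            raw[(ind, taxon)] = int((masks[taxon] & pres).sum())
    return TraceMatrix(list(targets), ancestors, raw, n_sites)


# ---------------------------------------------------------------------------
# Boxplot summaries (quartiles by linear interpolation; 1.5/3.0 fences)
# ---------------------------------------------------------------------------

def boxplot_stats(values: Sequence[float]) -> BoxplotStats:
    x = np.asarray([v for v in values if not np.isnan(v)], dtype=float)
    if x.size == 0:
        nan = float("nan")
        return BoxplotStats(nan, nan, nan, nan, nan, [], [], 0)
    q1, q2, q3 = (float(np.percentile(x, q)) for q in (25, 50, 75))
    iqr = q3 - q1
    lo_mild, hi_mild = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    lo_sev, hi_sev = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    inside = x[(x >= lo_mild) & (x <= hi_mild)]
    whisk_lo = float(inside.min()) if inside.size else q1
    whisk_hi = float(inside.max()) if inside.size else q3
    mild = [float(v) for v in x if (lo_sev <= v < lo_mild) or (hi_mild < v <= hi_sev)]
    severe = [float(v) for v in x if v < lo_sev or v > hi_sev]
    return BoxplotStats(q1, q2, q3, whisk_lo, whisk_hi, mild, severe, int(x.size))


def summarize_trace(trace_matrix: TraceMatrix, pops: PopulationMap) -> BoxplotSummary:
    """Per population x ancestor boxplot statistics of traced proportions."""
    summary = BoxplotSummary()
    by_pop: Dict[str, List[str]] = {}
    for ind in trace_matrix.individuals:
        by_pop.setdefault(pops.population(ind), []).append(ind)
    for pop, members in by_pop.items():
        for anc in trace_matrix.ancestors:
            vals = [trace_matrix.proportion(i, anc) for i in members]
            summary.cells[(pop, anc)] = boxplot_stats(vals)
    return summary
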