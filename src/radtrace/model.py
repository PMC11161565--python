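"""Core domain types: genotype tables, population maps, locus sequences, filters.

Genotypes are *pseudo-diploid*: each call is an unordered set of one or two
observed nucleotides with unknown dosage (the output of a diploid caller
applied to material of arbitrary ploidy). Internally calls are stored as two
``int8`` allele-code matrices for speed; the :class:`AlleleCall` view is the
public per-cell representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

NUCLEOTIDES = ("A", "C", "G", "T")
CODE = {b: i for i, b in enumerate(NUCLEOTIDES)}
MISSING = -1

Role = str
ROLES = ("ancestral", "derived", "proxy_polyploid")


class RadtraceError(Exception):
    """Base class for user-facing errors."""


class ConfigError(RadtraceError):
    pass


class SchemaError(RadtraceError):
    pass


@dataclass(frozen=True)
class SiteRecord:
    """One variant site: a column of the genotype matrix.

    ``(locus_id, column)`` identifies the site within its RAD locus;
    ``chrom``/``pos`` are optional genomic coordinates (1-based, kept as-is).
    """

    site_id: str
    locus_id: str
    column: int
    chrom: Optional[str] = None
    pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.column < 0:
            raise ValueError(f"column must be >= 0, got {self.column}")
        if (self.chrom is None) != (self.pos is None):
            raise ValueError("chrom and pos must be both present or both absent")


@dataclass(frozen=True)
class AlleleCall:
    """A pseudo-diploid call: one or two distinct nucleotides, or missing."""

    alleles: frozenset = frozenset()
    missing: bool = True

    def __post_init__(self) -> None:
        if self.missing:
            if self.alleles:
                raise ValueError("missing call must carry no alleles")
        else:
            if not 1 <= len(self.alleles) <= 2:
                raise ValueError("non-missing call must carry 1 or 2 alleles")
            bad = set(self.alleles) - set(NUCLEOTIDES)
            if bad:
                raise ValueError(f"invalid nucleotides {sorted(bad)}")

    @classmethod
    def of(cls, *alleles: str) -> "AlleleCall":
        if not alleles:
            return cls()
        return cls(alleles=frozenset(alleles), missing=False)

    @property
    def is_het(self) -> bool:
        return not self.missing and len(self.alleles) == 2


class GenotypeTable:
    """Individuals x variant sites matrix of pseudo-diploid calls.

    Storage: two ``int8`` arrays ``a_lo``/``a_hi`` of shape
    ``(n_individuals, n_sites)`` holding allele codes with ``a_lo <= a_hi``;
    homozygotes have ``a_lo == a_hi`` and missing cells are ``-1`` in both.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        sites: Sequence[SiteRecord],
        a_lo: np.ndarray,
        a_hi: np.ndarray,
    ) -> None:
        if len(set(individuals)) != len(individuals):
            raise ValueError("duplicate individual ids")
        site_ids = [s.site_id for s in sites]
        if len(set(site_ids)) != len(site_ids):
            raise ValueError("duplicate site ids")
        keys = {(s.locus_id, s.column) for s in sites}
        if len(keys) != len(sites):
            raise ValueError("duplicate (locus_id, column) pairs")
        expected = (len(individuals), len(sites))
        if a_lo.shape != expected or a_hi.shape != expected:
            raise ValueError(f"call matrices must have shape {expected}")
        self.individuals: List[str] = list(individuals)
        self.sites: List[SiteRecord] = list(sites)
        self.a_lo = np.ascontiguousarray(a_lo, dtype=np.int8)
        self.a_hi = np.ascontiguousarray(a_hi, dtype=np.int8)
        miss = self.a_lo < 0
        if not np.array_equal(miss, self.a_hi < 0):
            raise ValueError("inconsistent missing encoding between a_lo and a_hi")
        if np.any(self.a_lo[~miss] > self.a_hi[~miss]):
            raise ValueError("a_lo must be <= a_hi")
        self._ind_index = {ind: i for i, ind in enumerate(self.individuals)}
        self._site_index = {s.site_id: j for j, s in enumerate(self.sites)}

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_calls(
        cls,
        individuals: Sequence[str],
        sites: Sequence[SiteRecord],
        calls: Mapping[Tuple[str, str], AlleleCall],
    ) -> "GenotypeTable":
        """Build from a sparse ``(individual, site_id) -> AlleleCall`` mapping.

        Unlisted cells default to missing.
        """
        n, m = len(individuals), len(sites)
        a_lo = np.full((n, m), MISSING, dtype=np.int8)
        a_hi = np.full((n, m), MISSING, dtype=np.int8)
        ind_index = {ind: i for i, ind in enumerate(individuals)}
        site_index = {s.site_id: j for j, s in enumerate(sites)}
        for (ind, sid), call in calls.items():
            i, j = ind_index[ind], site_index[sid]
            if call.missing:
                continue
            codes = sorted(CODE[a] for a in call.alleles)
            a_lo[i, j] = codes[0]
            a_hi[i, j] = codes[-1]
        return cls(individuals, sites, a_lo, a_hi)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def individual_index(self, ind: str) -> int:
        return self._ind_index[ind]

    def site_index(self, site_id: str) -> int:
        return self._site_index[site_id]

    def call(self, individual: str, site_id: str) -> AlleleCall:
        i = self._ind_index[individual]
        j = self._site_index[site_id]
        lo, hi = int(self.a_lo[i, j]), int(self.a_hi[i, j])
        if lo < 0:
            return AlleleCall()
        return AlleleCall.of(NUCLEOTIDES[lo], NUCLEOTIDES[hi])

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_sites), True where the call is missing."""
        return self.a_lo < 0

    def het_mask(self) -> np.ndarray:
        """True where the call is non-missing and heterozygous."""
        return (self.a_lo >= 0) & (self.a_lo != self.a_hi)

    def presence(self, rows: Optional[Sequence[int]] = None) -> np.ndarray:
        """Boolean (n_sites, 4): allele observed in >=1 non-missing call of
        the selected individuals (all by default)."""
        lo = self.a_lo if rows is None else self.a_lo[list(rows)]
        hi = self.a_hi if rows is None else self.a_hi[list(rows)]
        out = np.zeros((self.n_sites, 4), dtype=bool)
        for arr in (lo, hi):
            ok = arr >= 0
            ii, jj = np.nonzero(ok)
            out[jj, arr[ii, jj]] = True
        return out

    def allele_counts(self, rows: Optional[Sequence[int]] = None) -> np.ndarray:
        """Integer (n_sites, 4) allele-copy counts: each non-missing call
        contributes two draws (homozygote 2 copies, heterozygote 1+1)."""
        lo = self.a_lo if rows is None else self.a_lo[list(rows)]
        hi = self.a_hi if rows is None else self.a_hi[list(rows)]
        counts = np.zeros((self.n_sites, 4), dtype=np.int64)
        for arr in (lo, hi):
            ok = arr >= 0
            ii, jj = np.nonzero(ok)
            np.add.at(counts, (jj, arr[ii, jj]), 1)
        return counts

    def subset_sites(self, keep: np.ndarray) -> "GenotypeTable":
        """New table with the boolean/index-selected site columns."""
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        sites = [self.sites[j] for j in idx]
        return GenotypeTable(self.individuals, sites, self.a_lo[:, idx], self.a_hi[:, idx])

    def subset_individuals(self, inds: Sequence[str]) -> "GenotypeTable":
        rows = [self._ind_index[i] for i in inds]
        return GenotypeTable(list(inds), self.sites, self.a_lo[rows], self.a_hi[rows])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.sites == other.sites
            and np.array_equal(self.a_lo, other.a_lo)
            and np.array_equal(self.a_hi, other.a_hi)
        )

    def __repr__(self) -> str:
        return f"GenotypeTable({self.n_individuals} individuals x {self.n_sites} sites)"


@dataclass
class PopulationMap:
    """individual id -> (population label, role)."""

    assignment: Dict[str, Tuple[str, Role]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ind, (pop, role) in self.assignment.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for {ind!r}; expected one of {ROLES}")

    def population(self, ind: str) -> str:
        return self.assignment[ind][0]

    def role(self, ind: str) -> Role:
        return self.assignment[ind][1]

    def populations(self) -> List[str]:
        seen: List[str] = []
        for pop, _ in self.assignment.values():
            if pop not in seen:
                seen.append(pop)
        return seen

    def members(self, pop: str) -> List[str]:
        return [i for i, (p, _) in self.assignment.items() if p == pop]

    def by_role(self, role: Role) -> List[str]:
        return [i for i, (_, r) in self.assignment.items() if r == role]

    def validate_against(self, table: GenotypeTable, require_roles: bool = False) -> None:
        missing = [i for i in table.individuals if i not in self.assignment]
        if missing:
            raise ValueError(f"individuals not in popmap: {missing[:5]}")
        extra = [i for i in self.assignment if i not in table._ind_index]
        if extra:
            warnings.warn(f"popmap individuals absent from table: {extra[:5]}",
                          stacklevel=2)
        if require_roles:
            roles = {r for _, r in self.assignment.values()}
            if "ancestral" not in roles or "derived" not in roles:
                raise ValueError("tracing needs >=1 ancestral and >=1 derived population")


@dataclass
class LocusSequenceSet:
    """Per-locus, per-individual consensus sequences.

    All sequences of one locus must have equal length; alphabet ACGTN.
    """

    entries: Dict[Tuple[str, str], str] = field(default_factory=dict)

    def add(self, locus_id: str, individual: str, seq: str) -> None:
        seq = seq.upper()
        if set(seq) - set("ACGTN"):
            raise ValueError(f"invalid characters in sequence for {locus_id}/{individual}")
        cur = self.locus_length(locus_id)
        if cur is not None and cur != len(seq):
            raise ValueError(
                f"sequence length {len(seq)} != {cur} for locus {locus_id}"
            )
        self.entries[(locus_id, individual)] = seq

    def locus_length(self, locus_id: str) -> Optional[int]:
        for (lid, _), seq in self.entries.items():
            if lid == locus_id:
                return len(seq)
        return None

    def loci(self) -> List[str]:
        seen: List[str] = []
        for lid, _ in self.entries.keys():
            if lid not in seen:
                seen.append(lid)
        return seen

    def individuals(self) -> List[str]:
        seen: List[str] = []
        for _, ind in self.entries.keys():
            if ind not in seen:
                seen.append(ind)
        return seen

    def of_individual(self, ind: str) -> Dict[str, str]:
        return {lid: s for (lid, i), s in self.entries.items() if i == ind}


@dataclass
class FilterConfig:
    """Site filters: minimum genotyped proportion R, minimum minor-allele
    frequency, and optional one-random-SNP-per-locus thinning."""

    r: float = 0.5
    min_maf: float = 0.0
    scope: str = "overall"  # or "per_population"
    one_snp_per_locus: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ConfigError(f"R must be in [0,1], got {self.r}")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ConfigError(f"min_maf must be in [0,0.5], got {self.min_maf}")
        if self.scope not in ("overall", "per_population"):
            raise ConfigError(f"scope must be 'overall' or 'per_population', got {self.scope!r}")


def codes_to_bases(codes: Iterable[int]) -> List[str]:
    return [NUCLEOTIDES[c] for c in codes]
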