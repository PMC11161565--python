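"""Pseudoreference mapping-affinity proxy.

Per ancestral taxon, the pseudoreference keeps every contributing
individual's locus consensus verbatim ("mixed together"). A target's locus
counts as mapped to a taxon when the minimum Hamming distance to any of that
taxon's entries for the locus is <= ``max_mismatch`` (N matches anything) —
a desk-scale, deterministic stand-in for mismatch-bounded read mapping.
Raw mapped fractions are centered by the within-individual mean across
taxa, so values express relative affinity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import LocusSequenceSet, PopulationMap, RadtraceError

_N_CODE = ord("N")


@dataclass
class Pseudoreference:
    taxon: str
    sequences: Dict[str, List[str]] = field(default_factory=dict)  # locus -> entries

    def n_entries(self, locus_id: str) -> int:
        return len(self.sequences.get(locus_id, []))


@dataclass
class AffinityResult:
    individuals: List[str]
    taxa: List[str]
    raw_matrix: np.ndarray       # (n_individuals, n_taxa), NaN when no loci
    centered_matrix: np.ndarray

    def raw(self, ind: str, taxon: str) -> float:
        return float(self.raw_matrix[self.individuals.index(ind), self.taxa.index(taxon)])

    def centered(self, ind: str, taxon: str) -> float:
        return float(self.centered_matrix[self.individuals.index(ind), self.taxa.index(taxon)])


def build_pseudoreference(
    seqs: LocusSequenceSet, pops: PopulationMap, taxon: str
) -> Pseudoreference:
    """Collect the taxon's per-individual locus consensus sequences."""
    members = set(pops.members(taxon))
    ref = Pseudoreference(taxon)
    for (locus, ind), seq in seqs.entries.items():
        if ind in members:
            ref.sequences.setdefault(locus, []).append(seq)
    if not ref.sequences:
        raise RadtraceError(f"taxon {taxon!r} has no locus sequences")
    return ref


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length sequences; N matches anything."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length within a locus")
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    return int(((xa != xb) & (xa != _N_CODE) & (xb != _N_CODE)).sum())


def _entry_matrix(entries: List[str]) -> np.ndarray:
    return np.frombuffer("".join(entries).encode(), dtype=np.uint8).reshape(len(entries), -1)


def affinity(
    seqs: LocusSequenceSet,
    refs: Sequence[Pseudoreference],
    targets: Sequence[str],
    max_mismatch: int = 1,
) -> AffinityResult:
    """Fraction of each target's loci matching each pseudoreference.

    ``raw_fraction_mapped`` = mapped loci / target's non-missing loci; loci
    absent from a reference count as unmapped for that taxon. Centered
    values subtract the within-individual mean across taxa.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    taxa = [r.taxon for r in refs]
    # pre-encode reference entries per (taxon, locus)
    ref_mats: Dict[Tuple[str, str], np.ndarray] = {}
    for r in refs:
        for locus, entries in r.sequences.items():
            ref_mats[(r.taxon, locus)] = _entry_matrix(entries)

    raw = np.full((len(targets), len(taxa)), np.nan)
    for i, ind in enumerate(targets):
        own = seqs.of_individual(ind)
        if not own:
            continue
        mapped = np.zeros(len(taxa), dtype=np.int64)
        for locus, seq in own.items():
            x = np.frombuffer(seq.encode(), dtype=np.uint8)
            x_isn = x == _N_CODE
            for t, taxon in enumerate(taxa):
                mat = ref_mats.get((taxon, locus))
                if mat is None:
                    continue
                if mat.shape[1] != x.size:
                    raise ValueError(f"length mismatch at locus {locus}")
                mism = ((mat != x) & (mat != _N_CODE) & ~x_isn).sum(axis=1)
                if int(mism.min()) <= max_mismatch:
                    mapped[t] += 1
        raw[i] = mapped / len(own)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows stay NaN
        centered = raw - np.nanmean(raw, axis=1, keepdims=True)
    return AffinityResult(list(targets), taxa, raw, centered)
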