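"""Readers and writers for the formats the pipeline touches.

VCF is read with :mod:`cyvcf2`; everything else is plain text. The VCF
writer annotates each record with ``INFO/LOCID`` and ``INFO/COL`` so locus
structure round-trips; the reader falls back to positional binning when
those annotations are absent.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    CODE,
    MISSING,
    NUCLEOTIDES,
    AlleleCall,
    GenotypeTable,
    LocusSequenceSet,
    PopulationMap,
    SchemaError,
    SiteRecord,
)

logger = logging.getLogger(__name__)

DEFAULT_LOCUS_BIN = 1000

SUMSTATS_COLUMNS = [
    "Locus ID",
    "Col",
    "Pop ID",
    "P Nuc",
    "Q Nuc",
    "N",
    "P",
    "Obs Het",
    "Exp Het",
    "Private",
]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, locus_bin: int = DEFAULT_LOCUS_BIN) -> GenotypeTable:
    """Read a VCF into a :class:`GenotypeTable`.

    Diploid GT fields become pseudo-diploid calls (the set of distinct
    called bases); ``./.`` becomes missing. Non-SNP records are skipped and
    counted. Locus ids come from ``INFO/LOCID`` when present, otherwise
    sites are binned as ``chrom:(pos-1)//locus_bin``.
    """
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    sites: List[SiteRecord] = []
    rows_lo: List[np.ndarray] = []
    rows_hi: List[np.ndarray] = []
    skipped = 0
    for rec in vcf:
        alleles = [rec.REF] + list(rec.ALT)
        if any(len(a) != 1 or a not in NUCLEOTIDES for a in alleles if a != "."):
            skipped += 1
            continue
        locid = rec.INFO.get("LOCID")
        col = rec.INFO.get("COL")
        if locid is None:
            locid = f"{rec.CHROM}:{(rec.POS - 1) // locus_bin}"
            col = (rec.POS - 1) % locus_bin
        site_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        sites.append(
            SiteRecord(site_id=site_id, locus_id=str(locid), column=int(col),
                       chrom=rec.CHROM, pos=rec.POS)
        )
        lo = np.full(len(individuals), MISSING, dtype=np.int8)
        hi = np.full(len(individuals), MISSING, dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            idx = [g for g in gt[:-1] if g >= 0]
            if not idx:
                continue
            codes = sorted(CODE[alleles[g]] for g in idx)
            lo[i] = codes[0]
            hi[i] = codes[-1]
        rows_lo.append(lo)
        rows_hi.append(hi)
    if skipped:
        logger.info("read_vcf: skipped %d non-SNP records", skipped)
    if sites:
        a_lo = np.stack(rows_lo, axis=1)
        a_hi = np.stack(rows_hi, axis=1)
    else:
        a_lo = np.zeros((len(individuals), 0), dtype=np.int8)
        a_hi = np.zeros((len(individuals), 0), dtype=np.int8)
    return GenotypeTable(individuals, sites, a_lo, a_hi)


def write_vcf(table: GenotypeTable, path) -> None:
    """Write a minimal VCF 4.2 with GT calls and LOCID/COL annotations.

    The major allele (by copy count) is emitted as REF. Sites lacking
    chrom/pos get synthetic coordinates ``locus_id:(column+1)``.
    """
    counts = table.allele_counts()
    contigs: List[str] = []
    for s in table.sites:
        chrom = s.chrom if s.chrom is not None else s.locus_id
        if chrom not in contigs:
            contigs.append(chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=radtrace\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=LOCID,Number=1,Type=String,Description="RAD locus id">\n')
        fh.write('##INFO=<ID=COL,Number=1,Type=Integer,Description="Column within locus">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.individuals) + "\n")
        for j, site in enumerate(table.sites):
            c = counts[j]
            order = np.argsort(-c, kind="stable")
            present = [int(k) for k in order if c[k] > 0]
            if not present:
                present = [0]  # all-missing column: arbitrary REF, no ALT
            ref_code = present[0]
            alts = present[1:]
            code_to_gt = {code: k for k, code in enumerate(present)}
            chrom = site.chrom if site.chrom is not None else site.locus_id
            pos = site.pos if site.pos is not None else site.column + 1
            alt_field = ",".join(NUCLEOTIDES[a] for a in alts) if alts else "."
            info = f"LOCID={site.locus_id};COL={site.column}"
            row = [chrom, str(pos), site.site_id, NUCLEOTIDES[ref_code], alt_field,
                   ".", ".", info, "GT"]
            for i in range(table.n_individuals):
                lo, hi = int(table.a_lo[i, j]), int(table.a_hi[i, j])
                if lo < 0:
                    row.append("./.")
                else:
                    row.append(f"{code_to_gt[lo]}/{code_to_gt[hi]}")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Stacks-style per-site summary table
# ---------------------------------------------------------------------------

def read_sumstats_tsv(path) -> pd.DataFrame:
    """Read a per-site per-population summary table (Stacks populations
    ``sumstats`` dialect). Comment lines starting with '#' are skipped;
    unknown columns are preserved. Windows line endings are tolerated."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"Locus ID": str, "Pop ID": str})
    found = list(df.columns)
    missing = [c for c in SUMSTATS_COLUMNS if c not in found]
    if missing:
        raise SchemaError(
            f"sumstats file {path} missing columns {missing}; expected at least "
            f"{SUMSTATS_COLUMNS}, found {found}"
        )
    df["Col"] = df["Col"].astype(int)
    for c in ("P", "Obs Het", "Exp Het"):
        df[c] = df[c].astype(float)
    df["N"] = df["N"].astype(int)
    df["Private"] = df["Private"].astype(int)
    return df


def write_sumstats_tsv(table: GenotypeTable, pops: PopulationMap, path) -> pd.DataFrame:
    """Compute and write the per-site per-population summary for a table."""
    rows = []
    pop_rows = {
        pop: [table.individual_index(i) for i in pops.members(pop) if i in table._ind_index]
        for pop in pops.populations()
    }
    pres_by_pop = {pop: table.presence(rows=r) for pop, r in pop_rows.items() if r}
    for pop, rsel in pop_rows.items():
        if not rsel:
            continue
        counts = table.allele_counts(rows=rsel)
        lo = table.a_lo[rsel]
        hi = table.a_hi[rsel]
        nonmiss = lo >= 0
        het = nonmiss & (lo != hi)
        others = [p for p in pres_by_pop if p != pop]
        for j, site in enumerate(table.sites):
            n = int(nonmiss[:, j].sum())
            if n == 0:
                continue
            c = counts[j]
            tot = c.sum()
            order = np.argsort(-c, kind="stable")
            p_code = int(order[0])
            q_codes = [int(k) for k in order[1:] if c[k] > 0]
            p = c[p_code] / tot
            freqs = c / tot
            exp_het = float(1.0 - np.sum(freqs**2))
            obs_het = float(het[:, j].sum() / n)
            private = 0
            for code in np.nonzero(c)[0]:
                if not any(pres_by_pop[o][j, code] for o in others):
                    private = 1
                    break
            rows.append(
                {
                    "Locus ID": site.locus_id,
                    "Col": site.column,
                    "Pop ID": pop,
                    "P Nuc": NUCLEOTIDES[p_code],
                    "Q Nuc": NUCLEOTIDES[q_codes[0]] if q_codes else "-",
                    "N": n,
                    "P": round(float(p), 6),
                    "Obs Het": round(obs_het, 6),
                    "Exp Het": round(exp_het, 6),
                    "Private": private,
                }
            )
    df = pd.DataFrame(rows, columns=SUMSTATS_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# Popmap / coordinates / borderline
# ---------------------------------------------------------------------------

def read_popmap(path) -> PopulationMap:
    """Read a 3-column TSV: individual, population, role."""
    assignment: Dict[str, Tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise SchemaError(f"{path}:{lineno}: expected 3 tab-separated fields")
            ind, pop, role = parts
            if ind in assignment:
                raise ValueError(f"{path}:{lineno}: duplicate individual {ind!r}")
            assignment[ind] = (pop, role)
    return PopulationMap(assignment)


def write_popmap(pops: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for ind, (pop, role) in pops.assignment.items():
            fh.write(f"{ind}\t{pop}\t{role}\n")


def read_coords(path) -> List[Tuple[str, float, float]]:
    """Read CSV with header ``individual,lat,lon`` (decimal degrees WGS84)."""
    out: List[Tuple[str, float, float]] = []
    seen = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"individual", "lat", "lon"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise SchemaError(f"{path}: expected header columns {sorted(required)}")
        for row in reader:
            ind = row["individual"]
            if ind in seen:
                raise ValueError(f"duplicate individual {ind!r} in {path}")
            seen.add(ind)
            out.append((ind, float(row["lat"]), float(row["lon"])))
    return out


def write_coords(coords: Sequence[Tuple[str, float, float]], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["individual", "lat", "lon"])
        for ind, lat, lon in coords:
            w.writerow([ind, f"{lat:.6f}", f"{lon:.6f}"])


def read_borderline(path) -> List[Tuple[float, float]]:
    """Read an ordered point list: CSV of ``lat,lon`` rows (optional header)
    or a GeoJSON LineString (GeoJSON coordinates are [lon, lat])."""
    text = Path(path).read_text().strip()
    if not text:
        raise ValueError("borderline needs >=1 point")
    points: List[Tuple[float, float]] = []
    if text.lstrip().startswith("{"):
        obj = json.loads(text)
        geom = obj.get("geometry", obj)
        if geom.get("type") != "LineString":
            raise SchemaError("borderline GeoJSON must be a LineString")
        for lon, lat in geom["coordinates"]:
            points.append((float(lat), float(lon)))
    else:
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            a, b = line.split(",")[:2]
            if a.strip().lower() in ("lat", "latitude"):
                continue
            points.append((float(a), float(b)))
    if not points:
        raise ValueError("borderline needs >=1 point")
    return points


def write_borderline(points: Sequence[Tuple[float, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("lat,lon\n")
        for lat, lon in points:
            fh.write(f"{lat:.6f},{lon:.6f}\n")


# ---------------------------------------------------------------------------
# Locus sequences (FASTA, header ">locusID|individualID")
# ---------------------------------------------------------------------------

def read_locus_fasta(path) -> LocusSequenceSet:
    seqs = LocusSequenceSet()
    locus = ind = None
    chunks: List[str] = []

    def flush():
        if locus is not None:
            seqs.add(locus, ind, "".join(chunks))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                flush()
                header = line[1:]
                if "|" not in header:
                    raise SchemaError(f"FASTA header {header!r} lacks 'locusID|individualID'")
                locus, ind = header.split("|", 1)
                chunks = []
            elif line:
                chunks.append(line)
    flush()
    return seqs


def write_locus_fasta(seqs: LocusSequenceSet, path) -> None:
    with open(path, "w") as fh:
        for (locus, ind), seq in seqs.entries.items():
            fh.write(f">{locus}|{ind}\n{seq}\n")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_trace_matrix(trace, path) -> None:
    """Trace matrix as TSV: individual, ancestor, raw, n_sites, proportion."""
    with open(path, "w") as fh:
        fh.write("individual\tancestor\traw_count\tn_variant_sites\tproportion\n")
        for ind in trace.individuals:
            for anc in trace.ancestors:
                raw = trace.raw_count(ind, anc)
                n = trace.n_variant_sites[ind]
                prop = trace.proportion(ind, anc)
                prop_s = "NA" if prop is None or np.isnan(prop) else f"{prop:.8g}"
                fh.write(f"{ind}\t{anc}\t{raw}\t{n}\t{prop_s}\n")


def read_trace_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_diversity_table(records, path) -> None:
    """Diversity records as TSV in Table-2 column order."""
    cols = ["population", "N", "N_per_locus", "sd_N", "Hobs", "sd_Hobs",
            "Hexp", "sd_Hexp", "FIS", "sd_FIS", "PA", "PA_per_N"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            def fmt(x, nd=6):
                return "NA" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.{nd}g}"
            fh.write("\t".join([
                r.population, str(r.n), fmt(r.n_per_locus_mean), fmt(r.n_per_locus_sd),
                fmt(r.hobs), fmt(r.hobs_sd), fmt(r.hexp), fmt(r.hexp_sd),
                fmt(r.fis), fmt(r.fis_sd), str(r.pa), fmt(r.pa_per_n),
            ]) + "\n")


def write_catalog(catalog, path) -> None:
    """Private-allele catalogue as TSV: taxon, site, allele, provenance."""
    with open(path, "w") as fh:
        fh.write("taxon\tsite_id\tallele\tprovenance\n")
        for taxon in catalog.taxa():
            prov = catalog.provenance[taxon]
            for site_id, allele in sorted(catalog.entries[taxon]):
                fh.write(f"{taxon}\t{site_id}\t{allele}\t{prov}\n")


def write_affinity(result, path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\ttaxon\traw_fraction_mapped\tcentered\n")
        for ind in result.individuals:
            for taxon in result.taxa:
                raw = result.raw(ind, taxon)
                cen = result.centered(ind, taxon)
                raw_s = "NA" if raw is None or np.isnan(raw) else f"{raw:.8g}"
                cen_s = "NA" if cen is None or np.isnan(cen) else f"{cen:.8g}"
                fh.write(f"{ind}\t{taxon}\t{raw_s}\t{cen_s}\n")
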