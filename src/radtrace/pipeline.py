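"""End-to-end pipeline: simulate -> filter -> diversity -> catalog -> trace
-> affinity -> geo-regress, with a reproducibility manifest.

One global seed fans out to per-stage child seeds via
``np.random.SeedSequence([seed, STAGE_IDS[stage]])`` so stages can be rerun
independently with identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import yaml

from . import __version__, diversity, geo, io, privates, simulate
from .affinity import affinity as compute_affinity, build_pseudoreference
from .model import ConfigError, FilterConfig

logger = logging.getLogger(__name__)

STAGE_IDS = {
    "simulate": 1,
    "filter": 2,
    "diversity": 3,
    "catalog": 4,
    "trace": 5,
    "affinity": 6,
    "geo": 7,
}


def stage_seed(seed: int, stage: str) -> int:
    """Documented fan-out rule for per-stage child seeds."""
    return int(np.random.SeedSequence([seed, STAGE_IDS[stage]]).generate_state(1)[0])


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def load_run_config(path) -> Dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("run config must be a mapping")
    if "seed" not in cfg:
        raise ConfigError("run config requires a seed")
    if "outdir" not in cfg:
        raise ConfigError("run config requires an outdir")
    return cfg


def simulation_config_from_dict(d: Dict[str, Any], seed: int) -> simulate.SimulationConfig:
    d = dict(d)
    pops = [simulate.DerivedPopConfig(**{
        **p, "ancestry_weights": tuple(p["ancestry_weights"]),
        "distance_range_km": tuple(p["distance_range_km"]) if p.get("distance_range_km") else None,
    }) for p in d.pop("derived_populations", [])]
    geo_cfg = simulate.GeoConfig(**d.pop("geo")) if "geo" in d and d["geo"] else simulate.GeoConfig()
    d.pop("seed", None)
    if "missing_rate_range" in d:
        d["missing_rate_range"] = tuple(d["missing_rate_range"])
    return simulate.SimulationConfig(seed=seed, derived_populations=pops, geo=geo_cfg, **d)


def run_pipeline(cfg: Dict[str, Any]) -> Dict[str, Any]:
    """Run all configured stages; returns the manifest.

    On a stage failure, outputs already written are renamed with a
    ``.partial`` suffix and the exception propagates.
    """
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    manifest: Dict[str, Any] = {
        "radtrace_version": __version__,
        "numpy_version": np.__version__,
        "seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in STAGE_IDS},
        "parameters": cfg,
        "inputs": {},
        "outputs": {},
    }

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    try:
        t0 = time.monotonic()
        # ---- inputs: simulate or load ---------------------------------
        if "simulation" in cfg and cfg["simulation"]:
            sim_cfg = simulation_config_from_dict(cfg["simulation"], stage_seed(seed, "simulate"))
            ds = simulate.simulate_dataset(sim_cfg)
            table, pops = ds.table, ds.popmap
            emit("genotypes.vcf", lambda p: io.write_vcf(table, p))
            if ds.sequences.entries:
                emit("loci.fasta", lambda p: io.write_locus_fasta(ds.sequences, p))
            emit("popmap.tsv", lambda p: io.write_popmap(pops, p))
            emit("coords.csv", lambda p: io.write_coords(ds.coordinates, p))
            emit("borderline.csv", lambda p: io.write_borderline(ds.borderline, p))
            emit("truth_individuals.tsv",
                 lambda p: simulate.write_truth(ds.truth, p, outdir / "truth_private_alleles.tsv"))
            written.append(outdir / "truth_private_alleles.tsv")
            seqs, coords, borderline = ds.sequences, ds.coordinates, ds.borderline
        else:
            inputs = cfg["inputs"]
            table = io.read_vcf(inputs["vcf"])
            pops = io.read_popmap(inputs["popmap"])
            seqs = io.read_locus_fasta(inputs["fasta"]) if inputs.get("fasta") else None
            coords = io.read_coords(inputs["coords"]) if inputs.get("coords") else None
            borderline = io.read_borderline(inputs["borderline"]) if inputs.get("borderline") else None
            for key, p in inputs.items():
                if p:
                    manifest["inputs"][key] = sha256_file(Path(p))
        pops.validate_against(table)
        logger.info("input stage done in %.2fs (%s)", time.monotonic() - t0, table)

        # ---- filter -----------------------------------------------------
        fdict = dict(cfg.get("filter", {}))
        fdict.setdefault("seed", stage_seed(seed, "filter"))
        fcfg = FilterConfig(**fdict)
        filtered = diversity.filter_sites(table, pops, fcfg)
        emit("filtered.vcf", lambda p: io.write_vcf(filtered, p))
        logger.info("filter: %d -> %d sites", table.n_sites, filtered.n_sites)

        # ---- diversity --------------------------------------------------
        records = diversity.population_diversity(filtered, pops)
        emit("diversity.tsv", lambda p: io.write_diversity_table(records, p))
        ind_cfg_d = dict(cfg.get("individual_filter", {"r": 0.7, "min_maf": 0.05}))
        ind_cfg_d.setdefault("seed", stage_seed(seed, "diversity"))
        ind_div = diversity.individual_hexp(table, FilterConfig(**ind_cfg_d))

        def write_ind(p):
            with open(p, "w") as fh:
                fh.write("individual\tn_variant_sites\thexp_ind\n")
                for r in ind_div:
                    v = "NA" if np.isnan(r.hexp_ind) else f"{r.hexp_ind:.8g}"
                    fh.write(f"{r.individual}\t{r.n_variant_sites}\t{v}\n")
        emit("individual_hexp.tsv", write_ind)

        # ---- catalogue + trace -----------------------------------------
        tcfg = cfg.get("trace", {})
        ancestors = tcfg.get("ancestors") or [
            p for p in pops.populations()
            if all(pops.role(i) == "ancestral" for i in pops.members(p))
        ]
        catalog = privates.build_catalog(filtered, pops, ancestors,
                                         strict=bool(tcfg.get("strict", False)))
        proxy = tcfg.get("proxy_population")
        if proxy:
            ghost = privates.attribute_extinct(filtered, pops, proxy, ancestors)
            privates.extend_catalog_with_extinct(
                catalog, ghost, tcfg.get("extinct_label", "extinct"))
        emit("catalog.tsv", lambda p: io.write_catalog(catalog, p))

        targets = [i for i in table.individuals if pops.role(i) == "derived"]
        trace_matrix = privates.trace(filtered, catalog, targets, pops)
        emit("trace.tsv", lambda p: io.write_trace_matrix(trace_matrix, p))

        summary = privates.summarize_trace(trace_matrix, pops)

        def write_summary(p):
            with open(p, "w") as fh:
                fh.write("population\tancestor\tn\tq1\tq2\tq3\t"
                         "whisker_lo\twhisker_hi\tn_mild_outliers\tn_severe_outliers\n")
                for (pop, anc), s in summary.cells.items():
                    fh.write(f"{pop}\t{anc}\t{s.n}\t{s.q1:.8g}\t{s.q2:.8g}\t{s.q3:.8g}\t"
                             f"{s.whisker_lo:.8g}\t{s.whisker_hi:.8g}\t"
                             f"{len(s.mild_outliers)}\t{len(s.severe_outliers)}\n")
        emit("trace_summary.tsv", write_summary)

        # ---- affinity ----------------------------------------------------
        if seqs is not None and seqs.entries:
            acfg = cfg.get("affinity", {})
            refs = [build_pseudoreference(seqs, pops, a) for a in ancestors]
            aff = compute_affinity(seqs, refs, targets,
                                   max_mismatch=int(acfg.get("max_mismatch", 1)))
            emit("affinity.tsv", lambda p: io.write_affinity(aff, p))

        # ---- geo regression ----------------------------------------------
        if coords is not None and borderline is not None:
            gcfg = cfg.get("geo_regression", {})
            sexual = [c for c in coords
                      if pops.role(c[0]) == "derived" and c[0] in {r.individual for r in ind_div}]
            dists = geo.distance_to_borderline(sexual, borderline,
                                               method=gcfg.get("method", "nearest_vertex"))

            def write_dist(p):
                with open(p, "w") as fh:
                    fh.write("individual\tdistance_km\n")
                    for ind, d in dists.items():
                        fh.write(f"{ind}\t{d:.6f}\n")
            emit("distances.tsv", write_dist)

            rows = []
            for mode in ("naive", "residual"):
                try:
                    res = geo.hexp_distance_regression(
                        ind_div, dists, mode=mode,
                        min_sites=int(gcfg.get("min_sites", 0)),
                        exclude=gcfg.get("exclude", ()), pops=pops)
                    rows.append((mode, res))
                except Exception as exc:  # too few points is a data property, not fatal
                    logger.warning("geo regression (%s) skipped: %s", mode, exc)

            def write_reg(p):
                with open(p, "w") as fh:
                    fh.write("mode\tslope_per_km\tintercept\tr\tp\tn\n")
                    for mode, res in rows:
                        fh.write(f"{mode}\t{res.slope:.8g}\t{res.intercept:.8g}\t"
                                 f"{res.r:.8g}\t{res.p:.8g}\t{res.n}\n")
            emit("geo_regression.tsv", write_reg)

        # ---- manifest -----------------------------------------------------
        for path in written:
            manifest["outputs"][path.name] = sha256_file(path)
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
        logger.info("pipeline finished in %.2fs", time.monotonic() - t0)
        return manifest
    except Exception:
        for path in written:
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        raise
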