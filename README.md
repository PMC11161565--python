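# radtrace

Private-allele cataloguing and tracing for RADseq genotype matrices of
polyploid hybrid complexes, with the surrounding analysis layer: population
and per-individual diversity statistics, extinct ("ghost") ancestor
attribution through a proxy polyploid population, a pseudoreference
mapping-affinity proxy, contact-zone distance regression, and a fully seeded
synthetic-data generator with ground truth for parameter-recovery testing.

Genotypes are treated as *pseudo-diploid*: each call is an unordered set of
at most two observed nucleotides with unknown dosage (what a diploid caller
produces on polyploid material). All statistics are defined on allele
presence/absence plus diploid genotype frequencies.

## What it computes

- **Site filters** — minimum genotyped proportion *R* (overall or
  per-population), minimum minor-allele frequency, one random SNP per locus.
- **Diversity** — per population: Hobs, Hexp (1 − Σp²), FIS, private-allele
  counts (PA) and PA normalized by mean individuals per locus; per
  individual: Hexp from the individual's own genotype (het site → 0.5)
  and the recovered-variant-site count.
- **Private alleles** — per-ancestor catalogues (allele present in one
  listed ancestral taxon and absent from all others), extinct-ancestor
  attribution (present in a proxy polyploid population, absent from every
  extant ancestor), tracing through derived individuals with per-individual
  normalization by non-missing variant sites, and boxplot summaries with
  the 1.5×/3.0× IQR outlier convention.
- **Affinity** — per-taxon pseudoreferences (all contributing individuals'
  locus consensus sequences kept verbatim), mismatch-bounded Hamming
  matching (default max 1 mismatch, N matches anything), within-individual
  mean-centering.
- **Geography** — haversine distance (R = 6371 km) to the nearest borderline
  vertex, and the Hexp–distance regression pair: naive OLS versus the
  coverage-corrected variant (residuals of Hexp on recovered variant sites,
  regressed on distance).
- **Simulation** — K ancestral diploid taxa with injected taxon-private
  alleles, derived tetraploids with per-individual ancestry weights and
  pseudo-diploid collapse, clonal groups, an optional extinct taxon reaching
  the output only via polyploid mixtures, coverage-dependent missingness and
  het-loss confounds, and a geographic borderline with distance gradients.

## CLI

```sh
radtrace simulate --config sim.yaml --seed 1 --outdir data/
radtrace filter --vcf data/genotypes.vcf --popmap data/popmap.tsv \
    --r 0.5 --min-maf 0.05 --out filtered.vcf
radtrace diversity --vcf data/genotypes.vcf --popmap data/popmap.tsv \
    --r 0.5 --min-maf 0.05 --out diversity.tsv --per-individual hexp.tsv
radtrace catalog --vcf filtered.vcf --popmap data/popmap.tsv \
    --ancestors A1,A2,A3 --proxy-population Proxy --out catalog.tsv
radtrace trace --vcf filtered.vcf --popmap data/popmap.tsv \
    --catalog catalog.tsv --out trace.tsv --summary trace_summary.tsv
radtrace affinity --fasta data/loci.fasta --popmap data/popmap.tsv \
    --ancestors A1,A2,A3 --max-mismatch 1 --out affinity.tsv
radtrace geo-regress --hexp hexp.tsv --coords data/coords.csv \
    --borderline data/borderline.csv --popmap data/popmap.tsv \
    --mode residual --min-sites 6000 --exclude Fra,Pyr --out regression.tsv
radtrace run-all --config run.yaml
```

`run-all` chains every stage from one YAML config (see
`tests/test_cli.py::demo_run_config` for a complete example) and writes a
`manifest.json` with parameter and output hashes; a fixed seed yields
byte-identical reruns. One global seed fans out to per-stage child seeds via
`SeedSequence([seed, stage_id])`.

### Formats

VCF 4.x in/out (locus structure carried in `INFO/LOCID`/`INFO/COL`, with
positional binning as fallback on plain VCFs); Stacks-style per-site
sumstats TSV; 3-column popmap (individual, population, role ∈ ancestral /
derived / proxy_polyploid); FASTA locus consensus with `>locusID|individualID`
headers; coordinates CSV (decimal degrees WGS84); borderline as lat,lon CSV
or GeoJSON LineString.

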