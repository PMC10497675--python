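# phagedyn

Analysis pipeline for gut phageome dynamics in a two-arm faecal-filtrate
transplantation (FFT) trial, starting from the tabular outputs of upstream
sequencing tools. It covers:

- **viral_triage** — select viral contigs by a four-criteria evidence rule
  (≥1 viral gene, classifier score ≥0.95, ≥2 hallmark genes, or no
  viral/bacterial genes at all), deduplicate at 100% identity, and cluster
  into viral populations (VPs) by greedy length-sorted centroid clustering at
  a configurable ANI threshold (default 95%).
- **abundance** — zero read counts for contigs with <75% horizontal coverage,
  sum counts and lengths per VP, compute RPKM against per-sample library
  sizes, filter low-abundance VPs (total RPKM <100, or RPKM >20 in <10% of
  samples), richness/Shannon diversity, clr transform, and a permutation
  PERMANOVA (Anderson pseudo-F).
- **host_linkage** — gate MAGs by completeness − 5×contamination ≥ 50, link
  VPs to MAGs by prophage containment and by CRISPR spacer hits (spacer
  length 20–30 bp, ≤2 mismatches counting unaligned spacer ends), resolve
  links to host species.
- **dynamics** — donor-shared and novel-phage abundance fractions per
  participant and day, species-level VP/MAG abundance-change interaction
  points with per-group Spearman correlation (lytic vs lysogenic signal), and
  hypergeometric host-species enrichment among differentially abundant VPs
  with Benjamini–Hochberg adjustment.
- **clinical** — two-sided Fisher exact tests for adverse-event tables, CGM
  time-in-range (3.9–10 mmol/L), OGTT glucose AUC (trapezoid, 0–120 min),
  HOMA-IR with explicit insulin units.
- **synthetic_data** — generates every input table with planted ground truth
  (viral labels, cluster memberships, VP→MAG links, engraftment fraction,
  novelty rate, signed VP–MAG coupling), so the whole pipeline is testable
  offline.
- **pipeline / cli** — config-driven orchestration with deterministic seeds
  and a JSON run report; reruns reproduce outputs byte-identically.

## CLI

```bash
# write a synthetic input set with planted truth + a run-ready config
phagedyn simulate --out-dir sim --n-participants 12 --n-vps 120 \
    --regime antagonistic --engraftment-fraction 0.3 --novelty-rate 0.05 --seed 1

# run every stage end-to-end (triage → cluster → quantify → link → dynamics
# → enrich → clinical) and write results + report.json
phagedyn run-all --config sim/pipeline_config.yaml

# individual stages; any config key can be overridden by a flag
phagedyn triage --config sim/pipeline_config.yaml --min-contig-bp 5000
phagedyn quantify --config sim/pipeline_config.yaml --breadth-min 0.75
```

Exit codes: 0 ok, 1 validation error, 2 runtime error. Logs go to stderr;
all tables are tab-separated with fixed column orders.

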