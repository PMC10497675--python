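"""Stage functions orchestrating the full analysis, plus the run report.

Each stage reads its inputs from config paths, writes its outputs under
``out_dir`` and returns a row-count summary. ``run_all`` chains the stages and
writes a deterministic JSON run report (rerunning with identical inputs and
seed reproduces every output byte-wise).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from phagedyn import io as pio
from phagedyn.abundance import (
    AbundanceTable,
    aitchison_distance,
    apply_breadth_filter,
    filter_low_abundance,
    permanova,
    richness,
    rpkm_per_vp,
    shannon,
    to_proportions,
)
from phagedyn.clinical import CgmTrace, OgttCurve, ogtt_auc, time_in_range
from phagedyn.config import ConfigError, PipelineConfig
from phagedyn.dynamics import (
    engraftment_table,
    host_enrichment,
    interaction_correlation,
    interaction_points,
)
from phagedyn.host_linkage import (
    filter_mags,
    filter_spacer_hits,
    link_prophages,
    resolve_species,
    species_host_table,
)
from phagedyn.viral_triage import cluster_vps, dedup_exact, select_viral

logger = logging.getLogger("phagedyn")

INTERVALS = ((0, 2), (2, 28), (0, 28))


def stage_triage(cfg: PipelineConfig) -> dict:
    cfg.check_inputs(("annotations",))
    annotations = pio.read_annotations(cfg.path("annotations"))
    viral = select_viral(annotations, min_length_bp=cfg.min_contig_bp)
    out = cfg.out_dir() / "viral_contigs.tsv"
    pio.write_annotations(viral, out)
    logger.info("[triage] %d/%d contigs selected as viral", len(viral), len(annotations))
    return {"n_input_contigs": len(annotations), "n_viral_contigs": len(viral)}


def stage_cluster(cfg: PipelineConfig) -> dict:
    cfg.check_inputs(("ani",))
    viral = pio.read_annotations(cfg.out_dir() / "viral_contigs.tsv")
    pairs = pio.read_ani_pairs(cfg.path("ani"))
    known = {c.contig_id for c in viral}
    pairs = [p for p in pairs if p.query_id in known and p.subject_id in known]
    deduped = dedup_exact(viral, pairs)
    vps = cluster_vps(deduped, pairs, ani_threshold_pct=cfg.ani_threshold_pct)
    pio.write_vp_membership(vps, cfg.out_dir() / "vp_membership.tsv")
    logger.info("[cluster] %d contigs -> %d VPs", len(deduped), len(vps))
    return {"n_dedup_contigs": len(deduped), "n_vps": len(vps)}


def stage_quantify(cfg: PipelineConfig) -> dict:
    cfg.check_inputs(("coverage", "library_sizes", "metadata"))
    records = pio.read_coverage(cfg.path("coverage"))
    libs = pio.read_library_sizes(cfg.path("library_sizes"))
    membership = pio.read_vp_membership(cfg.out_dir() / "vp_membership.tsv")
    viral = pio.read_annotations(cfg.out_dir() / "viral_contigs.tsv")
    lengths = {c.contig_id: c.length_bp for c in viral}
    records = [r for r in records if r.contig_id in membership]
    filtered = apply_breadth_filter(records, breadth_min=cfg.breadth_min)
    table = rpkm_per_vp(filtered, membership, lengths, libs)
    pio.write_abundance_matrix(table, cfg.out_dir() / "rpkm.tsv")

    div = pd.DataFrame(
        [
            {"sample_id": s, "richness": richness(table, s), "shannon": shannon(table, s)}
            for s in table.sample_ids
        ],
        columns=["sample_id", "richness", "shannon"],
    )
    div.to_csv(cfg.out_dir() / "diversity.tsv", sep="\t", index=False, float_format="%.6g")

    # day-2 composition test between arms (Aitchison distance on filtered RPKM)
    meta = pio.read_metadata(cfg.path("metadata"))
    day2 = meta[(meta["day"] == 2) & meta["arm"].isin(["FFT", "placebo"])]
    perm_report: dict = {"tested": False}
    if len(day2) >= 4 and day2["arm"].nunique() == 2 and day2["arm"].value_counts().min() >= 2:
        sub = filter_low_abundance(table, cfg.rpkm_total_min, cfg.rpkm_value_min, cfg.prevalence_min)
        if len(sub.feature_ids) < 2:
            sub = table
        samples = [s for s in day2["sample_id"] if s in sub.data.index]
        day2 = day2[day2["sample_id"].isin(samples)]
        sub_day2 = AbundanceTable(
            data=sub.data.loc[samples], value_kind="rpkm",
            feature_length_bp=sub.feature_length_bp, library_size=sub.library_size,
        )
        dist = aitchison_distance(to_proportions(sub_day2))
        f, p = permanova(dist, list(day2["arm"]), n_perm=cfg.n_perm, seed=cfg.seed)
        perm_report = {
            "tested": True, "day": 2, "pseudo_F": f, "p": p,
            "n_perm": cfg.n_perm, "distance": "aitchison",
            "n_samples": len(samples), "n_features": len(sub.feature_ids),
        }
    (cfg.out_dir() / "permanova.json").write_text(json.dumps(perm_report, indent=1, sort_keys=True))
    logger.info("[quantify] %d samples x %d VPs quantified", len(table.sample_ids), len(table.feature_ids))
    return {
        "n_coverage_records": len(records),
        "n_samples": len(table.sample_ids),
        "n_vps_quantified": len(table.feature_ids),
        "permanova_tested": perm_report["tested"],
    }


def stage_link(cfg: PipelineConfig) -> dict:
    cfg.check_inputs(("mag_membership", "mag_quality", "mag_taxonomy", "spacer_hits"))
    mags = pio.read_mags(cfg.path("mag_membership"), cfg.path("mag_quality"), cfg.path("mag_taxonomy"))
    good = filter_mags(mags, quality_min=cfg.mag_quality_min)
    membership = pio.read_vp_membership(cfg.out_dir() / "vp_membership.tsv")
    by_vp: dict[str, set[str]] = {}
    for cid, vp in membership.items():
        by_vp.setdefault(vp, set()).add(cid)
    prophage = link_prophages(by_vp, good)
    hits = pio.read_spacer_hits(cfg.path("spacer_hits"))
    good_ids = {m.mag_id for m in good}
    hits = [h for h in hits if h.mag_id in good_ids]
    crispr = filter_spacer_hits(
        hits,
        membership,
        len_min=cfg.spacer_len[0],
        len_max=cfg.spacer_len[1],
        max_mismatch=cfg.spacer_max_mismatch,
    )
    links = resolve_species(prophage + crispr, good)
    links = sorted(set(links), key=lambda l: (l.vp_id, l.mag_id, l.evidence))
    pio.write_host_links(links, cfg.out_dir() / "host_links.tsv")
    logger.info("[link] %d MAGs passed quality; %d links", len(good), len(links))
    return {
        "n_mags": len(mags),
        "n_mags_quality": len(good),
        "n_prophage_links": len(prophage),
        "n_crispr_links": len(crispr),
        "n_links": len(links),
    }


def stage_dynamics(cfg: PipelineConfig) -> dict:
    cfg.check_inputs(("metadata", "mag_counts"))
    table = pio.read_abundance_matrix(cfg.out_dir() / "rpkm.tsv", value_kind="rpkm")
    mag_table = pio.read_abundance_matrix(cfg.path("mag_counts"), value_kind="count")
    meta = pio.read_metadata(cfg.path("metadata"))
    links = pio.read_host_links(cfg.out_dir() / "host_links.tsv")

    engraft = engraftment_table(table, meta)
    engraft.to_csv(cfg.out_dir() / "engraftment.tsv", sep="\t", index=False, float_format="%.6g")

    groups = {
        str(r["participant_id"]): str(r["arm"])
        for _, r in meta[meta["arm"].isin(["FFT", "placebo"])].iterrows()
    }
    days_present = set(meta["day"].dropna().astype(int))
    point_rows = []
    correlations: dict[str, dict] = {}
    for day_a, day_b in INTERVALS:
        if day_a not in days_present or day_b not in days_present:
            continue
        pts = interaction_points(table, mag_table, links, meta, day_a, day_b, scale="proportion")
        for pt in pts:
            point_rows.append(
                {
                    "participant_id": pt.participant_id,
                    "species": pt.species,
                    "day_a": day_a,
                    "day_b": day_b,
                    "delta_vp": pt.delta_vp,
                    "delta_mag": pt.delta_mag,
                }
            )
        per_group = interaction_correlation(pts, groups)
        correlations[f"{day_a}-{day_b}"] = {
            g: {"rho": rho, "p": p, "n_points": n} for g, (rho, p, n) in per_group.items()
        }
    pd.DataFrame(
        point_rows, columns=["participant_id", "species", "day_a", "day_b", "delta_vp", "delta_mag"]
    ).to_csv(cfg.out_dir() / "interaction_points.tsv", sep="\t", index=False, float_format="%.6g")
    (cfg.out_dir() / "correlations.json").write_text(_json_dumps(correlations))
    logger.info("[dynamics] %d interaction points across %d intervals", len(point_rows), len(correlations))
    return {"n_interaction_points": len(point_rows), "n_intervals": len(correlations)}


def stage_enrich(cfg: PipelineConfig) -> dict:
    cfg.check_inputs(("da_vp_list",))
    da = pio.read_da_vp_list(cfg.path("da_vp_list"))
    links = pio.read_host_links(cfg.out_dir() / "host_links.tsv")
    results = host_enrichment(da, species_host_table(links), alpha=cfg.alpha)
    df = pd.DataFrame(
        [
            {"species": r.species, "q": r.q, "m": r.m, "n": r.n, "k": r.k, "p": r.p, "p_adj": r.p_adj}
            for r in results
        ],
        columns=["species", "q", "m", "n", "k", "p", "p_adj"],
    )
    df.to_csv(cfg.out_dir() / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    n_sig = int((df["p_adj"] < cfg.alpha).sum()) if len(df) else 0
    logger.info("[enrich] %d species tested, %d significant at %.2f", len(df), n_sig, cfg.alpha)
    return {"n_da_vps": len(da), "n_species_tested": len(df), "n_significant": n_sig}


def stage_clinical(cfg: PipelineConfig) -> dict:
    report: dict = {}
    if "cgm" in cfg.paths and Path(cfg.paths["cgm"]).exists():
        df = pd.read_csv(cfg.paths["cgm"], sep="\t")
        trace = CgmTrace(
            timestamps_min=tuple(df["timestamp_min"].astype(float)),
            glucose_mmol_per_l=tuple(df["glucose"].astype(float)),
        )
        report["time_in_range_pct"] = time_in_range(trace, lo=cfg.tir_range[0], hi=cfg.tir_range[1])
    if "ogtt" in cfg.paths and Path(cfg.paths["ogtt"]).exists():
        df = pd.read_csv(cfg.paths["ogtt"], sep="\t")
        curve = OgttCurve(
            minutes=tuple(int(m) for m in df["minute"]),
            glucose_mmol_per_l=tuple(df["glucose"].astype(float)),
        )
        report["ogtt_auc"] = ogtt_auc(curve)
    (cfg.out_dir() / "clinical.json").write_text(_json_dumps(report))
    logger.info("[clinical] computed %s", sorted(report))
    return {"clinical_metrics": sorted(report)}


def _json_dumps(obj) -> str:
    return json.dumps(obj, indent=1, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _recovered_partition(cfg: PipelineConfig) -> bool | None:
    """Compare the recovered VP partition against a planted truth, if given."""
    if "truth" not in cfg.paths or not Path(cfg.paths["truth"]).exists():
        return None
    truth = pio.read_truth(cfg.paths["truth"])
    membership = pio.read_vp_membership(cfg.out_dir() / "vp_membership.tsv")
    planted: dict[str, set[str]] = {}
    for cid, vp in truth.cluster_assignment.items():
        if truth.viral_labels.get(cid, False):
            planted.setdefault(vp, set()).add(cid)
    recovered: dict[str, set[str]] = {}
    for cid, vp in membership.items():
        recovered.setdefault(vp, set()).add(cid)
    return sorted(planted.values(), key=sorted) == sorted(recovered.values(), key=sorted)


def simulate_scenario(
    out_dir: str | Path,
    scenario,
    regime: str = "null",
    engraftment_fraction: float = 0.3,
    novelty_rate: float = 0.05,
    decoy_rate: float = 0.2,
    n_nonviral: int = 10,
    n_short: int = 5,
) -> Path:
    """Write a complete synthetic input set plus a ready-to-run config YAML.

    Besides the planted community, the annotation table gains non-viral and
    too-short decoy contigs that triage must reject. Returns the path of the
    written pipeline config.
    """
    import yaml

    from phagedyn.synthetic_data import (
        ScenarioConfig,
        SyntheticTruth,
        generate_cgm_trace,
        generate_community,
        generate_ogtt_curve,
        generate_spacer_hits,
        make_truth,
    )
    from phagedyn.viral_triage import ContigAnnotation
    from phagedyn.synthetic_data import generate_ani_pairs

    if not isinstance(scenario, ScenarioConfig):
        raise ConfigError("scenario must be a ScenarioConfig")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(scenario.seed)

    truth = make_truth(
        scenario,
        regime=regime,
        engraftment_fraction=engraftment_fraction,
        novelty_rate=novelty_rate,
    )
    fixture = generate_community(scenario, truth)

    annotations = []
    for cid in sorted(truth.cluster_assignment):
        annotations.append(
            ContigAnnotation(
                contig_id=cid,
                length_bp=fixture.contig_lengths[cid],
                source_fraction="WGS" if rng.random() < 0.5 else "VLP",
                viral_gene_count=int(rng.integers(1, 5)),
                host_gene_count=int(rng.integers(0, 4)),
                vs_score=float(rng.uniform(0.2, 1.0)),
                hallmark_count=int(rng.integers(0, 3)),
            )
        )
    extra_labels: dict[str, bool] = {}
    extra_clusters: dict[str, str] = {}
    for j in range(n_nonviral):
        cid = f"nonviral{j:04d}"
        annotations.append(
            ContigAnnotation(
                contig_id=cid,
                length_bp=int(rng.integers(5000, 30001)),
                source_fraction="WGS",
                viral_gene_count=0,
                host_gene_count=int(rng.integers(1, 10)),
                vs_score=float(rng.uniform(0.0, 0.9)),
                hallmark_count=int(rng.integers(0, 2)),
            )
        )
        extra_labels[cid] = False
        extra_clusters[cid] = f"NV{j:04d}"
    for j in range(n_short):
        cid = f"short{j:04d}"
        annotations.append(
            ContigAnnotation(
                contig_id=cid,
                length_bp=int(rng.integers(500, 4999)),
                source_fraction="VLP",
                viral_gene_count=0,
                host_gene_count=int(rng.integers(1, 5)),
                vs_score=None,
                hallmark_count=0,
            )
        )
        extra_labels[cid] = False
        extra_clusters[cid] = f"SH{j:04d}"

    truth_out = SyntheticTruth(
        viral_labels={**truth.viral_labels, **extra_labels},
        cluster_assignment={**truth.cluster_assignment, **extra_clusters},
        true_links=truth.true_links,
        engraftment_fraction=truth.engraftment_fraction,
        novelty_rate=truth.novelty_rate,
        coupling_beta=truth.coupling_beta,
        noise_sd=truth.noise_sd,
        regime=truth.regime,
    )

    ani_threshold = 95.0
    ani = generate_ani_pairs(truth.cluster_assignment, ani_threshold, seed=scenario.seed + 1)

    members_of: dict[str, list[str]] = {}
    for cid, vp in sorted(truth.cluster_assignment.items()):
        members_of.setdefault(vp, []).append(cid)
    crispr_links = {(l.vp_id, l.mag_id) for l in fixture.links if l.evidence == "crispr"}
    hits, _ = generate_spacer_hits(
        crispr_links,
        decoy_rate=decoy_rate,
        seed=scenario.seed + 2,
        contig_of={vp: members[0] for vp, members in members_of.items()},
    )

    hosted = sorted({l.vp_id for l in fixture.links})
    da_vps = hosted[::3]

    cgm = generate_cgm_trace(seed=scenario.seed + 3, minutes=7 * 24 * 60, mean=6.0, sd=1.2)
    ogtt = generate_ogtt_curve(seed=scenario.seed + 4)

    pio.write_annotations(annotations, out / "annotations.tsv")
    pio.write_ani_pairs(ani, out / "ani.tsv")
    pio.write_coverage(fixture.coverage, out / "coverage.tsv")
    pio.write_library_sizes(fixture.vp_counts.library_size or {}, out / "library_sizes.tsv")
    pio.write_mag_tables(
        fixture.mags, out / "mag_membership.tsv", out / "mag_quality.tsv", out / "mag_taxonomy.tsv"
    )
    pio.write_spacer_hits(hits, out / "spacer_hits.tsv")
    pio.write_metadata(fixture.metadata, out / "metadata.tsv")
    pio.write_abundance_matrix(fixture.mag_counts, out / "mag_counts.tsv")
    pio.write_da_vp_list(da_vps, out / "da_vps.txt")
    pio.write_truth(truth_out, out / "truth.json")
    pd.DataFrame(
        {"timestamp_min": cgm.timestamps_min, "glucose": cgm.glucose_mmol_per_l}
    ).to_csv(out / "cgm.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame({"minute": ogtt.minutes, "glucose": ogtt.glucose_mmol_per_l}).to_csv(
        out / "ogtt.tsv", sep="\t", index=False, float_format="%.6g"
    )

    cfg = {
        "ani_threshold_pct": ani_threshold,
        "seed": scenario.seed,
        "paths": {
            "annotations": str(out / "annotations.tsv"),
            "ani": str(out / "ani.tsv"),
            "coverage": str(out / "coverage.tsv"),
            "library_sizes": str(out / "library_sizes.tsv"),
            "mag_membership": str(out / "mag_membership.tsv"),
            "mag_quality": str(out / "mag_quality.tsv"),
            "mag_taxonomy": str(out / "mag_taxonomy.tsv"),
            "spacer_hits": str(out / "spacer_hits.tsv"),
            "metadata": str(out / "metadata.tsv"),
            "mag_counts": str(out / "mag_counts.tsv"),
            "da_vp_list": str(out / "da_vps.txt"),
            "truth": str(out / "truth.json"),
            "cgm": str(out / "cgm.tsv"),
            "ogtt": str(out / "ogtt.tsv"),
            "out_dir": str(out / "results"),
        },
    }
    cfg_path = out / "pipeline_config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return cfg_path


STAGES = {
    "triage": stage_triage,
    "cluster": stage_cluster,
    "quantify": stage_quantify,
    "link": stage_link,
    "dynamics": stage_dynamics,
    "enrich": stage_enrich,
}


def run_all(cfg: PipelineConfig) -> dict:
    """Execute all stages in order and write the run report.

    Any stage failure raises with a stage-named message; the clinical stage
    runs only when its inputs are configured.
    """
    cfg.check_inputs()
    from phagedyn import __version__

    report: dict = {"version": __version__, "seed": cfg.seed, "config": cfg.echo(), "stages": {}}
    for name, fn in STAGES.items():
        try:
            report["stages"][name] = fn(cfg)
        except ConfigError:
            raise
        except Exception as exc:  # annotate with the failing stage
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    if any(Path(cfg.paths.get(k, "")).exists() for k in ("cgm", "ogtt") if k in cfg.paths):
        report["stages"]["clinical"] = stage_clinical(cfg)
    recovered = _recovered_partition(cfg)
    if recovered is not None:
        report["recovered_partition"] = recovered
    (cfg.out_dir() / "report.json").write_text(_json_dumps(report))
    return report
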