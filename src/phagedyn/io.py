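"""TSV/JSON readers and writers for every pipeline table.

All tables are tab-separated with fixed column orders; floats are written at 6
significant digits. BLAST tabular input follows the outfmt-6 column order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from phagedyn.abundance import AbundanceTable, CoverageRecord
from phagedyn.host_linkage import HostLink, Mag, SpacerHit
from phagedyn.synthetic_data import SyntheticTruth
from phagedyn.viral_triage import (
    BLAST6_COLUMNS,
    AniPair,
    ContigAnnotation,
    ViralPopulation,
    aggregate_blast_ani,
)

FLOAT_FMT = "%.6g"


def _write(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# --- contig annotations -----------------------------------------------------

ANNOTATION_COLUMNS = ["contig_id", "length", "source", "viral_genes", "host_genes", "score", "hallmarks"]


def write_annotations(annotations: Iterable[ContigAnnotation], path: str | Path) -> None:
    rows = [
        {
            "contig_id": a.contig_id,
            "length": a.length_bp,
            "source": a.source_fraction,
            "viral_genes": a.viral_gene_count,
            "host_genes": a.host_gene_count,
            "score": "" if a.vs_score is None else a.vs_score,
            "hallmarks": a.hallmark_count,
        }
        for a in annotations
    ]
    _write(pd.DataFrame(rows, columns=ANNOTATION_COLUMNS), path)


def read_annotations(path: str | Path) -> list[ContigAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str})
    out = []
    for _, r in df.iterrows():
        score = r["score"]
        out.append(
            ContigAnnotation(
                contig_id=str(r["contig_id"]),
                length_bp=int(r["length"]),
                source_fraction=str(r["source"]),
                viral_gene_count=int(r["viral_genes"]),
                host_gene_count=int(r["host_genes"]),
                vs_score=None if pd.isna(score) else float(score),
                hallmark_count=int(r["hallmarks"]),
            )
        )
    return out


# --- ANI tables --------------------------------------------------------------

ANI_COLUMNS = ["query_id", "subject_id", "ani_pct", "aligned_fraction"]


def write_ani_pairs(pairs: Iterable[AniPair], path: str | Path) -> None:
    rows = [
        {
            "query_id": p.query_id,
            "subject_id": p.subject_id,
            "ani_pct": p.ani_pct,
            "aligned_fraction": "" if p.aligned_fraction is None else p.aligned_fraction,
        }
        for p in pairs
    ]
    _write(pd.DataFrame(rows, columns=ANI_COLUMNS), path)


def read_ani_pairs(path: str | Path) -> list[AniPair]:
    """Read either the aggregated ANI TSV dialect or raw BLAST outfmt-6.

    outfmt-6 is detected by the absence of a header and 12+ columns; per-HSP
    rows are aggregated into identity-weighted directed ANI values.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("query_id\t"):
        df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "subject_id": str})
        return [
            AniPair(
                query_id=str(r["query_id"]),
                subject_id=str(r["subject_id"]),
                ani_pct=float(r["ani_pct"]),
                aligned_fraction=None if pd.isna(r["aligned_fraction"]) else float(r["aligned_fraction"]),
            )
            for _, r in df.iterrows()
        ]
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS, dtype={"qseqid": str, "sseqid": str})
    return aggregate_blast_ani(df)


# --- VP membership -----------------------------------------------------------

VP_COLUMNS = ["vp_id", "contig_id", "representative"]


def write_vp_membership(vps: Iterable[ViralPopulation], path: str | Path) -> None:
    rows = []
    for vp in vps:
        for cid in sorted(vp.member_ids):
            rows.append(
                {"vp_id": vp.vp_id, "contig_id": cid, "representative": int(cid == vp.representative_id)}
            )
    _write(pd.DataFrame(rows, columns=VP_COLUMNS), path)


def read_vp_membership(path: str | Path) -> dict[str, str]:
    """contig_id -> vp_id."""
    df = pd.read_csv(path, sep="\t", dtype={"vp_id": str, "contig_id": str})
    return dict(zip(df["contig_id"], df["vp_id"]))


# --- coverage and library sizes ----------------------------------------------

COVERAGE_COLUMNS = ["contig_id", "sample_id", "read_count", "fraction_covered"]


def write_coverage(records: Iterable[CoverageRecord], path: str | Path) -> None:
    rows = [
        {
            "contig_id": r.contig_id,
            "sample_id": r.sample_id,
            "read_count": r.read_count,
            "fraction_covered": r.fraction_covered,
        }
        for r in records
    ]
    _write(pd.DataFrame(rows, columns=COVERAGE_COLUMNS), path)


def read_coverage(path: str | Path) -> list[CoverageRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "sample_id": str})
    return [
        CoverageRecord(
            contig_id=str(r["contig_id"]),
            sample_id=str(r["sample_id"]),
            read_count=int(r["read_count"]),
            fraction_covered=float(r["fraction_covered"]),
        )
        for _, r in df.iterrows()
    ]


def write_library_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"sample_id": s, "library_size": int(n)} for s, n in sorted(sizes.items())],
        columns=["sample_id", "library_size"],
    )
    _write(df, path)


def read_library_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return {str(r["sample_id"]): int(r["library_size"]) for _, r in df.iterrows()}


# --- abundance matrices ------------------------------------------------------


def write_abundance_matrix(table: AbundanceTable, path: str | Path) -> None:
    """Features x samples matrix TSV; first column 'feature_id'."""
    out = table.data.T
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_abundance_matrix(path: str | Path, value_kind: str) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    return AbundanceTable(data=df.T, value_kind=value_kind)


# --- MAG tables ---------------------------------------------------------------


def write_mag_tables(
    mags: Sequence[Mag],
    membership_path: str | Path,
    quality_path: str | Path,
    taxonomy_path: str | Path,
) -> None:
    mem_rows = [
        {"mag_id": m.mag_id, "contig_id": cid} for m in mags for cid in sorted(m.contig_ids)
    ]
    _write(pd.DataFrame(mem_rows, columns=["mag_id", "contig_id"]), membership_path)
    q_rows = [
        {
            "mag_id": m.mag_id,
            "participant_id": m.participant_id,
            "completeness": m.completeness_pct,
            "contamination": m.contamination_pct,
        }
        for m in mags
    ]
    _write(pd.DataFrame(q_rows, columns=["mag_id", "participant_id", "completeness", "contamination"]), quality_path)
    t_rows = [
        {"mag_id": m.mag_id, "species": "" if m.species is None else m.species} for m in mags
    ]
    _write(pd.DataFrame(t_rows, columns=["mag_id", "species"]), taxonomy_path)


def read_mags(
    membership_path: str | Path, quality_path: str | Path, taxonomy_path: str | Path
) -> list[Mag]:
    mem = pd.read_csv(membership_path, sep="\t", dtype=str)
    qual = pd.read_csv(quality_path, sep="\t", dtype={"mag_id": str, "participant_id": str})
    tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str)
    contigs: dict[str, set[str]] = {}
    for _, r in mem.iterrows():
        contigs.setdefault(r["mag_id"], set()).add(r["contig_id"])
    species = {
        r["mag_id"]: (None if pd.isna(r["species"]) or r["species"] == "" else r["species"])
        for _, r in tax.iterrows()
    }
    mags = []
    for _, r in qual.iterrows():
        mid = r["mag_id"]
        mags.append(
            Mag(
                mag_id=mid,
                participant_id=str(r["participant_id"]),
                completeness_pct=float(r["completeness"]),
                contamination_pct=float(r["contamination"]),
                species=species.get(mid),
                contig_ids=frozenset(contigs.get(mid, set())),
            )
        )
    return mags


# --- spacer hits ---------------------------------------------------------------

SPACER_COLUMNS = BLAST6_COLUMNS + ["spacer_len"]


def write_spacer_hits(hits: Iterable[SpacerHit], path: str | Path) -> None:
    """outfmt-6 dialect plus a spacer_len column; qseqid is '<mag_id>:<spacer>'."""
    rows = []
    for h in hits:
        mism = max(0, h.align_len - h.n_identical)
        rows.append(
            {
                "qseqid": h.spacer_id,
                "sseqid": h.target_contig,
                "pident": 100.0 * h.n_identical / h.align_len if h.align_len else 0.0,
                "length": h.align_len,
                "mismatch": mism,
                "gapopen": h.gapopen,
                "qstart": 1,
                "qend": h.align_len,
                "sstart": 1,
                "send": h.align_len,
                "evalue": 1e-5,
                "bitscore": 2.0 * h.n_identical,
                "spacer_len": h.spacer_len,
            }
        )
    _write(pd.DataFrame(rows, columns=SPACER_COLUMNS), path)


def read_spacer_hits(path: str | Path) -> list[SpacerHit]:
    df = pd.read_csv(path, sep="\t", dtype={"qseqid": str, "sseqid": str})
    hits = []
    for _, r in df.iterrows():
        qid = str(r["qseqid"])
        mag_id = qid.split(":", 1)[0]
        align_len = int(r["length"])
        n_identical = int(round(float(r["pident"]) / 100.0 * align_len))
        hits.append(
            SpacerHit(
                spacer_id=qid,
                mag_id=mag_id,
                spacer_len=int(r["spacer_len"]),
                target_contig=str(r["sseqid"]),
                n_identical=n_identical,
                align_len=align_len,
                gapopen=int(r["gapopen"]),
            )
        )
    return hits


# --- host links -----------------------------------------------------------------

LINK_COLUMNS = ["vp_id", "mag_id", "species", "evidence"]


def write_host_links(links: Iterable[HostLink], path: str | Path) -> None:
    rows = [
        {
            "vp_id": l.vp_id,
            "mag_id": l.mag_id,
            "species": "" if l.species is None else l.species,
            "evidence": l.evidence,
        }
        for l in links
    ]
    _write(pd.DataFrame(rows, columns=LINK_COLUMNS), path)


def read_host_links(path: str | Path) -> list[HostLink]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        HostLink(
            vp_id=str(r["vp_id"]),
            mag_id=str(r["mag_id"]),
            species=(None if pd.isna(r["species"]) or r["species"] == "" else str(r["species"])),
            evidence=str(r["evidence"]),
        )
        for _, r in df.iterrows()
    ]


# --- metadata, DA lists, truth ---------------------------------------------------

META_COLUMNS = ["sample_id", "participant_id", "arm", "day", "donor_id", "fraction"]


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    _write(meta[META_COLUMNS], path)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "participant_id": str, "arm": str, "donor_id": str})
    df["day"] = pd.to_numeric(df["day"], errors="coerce").astype("Int64")
    df["donor_id"] = df["donor_id"].fillna("")
    return df


def write_da_vp_list(vp_ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{v}\n" for v in vp_ids))


def read_da_vp_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "viral_labels": truth.viral_labels,
        "cluster_assignment": truth.cluster_assignment,
        "true_links": sorted(list(t) for t in truth.true_links),
        "engraftment_fraction": truth.engraftment_fraction,
        "novelty_rate": truth.novelty_rate,
        "coupling_beta": truth.coupling_beta,
        "noise_sd": truth.noise_sd,
        "regime": truth.regime,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        viral_labels={k: bool(v) for k, v in payload["viral_labels"].items()},
        cluster_assignment=payload["cluster_assignment"],
        true_links={(a, b) for a, b in payload["true_links"]},
        engraftment_fraction=payload["engraftment_fraction"],
        novelty_rate=payload["novelty_rate"],
        coupling_beta=payload["coupling_beta"],
        noise_sd=payload["noise_sd"],
        regime=payload["regime"],
    )
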