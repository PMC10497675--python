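"""Viral contig triage, exact deduplication and ANI clustering into VPs.

Contigs are selected as viral when at least one of four annotation-evidence
criteria holds, deduplicated at 100% identity / full-length alignment, then
greedily clustered into viral populations (VPs) around length-sorted centroid
representatives at a configurable ANI threshold (default 95).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

DEFAULT_MIN_CONTIG_BP = 5000
DEFAULT_ANI_THRESHOLD_PCT = 95.0

BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass(frozen=True)
class ContigAnnotation:
    """Per-contig annotation evidence feeding the viral selection rule.

    ``vs_score`` may be None when the classifier produced no score for the
    contig; such contigs can never pass the score criterion.
    """

    contig_id: str
    length_bp: int
    source_fraction: str = "WGS"  # WGS | VLP
    viral_gene_count: int = 0
    host_gene_count: int = 0
    vs_score: float | None = None
    hallmark_count: int = 0

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.contig_id}: length_bp must be positive")
        if self.viral_gene_count < 0 or self.host_gene_count < 0 or self.hallmark_count < 0:
            raise ValueError(f"{self.contig_id}: gene/hallmark counts must be non-negative")


@dataclass(frozen=True)
class AniPair:
    """One directed pairwise ANI value, BLAST outfmt-6 dialect.

    ``aligned_fraction`` is the fraction of the *query* covered by the
    alignment; None when unknown (pre-aggregated ANI input).
    """

    query_id: str
    subject_id: str
    ani_pct: float
    aligned_fraction: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.ani_pct <= 100.0:
            raise ValueError(f"ani_pct {self.ani_pct} outside [0, 100]")


@dataclass
class ViralPopulation:
    vp_id: str
    representative_id: str
    member_ids: set[str] = field(default_factory=set)
    total_length_bp: int = 0

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError(f"{self.vp_id}: representative not among members")


def classify_viral(contig: ContigAnnotation) -> bool:
    """Apply the four-criteria viral selection rule.

    A contig is viral if at least one of:
      1. at least one viral gene was identified,
      2. classifier score >= 0.95,
      3. at least 2 viral hallmark genes,
      4. neither viral nor bacterial genes were identified.
    """
    score_ok = contig.vs_score is not None and contig.vs_score >= 0.95
    return (
        contig.viral_gene_count >= 1
        or score_ok
        or contig.hallmark_count >= 2
        or (contig.viral_gene_count == 0 and contig.host_gene_count == 0)
    )


def select_viral(
    contigs: Iterable[ContigAnnotation], min_length_bp: int = DEFAULT_MIN_CONTIG_BP
) -> list[ContigAnnotation]:
    """Length-gate then triage contigs; returns the viral subset."""
    return [c for c in contigs if c.length_bp >= min_length_bp and classify_viral(c)]


def aggregate_blast_ani(blast6: pd.DataFrame) -> list[AniPair]:
    """Collapse per-HSP blastn outfmt-6 rows into one directed ANI per pair.

    ANI is the identity-weighted mean over alignment lengths; aligned_fraction
    is left None (query lengths are not part of outfmt-6). Self-hits dropped.
    """
    df = blast6.copy()
    if list(df.columns[: len(BLAST6_COLUMNS)]) != BLAST6_COLUMNS:
        df.columns = BLAST6_COLUMNS + list(df.columns[len(BLAST6_COLUMNS) :])
    df = df[df["qseqid"] != df["sseqid"]]
    if df.empty:
        return []
    df["_wsum"] = df["pident"] * df["length"]
    agg = df.groupby(["qseqid", "sseqid"], sort=True).agg(
        wsum=("_wsum", "sum"), alen=("length", "sum")
    )
    return [
        AniPair(query_id=q, subject_id=s, ani_pct=row.wsum / row.alen)
        for (q, s), row in agg.iterrows()
    ]


def _symmetric_ani(ani_pairs: Iterable[AniPair]) -> dict[tuple[str, str], float]:
    """Max-of-directed ANI lookup keyed by unordered pair."""
    out: dict[tuple[str, str], float] = {}
    for p in ani_pairs:
        if p.query_id == p.subject_id:
            continue
        key = (p.query_id, p.subject_id) if p.query_id < p.subject_id else (p.subject_id, p.query_id)
        prev = out.get(key)
        if prev is None or p.ani_pct > prev:
            out[key] = p.ani_pct
    return out


def dedup_exact(
    contigs: Sequence[ContigAnnotation], ani_pairs: Iterable[AniPair]
) -> list[ContigAnnotation]:
    """Remove exact duplicates (100% ANI over the shorter contig's full length).

    Contigs connected by pairs with ani_pct == 100 and aligned_fraction == 1
    for the shorter member form duplicate groups; only the longest member is
    kept (ties broken by lexicographically smallest id). Containment-only hits
    (aligned_fraction < 1) do not trigger removal.
    """
    lengths = {c.contig_id: c.length_bp for c in contigs}
    parent: dict[str, str] = {c.contig_id: c.contig_id for c in contigs}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in ani_pairs:
        if p.query_id not in lengths or p.subject_id not in lengths:
            continue
        if p.ani_pct != 100.0 or p.aligned_fraction is None or p.aligned_fraction < 1.0:
            continue
        # full-length alignment must cover the shorter member: the query side
        # carries aligned_fraction, so require the query be the shorter (or tied)
        if lengths[p.query_id] > lengths[p.subject_id]:
            continue
        ra, rb = find(p.query_id), find(p.subject_id)
        if ra != rb:
            parent[ra] = rb

    groups: dict[str, list[ContigAnnotation]] = {}
    for c in contigs:
        groups.setdefault(find(c.contig_id), []).append(c)
    kept = [min(g, key=lambda c: (-c.length_bp, c.contig_id)) for g in groups.values()]
    order = {c.contig_id: i for i, c in enumerate(contigs)}
    kept.sort(key=lambda c: order[c.contig_id])
    return kept


def cluster_vps(
    contigs: Sequence[ContigAnnotation],
    ani_pairs: Iterable[AniPair],
    ani_threshold_pct: float = DEFAULT_ANI_THRESHOLD_PCT,
    single_linkage: bool = False,
) -> list[ViralPopulation]:
    """Cluster deduplicated contigs into viral populations.

    Default is greedy centroid clustering: contigs sorted by descending length
    (ties by id) either join the first existing VP whose *representative* they
    match at >= threshold, or found a new VP. ``single_linkage=True`` instead
    merges any two contigs matching at >= threshold (connected components).
    Directed ANI values are reconciled by maximum.
    """
    if not 0.0 < ani_threshold_pct <= 100.0:
        raise ValueError("ani_threshold_pct must be in (0, 100]")
    known = {c.contig_id for c in contigs}
    pairs = list(ani_pairs)
    for p in pairs:
        if p.query_id not in known or p.subject_id not in known:
            raise ValueError(f"ANI pair references unknown contig: {p.query_id}/{p.subject_id}")
    ani = _symmetric_ani(pairs)

    def get_ani(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        return ani.get(key, 0.0)

    ordered = sorted(contigs, key=lambda c: (-c.length_bp, c.contig_id))
    lengths = {c.contig_id: c.length_bp for c in contigs}

    if single_linkage:
        parent = {c.contig_id: c.contig_id for c in contigs}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for (a, b), v in ani.items():
            if v >= ani_threshold_pct:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
        comp: dict[str, set[str]] = {}
        for c in contigs:
            comp.setdefault(find(c.contig_id), set()).add(c.contig_id)
        clusters = sorted(
            comp.values(),
            key=lambda m: (-max(lengths[i] for i in m), min(sorted(m, key=lambda i: (-lengths[i], i)))),
        )
        members_list = clusters
    else:
        reps: list[str] = []
        members: list[set[str]] = []
        for c in ordered:
            for i, rep in enumerate(reps):
                if get_ani(c.contig_id, rep) >= ani_threshold_pct:
                    members[i].add(c.contig_id)
                    break
            else:
                reps.append(c.contig_id)
                members.append({c.contig_id})
        members_list = members

    vps: list[ViralPopulation] = []
    width = max(4, len(str(len(members_list))))
    for i, mem in enumerate(members_list, start=1):
        rep = min(mem, key=lambda cid: (-lengths[cid], cid))
        vps.append(
            ViralPopulation(
                vp_id=f"VP{i:0{width}d}",
                representative_id=rep,
                member_ids=set(mem),
                total_length_bp=sum(lengths[m] for m in mem),
            )
        )
    return vps


def vp_membership(vps: Iterable[ViralPopulation]) -> dict[str, str]:
    """contig_id -> vp_id mapping (asserts the VPs partition their members)."""
    out: dict[str, str] = {}
    for vp in vps:
        for cid in vp.member_ids:
            if cid in out:
                raise ValueError(f"contig {cid} assigned to {out[cid]} and {vp.vp_id}")
            out[cid] = vp.vp_id
    return out
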