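"""Phage-host linkage: MAG quality gating, prophage containment, CRISPR spacers.

MAGs pass when completeness - 5 x contamination >= 50. A VP is linked to a
MAG either because one of its member contigs is binned into the MAG (prophage)
or because a MAG CRISPR spacer of 20-30 bp hits a member contig with at most 2
mismatches, where mismatches = spacer_len - n_identical (unaligned spacer ends
count against the hit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

DEFAULT_MAG_QUALITY_MIN = 50.0
DEFAULT_SPACER_LEN_MIN = 20
DEFAULT_SPACER_LEN_MAX = 30
DEFAULT_SPACER_MAX_MISMATCH = 2

EVIDENCE_TYPES = ("prophage", "crispr")


@dataclass(frozen=True)
class Mag:
    mag_id: str
    participant_id: str
    completeness_pct: float
    contamination_pct: float
    species: str | None = None
    contig_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness_pct <= 100.0:
            raise ValueError(f"{self.mag_id}: completeness outside [0, 100]")
        if self.contamination_pct < 0.0:
            raise ValueError(f"{self.mag_id}: contamination must be >= 0")

    @property
    def quality_score(self) -> float:
        return self.completeness_pct - 5.0 * self.contamination_pct


@dataclass(frozen=True)
class SpacerHit:
    """A blastn-short hit of a CRISPR spacer (query) against a viral contig."""

    spacer_id: str
    mag_id: str
    spacer_len: int
    target_contig: str
    n_identical: int
    align_len: int
    gapopen: int = 0

    def __post_init__(self) -> None:
        if self.n_identical < 0:
            raise ValueError("n_identical must be >= 0")

    @property
    def mismatches(self) -> int:
        # full-length convention: unaligned spacer ends count as mismatches
        return self.spacer_len - self.n_identical


@dataclass(frozen=True)
class HostLink:
    vp_id: str
    mag_id: str
    species: str | None
    evidence: str

    def __post_init__(self) -> None:
        if self.evidence not in EVIDENCE_TYPES:
            raise ValueError(f"evidence must be one of {EVIDENCE_TYPES}")


def filter_mags(mags: Iterable[Mag], quality_min: float = DEFAULT_MAG_QUALITY_MIN) -> list[Mag]:
    """Keep MAGs with completeness - 5 x contamination >= quality_min."""
    return [m for m in mags if m.quality_score >= quality_min]


def link_prophages(
    vp_membership: Mapping[str, set[str]] | Mapping[str, frozenset[str]],
    mags: Sequence[Mag],
) -> list[HostLink]:
    """One prophage HostLink per (VP, MAG) sharing at least one contig id."""
    links: list[HostLink] = []
    seen: set[tuple[str, str]] = set()
    contig_to_vp: dict[str, str] = {}
    for vp_id, members in vp_membership.items():
        for cid in members:
            contig_to_vp[cid] = vp_id
    for mag in mags:
        for cid in sorted(mag.contig_ids):
            vp_id = contig_to_vp.get(cid)
            if vp_id is not None and (vp_id, mag.mag_id) not in seen:
                seen.add((vp_id, mag.mag_id))
                links.append(HostLink(vp_id=vp_id, mag_id=mag.mag_id, species=mag.species, evidence="prophage"))
    return links


def filter_spacer_hits(
    hits: Iterable[SpacerHit],
    contig_to_vp: Mapping[str, str],
    len_min: int = DEFAULT_SPACER_LEN_MIN,
    len_max: int = DEFAULT_SPACER_LEN_MAX,
    max_mismatch: int = DEFAULT_SPACER_MAX_MISMATCH,
) -> list[HostLink]:
    """Filter spacer hits and emit deduplicated crispr HostLinks.

    A hit passes when len_min <= spacer_len <= len_max and
    spacer_len - n_identical <= max_mismatch. Hits to contigs outside every
    VP are dropped with a warning.
    """
    links: list[HostLink] = []
    seen: set[tuple[str, str]] = set()
    for h in hits:
        if not len_min <= h.spacer_len <= len_max:
            continue
        if h.mismatches > max_mismatch:
            continue
        vp_id = contig_to_vp.get(h.target_contig)
        if vp_id is None:
            logger.warning("spacer hit %s targets contig %s outside any VP; dropped", h.spacer_id, h.target_contig)
            continue
        if (vp_id, h.mag_id) not in seen:
            seen.add((vp_id, h.mag_id))
            links.append(HostLink(vp_id=vp_id, mag_id=h.mag_id, species=None, evidence="crispr"))
    return links


def resolve_species(links: Iterable[HostLink], mags: Sequence[Mag]) -> list[HostLink]:
    """Fill each link's species from its MAG's taxonomy; missing stays missing."""
    species_of = {m.mag_id: m.species for m in mags}
    out: list[HostLink] = []
    for link in links:
        if link.mag_id not in species_of:
            raise KeyError(f"link references unknown MAG {link.mag_id}")
        out.append(replace(link, species=species_of[link.mag_id]))
    return out


def species_host_table(links: Iterable[HostLink]) -> dict[str, set[str]]:
    """vp_id -> set of host species (links without species excluded)."""
    out: dict[str, set[str]] = {}
    for link in links:
        if link.species is None:
            continue
        out.setdefault(link.vp_id, set()).add(link.species)
    return out
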