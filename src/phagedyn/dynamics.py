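"""Longitudinal phageome metrics.

Donor engraftment and novel-phage fractions per participant-day, species-level
VP/MAG abundance-change points with a per-group Spearman correlation (lytic vs
lysogenic signal), and hypergeometric host-species enrichment among
differentially abundant VPs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from phagedyn.abundance import AbundanceTable, clr_transform, to_proportions
from phagedyn.host_linkage import HostLink

DEFAULT_INTERVALS = ((0, 2), (2, 28), (0, 28))
EXACT_SPEARMAN_MAX_N = 10


@dataclass(frozen=True)
class InteractionPoint:
    participant_id: str
    species: str
    interval: tuple[int, int]
    delta_vp: float
    delta_mag: float


@dataclass(frozen=True)
class EnrichmentResult:
    species: str
    q: int  # DA VPs linked to the species
    m: int  # VPs linked to the species
    n: int  # hosted VPs not linked to the species
    k: int  # DA VPs within the hosted universe
    p: float
    p_adj: float


def _sample_id_for(meta: pd.DataFrame, participant: str, day: int | None) -> str:
    if day is None:
        rows = meta[(meta["participant_id"] == participant) & (meta["arm"] == "donor")]
    else:
        rows = meta[(meta["participant_id"] == participant) & (meta["day"] == day)]
    if rows.empty:
        raise KeyError(f"no sample for participant {participant!r} day {day!r}")
    return str(rows.iloc[0]["sample_id"])


def donor_shared_fraction(
    vp_table: AbundanceTable, meta: pd.DataFrame, participant: str, day: int
) -> float:
    """Percent of the participant-day RPKM carried by VPs detected in the donor.

    The donor is the participant's assigned donor; detection is RPKM > 0 in
    the donor's (single, pre-intervention) sample. Returns 0 when the
    recipient sample is empty.
    """
    prow = meta[(meta["participant_id"] == participant) & (meta["day"] == day)]
    if prow.empty:
        raise KeyError(f"no sample for {participant} at day {day}")
    donor_id = prow.iloc[0].get("donor_id")
    if donor_id is None or (isinstance(donor_id, float) and np.isnan(donor_id)) or donor_id == "":
        raise KeyError(f"participant {participant} has no assigned donor")
    donor_sample = _sample_id_for(meta, str(donor_id), None)
    sample = _sample_id_for(meta, participant, day)
    donor_present = vp_table.sample(donor_sample) > 0
    values = vp_table.sample(sample)
    total = float(values.sum())
    if total == 0.0:
        return 0.0
    return 100.0 * float(values[donor_present].sum()) / total


def novel_fraction(
    vp_table: AbundanceTable, meta: pd.DataFrame, participant: str, day: int
) -> float:
    """Percent of the participant-day RPKM on VPs absent at the participant's day 0."""
    baseline = _sample_id_for(meta, participant, 0)
    sample = _sample_id_for(meta, participant, day)
    absent_at_baseline = vp_table.sample(baseline) == 0
    values = vp_table.sample(sample)
    total = float(values.sum())
    if total == 0.0:
        return 0.0
    return 100.0 * float(values[absent_at_baseline].sum()) / total


def engraftment_table(
    vp_table: AbundanceTable, meta: pd.DataFrame
) -> pd.DataFrame:
    """Long-format donor-shared and novel percentages for every recipient sample.

    Donor-shared is only computed for participants with an assigned donor;
    novel requires a day-0 baseline.
    """
    rows = []
    recip = meta[meta["arm"].isin(["FFT", "placebo"])]
    for _, r in recip.iterrows():
        participant, day = str(r["participant_id"]), int(r["day"])
        has_donor = pd.notna(r.get("donor_id")) and r.get("donor_id") != ""
        shared = (
            donor_shared_fraction(vp_table, meta, participant, day) if has_donor else np.nan
        )
        novel = novel_fraction(vp_table, meta, participant, day) if day >= 0 else np.nan
        rows.append(
            {
                "participant_id": participant,
                "arm": r["arm"],
                "day": day,
                "donor_shared_pct": shared,
                "novel_pct": novel,
            }
        )
    return pd.DataFrame(rows)


def _species_maps(links: Iterable[HostLink]) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """(species -> linked VPs, species -> linked MAGs), ignoring species-less links."""
    vps: dict[str, set[str]] = {}
    mags: dict[str, set[str]] = {}
    for link in links:
        if link.species is None:
            continue
        vps.setdefault(link.species, set()).add(link.vp_id)
        mags.setdefault(link.species, set()).add(link.mag_id)
    return vps, mags


def interaction_points(
    vp_table: AbundanceTable,
    mag_table: AbundanceTable,
    links: Sequence[HostLink],
    meta: pd.DataFrame,
    day_a: int,
    day_b: int,
    scale: str = "proportion",
) -> list[InteractionPoint]:
    """Species-level mean abundance changes for VPs and their host MAGs.

    For each participant with samples at both days and each species with >=1
    linked VP and >=1 linked MAG: delta_vp is the mean change over the
    species' VPs, delta_mag over its MAGs, on per-sample proportions
    (scale='proportion') or clr values (scale='clr'). Species silent at both
    days on either side are omitted.
    """
    if scale == "proportion":
        vp_scaled = to_proportions(vp_table)
        mag_scaled = to_proportions(mag_table)
    elif scale == "clr":
        vp_scaled = clr_transform(to_proportions(vp_table))
        mag_scaled = clr_transform(to_proportions(mag_table))
    else:
        raise ValueError("scale must be 'proportion' or 'clr'")

    species_vps, species_mags = _species_maps(links)
    species_list = sorted(set(species_vps) & set(species_mags))

    # resolve feature ids to column positions once
    vp_pos = {f: i for i, f in enumerate(vp_table.feature_ids)}
    mag_pos = {f: i for i, f in enumerate(mag_table.feature_ids)}
    sp_vp_idx: dict[str, np.ndarray] = {}
    sp_mag_idx: dict[str, np.ndarray] = {}
    for species in species_list:
        vi = np.array([vp_pos[v] for v in sorted(species_vps[species]) if v in vp_pos], dtype=int)
        mi = np.array([mag_pos[m] for m in sorted(species_mags[species]) if m in mag_pos], dtype=int)
        if vi.size and mi.size:
            sp_vp_idx[species] = vi
            sp_mag_idx[species] = mi
    species_list = [s for s in species_list if s in sp_vp_idx]

    vp_rows = {s: i for i, s in enumerate(vp_table.sample_ids)}
    mag_rows = {s: i for i, s in enumerate(mag_table.sample_ids)}
    vp_sc = vp_scaled.data.to_numpy(dtype=float)
    mag_sc = mag_scaled.data.to_numpy(dtype=float)
    vp_raw = vp_table.data.to_numpy(dtype=float)
    mag_raw = mag_table.data.to_numpy(dtype=float)

    points: list[InteractionPoint] = []
    recip = meta[meta["arm"].isin(["FFT", "placebo"])]
    sample_of = {
        (str(r["participant_id"]), int(r["day"])): str(r["sample_id"]) for _, r in recip.iterrows()
    }
    for participant in sorted(recip["participant_id"].astype(str).unique()):
        s_a = sample_of.get((participant, day_a))
        s_b = sample_of.get((participant, day_b))
        if s_a is None or s_b is None:
            continue
        ia, ib = vp_rows[s_a], vp_rows[s_b]
        ja, jb = mag_rows[s_a], mag_rows[s_b]
        for species in species_list:
            vi, mi = sp_vp_idx[species], sp_mag_idx[species]
            # no abundance signal at either day on one side -> no point
            if (vp_raw[ia, vi].sum() == 0 and vp_raw[ib, vi].sum() == 0) or (
                mag_raw[ja, mi].sum() == 0 and mag_raw[jb, mi].sum() == 0
            ):
                continue
            delta_vp = float((vp_sc[ib, vi] - vp_sc[ia, vi]).mean())
            delta_mag = float((mag_sc[jb, mi] - mag_sc[ja, mi]).mean())
            points.append(
                InteractionPoint(
                    participant_id=participant,
                    species=species,
                    interval=(day_a, day_b),
                    delta_vp=delta_vp,
                    delta_mag=delta_mag,
                )
            )
    return points


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (n <= 10), vectorized."""
    n = x.size
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    ry_c = ry - ry.mean()
    denom_y = float((ry_c**2).sum())
    rx_c = rx - rx.mean()
    denom_x = float((rx_c**2).sum())
    if denom_x == 0 or denom_y == 0:
        return float("nan")
    count = 0
    total = 0
    chunk: list[np.ndarray] = []
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        chunk.append(rx_c[list(perm)])
        if len(chunk) == 40320:
            mat = np.asarray(chunk)
            rhos = (mat @ ry_c) / math.sqrt(denom_x * denom_y)
            count += int((np.abs(rhos) >= target).sum())
            total += mat.shape[0]
            chunk = []
    if chunk:
        mat = np.asarray(chunk)
        rhos = (mat @ ry_c) / math.sqrt(denom_x * denom_y)
        count += int((np.abs(rhos) >= target).sum())
        total += mat.shape[0]
    return count / total


def spearman(
    delta_vp: Sequence[float], delta_mag: Sequence[float]
) -> tuple[float, float]:
    """(rho, two-sided p); exact permutation p for n <= 10, t-approx above.

    Constant input on either axis leaves rho undefined -> (nan, nan).
    """
    x = np.asarray(delta_vp, dtype=float)
    y = np.asarray(delta_mag, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p_t = stats.spearmanr(x, y)
    if x.size <= EXACT_SPEARMAN_MAX_N:
        return float(rho), _exact_spearman_p(x, y, float(rho))
    return float(rho), float(p_t)


def interaction_correlation(
    points: Sequence[InteractionPoint],
    group_assignment: Mapping[str, str],
) -> dict[str, tuple[float, float, int]]:
    """Per-group Spearman correlation of delta_vp vs delta_mag.

    Returns {group: (rho, p, n_points)}; groups with <3 points are skipped.
    """
    by_group: dict[str, list[InteractionPoint]] = {}
    for pt in points:
        group = group_assignment.get(pt.participant_id)
        if group is None:
            continue
        by_group.setdefault(group, []).append(pt)
    out: dict[str, tuple[float, float, int]] = {}
    for group, pts in sorted(by_group.items()):
        if len(pts) < 3:
            continue
        rho, p = spearman([p_.delta_vp for p_ in pts], [p_.delta_mag for p_ in pts])
        out[group] = (rho, p, len(pts))
    return out


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * n / (rank + 1))
        adj[idx] = running
    return adj.tolist()


def host_enrichment(
    da_vp_ids: Iterable[str],
    host_table: Mapping[str, set[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of host species among DA VPs.

    The universe is VPs with >=1 host species; DA VPs without a host are
    excluded from k. For each species with q >= 1 DA VPs:
    p = P[X >= q], X ~ Hypergeom(population m+n, successes m, draws k),
    equivalently R's phyper(q-1, m, n, k, lower.tail=FALSE). BH-adjusted
    across tested species; ``alpha`` is recorded for callers, not applied.
    """
    hosted = {vp: set(sp) for vp, sp in host_table.items() if sp}
    universe = set(hosted)
    da = set(da_vp_ids)
    da_hosted = da & universe
    k = len(da_hosted)

    species_all: dict[str, set[str]] = {}
    for vp, specs in hosted.items():
        for s in specs:
            species_all.setdefault(s, set()).add(vp)

    tested: list[EnrichmentResult] = []
    raw_p: list[float] = []
    for species in sorted(species_all):
        vps = species_all[species]
        q = len(vps & da_hosted)
        if q == 0:
            continue
        m = len(vps)
        n = len(universe) - m
        if q > m or k > m + n:
            raise ValueError(f"inconsistent enrichment inputs for {species}")
        p = float(stats.hypergeom.sf(q - 1, m + n, m, k))
        p = min(max(p, 0.0), 1.0)
        tested.append(EnrichmentResult(species=species, q=q, m=m, n=n, k=k, p=p, p_adj=np.nan))
        raw_p.append(p)
    if not tested:
        return []
    adj = bh_adjust(raw_p)
    return [
        EnrichmentResult(species=r.species, q=r.q, m=r.m, n=r.n, k=r.k, p=r.p, p_adj=a)
        for r, a in zip(tested, adj)
    ]
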