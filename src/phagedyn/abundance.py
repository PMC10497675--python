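"""Coverage-filtered abundance tables and community statistics.

Read counts whose contig breadth (horizontal coverage) falls below the cutoff
are zeroed, counts and lengths are summed per viral population, and RPKM is
computed against per-sample library sizes. Downstream: low-abundance
filtering, richness/Shannon, clr transform, and a permutation PERMANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_BREADTH_MIN = 0.75
DEFAULT_RPKM_TOTAL_MIN = 100.0
DEFAULT_RPKM_VALUE_MIN = 20.0
DEFAULT_PREVALENCE_MIN = 0.10


@dataclass(frozen=True)
class CoverageRecord:
    """Mapped-read summary for one contig in one sample.

    ``read_count`` counts reads mapped at or above the upstream identity
    cutoff (>=90% by default, applied by the mapper, not here);
    ``fraction_covered`` is the breadth: fraction of bases hit by >=1 read.
    """

    contig_id: str
    sample_id: str
    read_count: int
    fraction_covered: float

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")
        if not 0.0 <= self.fraction_covered <= 1.0:
            raise ValueError("fraction_covered must be in [0, 1]")


@dataclass
class AbundanceTable:
    """Samples x features matrix with optional lengths and library sizes.

    ``data`` is indexed by sample_id with feature_id columns. ``value_kind``
    is one of {"count", "rpkm", "proportion", "clr"}.
    """

    data: pd.DataFrame
    value_kind: str
    feature_length_bp: dict[str, int] | None = None
    library_size: dict[str, int] | None = None

    VALUE_KINDS = ("count", "rpkm", "proportion", "clr")

    def __post_init__(self) -> None:
        if self.value_kind not in self.VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        vals = self.data.to_numpy(dtype=float)
        if self.value_kind in ("count", "rpkm") and vals.size and (vals < 0).any():
            raise ValueError(f"{self.value_kind} values must be non-negative")
        if self.value_kind == "proportion" and vals.size:
            sums = vals.sum(axis=1)
            # all-zero rows are tolerated (empty sample kept for alignment)
            bad = ~(np.isclose(sums, 1.0, atol=1e-9) | (sums == 0.0))
            if bad.any():
                raise ValueError("proportion rows must sum to 1")
        if self.value_kind == "clr" and vals.size:
            if not np.allclose(vals.sum(axis=1), 0.0, atol=1e-9):
                raise ValueError("clr rows must sum to 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    def sample(self, sample_id: str) -> pd.Series:
        return self.data.loc[sample_id]


def apply_breadth_filter(
    records: Iterable[CoverageRecord], breadth_min: float = DEFAULT_BREADTH_MIN
) -> list[CoverageRecord]:
    """Zero read counts where breadth < breadth_min; everything else unchanged."""
    if not 0.0 <= breadth_min <= 1.0:
        raise ValueError("breadth_min must be in [0, 1]")
    out = []
    for r in records:
        if r.fraction_covered < breadth_min and r.read_count != 0:
            out.append(replace(r, read_count=0))
        else:
            out.append(r)
    return out


def breadth_from_depth(depth: pd.DataFrame, contig_lengths: Mapping[str, int]) -> dict[tuple[str, str], float]:
    """Breadth per (contig, sample) from a genomecov-style capped-depth table.

    ``depth`` columns: contig_id, sample_id, depth (0 or 1 with -max 1),
    n_bases. Breadth = covered bases / contig length.
    """
    covered = depth[depth["depth"] >= 1].groupby(["contig_id", "sample_id"])["n_bases"].sum()
    return {
        (cid, sid): float(n) / contig_lengths[cid] for (cid, sid), n in covered.items()
    }


def rpkm_per_vp(
    records: Sequence[CoverageRecord],
    vp_membership: Mapping[str, str],
    contig_lengths: Mapping[str, int],
    library_sizes: Mapping[str, int],
) -> AbundanceTable:
    """Sum counts and lengths per VP, then RPKM per (sample, VP).

    RPKM = sum(counts) / ((sum(member lengths)/1e3) * (library_size/1e6)).
    Member contigs absent from a sample contribute zero counts, but their
    lengths still enter the VP length sum.
    """
    for sid, ls in library_sizes.items():
        if ls <= 0:
            raise ValueError(f"library size for {sid} must be positive")
    vp_ids = sorted(set(vp_membership.values()))
    sample_ids = sorted(library_sizes)
    vp_len: dict[str, int] = {v: 0 for v in vp_ids}
    for cid, vp in vp_membership.items():
        vp_len[vp] += contig_lengths[cid]

    counts = pd.DataFrame(0.0, index=sample_ids, columns=vp_ids)
    for r in records:
        if r.contig_id not in vp_membership:
            raise ValueError(f"contig {r.contig_id} has no VP assignment")
        if r.sample_id not in library_sizes:
            raise ValueError(f"sample {r.sample_id} has no library size")
        counts.loc[r.sample_id, vp_membership[r.contig_id]] += r.read_count

    lens_kb = np.array([vp_len[v] / 1e3 for v in vp_ids])
    libs_m = np.array([library_sizes[s] / 1e6 for s in sample_ids])
    rpkm = counts.to_numpy() / (lens_kb[None, :] * libs_m[:, None])
    return AbundanceTable(
        data=pd.DataFrame(rpkm, index=sample_ids, columns=vp_ids),
        value_kind="rpkm",
        feature_length_bp=dict(vp_len),
        library_size={s: int(library_sizes[s]) for s in sample_ids},
    )


def filter_low_abundance(
    table: AbundanceTable,
    total_min: float = DEFAULT_RPKM_TOTAL_MIN,
    value_min: float = DEFAULT_RPKM_VALUE_MIN,
    prevalence_min: float = DEFAULT_PREVALENCE_MIN,
) -> AbundanceTable:
    """Drop low-abundance/low-prevalence features from an RPKM table.

    Keeps features with total RPKM >= total_min over all samples AND
    RPKM > value_min in at least prevalence_min of samples.
    """
    if table.value_kind != "rpkm":
        raise ValueError("filter_low_abundance expects an rpkm table")
    vals = table.data
    total_ok = vals.sum(axis=0) >= total_min
    prev_ok = (vals > value_min).mean(axis=0) >= prevalence_min
    keep = vals.columns[total_ok & prev_ok]
    return AbundanceTable(
        data=vals[keep].copy(),
        value_kind="rpkm",
        feature_length_bp=(
            {f: table.feature_length_bp[f] for f in keep} if table.feature_length_bp else None
        ),
        library_size=table.library_size,
    )


def richness(table: AbundanceTable, sample_id: str) -> int:
    """Number of features observed (> 0) in the sample."""
    return int((table.sample(sample_id) > 0).sum())


def shannon(table: AbundanceTable, sample_id: str) -> float:
    """Shannon index H = -sum p_i ln p_i over positive proportions; 0 if empty."""
    v = table.sample(sample_id).to_numpy(dtype=float)
    v = v[v > 0]
    if v.size == 0:
        return 0.0
    p = v / v.sum()
    return float(-(p * np.log(p)).sum())


def to_proportions(table: AbundanceTable) -> AbundanceTable:
    """Per-sample closure to proportions; all-zero samples stay all-zero."""
    vals = table.data.to_numpy(dtype=float)
    sums = vals.sum(axis=1, keepdims=True)
    props = np.where(sums > 0, vals / np.where(sums == 0, 1.0, sums), 0.0)
    return AbundanceTable(
        data=pd.DataFrame(props, index=table.data.index, columns=table.data.columns),
        value_kind="proportion",
        feature_length_bp=table.feature_length_bp,
        library_size=table.library_size,
    )


def default_pseudocount(table: AbundanceTable) -> float:
    """Half the smallest positive value in the table (standard clr practice)."""
    vals = table.data.to_numpy(dtype=float)
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ValueError("cannot derive a pseudocount from an all-zero table")
    return float(pos.min()) / 2.0


def clr_transform(table: AbundanceTable, pseudocount: float | None = None) -> AbundanceTable:
    """Centred log-ratio: ln(x + pc) minus the per-sample mean of ln(x + pc)."""
    if pseudocount is None:
        pseudocount = default_pseudocount(table)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logged = np.log(table.data.to_numpy(dtype=float) + pseudocount)
    clr = logged - logged.mean(axis=1, keepdims=True)
    return AbundanceTable(
        data=pd.DataFrame(clr, index=table.data.index, columns=table.data.columns),
        value_kind="clr",
        feature_length_bp=table.feature_length_bp,
        library_size=table.library_size,
    )


def aitchison_distance(table: AbundanceTable, pseudocount: float | None = None) -> pd.DataFrame:
    """Euclidean distance on clr-transformed values (square symmetric matrix)."""
    clr = table if table.value_kind == "clr" else clr_transform(table, pseudocount)
    x = clr.data.to_numpy(dtype=float)
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    return pd.DataFrame(np.sqrt(sq), index=clr.data.index, columns=clr.data.index)


def bray_curtis_distance(table: AbundanceTable) -> pd.DataFrame:
    """Bray-Curtis dissimilarity on per-sample proportions."""
    props = to_proportions(table).data.to_numpy(dtype=float)
    num = np.abs(props[:, None, :] - props[None, :, :]).sum(axis=2)
    den = (props[:, None, :] + props[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / den, 0.0)
    return pd.DataFrame(d, index=table.data.index, columns=table.data.index)


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Anderson's PERMANOVA pseudo-F from squared distances and group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size < 1:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if ss_within <= 0.0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / df_between) / (ss_within / df_within)


def permanova(
    dist: pd.DataFrame | np.ndarray,
    groups: Sequence[str],
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """One-way PERMANOVA: (pseudo_F, permutation p).

    p = (1 + #{permuted F >= observed F}) / (1 + n_perm), labels permuted
    uniformly with numpy's default_rng(seed).
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12) or not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    labels = np.asarray(list(groups))
    if labels.shape[0] != d.shape[0]:
        raise ValueError("groups length must match matrix size")
    uniq, codes = np.unique(labels, return_inverse=True)
    if uniq.size < 2 or np.bincount(codes).min() < 2:
        raise ValueError("need >=2 groups with >=2 members each")

    d2 = d**2
    f_obs = _pseudo_f(d2, codes, uniq.size)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, uniq.size) >= f_obs:
            count += 1
    return float(f_obs), (1 + count) / (1 + n_perm)


def permanova_with_covariates(
    dist: pd.DataFrame | np.ndarray,
    groups: Sequence[str],
    covariate: Sequence[str],
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Sequential two-term PERMANOVA with the group term last.

    The covariate partition is removed first; the group pseudo-F is computed
    on the residual within-covariate strata. Approximates covariate-controlled
    reference implementations; documented as such.
    """
    d = np.asarray(dist, dtype=float)
    labels = np.asarray(list(groups))
    cov = np.asarray(list(covariate))
    if not (d.shape[0] == labels.shape[0] == cov.shape[0]):
        raise ValueError("inconsistent sizes")
    _, gcodes = np.unique(labels, return_inverse=True)
    _, ccodes = np.unique(cov, return_inverse=True)
    ng, nc = gcodes.max() + 1, ccodes.max() + 1
    n = d.shape[0]
    d2 = d**2

    def stat(g: np.ndarray) -> float:
        ss_total = d2[np.triu_indices(n, k=1)].sum() / n
        ss_w_cov = 0.0
        for c in range(nc):
            idx = np.flatnonzero(ccodes == c)
            if idx.size:
                sub = d2[np.ix_(idx, idx)]
                ss_w_cov += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
        ss_w_both = 0.0
        cells = 0
        for c in range(nc):
            for gg in range(ng):
                idx = np.flatnonzero((ccodes == c) & (g == gg))
                if idx.size:
                    cells += 1
                    sub = d2[np.ix_(idx, idx)]
                    ss_w_both += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
        ss_group = ss_w_cov - ss_w_both
        df_group = ng - 1
        df_resid = n - cells
        if ss_w_both <= 0 or df_resid <= 0:
            return np.inf if ss_group > 0 else 0.0
        return (ss_group / df_group) / (ss_w_both / df_resid)

    f_obs = stat(gcodes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        # permute group labels within covariate strata
        perm = gcodes.copy()
        for c in range(nc):
            idx = np.flatnonzero(ccodes == c)
            perm[idx] = perm[idx][rng.permutation(idx.size)]
        if stat(perm) >= f_obs:
            count += 1
    return float(f_obs), (1 + count) / (1 + n_perm)
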