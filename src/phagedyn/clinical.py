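"""Trial-level clinical statistics: Fisher exact, CGM time-in-range, OGTT AUC,
HOMA-IR."""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import stats

OGTT_MINUTES = (0, 15, 30, 45, 60, 90, 120)
TIR_LO = 3.9
TIR_HI = 10.0

# p-value comparison slack for "as extreme as observed"
_FISHER_EPS = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = arms, columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must have at least one observation")


@dataclass(frozen=True)
class CgmTrace:
    timestamps_min: tuple[float, ...]
    glucose_mmol_per_l: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.timestamps_min) != len(self.glucose_mmol_per_l):
            raise ValueError("timestamps and readings must have equal length")
        t = np.asarray(self.timestamps_min)
        if t.size and not (np.diff(t) > 0).all():
            raise ValueError("timestamps must be strictly increasing")


@dataclass(frozen=True)
class OgttCurve:
    minutes: tuple[int, ...]
    glucose_mmol_per_l: tuple[float, ...]
    c_peptide: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.minutes) != len(self.glucose_mmol_per_l):
            raise ValueError("minutes and glucose must have equal length")


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by the sum-of-small-probabilities rule.

    All tables with the observed margins whose hypergeometric point
    probability is <= the observed one (within 1e-7 relative slack)
    contribute to p.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1 = a + b
    col1 = a + c
    n = a + b + c + d
    dist = stats.hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_EPS)].sum())
    return min(p, 1.0)


def time_in_range(trace: CgmTrace, lo: float = TIR_LO, hi: float = TIR_HI) -> float:
    """Percentage of CGM readings with lo <= glucose <= hi (equal weighting)."""
    g = np.asarray(trace.glucose_mmol_per_l, dtype=float)
    if g.size == 0:
        raise ValueError("empty CGM trace")
    return 100.0 * float(((g >= lo) & (g <= hi)).mean())


def ogtt_auc(curve: OgttCurve) -> float:
    """Total glucose AUC over 0-120 min by the trapezoidal rule (mmol/L x min)."""
    if tuple(curve.minutes) != OGTT_MINUTES:
        raise ValueError(f"OGTT requires the full grid {OGTT_MINUTES}")
    return float(np.trapezoid(np.asarray(curve.glucose_mmol_per_l, dtype=float), np.asarray(curve.minutes, dtype=float)))


# pmol/L per uU/mL for human insulin (standard conversion)
_PMOL_PER_UU = 6.0

_INSULIN_FACTORS_TO_UU_PER_ML = {
    "uU/mL": 1.0,
    "mU/L": 1.0,  # identical magnitude
    "pmol/L": 1.0 / _PMOL_PER_UU,
    "nmol/L": 1000.0 / _PMOL_PER_UU,
}


def homa_ir(glucose_mmol_per_l: float, insulin: float, insulin_unit: str) -> float:
    """HOMA1-IR = fasting glucose (mmol/L) x fasting insulin (uU/mL) / 22.5.

    The insulin unit must be declared explicitly (one of
    {'uU/mL', 'mU/L', 'pmol/L', 'nmol/L'}); values are converted to uU/mL.
    """
    if glucose_mmol_per_l <= 0 or insulin <= 0:
        raise ValueError("glucose and insulin must be positive")
    try:
        factor = _INSULIN_FACTORS_TO_UU_PER_ML[insulin_unit]
    except KeyError:
        raise ValueError(
            f"insulin_unit must be one of {sorted(_INSULIN_FACTORS_TO_UU_PER_ML)}, got {insulin_unit!r}"
        ) from None
    return glucose_mmol_per_l * insulin * factor / 22.5
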