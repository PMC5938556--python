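"""Alpha diversity, two-group rank statistics, and qPCR absolute quantification.

Diversity is summarised per sample as observed richness and the Shannon
index (natural-log units).  Group contrasts use the two-sided Wilcoxon
rank-sum test paired with the Hodges–Lehmann shift estimator, the
nonparametric effect-size companion of that test.  qPCR Ct values are
converted to 16S rRNA gene copies per m² of collector surface through a
standard-curve regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError
from .io_tables import CountTable

#: Exposure area (m²) of the electrostatic dust fall collector cloth.
EDC_AREA_M2 = 0.0209


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def richness(column) -> int:
    """Number of OTUs observed (count > 0) in one sample column."""
    col = np.asarray(column)
    if (col < 0).any():
        raise DataError("counts must be non-negative")
    return int((col > 0).sum())


def shannon(column) -> float:
    """Shannon index H = -sum p_i ln p_i, natural log, over observed OTUs."""
    col = np.asarray(column, dtype=float)
    total = col.sum()
    if total <= 0:
        raise DataError("Shannon index undefined for a zero-total sample")
    p = col[col > 0] / total
    return float(-(p * np.log(p)).sum())


def diversity_table(counts: CountTable) -> pd.DataFrame:
    """Richness and Shannon index for every sample column."""
    rows = [
        {
            "sample_id": sid,
            "richness": richness(counts.df[sid]),
            "shannon": shannon(counts.df[sid]),
        }
        for sid in counts.sample_ids
    ]
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum + Hodges–Lehmann
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """Two-sided Wilcoxon rank-sum result with the Hodges–Lehmann shift.

    ``statistic`` is the Mann–Whitney U of the first group (the convention
    R's ``wilcox.test`` prints as W).  ``hl_estimate`` is the median of all
    pairwise differences x_i - y_j; positive means the first group is larger.
    """

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    hl_estimate: float
    hl_abs: float = field(init=False)
    degenerate: bool = False
    method: str = ""

    def __post_init__(self) -> None:
        self.hl_abs = abs(self.hl_estimate)
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def wilcoxon_rank_sum(x, y, group_a: str = "a", group_b: str = "b") -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test with midranks.

    Uses the exact null distribution when n+m <= 20 and there are no ties,
    and the normal approximation with tie correction and continuity
    correction otherwise.  If every value in both samples is identical the
    comparison is degenerate: p = 1 by convention, flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        u = x.size * y.size / 2.0
        return GroupComparison(group_a, group_b, x.size, y.size, u, 1.0,
                               hodges_lehmann(x, y), degenerate=True, method="degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return GroupComparison(group_a, group_b, x.size, y.size, float(res.statistic),
                           float(min(res.pvalue, 1.0)), hodges_lehmann(x, y),
                           method=method)


def hodges_lehmann(x, y) -> float:
    """Median of all pairwise differences x_i - y_j (two-sample HL estimator)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both samples must be non-empty")
    return float(np.median(np.subtract.outer(x, y)))


# ---------------------------------------------------------------------------
# qPCR quantification
# ---------------------------------------------------------------------------


@dataclass
class QpcrCalibration:
    """Standard-curve fit Ct = slope * log10(copies) + intercept.

    ``efficiency`` is the per-cycle amplification gain 10^(-1/slope) - 1;
    a perfect doubling per cycle (slope -3.3219) gives 1.0.  A non-negative
    slope is physically invalid and recorded as a warning rather than an
    exception so that a calibration table can still be inspected.
    """

    slope: float
    intercept: float
    efficiency: float = field(init=False)
    edc_area_m2: float = EDC_AREA_M2
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.edc_area_m2 <= 0:
            raise ConfigurationError("edc_area_m2 must be positive")
        if self.slope != 0:
            self.efficiency = 10.0 ** (-1.0 / self.slope) - 1.0
        else:
            self.efficiency = float("nan")
        if self.slope >= 0 and "invalid slope" not in " ".join(self.warnings):
            self.warnings = self.warnings + (
                f"invalid slope {self.slope:.4g} >= 0: Ct must decrease with template",
            )


def fit_standard_curve(ct, log10_copies, edc_area_m2: float = EDC_AREA_M2) -> QpcrCalibration:
    """Least-squares standard curve from a dilution series."""
    ct = np.asarray(ct, dtype=float)
    log10_copies = np.asarray(log10_copies, dtype=float)
    if ct.size != log10_copies.size or ct.size < 2:
        raise DataError("need >= 2 matched (ct, log10_copies) points")
    if np.unique(log10_copies).size < 2:
        raise DataError("all dilution points identical; standard curve is singular")
    slope, intercept = np.polyfit(log10_copies, ct, 1)
    return QpcrCalibration(float(slope), float(intercept), edc_area_m2=edc_area_m2)


def quantify_copies_per_m2(
    ct: float, calibration: QpcrCalibration, dilution_factor: float = 1.0
) -> float:
    """Invert the standard curve and scale to copies per m² of collector.

    ``dilution_factor`` collapses the template-to-filter volume chain
    (extract volume / template volume x any dilution) into one multiplier.
    """
    if calibration.slope == 0:
        raise ConfigurationError("calibration slope of zero cannot be inverted")
    copies_reaction = 10.0 ** ((ct - calibration.intercept) / calibration.slope)
    return copies_reaction * dilution_factor / calibration.edc_area_m2
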