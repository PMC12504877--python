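"""Differential cell count aggregation and method-agreement statistics.

The terminal product of the pipeline is a 16-component differential cell
count (DCC): per-class counts and proportions over the countable classes
only. Agreement between an automated DCC and a manual one is summarised by
the Pearson correlation coefficient, Lin's concordance correlation
coefficient (CCC) and Bland–Altman limits of agreement.

Lin's CCC uses population (``n``-denominator) moments:

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)

which penalises both decorrelation and location/scale shift; ``|CCC| <= |r|``
with equality iff the first two moments match. Bland–Altman limits are
``mean(d) ± 1.96 sd(d)`` with the sample (``n-1``) standard deviation of the
paired differences ``d``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .taxonomy import DEFAULT_TAXONOMY, CellTaxonomy


class NoCountableCellsError(ValueError):
    """Raised when a DCC is requested but no countable cells are present."""


@dataclass(frozen=True)
class DCCResult:
    """Counts and proportions over the countable classes of a taxonomy."""

    counts: Mapping[str, int]
    proportions: Mapping[str, float]
    total_countable: int
    total_segmented: int
    excluded_count: int

    def as_vector(self, taxonomy: CellTaxonomy = DEFAULT_TAXONOMY) -> np.ndarray:
        """Proportions ordered by the taxonomy's countable classes."""
        return np.array([self.proportions[n] for n in taxonomy.countable_names])

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "proportions": dict(self.proportions),
            "total_countable": self.total_countable,
            "total_segmented": self.total_segmented,
            "excluded_count": self.excluded_count,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DCCResult":
        return cls(
            counts={k: int(v) for k, v in d["counts"].items()},
            proportions={k: float(v) for k, v in d["proportions"].items()},
            total_countable=int(d["total_countable"]),
            total_segmented=int(d["total_segmented"]),
            excluded_count=int(d["excluded_count"]),
        )


def aggregate_dcc(records: Iterable, taxonomy: CellTaxonomy = DEFAULT_TAXONOMY) -> DCCResult:
    """Tally classified cells into the 16-component differential count.

    ``records`` may be cell records carrying a ``label`` attribute or plain
    label strings. Cells of excluded classes are tallied separately and do
    not enter the proportion denominator.
    """
    labels = [r.label if hasattr(r, "label") else str(r) for r in records]
    for lab in labels:
        if lab not in taxonomy:
            raise ValueError(f"label {lab!r} not in taxonomy")
    counts = {n: 0 for n in taxonomy.countable_names}
    excluded = 0
    for lab in labels:
        if taxonomy.is_countable(lab):
            counts[lab] += 1
        else:
            excluded += 1
    total = sum(counts.values())
    if total == 0:
        raise NoCountableCellsError("no-countable-cells")
    proportions = {n: counts[n] / total for n in counts}
    return DCCResult(
        counts=counts,
        proportions=proportions,
        total_countable=total,
        total_segmented=len(labels),
        excluded_count=excluded,
    )


# ---------------------------------------------------------------------------
# agreement statistics


def concordance_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient with population moments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be 1-D vectors of equal length >= 2")
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    sx2 = np.mean((x - x.mean()) ** 2)
    sy2 = np.mean((y - y.mean()) ** 2)
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0:
        return 1.0  # identical constant vectors agree perfectly
    return float(2.0 * sxy / denom)


@dataclass(frozen=True)
class BlandAltman:
    """Mean paired difference and 95% limits of agreement."""

    mean_diff: float
    sd_diff: float
    lower_limit: float
    upper_limit: float
    within_limits_fraction: float


def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltman:
    """Limits of agreement for differences ``x - y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    within = float(np.mean((d >= lo) & (d <= hi)))
    return BlandAltman(mean, sd, lo, hi, within)


@dataclass(frozen=True)
class DCCAgreement:
    pearson_r: float | None
    ccc: float
    bland_altman: BlandAltman
    n_components: int

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "ccc": self.ccc,
            "mean_diff": self.bland_altman.mean_diff,
            "loa_lower": self.bland_altman.lower_limit,
            "loa_upper": self.bland_altman.upper_limit,
            "n_components": self.n_components,
        }


def dcc_agreement(
    auto: DCCResult | Sequence[float],
    manual: Sequence[float],
    taxonomy: CellTaxonomy = DEFAULT_TAXONOMY,
) -> DCCAgreement:
    """Agreement between automated and manual 16-component proportions.

    ``auto`` may be a :class:`DCCResult` or a bare proportion vector ordered
    like ``taxonomy.countable_names``. Pearson ``r`` is ``None`` (undefined)
    when either vector has zero variance.
    """
    a = auto.as_vector(taxonomy) if isinstance(auto, DCCResult) else np.asarray(auto, dtype=float)
    m = np.asarray(manual, dtype=float)
    if a.shape != m.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {m.shape}")
    if a.std() == 0 or m.std() == 0:
        r = None
    else:
        r = float(stats.pearsonr(a, m).statistic)
    return DCCAgreement(
        pearson_r=r,
        ccc=concordance_correlation(a, m),
        bland_altman=bland_altman(a, m),
        n_components=int(a.size),
    )
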