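"""Trait-group partitioning of OTUs.

Two orthogonal partitions are produced from a (rarefied) relative-abundance
matrix:

* abundant vs rare — an OTU is *abundant* if its relative abundance exceeds
  1% in at least one sample, *rare* if it stays below 1% everywhere;
* generalist / specialist / neither — ranked by the Levins niche-breadth
  index ``B_j = 1 / sum_i q_ij**2`` where ``q_ij`` is OTU j's abundance in
  sample i divided by its total abundance over all samples.  The top 10% of
  B are generalists, the bottom 10% specialists, and every OTU attaining the
  minimum B is a specialist regardless of how large that tie group is.

Percentile cuts use the nearest-rank convention and are inclusive at the
boundary, so tied boundary values fall into the named class.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def classify_abundance(relab: pd.DataFrame, threshold: float = 0.01) -> pd.Series:
    """Label each OTU ``abundant`` or ``rare``.

    ``abundant`` iff max per-sample relative abundance is strictly greater
    than ``threshold``; otherwise ``rare``.  The two classes are exhaustive.
    """
    if relab.size == 0:
        raise ValueError("empty table")
    peak = relab.max(axis=0)
    labels = np.where(peak > threshold, "abundant", "rare")
    return pd.Series(labels, index=relab.columns, name="abundance_class")


def levins_niche_breadth(relab: pd.DataFrame) -> pd.Series:
    """Levins niche-breadth B per OTU; NaN for all-zero OTUs.

    B is the inverse Simpson concentration of the OTU's abundance profile
    across samples: 1 for single-sample OTUs, n_samples for a perfectly even
    spread.
    """
    totals = relab.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = relab.div(totals, axis=1)
        b = 1.0 / (q ** 2).sum(axis=0)
    b[totals == 0] = np.nan
    n_undefined = int(b.isna().sum())
    if n_undefined:
        logger.warning("niche breadth undefined for %d all-zero OTUs",
                       n_undefined)
    return b.rename("B")


def _bottom_cut(sorted_values: np.ndarray, fraction: float) -> float:
    """Threshold of the ceil(fraction*n) smallest values (nearest rank)."""
    n = len(sorted_values)
    k = max(1, math.ceil(fraction * n))
    return sorted_values[min(k, n) - 1]


def _top_cut(sorted_values: np.ndarray, fraction: float) -> float:
    """Threshold of the ceil(fraction*n) largest values (nearest rank)."""
    n = len(sorted_values)
    k = max(1, math.ceil(fraction * n))
    return sorted_values[max(n - k, 0)]


def classify_niche(b: pd.Series, fraction: float = 0.10) -> pd.Series:
    """Label OTUs ``generalist`` / ``specialist`` / ``neither`` from B.

    Specialists: B at or below the nearest-rank ``fraction`` percentile, plus
    every OTU tied at min(B) whatever their proportion.  Generalists: B at or
    above the (1 - fraction) percentile and not specialist.  OTUs with
    undefined B (all-zero) are labeled ``neither``.
    """
    defined = b.dropna()
    if len(defined) == 0:
        raise ValueError("no OTUs with defined niche breadth")
    if len(defined) < 10:
        logger.warning("classify_niche on only %d OTUs", len(defined))
    values = np.sort(defined.to_numpy())
    lo_cut = _bottom_cut(values, fraction)
    hi_cut = _top_cut(values, fraction)
    b_min = values[0]
    labels = pd.Series("neither", index=b.index, name="niche_class")
    specialist = (b <= lo_cut) | (b == b_min)
    generalist = (b >= hi_cut) & ~specialist
    labels[specialist.fillna(False)] = "specialist"
    labels[generalist.fillna(False)] = "generalist"
    return labels


def partition_traits(relab: pd.DataFrame, abundance_threshold: float = 0.01,
                     niche_fraction: float = 0.10) -> pd.DataFrame:
    """Full trait partition: one row per OTU with B and both class labels."""
    b = levins_niche_breadth(relab)
    return pd.DataFrame({
        "B": b,
        "abundance_class": classify_abundance(relab, abundance_threshold),
        "niche_class": classify_niche(b, niche_fraction),
    })


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """Share of ``count`` in ``total`` as a percentage rounded to ndigits."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)
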