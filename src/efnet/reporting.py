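"""Summary tables, top-network coverage and spider-plot data export.

Display rounding follows the conventions of the reported results: one
decimal for percentages, nearest integer for coverage sums; files always
keep full precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .connectivity import EngagementProfile
from .networks import NETWORKS, N_NETWORKS, network_index
from .variants import VariantResult, most_engaged_counts

log = logging.getLogger(__name__)


def summarize_variant(res: VariantResult, population_sd: bool = False) -> pd.DataFrame:
    """Per-network mean +/- sd engagement and most-engaged counts.

    One row per network (eight rows), over included subjects only.
    Sample sd (ddof=1) by default; the choice is recorded in the
    ``sd_kind`` column. A single-subject result reports sd 0 with a
    warning.
    """
    if not res.subjects:
        raise ValueError("variant result has no included subjects")
    m = res.engagement_matrix().to_numpy()
    means = m.mean(axis=0)
    if m.shape[0] == 1:
        log.warning("single subject: sd reported as 0")
        sds = np.zeros(N_NETWORKS)
    else:
        sds = m.std(axis=0, ddof=0 if population_sd else 1)
    counts = most_engaged_counts(res)
    return pd.DataFrame(
        {
            "target": res.target,
            "variant": res.variant.value,
            "network": list(NETWORKS),
            "mean_percent": means,
            "sd_percent": sds,
            "sd_kind": "population" if population_sd else "sample",
            "most_engaged_count": [counts[n] for n in NETWORKS],
        }
    )


def topk_coverage(rows: pd.DataFrame, networks: Sequence[str]) -> int:
    """Sum of mean engagement over a chosen network subset, display-rounded.

    ``rows`` is a summary table (as from :func:`summarize_variant`, or any
    frame with ``network`` and ``mean_percent`` columns). The sum is
    rounded to the nearest integer for display; retain the frame for full
    precision.
    """
    if len(networks) == 0:
        raise ValueError("network subset must be nonempty")
    for n in networks:
        network_index(n)
    indexed = rows.set_index("network")["mean_percent"]
    missing = [n for n in networks if n not in indexed.index]
    if missing:
        raise ValueError(f"networks missing from summary: {missing}")
    return int(round(float(indexed.loc[list(networks)].sum())))


@dataclass(frozen=True)
class SpiderData:
    """Spider/radar-plot data: radii in fixed network order + polygon area."""

    networks: tuple[str, ...]
    percent: np.ndarray
    area_fraction: float


def polygon_area_fraction(percent) -> float:
    """Spider polygon area for raw radii percent_i, unit-octagon normalized.

    Radii r_i = percent_i / 100 on the regular 8-direction fan; the
    polygon area (sum of triangle areas between adjacent spokes,
    (1/2) sin(2 pi / 8) sum_i r_i r_{i+1}) is divided by the area of the
    unit regular octagon, giving (sum_i r_i r_{i+1}) / 8 with cyclic
    indices.
    """
    r = np.asarray(percent, dtype=float).ravel() / 100.0
    if r.shape[0] != N_NETWORKS:
        raise ValueError(f"expected {N_NETWORKS} radii")
    return float((r * np.roll(r, -1)).sum() / N_NETWORKS)


def spider_polygon_area(profile: EngagementProfile) -> float:
    """Normalized spider-polygon area of an engagement profile."""
    return polygon_area_fraction(profile.percent)


def spider_data(profile: EngagementProfile) -> SpiderData:
    return SpiderData(
        networks=NETWORKS,
        percent=profile.percent.copy(),
        area_fraction=spider_polygon_area(profile),
    )


def plot_spider(profile: EngagementProfile, ax=None, **kwargs):
    """Convenience matplotlib radar plot of an engagement profile."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    theta = np.linspace(0, 2 * np.pi, N_NETWORKS, endpoint=False)
    r = np.append(profile.percent, profile.percent[0])
    ax.plot(np.append(theta, theta[0]), r, **kwargs)
    ax.fill(np.append(theta, theta[0]), r, alpha=0.25)
    ax.set_xticks(theta)
    ax.set_xticklabels(NETWORKS)
    return ax


def format_percent(x: float) -> str:
    """One-decimal display formatting for percentages."""
    return f"{x:.1f}"
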