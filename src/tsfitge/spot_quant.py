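"""Intra-gel ratio analysis.

For one gel, every quantified spot yields a Cy5/Cy3 ratio: spots with equal
vehicle and drug signal render yellow in an overlay (log2 ratio 0), thermal
stabilization renders red (Cy5 excess, positive log2 ratio), destabilization
green.  Ratios are stored in log2, summarized as a box plot with whiskers at
the 1st/99th percentiles, and ranked to propose drug-target candidates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .gel_image import GelImage, Spot

log = logging.getLogger(__name__)


@dataclass
class RatioEntry:
    spot_id: str
    gel_id: str
    log2_ratio: float
    percentile_rank: float = float("nan")
    outlier_flag: str = "none"  # {high, low, none}
    temperature: float = float("nan")
    x: float = float("nan")
    y: float = float("nan")


@dataclass
class BoxPlotSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float   # 1st percentile
    whisker_high: float  # 99th percentile
    n_spots: int

    def __post_init__(self):
        ordered = (self.whisker_low, self.q1, self.median, self.q3, self.whisker_high)
        if any(a > b + 1e-12 for a, b in zip(ordered, ordered[1:])):
            raise ValueError("box-plot summary violates whisker ordering")


def ratio_table(
    spots: list[Spot],
    intensity_floor: float,
    gel_id: str = "",
    temperature: float = float("nan"),
) -> list[RatioEntry]:
    """One entry per spot whose Cy3 AND Cy5 intensities exceed the floor.

    Below-floor spots are excluded (and counted in the log) rather than
    clamped, to avoid fabricating extreme ratios from background.
    """
    if intensity_floor <= 0:
        raise ValueError("intensity_floor must be > 0")
    entries = []
    n_excluded = 0
    for s in spots:
        if s.intensity_cy3 <= intensity_floor or s.intensity_cy5 <= intensity_floor:
            n_excluded += 1
            continue
        entries.append(
            RatioEntry(
                spot_id=s.spot_id,
                gel_id=gel_id or "",
                log2_ratio=math.log2(s.intensity_cy5 / s.intensity_cy3),
                temperature=temperature,
                x=s.x,
                y=s.y,
            )
        )
    if n_excluded:
        log.info("ratio_table: %d spot(s) below intensity floor excluded", n_excluded)
    if entries:
        vals = np.array([e.log2_ratio for e in entries])
        from scipy.stats import rankdata

        pct = 100.0 * (rankdata(vals) - 0.5) / len(vals)
        for e, p in zip(entries, pct):
            e.percentile_rank = float(p)
    return entries


def summarize_ratios(entries: list[RatioEntry]) -> BoxPlotSummary:
    """Box-plot summary with 1-99 percentile whiskers (linear-interpolation
    percentiles); sets ``outlier_flag`` on entries beyond the whiskers."""
    if len(entries) < 2:
        raise ValueError("insufficient data: need at least 2 ratio entries")
    vals = np.array([e.log2_ratio for e in entries])
    w_lo, q1, med, q3, w_hi = np.percentile(vals, [1, 25, 50, 75, 99])
    for e in entries:
        if e.log2_ratio > w_hi:
            e.outlier_flag = "high"
        elif e.log2_ratio < w_lo:
            e.outlier_flag = "low"
        else:
            e.outlier_flag = "none"
    return BoxPlotSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_low=float(w_lo), whisker_high=float(w_hi), n_spots=len(entries),
    )


def rank_candidates(entries: list[RatioEntry], direction: str = "both") -> list[RatioEntry]:
    """Candidates ordered by ratio extremity in the requested direction.

    ``stabilized``: descending log2 ratio (red first); ``destabilized``:
    ascending (green first); ``both``: by |log2 ratio| descending.  The full
    ordered list is returned — any outlier cut is advisory and carried by
    ``outlier_flag``.
    """
    if direction == "stabilized":
        key = lambda e: (-e.log2_ratio, e.spot_id)
    elif direction == "destabilized":
        key = lambda e: (e.log2_ratio, e.spot_id)
    elif direction == "both":
        key = lambda e: (-abs(e.log2_ratio), e.spot_id)
    else:
        raise ValueError("direction must be stabilized/destabilized/both")
    return sorted(entries, key=key)


def compose_overlay(
    gel: GelImage,
    stretch_percentiles: tuple[float, float] = (1.0, 99.5),
    include_cy2: bool = False,
) -> np.ndarray:
    """False-color overlay: Cy3 -> green, Cy5 -> red, optional Cy2 -> blue.

    Channels are contrast-stretched between the given percentiles of their
    nonzero support; equal Cy3/Cy5 renders yellow, and with Cy2 included an
    unshifted baseline spot renders white.  Returns float RGB in [0, 1].
    """
    lo_p, hi_p = stretch_percentiles

    def stretch(chan):
        lo, hi = np.percentile(chan, [lo_p, hi_p])
        if hi <= lo:
            return np.zeros_like(chan)
        return np.clip((chan - lo) / (hi - lo), 0.0, 1.0)

    # use one common scale for Cy3/Cy5 (and Cy2 if shown) so equal signals
    # map to equal brightness -> yellow/white
    pool = [gel.cy3, gel.cy5] + ([gel.cy2] if include_cy2 else [])
    allv = np.concatenate([c.ravel() for c in pool])
    lo, hi = np.percentile(allv, [lo_p, hi_p])
    span = hi - lo if hi > lo else 1.0

    def scale(chan):
        return np.clip((chan - lo) / span, 0.0, 1.0)

    rgb = np.zeros(gel.shape + (3,))
    rgb[..., 0] = scale(gel.cy5)
    rgb[..., 1] = scale(gel.cy3)
    if include_cy2:
        rgb[..., 2] = scale(gel.cy2)
    return rgb
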