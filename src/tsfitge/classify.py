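"""Final spot calling.

Distinguishes genuine thermal stabilization/destabilization from two
confounders visible already in the unheated baseline gel:

* **PTM pairs** — a drug-induced post-translational modification shifts a
  substrate's isoelectric point, producing a red and a green spot
  *horizontally* adjacent at baseline.  These are downstream-signaling
  readouts, not thermally shifted targets.
* **Registration artifacts** — a small vertical offset between the Cy3 and
  Cy5 rasters splits one yellow spot into a red/green pair stacked
  *vertically*, with essentially identical size and intensity.

Precedence for calling: artifact > ptm_pair > thermal > unchanged, and a
track that is already colored in the unheated gel is never called thermal.
Isothermal dose-response confirmation uses a four-parameter logistic fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .gel_image import Spot
from .melting import four_pl
from .spot_quant import RatioEntry
from .thermal_profile import ShiftResult, SpotTrack

# Default color threshold tau on |log2(Cy5/Cy3)|: under the default 3%-CV
# measurement model the baseline log2 ratio of an inert spot has
# sd ~= sqrt(2)*cv/ln 2 ~= 0.061, whose 99th percentile of |.| is ~0.16;
# 0.25 adds headroom for quantification error on real footprints.
DEFAULT_COLOR_TAU = 0.25


def color_threshold(proportional_cv: float) -> float:
    """99th percentile of |log2 ratio| for an inert spot at the given CV."""
    sd = math.sqrt(2.0) * proportional_cv / math.log(2.0)
    return 2.576 * sd


@dataclass
class CallThresholds:
    """Rule parameters for spot calling, with documented defaults."""

    color_tau: float = DEFAULT_COLOR_TAU
    z_score_min: float = 3.0
    # absolute floor on the longitudinal y-deviation for a thermal call:
    # >5 sigma of the per-point noise of the default forward model and well
    # below the >=0.45 deviation of shifts of interest (|dTm| >= ~3 C)
    y_dev_min: float = 0.30
    ptm_dy_tol: float = 2.0
    ptm_dx_min: float = 2.0
    ptm_dx_max: float | None = None  # default 8 * sigma_x of the spots
    artifact_dx_tol: float = 1.0
    artifact_dy_max: float = 4.0
    artifact_intensity_tol: float = 0.3


@dataclass
class SpotCall:
    track_id: str
    label: str  # {stabilized, destabilized, ptm_pair, registration_artifact, unchanged, ambiguous}
    partner_id: str | None = None
    evidence: dict = field(default_factory=dict)


@dataclass
class DoseResponseFit:
    ec50: float = float("nan")
    hill: float = float("nan")
    top: float = float("nan")
    bottom: float = float("nan")
    r_squared: float = float("nan")
    converged: bool = False
    ec50_within_range: bool = False  # interpolated vs extrapolated


# ---------------------------------------------------------------------------
# Baseline pair rules


def _pseudo_ratios(spots: list[Spot], floor: float) -> dict[str, float]:
    """log2((I5 + floor)/(I3 + floor)) for every baseline spot.

    The floor regularizes channels at background level so that single-
    channel spots (e.g. PTM satellites with no Cy3) still yield a strong,
    finite color score.
    """
    return {
        s.spot_id: math.log2((s.intensity_cy5 + floor) / (s.intensity_cy3 + floor))
        for s in spots
    }


def detect_ptm_pairs(
    baseline_entries: list[RatioEntry],
    spots: list[Spot],
    dy_tol: float = 2.0,
    dx_range: tuple[float, float] | None = None,
    color_tau: float = DEFAULT_COLOR_TAU,
    intensity_floor: float = 1.0,
) -> list[tuple[str, str]]:
    """Horizontally adjacent red/green pairs in the unheated gel.

    Returns (red_id, green_id) pairs with opposite color signs beyond
    ``color_tau``, |dy| <= dy_tol and dx within ``dx_range`` (default
    (2 px, 8 * median sigma_x)); each spot joins at most one pair, greedily
    by combined color strength.
    """
    if dx_range is None:
        sx = float(np.median([s.sigma_x for s in spots])) if spots else 1.3
        dx_range = (2.0, 8.0 * sx)
    ratios = _pseudo_ratios(spots, intensity_floor)
    by_id = {s.spot_id: s for s in spots}
    reds = [i for i, r in ratios.items() if r > color_tau]
    greens = [i for i, r in ratios.items() if r < -color_tau]
    cands = []
    for ri in reds:
        for gi in greens:
            a, b = by_id[ri], by_id[gi]
            dx, dy = abs(a.x - b.x), abs(a.y - b.y)
            if dy <= dy_tol and dx_range[0] <= dx <= dx_range[1]:
                cands.append((abs(ratios[ri]) + abs(ratios[gi]), ri, gi))
    cands.sort(key=lambda c: (-c[0], c[1], c[2]))
    used: set[str] = set()
    pairs = []
    for _, ri, gi in cands:
        if ri in used or gi in used:
            continue
        used.update((ri, gi))
        pairs.append((ri, gi))
    return pairs


def detect_registration_artifacts(
    entries: list[RatioEntry],
    spots: list[Spot],
    dy_range: tuple[float, float] = (0.5, 4.0),
    intensity_tol: float = 0.3,
    color_tau: float = DEFAULT_COLOR_TAU,
    intensity_floor: float = 1.0,
) -> list[tuple[str, str]]:
    """Vertically offset red/green pairs with matching size and intensity.

    Pairs must satisfy |dx| <= 1 px, dy within ``dy_range``, and agree in
    total intensity and Gaussian widths within ``intensity_tol`` (relative)
    — a genuinely shifted target fails the equal-intensity test and is not
    flagged.
    """
    ratios = _pseudo_ratios(spots, intensity_floor)
    by_id = {s.spot_id: s for s in spots}
    reds = [i for i, r in ratios.items() if r > color_tau]
    greens = [i for i, r in ratios.items() if r < -color_tau]
    cands = []
    for ri in reds:
        for gi in greens:
            a, b = by_id[ri], by_id[gi]
            dx, dy = abs(a.x - b.x), abs(a.y - b.y)
            if dx > 1.0 or not (dy_range[0] <= dy <= dy_range[1]):
                continue
            ta = a.total_intensity
            tb = b.total_intensity
            if ta <= 0 or tb <= 0:
                continue
            if abs(ta - tb) / max(ta, tb) > intensity_tol:
                continue
            if abs(a.sigma_x - b.sigma_x) / max(a.sigma_x, b.sigma_x) > intensity_tol:
                continue
            if abs(a.sigma_y - b.sigma_y) / max(a.sigma_y, b.sigma_y) > intensity_tol:
                continue
            cands.append((abs(ratios[ri]) + abs(ratios[gi]), ri, gi))
    cands.sort(key=lambda c: (-c[0], c[1], c[2]))
    used: set[str] = set()
    pairs = []
    for _, ri, gi in cands:
        if ri in used or gi in used:
            continue
        used.update((ri, gi))
        pairs.append((ri, gi))
    return pairs


# ---------------------------------------------------------------------------
# Calling


def call_spots(
    shifts: list[ShiftResult],
    tracks: list[SpotTrack],
    baseline_entries: list[RatioEntry],
    ptm_pairs: list[tuple[str, str]],
    artifact_pairs: list[tuple[str, str]],
    thresholds: CallThresholds | None = None,
) -> list[SpotCall]:
    """Assign exactly one label per track, by fixed precedence.

    artifact > ptm_pair > thermal (z >= z_min AND y_dev_max >= y_dev_min;
    stabilized when the drug curve lies above the vehicle curve at maximum
    deviation, destabilized when below) > unchanged.  A track colored at
    baseline (|log2 ratio| > tau) that is not part of a pair is labeled
    ambiguous and is never called thermal.  Deterministic and independent
    of input ordering.
    """
    th = thresholds or CallThresholds()
    baseline_ratio = {e.spot_id: e.log2_ratio for e in baseline_entries}
    partner_of: dict[str, tuple[str, str]] = {}
    for a, b in artifact_pairs:
        partner_of[a] = (b, "registration_artifact")
        partner_of[b] = (a, "registration_artifact")
    for a, b in ptm_pairs:
        partner_of.setdefault(a, (b, "ptm_pair"))
        partner_of.setdefault(b, (a, "ptm_pair"))
    shift_by_track = {s.track_id: s for s in shifts}

    calls = []
    for tr in sorted(tracks, key=lambda t: t.track_id):
        sid = tr.reference_spot.spot_id
        sh = shift_by_track.get(tr.track_id)
        ev: dict = {}
        if sh is not None:
            ev = {
                "z_score": sh.z_score,
                "y_dev_max": sh.y_dev_max,
                "delta_tm": sh.delta_tm,
            }
        ev["baseline_log2_ratio"] = baseline_ratio.get(sid, float("nan"))
        if sid in partner_of:
            pid, label = partner_of[sid]
            calls.append(SpotCall(tr.track_id, label, partner_id=pid, evidence=ev))
            continue
        colored = (
            sid in baseline_ratio and abs(baseline_ratio[sid]) > th.color_tau
        ) or (sid not in baseline_ratio and _spot_colored(tr.reference_spot, th.color_tau))
        if colored:
            # colored in the unheated gel -> never a thermal call
            calls.append(SpotCall(tr.track_id, "ambiguous", evidence=ev))
            continue
        if (
            sh is not None
            and np.isfinite(sh.z_score)
            and sh.z_score >= th.z_score_min
            and sh.y_dev_max >= th.y_dev_min
        ):
            label = "stabilized" if sh.direction == "up" else "destabilized"
            calls.append(SpotCall(tr.track_id, label, evidence=ev))
            continue
        calls.append(SpotCall(tr.track_id, "unchanged", evidence=ev))
    return calls


def _spot_colored(spot: Spot, tau: float, floor: float = 1.0) -> bool:
    r = math.log2((spot.intensity_cy5 + floor) / (spot.intensity_cy3 + floor))
    return abs(r) > tau


# ---------------------------------------------------------------------------
# Dose-response fitting


def fit_dose_response(doses, responses, direction: str = "up") -> DoseResponseFit:
    """Least-squares four-parameter-logistic fit of an isothermal
    dose-response series.

    Requires >= 5 distinct doses.  EC50 is initialized at the median
    log-dose; the fit is flagged interpolated when EC50 falls inside the
    dosed range.  Flat responses yield converged=False.
    """
    c = np.asarray(doses, float)
    r = np.asarray(responses, float)
    if np.any(c <= 0):
        raise ValueError("doses must be strictly positive")
    if len(np.unique(c)) < 5:
        raise ValueError("need at least 5 distinct doses")
    if float(r.max() - r.min()) < 1e-12 or float(np.std(r)) == 0.0:
        return DoseResponseFit()
    span = float(r.max() - r.min())
    if span < 3.0 * _replicate_noise(c, r):
        return DoseResponseFit()

    logc = np.log(c)
    ec0 = float(np.exp(np.median(logc)))
    if direction == "up":
        top0, bot0 = float(r.max()), float(r.min())
    else:
        top0, bot0 = float(r.min()), float(r.max())

    def resid(p):
        ec50, hill, top, bottom = p
        return four_pl(c, ec50, hill, top, bottom) - r

    lb = [float(c.min()) / 1e3, 0.1, -np.inf, -np.inf]
    ub = [float(c.max()) * 1e3, 10.0, np.inf, np.inf]
    try:
        res = optimize.least_squares(
            resid, [ec0, 1.0, top0, bot0], bounds=(lb, ub), max_nfev=1000
        )
    except Exception:  # pragma: no cover
        return DoseResponseFit()
    ec50, hill, top, bottom = (float(v) for v in res.x)
    ss_res = float(np.sum(res.fun**2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    if not np.isfinite(ec50) or ec50 <= 0 or (np.isfinite(r2) and r2 < 0.2):
        return DoseResponseFit()
    return DoseResponseFit(
        ec50=ec50, hill=hill, top=top, bottom=bottom, r_squared=r2, converged=True,
        ec50_within_range=bool(c.min() <= ec50 <= c.max()),
    )


def _replicate_noise(c: np.ndarray, r: np.ndarray) -> float:
    """Pooled within-dose sd; 0 when there are no replicates."""
    sds = []
    for dose in np.unique(c):
        vals = r[c == dose]
        if len(vals) > 1:
            sds.append(np.std(vals, ddof=1))
    return float(np.mean(sds)) if sds else 0.0
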