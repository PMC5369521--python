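"""End-to-end pipeline: configuration, execution, and reporting.

``run_pipeline`` drives read → background → detect → quantify → ratios →
match → normalize → fit → score → call, writing every intermediate table,
and is a pure function of (config, inputs).  ``render_report`` turns a
finished run directory into a human-readable bundle (overlays, box plots,
melting curves, calls table, summary JSON).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import classify, gel_image, spot_quant, thermal_profile
from .classify import CallThresholds
from .gel_image import GelImage, Spot

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"  # fixed text formatting -> byte-identical reruns


@dataclass
class DetectionConfig:
    min_snr: float = 5.0
    min_separation: int = 1
    ball_radius: float = 8.0
    smooth_sigma: float = 0.7
    sigma_guess: tuple[float, float] = (1.3, 0.9)


@dataclass
class MatchingConfig:
    max_distance: float = 3.0
    registration_max_distance: float = 6.0


@dataclass
class RunConfig:
    """All pipeline parameters, each with a documented default; round-trips
    losslessly through YAML."""

    manifest: str | None = None
    outdir: str = "tsfitge_run"
    seed: int = 0
    intensity_floor: float | None = None  # None -> 3x background MAD per gel
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    matching: MatchingConfig = field(default_factory=MatchingConfig)
    thresholds: CallThresholds = field(default_factory=CallThresholds)

    def to_yaml(self, path) -> None:
        pathlib.Path(path).write_text(yaml.safe_dump(_plain(asdict(self)), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        det = DetectionConfig(**{**raw.pop("detection", {})})
        if isinstance(det.sigma_guess, list):
            det.sigma_guess = tuple(det.sigma_guess)
        mat = MatchingConfig(**raw.pop("matching", {}))
        th = CallThresholds(**raw.pop("thresholds", {}))
        return cls(detection=det, matching=mat, thresholds=th, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(_plain(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def default_intensity_floor(gel: GelImage, sigma_guess=(1.3, 0.9)) -> float:
    """3x the background MAD, on the integrated-intensity scale.

    Per-pixel robust noise is propagated to a ~3-sigma elliptical footprint
    (sum of N independent pixels scales as sqrt(N)).
    """
    mads = [gel_image.background_mad(c) for c in gel.channels().values()]
    foot_px = math.pi * (3 * sigma_guess[0]) * (3 * sigma_guess[1])
    return 3.0 * max(max(mads), 1e-9) * math.sqrt(foot_px)


# ---------------------------------------------------------------------------


def load_manifest(path) -> pd.DataFrame:
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    mf = pd.read_csv(path, sep="\t")
    for col in ("filename", "temperature_C"):
        if col not in mf.columns:
            raise ValueError(f"manifest {path} lacks required column {col!r}")
    base = path.parent
    for fname in mf["filename"]:
        if not (base / fname).exists():
            raise FileNotFoundError(f"manifest references missing file: {base / fname}")
    return mf


def analyze_gels(
    gels: dict[float, GelImage], config: RunConfig
) -> dict:
    """Run the in-memory analysis on already-loaded gels.

    Returns a dict with spot tables, ratio entries/summaries, tracks,
    shifts, pairs and calls — the pipeline core shared by the file-based
    and the simulation-driven entry points.
    """
    det = config.detection
    spot_tables: dict[float, list[Spot]] = {}
    corrected: dict[float, GelImage] = {}
    floors: dict[float, float] = {}
    for t, gel in sorted(gels.items()):
        bg = {
            name: gel_image.subtract_background(chan, det.ball_radius)
            for name, chan in gel.channels().items()
        }
        cgel = GelImage(
            cy2=bg["cy2"], cy3=bg["cy3"], cy5=bg["cy5"],
            temperature=gel.temperature, gel_id=gel.gel_id,
        )
        corrected[t] = cgel
        spots = gel_image.detect_spots(
            cgel,
            min_snr=det.min_snr,
            min_separation=det.min_separation,
            sigma_guess=tuple(det.sigma_guess),
            smooth_sigma=det.smooth_sigma,
        )
        spot_tables[t] = spots
        floors[t] = (
            config.intensity_floor
            if config.intensity_floor is not None
            else default_intensity_floor(gel, det.sigma_guess)
        )
    return analyze_spot_tables(spot_tables, config, floors=floors, corrected=corrected)


def analyze_spot_tables(
    spot_tables: dict[float, list[Spot]],
    config: RunConfig | None = None,
    floors: dict[float, float] | None = None,
    corrected: dict[float, GelImage] | None = None,
) -> dict:
    """Pipeline core for pre-quantified spot tables (the TSV input route)."""
    config = config or RunConfig()
    temps = sorted(spot_tables)
    t0 = temps[0]
    if floors is None:
        floors = {t: 1.0 for t in temps}

    entries_by_temp = {}
    summaries = {}
    for t in temps:
        gel_id = f"T{t:g}"
        entries = spot_quant.ratio_table(
            spot_tables[t], intensity_floor=floors[t], gel_id=gel_id, temperature=t
        )
        entries_by_temp[t] = entries
        if len(entries) >= 2:
            summaries[t] = spot_quant.summarize_ratios(entries)

    tracks = thermal_profile.match_spots(
        spot_tables,
        max_distance=config.matching.max_distance,
        registration_max_distance=config.matching.registration_max_distance,
    )
    for tr in tracks:
        thermal_profile.normalize_track(tr)
    shifts = thermal_profile.score_run(tracks)

    baseline_entries = entries_by_temp[t0]
    baseline_spots = spot_tables[t0]
    th = config.thresholds
    dx_max = th.ptm_dx_max
    ptm_pairs = classify.detect_ptm_pairs(
        baseline_entries,
        baseline_spots,
        dy_tol=th.ptm_dy_tol,
        dx_range=None if dx_max is None else (th.ptm_dx_min, dx_max),
        color_tau=th.color_tau,
        intensity_floor=floors[t0],
    )
    artifact_pairs = classify.detect_registration_artifacts(
        baseline_entries,
        baseline_spots,
        dy_range=(0.5, th.artifact_dy_max),
        intensity_tol=th.artifact_intensity_tol,
        color_tau=th.color_tau,
        intensity_floor=floors[t0],
    )
    calls = classify.call_spots(
        shifts, tracks, baseline_entries, ptm_pairs, artifact_pairs, thresholds=th
    )
    return {
        "temperatures": temps,
        "spot_tables": spot_tables,
        "corrected": corrected,
        "floors": floors,
        "entries_by_temp": entries_by_temp,
        "summaries": summaries,
        "tracks": tracks,
        "shifts": shifts,
        "ptm_pairs": ptm_pairs,
        "artifact_pairs": artifact_pairs,
        "calls": calls,
    }


# ---------------------------------------------------------------------------
# Table serialization


def _write_tables(result: dict, outdir: pathlib.Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    for t, spots in sorted(result["spot_tables"].items()):
        frames.append(gel_image.spots_to_frame(spots, gel_id=f"T{t:g}"))
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "spots.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )

    rows = []
    for t, entries in sorted(result["entries_by_temp"].items()):
        for e in entries:
            rows.append(dataclasses.asdict(e))
    pd.DataFrame(rows).to_csv(
        outdir / "ratios.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )

    summaries = {
        f"T{t:g}": dataclasses.asdict(s) for t, s in sorted(result["summaries"].items())
    }
    (outdir / "boxplot_summaries.json").write_text(json.dumps(summaries, indent=1))

    rows = []
    for tr in result["tracks"]:
        for t in sorted(set(tr.rel_vehicle) | set(tr.rel_drug)):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "temperature": t,
                    "rel_vehicle": tr.rel_vehicle.get(t, float("nan")),
                    "rel_drug": tr.rel_drug.get(t, float("nan")),
                }
            )
    pd.DataFrame(rows).to_csv(
        outdir / "curves.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )

    rows = []
    for sh in result["shifts"]:
        rows.append(
            {
                "track_id": sh.track_id,
                "tm_vehicle": sh.fit_vehicle.tm,
                "tm_drug": sh.fit_drug.tm,
                "delta_tm": sh.delta_tm,
                "y_dev_max": sh.y_dev_max,
                "y_dev_area": sh.y_dev_area,
                "z_score": sh.z_score,
                "direction": sh.direction,
            }
        )
    pd.DataFrame(rows).to_csv(
        outdir / "shifts.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )

    rows = []
    for c in result["calls"]:
        rows.append(
            {
                "track_id": c.track_id,
                "label": c.label,
                "partner_id": c.partner_id or "",
                "z_score": c.evidence.get("z_score", float("nan")),
                "delta_tm": c.evidence.get("delta_tm", float("nan")),
                "evidence": json.dumps(
                    {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
                     for k, v in c.evidence.items()},
                    sort_keys=True,
                ),
            }
        )
    pd.DataFrame(rows).to_csv(
        outdir / "calls.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )


def run_pipeline(config: RunConfig) -> dict:
    """File-based end-to-end run: manifest in, tables + summary out."""
    if config.manifest is None:
        raise ValueError("config.manifest is required")
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("run config hash: %s", config.config_hash())
    mf = load_manifest(config.manifest)
    base = pathlib.Path(config.manifest).parent
    gels: dict[float, GelImage] = {}
    for row in mf.to_dict("records"):
        gel = gel_image.read_gel(base / row["filename"], row)
        gels[gel.temperature] = gel
    result = analyze_gels(gels, config)
    _write_tables(result, outdir)

    label_counts: dict[str, int] = {}
    for c in result["calls"]:
        label_counts[c.label] = label_counts.get(c.label, 0) + 1
    candidates = [
        c.track_id
        for c in sorted(
            result["calls"],
            key=lambda c: -(c.evidence.get("z_score") or float("-inf"))
            if c.label in ("stabilized", "destabilized") else float("inf"),
        )
        if c.label in ("stabilized", "destabilized")
    ]
    summary = {
        "config_hash": config.config_hash(),
        "n_gels": len(gels),
        "temperatures": sorted(gels),
        "n_tracks": len(result["tracks"]),
        "label_counts": label_counts,
        "candidates": candidates,
        "n_ptm_pairs": len(result["ptm_pairs"]),
        "n_artifact_pairs": len(result["artifact_pairs"]),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    result["summary"] = summary
    result["gels"] = gels
    return result


# ---------------------------------------------------------------------------
# Reporting


def render_report(run_dir, gels: dict[float, GelImage] | None = None, top_k: int = 5) -> pathlib.Path:
    """Produce a self-contained report bundle inside ``run_dir``/report.

    Overlay PNG per gel (when images are available), box plot per gel with
    flagged outliers marked, melting-curve images for the top-k candidate
    tracks (all tracks when fewer), the calls table, and a machine-readable
    summary including an explicit no-candidates note when applicable.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = pathlib.Path(run_dir)
    report = run_dir / "report"
    report.mkdir(parents=True, exist_ok=True)

    summary = json.loads((run_dir / "summary.json").read_text())
    ratios = pd.read_csv(run_dir / "ratios.tsv", sep="\t")
    curves = pd.read_csv(run_dir / "curves.tsv", sep="\t")
    shifts = pd.read_csv(run_dir / "shifts.tsv", sep="\t")
    calls = pd.read_csv(run_dir / "calls.tsv", sep="\t")

    if gels:
        for t, gel in sorted(gels.items()):
            rgb = spot_quant.compose_overlay(gel)
            plt.imsave(report / f"overlay_T{t:g}.png", rgb)

    for gel_id, grp in ratios.groupby("gel_id"):
        vals = grp["log2_ratio"].to_numpy()
        if len(vals) < 2:
            continue
        fig, ax = plt.subplots(figsize=(3, 4))
        ax.boxplot(vals, whis=(1, 99), showfliers=False)
        out = grp[grp["outlier_flag"] != "none"]
        if len(out):
            ax.plot(np.ones(len(out)), out["log2_ratio"], "r<", ms=8)
        ax.set_ylabel("log2(Cy5/Cy3)")
        ax.set_title(str(gel_id))
        fig.tight_layout()
        fig.savefig(report / f"boxplot_{gel_id}.png", dpi=100)
        plt.close(fig)

    cand = calls[calls["label"].isin(["stabilized", "destabilized"])]
    cand = cand.sort_values("z_score", ascending=False)
    chosen = list(cand["track_id"].head(top_k))
    if not chosen:  # plot the top tracks by z-score anyway
        chosen = list(
            shifts.sort_values("z_score", ascending=False)["track_id"].head(top_k)
        )
    for tid in chosen:
        sub = curves[curves["track_id"] == tid].sort_values("temperature")
        if sub.empty:
            continue
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(sub["temperature"], sub["rel_vehicle"], "o-", color="green", label="vehicle (Cy3)")
        ax.plot(sub["temperature"], sub["rel_drug"], "s-", color="red", label="drug (Cy5)")
        ax.set_xlabel("temperature (°C)")
        ax.set_ylabel("relative soluble fraction")
        ax.set_title(tid)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(report / f"melting_{tid}.png", dpi=100)
        plt.close(fig)

    calls.to_csv(report / "calls.tsv", sep="\t", index=False)
    report_summary = dict(summary)
    if not summary.get("candidates"):
        report_summary["no_candidates"] = (
            "no stabilized or destabilized candidate tracks at the configured thresholds"
        )
    (report / "summary.json").write_text(json.dumps(report_summary, indent=1, sort_keys=True))
    return report
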