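"""Reproducible end-to-end runs: config parsing, orchestration, manifests.

A run is described by a small YAML config (analysis kind, seed, output
directory, analysis parameters). Every stage's outputs are checksummed into a
JSON manifest; identical config + seed reproduces byte-identical outputs and
manifest. Timestamps live only in the plain-text run log, which the manifest
does not cover. All randomness derives from the single config seed through
named substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as fio
from .bindfit import fit_kd, fit_lifetime
from .coloc import pearson_coloc, vesicle_overlap, RegionMask
from .frapfit import fit_recovery, normalize_trace
from .motility import condition_summary, track_speed
from .simkit import (
    BindingTruth,
    DecayTruth,
    FrapTruth,
    TrackTruth,
    make_decay,
    make_frap_series,
    make_titration,
    make_tracks,
    make_vesicle_scene,
    random_scene_truth,
    write_truth,
)
from .spotdetect import DetectionParams, detect_vesicles

__all__ = ["RunConfig", "PipelineError", "load_config", "run_pipeline", "substream_seed"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def substream_seed(seed: int, name: str) -> int:
    """Deterministic per-stage seed derived from the run seed and stage name."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


_PARAM_KEYS = {
    "scene_coloc": {
        "n_vesicles", "shape", "coloc_fraction", "amplitude", "background_level",
        "noise_sigma", "vesicle_sigma", "min_separation",
        "n_scales", "threshold_k", "scales_used", "min_area", "split_touching",
    },
    "frap": {
        "rate_k", "mobile_fraction", "postbleach_floor", "fading_rate",
        "frame_interval", "n_prebleach", "noise_sigma", "n_post",
    },
    "tracks": {
        "mean_speed", "persistence", "frame_interval", "n_frames",
        "pixel_size", "speed_cv", "n_cells",
    },
    "titration": {
        "kd", "target_conc", "response_unbound", "response_bound", "noise_sigma",
        "ligand_top", "n_points", "dilution_factor",
    },
    "decay": {
        "lifetime_tau", "total_counts", "bin_width", "n_bins", "fit_start",
    },
}


@dataclass
class RunConfig:
    analysis: str
    seed: int
    out_dir: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.analysis not in _PARAM_KEYS:
            raise ValueError(
                f"unknown analysis {self.analysis!r}; choose from {sorted(_PARAM_KEYS)}"
            )
        unknown = set(self.params) - _PARAM_KEYS[self.analysis]
        if unknown:
            raise ValueError(
                f"unknown parameter key(s) for analysis {self.analysis!r}: {sorted(unknown)}"
            )
        self.seed = int(self.seed)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    allowed = {"analysis", "seed", "out_dir", "params"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    missing = {"analysis", "seed", "out_dir"} - set(raw)
    if missing:
        raise ValueError(f"missing config key(s): {sorted(missing)}")
    return RunConfig(
        analysis=raw["analysis"],
        seed=raw["seed"],
        out_dir=str(raw["out_dir"]),
        params=dict(raw.get("params") or {}),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.stages: list[dict] = []
        self.log_lines: list[str] = []

    def log(self, stage: str, message: str) -> None:
        self.log_lines.append(f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] [{stage}] {message}")

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.stages.append(
            {"name": stage, "outputs": {p.name: _sha256(p) for p in sorted(outputs)}}
        )

    def finish(self) -> dict:
        manifest = {
            "version": __version__,
            "analysis": self.config.analysis,
            "config": dataclasses.asdict(self.config),
            "stages": self.stages,
        }
        (self.out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        (self.out / "run.log").write_text("\n".join(self.log_lines) + "\n")
        return manifest


def _run_scene_coloc(run: _Run) -> None:
    p = run.config.params
    seed = substream_seed(run.config.seed, "scene")
    truth = random_scene_truth(
        n_vesicles=int(p.get("n_vesicles", 25)),
        shape=tuple(p.get("shape", (256, 256))),
        seed=seed,
        coloc_fraction=float(p.get("coloc_fraction", 0.5)),
        amplitude=float(p.get("amplitude", 200.0)),
        background_level=float(p.get("background_level", 100.0)),
        noise_sigma=float(p.get("noise_sigma", 20.0)),
        vesicle_sigma=float(p.get("vesicle_sigma", 1.5)),
        min_separation=float(p.get("min_separation", 12.0)),
    )
    img_a, img_b, truth = make_vesicle_scene(truth, tuple(p.get("shape", (256, 256))))
    fio.save_image(run.out / "channelA.tif", img_a)
    fio.save_image(run.out / "channelB.tif", img_b)
    write_truth(run.out / "scene_truth.json", truth)
    run.log("scene", f"{truth.n_vesicles} vesicles, coloc_fraction={truth.coloc_fraction}")
    run.record("scene", [run.out / "channelA.tif", run.out / "channelB.tif",
                         run.out / "scene_truth.json"])

    params = DetectionParams(
        n_scales=int(p.get("n_scales", 3)),
        threshold_k=float(p.get("threshold_k", 3.0)),
        scales_used=tuple(p.get("scales_used", (2, 3))),
        min_area=int(p.get("min_area", 4)),
        split_touching=bool(p.get("split_touching", True)),
    )
    # analyse the quantized on-disk images: what a user would actually measure
    chan_a = fio.read_image_stack(run.out / "channelA.tif")[0]
    chan_b = fio.read_image_stack(run.out / "channelB.tif")[0]
    ves_a = detect_vesicles(chan_a, params)
    ves_b = detect_vesicles(chan_b, params)
    ves_a.records.to_csv(run.out / "vesicles_a.csv", index=False)
    ves_b.records.to_csv(run.out / "vesicles_b.csv", index=False)
    fio.save_image(run.out / "labels_a.tif", ves_a.label_map.astype(float))
    fio.save_image(run.out / "labels_b.tif", ves_b.label_map.astype(float))
    run.log("vesicles", f"A: {ves_a.n_vesicles}, B: {ves_b.n_vesicles}")
    run.record("vesicles", [run.out / "vesicles_a.csv", run.out / "vesicles_b.csv",
                            run.out / "labels_a.tif", run.out / "labels_b.tif"])

    overlap = vesicle_overlap(ves_a, ves_b)
    whole = RegionMask(np.ones(chan_a.shape, dtype=bool), kind="whole_cell")
    pear = pearson_coloc(chan_a, chan_b, whole)
    results = {
        "n_vesicles_a": ves_a.n_vesicles,
        "n_vesicles_b": ves_b.n_vesicles,
        "overlap_fraction": overlap.overlap_fraction,
        "pearson_r": pear.pearson_r,
        "true_coloc_fraction": truth.coloc_fraction,
    }
    (run.out / "coloc_results.json").write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")
    run.log("coloc", f"overlap={overlap.overlap_fraction:.3f}, pearson={pear.pearson_r:.3f}")
    run.record("coloc", [run.out / "coloc_results.json"])


def _run_frap(run: _Run) -> None:
    p = run.config.params
    truth = FrapTruth(
        rate_k=float(p.get("rate_k", np.log(2) / 30.0)),
        mobile_fraction=float(p.get("mobile_fraction", 0.75)),
        postbleach_floor=float(p.get("postbleach_floor", 0.2)),
        fading_rate=float(p.get("fading_rate", 0.001)),
        frame_interval=float(p.get("frame_interval", 5.0)),
        n_prebleach=int(p.get("n_prebleach", 3)),
        noise_sigma=float(p.get("noise_sigma", 0.02)),
        seed=substream_seed(run.config.seed, "frap"),
    )
    trace = make_frap_series(truth, n_post=int(p.get("n_post", 36)))
    fio.write_frap_trace(run.out / "trace.csv", trace)
    write_truth(run.out / "frap_truth.json", truth)
    run.record("simulate", [run.out / "trace.csv", run.out / "frap_truth.json"])
    run.log("simulate", f"k={truth.rate_k:.4g}/s, fading={truth.fading_rate:.4g}/s")

    fit = fit_recovery(normalize_trace(trace))
    (run.out / "frap_fit.json").write_text(
        json.dumps(dataclasses.asdict(fit), indent=2, sort_keys=True) + "\n"
    )
    run.log("fit", f"t_half={fit.t_half:.3g}s, mobile={fit.mobile_fraction_pct:.3g}%")
    run.record("fit", [run.out / "frap_fit.json"])


def _run_tracks(run: _Run) -> None:
    p = run.config.params
    truth = TrackTruth(
        mean_speed=float(p.get("mean_speed", 0.5)),
        persistence=float(p.get("persistence", 0.5)),
        frame_interval=float(p.get("frame_interval", 10.0)),
        n_frames=int(p.get("n_frames", 97)),
        pixel_size=float(p.get("pixel_size", 1.0)),
        speed_cv=float(p.get("speed_cv", 0.5)),
        seed=substream_seed(run.config.seed, "tracks"),
    )
    tracks = make_tracks(truth, n_cells=int(p.get("n_cells", 50)))
    fio.write_tracks(run.out / "tracks.csv", tracks)
    write_truth(run.out / "track_truth.json", truth)
    run.record("simulate", [run.out / "tracks.csv", run.out / "track_truth.json"])

    speeds = [track_speed(t) for t in tracks]
    rows = [dataclasses.asdict(s) for s in speeds]
    import pandas as pd

    pd.DataFrame(rows).to_csv(run.out / "speeds.csv", index=False)
    summary = condition_summary(tracks, ["simulated"] * len(tracks))
    summary.to_csv(run.out / "speed_summary.csv", index=False)
    run.log("speeds", f"grand mean {summary['mean_speed'].iloc[0]:.4g} um/min")
    run.record("speeds", [run.out / "speeds.csv", run.out / "speed_summary.csv"])


def _run_titration(run: _Run) -> None:
    p = run.config.params
    truth = BindingTruth(
        kd=float(p.get("kd", 250e-9)),
        target_conc=float(p.get("target_conc", 50e-9)),
        response_unbound=float(p.get("response_unbound", 0.0)),
        response_bound=float(p.get("response_bound", 1.0)),
        noise_sigma=float(p.get("noise_sigma", 0.01)),
        seed=substream_seed(run.config.seed, "titration"),
    )
    n = int(p.get("n_points", 16))
    top = float(p.get("ligand_top", 100e-6))
    dil = float(p.get("dilution_factor", 2.0))
    ligand = top / dil ** np.arange(n)[::-1]
    series = make_titration(truth, ligand)
    fio.write_titration(run.out / "titration.csv", series)
    write_truth(run.out / "binding_truth.json", truth)
    run.record("simulate", [run.out / "titration.csv", run.out / "binding_truth.json"])

    fit = fit_kd(series)
    payload = dataclasses.asdict(fit)
    payload["fraction_bound"] = fit.fraction_bound.tolist()
    (run.out / "kd_fit.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    run.log("fit", f"Kd={fit.kd * 1e9:.4g} nM")
    run.record("fit", [run.out / "kd_fit.json"])


def _run_decay(run: _Run) -> None:
    p = run.config.params
    truth = DecayTruth(
        lifetime_tau=float(p.get("lifetime_tau", 2.5)),
        total_counts=int(p.get("total_counts", 100_000)),
        bin_width=float(p.get("bin_width", 0.05)),
        n_bins=int(p.get("n_bins", 256)),
        seed=substream_seed(run.config.seed, "decay"),
    )
    decay = make_decay(truth)
    fio.write_decay(run.out / "decay.csv", decay)
    write_truth(run.out / "decay_truth.json", truth)
    run.record("simulate", [run.out / "decay.csv", run.out / "decay_truth.json"])

    fit = fit_lifetime(decay, fit_start=float(p.get("fit_start", 0.0)))
    payload = dataclasses.asdict(fit)
    payload["deviance"] = float(np.sum(fit.deviance))
    (run.out / "lifetime_fit.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    run.log("fit", f"tau={fit.tau_ns:.4g} ns")
    run.record("fit", [run.out / "lifetime_fit.json"])


_RUNNERS = {
    "scene_coloc": _run_scene_coloc,
    "frap": _run_frap,
    "tracks": _run_tracks,
    "titration": _run_titration,
    "decay": _run_decay,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute one analysis end to end; returns the written manifest."""
    run = _Run(config)
    runner = _RUNNERS[config.analysis]
    try:
        runner(run)
    except PipelineError:
        raise
    except Exception as exc:
        stage = run.stages[-1]["name"] if run.stages else "setup"
        raise PipelineError(f"stage after '{stage}' failed: {exc}") from exc
    return run.finish()
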