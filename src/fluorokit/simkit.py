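"""Synthetic inputs with recorded ground truth for every analysis stage.

Each generator emulates one kind of raw measurement the pipeline consumes:
two-channel images of diffraction-limited vesicles with a controlled
colocalized fraction, FRAP recoveries with whole-image photofading,
persistent-random-walk migration tracks, saturation-binding titrations at a
fixed labeled-protein concentration, and mono-exponential photon decays.
Truth parameters travel with the output, seeds are mandatory arguments, and
noise-free outputs match the closed-form models exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .bindfit import DecayHistogram, TitrationSeries, fraction_bound
from .frapfit import FrapTrace
from .motility import Track
from .spotdetect import PixelImage

__all__ = [
    "SceneTruth",
    "FrapTruth",
    "TrackTruth",
    "BindingTruth",
    "DecayTruth",
    "make_vesicle_scene",
    "random_scene_truth",
    "make_frap_series",
    "make_tracks",
    "make_titration",
    "make_decay",
    "write_truth",
]


@dataclass
class SceneTruth:
    """Ground truth of a two-channel vesicle scene.

    coloc_fraction of the channel-A vesicles are duplicated at identical
    centers in channel B (optionally jittered); the rest appear only in A.
    SNR here means amplitude / noise_sigma. coloc_indices records which
    vesicles were duplicated (filled in by the generator).
    """

    vesicle_centers: tuple
    vesicle_amplitudes: tuple
    coloc_fraction: float
    background_level: float
    noise_sigma: float
    seed: int
    vesicle_sigma: float = 1.5
    noise_model: str = "gaussian"
    coloc_jitter: float = 0.0
    coloc_indices: tuple = ()

    def __post_init__(self) -> None:
        centers = tuple((float(r), float(c)) for r, c in self.vesicle_centers)
        amps = self.vesicle_amplitudes
        if np.isscalar(amps):
            amps = (float(amps),) * len(centers)
        else:
            amps = tuple(float(a) for a in amps)
        if len(amps) != len(centers):
            raise ValueError("one amplitude per vesicle required")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if self.vesicle_sigma <= 0:
            raise ValueError("vesicle_sigma must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")
        self.vesicle_centers = centers
        self.vesicle_amplitudes = amps

    @property
    def n_vesicles(self) -> int:
        return len(self.vesicle_centers)


@dataclass
class FrapTruth:
    """Ground truth of a FRAP recovery.

    Defaults follow standard acquisition: 5 s per frame with three prebleach
    frames. fading_rate is the whole-image photofading the correction must
    remove; the post-bleach ROI follows
    floor + mobile_fraction * (1 - floor) * (1 - exp(-k t)), multiplied by
    exp(-fading_rate * t), with t measured from the bleach.
    """

    rate_k: float
    mobile_fraction: float
    postbleach_floor: float
    fading_rate: float = 0.0
    frame_interval: float = 5.0
    n_prebleach: int = 3
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_k <= 0:
            raise ValueError("rate_k must be positive")
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must lie in [0, 1]")
        if not 0.0 <= self.postbleach_floor < 1.0:
            raise ValueError("postbleach_floor must lie in [0, 1)")
        if self.n_prebleach < 1:
            raise ValueError("n_prebleach must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.noise_sigma < 0 or self.fading_rate < 0:
            raise ValueError("noise_sigma and fading_rate must be non-negative")


@dataclass
class TrackTruth:
    """Ground truth of a persistent-random-walk migration experiment.

    Defaults follow a 10-minute, 16-hour time lapse (97 frames). persistence
    is the expected cosine of the turn angle between consecutive steps;
    speed_cv is the coefficient of variation of per-step lengths (0 gives
    constant steps, the default 0.5 gives realistic step-length scatter).
    """

    mean_speed: float  # µm/min
    persistence: float = 0.5
    frame_interval: float = 10.0  # minutes
    n_frames: int = 97
    pixel_size: float = 1.0  # µm/pixel
    speed_cv: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_speed < 0:
            raise ValueError("mean_speed must be non-negative")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must lie in [0, 1]")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be positive")
        if self.speed_cv < 0:
            raise ValueError("speed_cv must be non-negative")


@dataclass
class BindingTruth:
    """Ground truth of a thermophoresis titration (labeled target at 50 nM)."""

    kd: float  # mol/L
    target_conc: float = 50e-9  # mol/L
    response_unbound: float = 0.0
    response_bound: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.target_conc <= 0:
            raise ValueError("kd and target_conc must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class DecayTruth:
    """Ground truth of a mono-exponential photon decay histogram."""

    lifetime_tau: float  # ns
    total_counts: int = 100_000
    bin_width: float = 0.05  # ns
    n_bins: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lifetime_tau <= 0:
            raise ValueError("lifetime_tau must be positive")
        if self.total_counts <= 0:
            raise ValueError("total_counts must be positive")
        if self.bin_width <= 0 or self.n_bins < 2:
            raise ValueError("invalid binning")


def _gaussian_spot(shape, center, sigma, amplitude):
    rr = np.arange(shape[0], dtype=float)[:, None]
    cc = np.arange(shape[1], dtype=float)[None, :]
    r0, c0 = center
    return amplitude * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma**2))


def make_vesicle_scene(
    truth: SceneTruth, shape: tuple[int, int]
) -> tuple[PixelImage, PixelImage, SceneTruth]:
    """Render a two-channel scene of Gaussian vesicles on a noisy background.

    Channel A contains every vesicle; exactly round(coloc_fraction * n) of
    them, chosen by the seeded RNG, are duplicated at identical centers in
    channel B. Returns the truth with the duplicated indices recorded.
    Identical truth + seed gives bit-identical images.
    """
    margin = 3.0 * truth.vesicle_sigma
    for i, (r, c) in enumerate(truth.vesicle_centers):
        if not (margin <= r <= shape[0] - 1 - margin and margin <= c <= shape[1] - 1 - margin):
            raise ValueError(
                f"vesicle {i} at ({r}, {c}) violates the 3-sigma margin for shape {shape}"
            )
    rng = np.random.default_rng(truth.seed)
    n = truth.n_vesicles
    k = int(round(truth.coloc_fraction * n))
    dup = tuple(sorted(rng.choice(n, size=k, replace=False).tolist())) if n else ()

    clean_a = np.full(shape, truth.background_level, dtype=float)
    for (r, c), a in zip(truth.vesicle_centers, truth.vesicle_amplitudes):
        clean_a += _gaussian_spot(shape, (r, c), truth.vesicle_sigma, a)

    clean_b = np.full(shape, truth.background_level, dtype=float)
    for i in dup:
        r, c = truth.vesicle_centers[i]
        if truth.coloc_jitter > 0:
            r += rng.normal(0.0, truth.coloc_jitter)
            c += rng.normal(0.0, truth.coloc_jitter)
        clean_b += _gaussian_spot(shape, (r, c), truth.vesicle_sigma, truth.vesicle_amplitudes[i])

    if truth.noise_model == "poisson":
        img_a = rng.poisson(np.maximum(clean_a, 0.0)).astype(float)
        img_b = rng.poisson(np.maximum(clean_b, 0.0)).astype(float)
    else:
        img_a = clean_a + rng.normal(0.0, truth.noise_sigma, shape) if truth.noise_sigma else clean_a
        img_b = clean_b + rng.normal(0.0, truth.noise_sigma, shape) if truth.noise_sigma else clean_b

    out_truth = dataclasses.replace(truth, coloc_indices=dup)
    return (
        PixelImage(img_a, channel_name="A"),
        PixelImage(img_b, channel_name="B"),
        out_truth,
    )


def random_scene_truth(
    n_vesicles: int,
    shape: tuple[int, int],
    seed: int,
    coloc_fraction: float = 0.0,
    amplitude: float = 200.0,
    background_level: float = 100.0,
    noise_sigma: float = 20.0,
    vesicle_sigma: float = 1.5,
    min_separation: float = 12.0,
    **kwargs,
) -> SceneTruth:
    """Sample non-overlapping vesicle centers and build a SceneTruth.

    Centers are placed uniformly with rejection until pairwise separation
    exceeds min_separation and a 3-sigma border margin holds. Defaults give
    SNR 10 scenes (amplitude 200, noise 20) at low spot density.
    """
    rng = np.random.default_rng(seed)
    margin = 3.0 * vesicle_sigma + 1.0
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_vesicles:
        attempts += 1
        if attempts > 100_000:
            raise ValueError("could not place vesicles at the requested density")
        r = rng.uniform(margin, shape[0] - 1 - margin)
        c = rng.uniform(margin, shape[1] - 1 - margin)
        if all((r - r2) ** 2 + (c - c2) ** 2 >= min_separation**2 for r2, c2 in centers):
            centers.append((r, c))
    return SceneTruth(
        vesicle_centers=tuple(centers),
        vesicle_amplitudes=amplitude,
        coloc_fraction=coloc_fraction,
        background_level=background_level,
        noise_sigma=noise_sigma,
        seed=seed,
        vesicle_sigma=vesicle_sigma,
        **kwargs,
    )


def make_frap_series(truth: FrapTruth, n_post: int) -> FrapTrace:
    """Simulate a FRAP trace with photofading.

    Prebleach ROI frames sit at 1.0; post-bleach frames follow the recovery
    model times the whole-image fading exp(-fading_rate * t) (t from the
    bleach). The whole-image trace carries the same fading, scaled to its
    prebleach mean, so the standard correction inverts it exactly. Noise is
    added after composition.
    """
    if n_post < 3:
        raise ValueError("need at least 3 post-bleach frames (fit under-determined)")
    dt = truth.frame_interval
    npre = truth.n_prebleach
    times = np.arange(npre + n_post) * dt
    t_post = dt * np.arange(1, n_post + 1)

    floor = truth.postbleach_floor
    recovery = floor + truth.mobile_fraction * (1.0 - floor) * (1.0 - np.exp(-truth.rate_k * t_post))
    fade = np.exp(-truth.fading_rate * t_post)

    roi = np.concatenate([np.ones(npre), recovery * fade])
    whole = np.concatenate([np.ones(npre), fade])

    if truth.noise_sigma > 0:
        rng = np.random.default_rng(truth.seed)
        roi = roi + rng.normal(0.0, truth.noise_sigma, roi.size)
        whole = whole + rng.normal(0.0, truth.noise_sigma / 4.0, whole.size)

    return FrapTrace(
        times=times,
        roi_intensity=roi,
        whole_image_intensity=whole,
        n_prebleach=npre,
    )


def _turn_half_width(persistence: float) -> float:
    """Half-width a of the uniform turn-angle law with E[cos] = sin(a)/a."""
    if persistence >= 1.0:
        return 0.0
    if persistence <= 0.0:
        return np.pi
    return brentq(lambda a: np.sin(a) / a - persistence, 1e-9, np.pi)


def make_tracks(truth: TrackTruth, n_cells: int) -> list[Track]:
    """Simulate persistent random walks with the requested mean speed.

    Per-step displacement lengths have mean mean_speed * frame_interval
    (gamma-distributed with CV speed_cv; constant when speed_cv = 0) and the
    direction correlation between consecutive steps equals persistence
    (uniform turn angles on [-a, a] with sin(a)/a = persistence).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(truth.seed)
    a = _turn_half_width(truth.persistence)
    s = truth.mean_speed * truth.frame_interval  # µm per step
    n_steps = truth.n_frames - 1
    tracks: list[Track] = []
    for i in range(n_cells):
        start = rng.uniform(0.0, 1000.0, size=2)
        theta0 = rng.uniform(-np.pi, np.pi)
        turns = rng.uniform(-a, a, size=n_steps) if a > 0 else np.zeros(n_steps)
        thetas = theta0 + np.concatenate([[0.0], np.cumsum(turns[:-1])])
        if s == 0.0:
            lengths = np.zeros(n_steps)
        elif truth.speed_cv == 0.0:
            lengths = np.full(n_steps, s)
        else:
            shape_k = 1.0 / truth.speed_cv**2
            lengths = rng.gamma(shape_k, s / shape_k, size=n_steps)
        steps = lengths[:, None] * np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
        pos_um = start + np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        tracks.append(
            Track(
                cell_id=f"cell{i:04d}",
                frames=np.arange(truth.n_frames),
                positions=pos_um / truth.pixel_size,
                frame_interval=truth.frame_interval,
                pixel_size=truth.pixel_size,
            )
        )
    return tracks


def make_titration(truth: BindingTruth, ligand_concs: Sequence[float]) -> TitrationSeries:
    """Simulate a titration following the depletion-corrected binding model."""
    lig = np.asarray(ligand_concs, dtype=float)
    if lig.size < 6:
        raise ValueError("need at least 6 titration points (fit unstable)")
    if np.any(lig <= 0):
        raise ValueError("ligand concentrations must be strictly positive")
    f = fraction_bound(lig, truth.kd, truth.target_conc)
    resp = truth.response_unbound + (truth.response_bound - truth.response_unbound) * f
    if truth.noise_sigma > 0:
        rng = np.random.default_rng(truth.seed)
        resp = resp + rng.normal(0.0, truth.noise_sigma, resp.size)
    return TitrationSeries(ligand_conc=lig, response=resp, target_conc=truth.target_conc)


def make_decay(truth: DecayTruth) -> DecayHistogram:
    """Simulate a photon decay: multinomial counts over exponential bins.

    Rejects acquisition windows shorter than 5 lifetimes (truncation bias).
    The histogram total equals total_counts exactly.
    """
    window = truth.n_bins * truth.bin_width
    if window < 5.0 * truth.lifetime_tau:
        raise ValueError(
            f"window {window:.3g} ns shorter than 5 lifetimes "
            f"({5 * truth.lifetime_tau:.3g} ns): truncation would bias the fit"
        )
    centers = (np.arange(truth.n_bins) + 0.5) * truth.bin_width
    w = np.exp(-centers / truth.lifetime_tau)
    p = w / w.sum()
    rng = np.random.default_rng(truth.seed)
    counts = rng.multinomial(truth.total_counts, p)
    return DecayHistogram(bin_centers=centers, counts=counts)


def write_truth(path: str | Path, truth) -> None:
    """Write a truth dataclass as a JSON sidecar next to its data file."""
    payload = {"truth_type": type(truth).__name__, **dataclasses.asdict(truth)}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
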