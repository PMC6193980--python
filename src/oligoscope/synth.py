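"""Synthetic-data generators emulating the microscopy inputs of each stage.

Every generator is driven by a numpy Generator seeded explicitly, emits a
``SyntheticTruth`` record holding the full generating parameterisation, and
is bit-reproducible given (parameters, seed).  The generators emulate:

* FLImP measurement sets — pairwise label separations drawn from polymer
  chains (approximately exponential species mix, ~20% internal labelling or
  2N:2 end labelling) with nm-scale 2-D Gaussian localisation error;
* TIRF spot movies of 1-2 emitters with stepwise photobleaching
  (0.28 s/frame, Gaussian PSF, Poisson shot noise plus Gaussian read noise);
* confocal photobleach image series of clustered emitters for pbICS
  (independent per-fluorophore survival per round);
* two-colour 50 ms/frame track sets with co-diffusing pairs whose bound
  intervals are exponentially distributed;
* FRET efficiency versus acceptor-density titrations for a donor at a fixed
  height above the membrane plane.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .chain import (
    ChainGeometry,
    LabelingScheme,
    MODE_END,
    OligomerComposition,
    chain_site_positions,
)
from .flimp import FLImPDataset, SeparationMeasurement, separation_posterior, Localization
from .fretdoca import FretObservation, mc_efficiency
from .sptcoloc import Track, TrackSet

DEFAULT_FLIMP_FRAME_S = 0.28
DEFAULT_SPT_FRAME_S = 0.05


@dataclass
class SyntheticTruth:
    """Generating parameters of a synthetic dataset, JSON-serialisable;
    together with the seed they regenerate the dataset bit-exactly."""

    generator: str
    params: dict
    seed: int | None

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=default)


# ---------------------------------------------------------------------------
# FLImP measurement sets
# ---------------------------------------------------------------------------


class GeneratorExhaustedError(RuntimeError):
    """Raised when a labelling scheme fails to produce a labelled pair."""


def simulate_flimp_measurements(
    geometry: ChainGeometry,
    composition: OligomerComposition,
    scheme: LabelingScheme,
    loc_sigma_nm: float,
    n_measurements: int,
    seed=None,
    site: str = "DIII",
    max_retries: int = 10000,
) -> FLImPDataset:
    """Pairwise-separation measurements from labelled polymer chains.

    Each measurement samples a chain size from the composition, labels sites
    per the scheme, picks one labelled pair uniformly, perturbs both sites by
    independent 2-D Gaussian localisation error of scale ``loc_sigma_nm``,
    and records the observed distance with its Rician posterior.  True pair
    separations are retained in the truth record.
    """
    if loc_sigma_nm < 0:
        raise ValueError("loc_sigma_nm must be >= 0")
    if n_measurements < 1:
        raise ValueError("n_measurements must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = composition.sizes
    probs = composition.fractions / composition.fractions.sum()

    measurements: list[SeparationMeasurement] = []
    true_nu: list[float] = []
    true_size: list[int] = []
    failures_in_a_row = 0
    while len(measurements) < n_measurements:
        if failures_in_a_row > max_retries:
            raise GeneratorExhaustedError(
                "labelling scheme produced no labelled pair within the retry budget"
            )
        failures_in_a_row += 1  # reset to 0 when a measurement is recorded
        n = int(rng.choice(sizes, p=probs))
        pos = chain_site_positions(geometry, n, site=site)
        if scheme.mode == MODE_END:
            if n < 2:
                continue
            i, k = 0, n - 1
        else:
            labelled = np.flatnonzero(rng.random(n) < scheme.p_label)
            if labelled.size < 2:
                continue
            pair_idx = rng.integers(0, labelled.size * (labelled.size - 1) // 2)
            iu = np.triu_indices(labelled.size, k=1)
            i, k = labelled[iu[0][pair_idx]], labelled[iu[1][pair_idx]]
        pa = pos[i] + rng.normal(0.0, loc_sigma_nm, 2)
        pb = pos[k] + rng.normal(0.0, loc_sigma_nm, 2)
        m = separation_posterior(
            Localization(pa[0], pa[1], loc_sigma_nm),
            Localization(pb[0], pb[1], loc_sigma_nm),
        )
        measurements.append(m)
        true_nu.append(float(np.hypot(*(pos[k] - pos[i]))))
        true_size.append(n)
        failures_in_a_row = 0

    truth = SyntheticTruth(
        "flimp_measurements",
        {
            "geometry": dataclasses.asdict(geometry),
            "composition": composition.fractions,
            "scheme": dataclasses.asdict(scheme),
            "loc_sigma_nm": loc_sigma_nm,
            "site": site,
            "true_nu_nm": np.array(true_nu),
            "true_size": np.array(true_size),
        },
        seed,
    )
    ds = FLImPDataset(measurements, condition="synthetic")
    ds.truth = dataclasses.asdict(truth)
    return ds


# ---------------------------------------------------------------------------
# Spot movies
# ---------------------------------------------------------------------------


@dataclass
class SpotMovie:
    """A TIRF spot movie of 1-2 emitters with stepwise photobleaching."""

    frames: np.ndarray  # (T, H, W) photon counts
    pixel_size_nm: float
    frame_interval_s: float
    psf_sigma_px: float
    truth: SyntheticTruth | None = None


def simulate_spot_movie(
    separation_nm: float,
    photons_per_frame: float = 2000.0,
    pixel_size_nm: float = 80.0,
    psf_sigma_px: float = 1.2,
    n_frames: int = 60,
    bleach_frames: tuple[int, int] | None = None,
    background: float = 10.0,
    read_noise_sd: float = 1.0,
    image_size_px: int = 15,
    n_emitters: int = 2,
    frame_interval_s: float = DEFAULT_FLIMP_FRAME_S,
    seed=None,
    noise: bool = True,
) -> SpotMovie:
    """Render a spot movie of one or two stepwise-bleaching emitters.

    Emitters sit symmetrically about the image centre along x, separated by
    ``separation_nm``; each contributes a Gaussian PSF with a constant
    photon budget until its bleach frame, after which its contribution is
    exactly zero.  Poisson shot noise and Gaussian read noise are applied
    when ``noise`` is true.
    """
    if photons_per_frame <= 0:
        raise ValueError("photon budget must be > 0")
    if n_emitters not in (1, 2):
        raise ValueError("spot movies support 1 or 2 emitters")
    rng = np.random.default_rng(seed)
    if bleach_frames is None:
        b1 = int(rng.integers(n_frames // 4, n_frames // 2))
        b2 = int(rng.integers(n_frames // 2 + 3, n_frames - 5))
        bleach_frames = (b1, b2)[:n_emitters]
    c = (image_size_px - 1) / 2.0
    half_px = 0.5 * separation_nm / pixel_size_nm
    if n_emitters == 2:
        positions = np.array([[c - half_px, c], [c + half_px, c]])
    else:
        positions = np.array([[c, c]])
        bleach_frames = bleach_frames[:1]
    yy, xx = np.mgrid[0:image_size_px, 0:image_size_px]
    psfs = [
        np.exp(-((xx - p[0]) ** 2 + (yy - p[1]) ** 2) / (2 * psf_sigma_px**2))
        for p in positions
    ]
    psfs = [p / p.sum() for p in psfs]
    frames = np.empty((n_frames, image_size_px, image_size_px))
    for t in range(n_frames):
        rate = np.full((image_size_px, image_size_px), background, dtype=float)
        for p, b in zip(psfs, bleach_frames):
            if t < b:
                rate += photons_per_frame * p
        if noise:
            frames[t] = rng.poisson(rate) + rng.normal(0.0, read_noise_sd, rate.shape)
        else:
            frames[t] = rate
    truth = SyntheticTruth(
        "spot_movie",
        {
            "separation_nm": separation_nm,
            "positions_px": positions,
            "bleach_frames": list(bleach_frames),
            "photons_per_frame": photons_per_frame,
            "background": background,
            "pixel_size_nm": pixel_size_nm,
            "psf_sigma_px": psf_sigma_px,
        },
        seed,
    )
    return SpotMovie(frames, pixel_size_nm, frame_interval_s, psf_sigma_px, truth)


# ---------------------------------------------------------------------------
# pbICS stacks
# ---------------------------------------------------------------------------


@dataclass
class PbicsStack:
    """Confocal image series across photobleach rounds."""

    rounds: np.ndarray  # (n_rounds+1, H, W)
    beam_waist_px: float
    truth: SyntheticTruth | None = None


def simulate_pbics_stack(
    composition: OligomerComposition,
    cluster_density_per_px2: float,
    survival_per_round: float,
    n_rounds: int,
    image_shape: tuple[int, int] = (256, 256),
    beam_waist_px: float = 2.5,
    photons_per_fluor: float = 100.0,
    noise_sd: float = 0.5,
    seed=None,
) -> PbicsStack:
    """Photobleach image series of Poisson-placed oligomer clusters.

    Clusters are placed by a homogeneous spatial Poisson process with sizes
    drawn from the composition; a size-j cluster carries j fluorophores,
    each of which survives each bleach round independently with probability
    ``survival_per_round`` (survival across rounds is monotone
    non-increasing).  Images are rendered with a Gaussian beam profile of
    1/e^2 waist ``beam_waist_px`` plus white Gaussian noise.
    """
    if not (0.0 < survival_per_round < 1.0):
        raise ValueError("survival_per_round must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    H, W = image_shape
    n_clusters = rng.poisson(cluster_density_per_px2 * H * W)
    pos = rng.uniform([0, 0], [W, H], size=(n_clusters, 2))
    sizes = rng.choice(composition.sizes, size=n_clusters, p=composition.fractions)

    # per-fluorophore alive indicator, shape (total_fluors,)
    total = int(sizes.sum())
    owner = np.repeat(np.arange(n_clusters), sizes)
    alive = np.ones(total, dtype=bool)
    survival_matrix = np.ones((n_rounds + 1, total), dtype=bool)
    for t in range(1, n_rounds + 1):
        alive &= rng.random(total) < survival_per_round
        survival_matrix[t] = alive

    # Gaussian beam: intensity ~ exp(-2 r^2 / omega^2), sigma = omega / 2
    sigma = beam_waist_px / 2.0
    yy, xx = np.mgrid[0:H, 0:W]
    rounds = np.empty((n_rounds + 1, H, W))
    for t in range(n_rounds + 1):
        img = np.zeros((H, W))
        counts = np.bincount(owner[survival_matrix[t]], minlength=n_clusters)
        for (x, y), k in zip(pos, counts):
            if k == 0:
                continue
            x0, x1 = max(0, int(x - 4 * sigma)), min(W, int(x + 4 * sigma) + 1)
            y0, y1 = max(0, int(y - 4 * sigma)), min(H, int(y + 4 * sigma) + 1)
            img[y0:y1, x0:x1] += (
                k
                * photons_per_fluor
                / (2 * np.pi * sigma**2)
                * np.exp(
                    -((xx[y0:y1, x0:x1] - x) ** 2 + (yy[y0:y1, x0:x1] - y) ** 2)
                    / (2 * sigma**2)
                )
            )
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        rounds[t] = img
    truth = SyntheticTruth(
        "pbics_stack",
        {
            "composition": composition.fractions,
            "cluster_density_per_px2": cluster_density_per_px2,
            "survival_per_round": survival_per_round,
            "n_rounds": n_rounds,
            "beam_waist_px": beam_waist_px,
            "cluster_sizes": sizes,
            "survivors_per_round": survival_matrix.sum(axis=1),
        },
        seed,
    )
    return PbicsStack(rounds, beam_waist_px, truth)


# ---------------------------------------------------------------------------
# Two-colour track sets
# ---------------------------------------------------------------------------

BOUND_OFFSET_PX = 0.2  # fixed inter-particle offset during bound intervals


def simulate_tracks(
    n_free_per_channel: int,
    n_pairs: int,
    diffusion_um2_s: float = 0.1,
    tau_on_mean_s: float = 0.5,
    frame_interval_s: float = DEFAULT_SPT_FRAME_S,
    n_frames: int = 100,
    fov_px: tuple[float, float] = (800.0, 300.0),  # 80 x 30 um at 0.1 um/px
    pixel_size_um: float = 0.1,
    loc_noise_px: float = 0.1,
    seed=None,
) -> tuple[TrackSet, TrackSet, SyntheticTruth]:
    """Two-colour track sets with known co-diffusing pairs.

    Free tracks are independent Brownian walks (toroidal FOV).  Each pair
    co-diffuses at a fixed offset of 0.2 px during bound intervals whose
    durations are exponential with mean ``tau_on_mean_s``; between bound
    intervals the partners diffuse independently.  The truth records, per
    pair, the bound/unbound label of every frame.
    """
    if min(n_free_per_channel, n_pairs) < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    W, H = fov_px
    step_px = np.sqrt(2.0 * diffusion_um2_s * frame_interval_s) / pixel_size_um

    def brownian(start):
        steps = rng.normal(0.0, step_px, (n_frames - 1, 2))
        path = np.vstack([start, start + np.cumsum(steps, axis=0)])
        return np.mod(path, [W, H])

    tracks_a: list[Track] = []
    tracks_b: list[Track] = []
    frames = np.arange(n_frames)
    tid = 0
    for _ in range(n_free_per_channel):
        for out in (tracks_a, tracks_b):
            path = brownian(rng.uniform([0, 0], [W, H]))
            noisy = path + rng.normal(0, loc_noise_px, path.shape)
            out.append(Track(tid, "A" if out is tracks_a else "B", frames, noisy, frame_interval_s))
            tid += 1

    bound_labels = np.zeros((n_pairs, n_frames), dtype=bool)
    bound_durations: list[float] = []
    movie_len_s = n_frames * frame_interval_s
    for p in range(n_pairs):
        # alternate bound/unbound intervals in continuous time, starting bound
        t_s = 0.0
        bound = True
        while t_s < movie_len_s:
            if np.isinf(tau_on_mean_s) and bound:
                dur = movie_len_s - t_s
            else:
                dur = rng.exponential(tau_on_mean_s)
            if bound:
                bound_durations.append(dur)  # raw draw, before end-of-movie truncation
                f0 = int(np.floor(t_s / frame_interval_s))
                f1 = min(int(np.floor((t_s + dur) / frame_interval_s)) + 1, n_frames)
                bound_labels[p, f0:f1] = True
            t_s += dur
            bound = not bound
        base = brownian(rng.uniform([0, 0], [W, H]))
        partner = np.empty_like(base)
        # bound frames: fixed offset from base; unbound: independent walk
        offset_dir = rng.normal(0, 1, 2)
        offset = BOUND_OFFSET_PX * offset_dir / np.linalg.norm(offset_dir)
        free_walk = brownian(rng.uniform([0, 0], [W, H]))
        # splice: during unbound stretches follow a displaced independent walk
        for t in range(n_frames):
            if bound_labels[p, t]:
                partner[t] = base[t] + offset
            else:
                partner[t] = free_walk[t]
        na = base + rng.normal(0, loc_noise_px, base.shape)
        nb = partner + rng.normal(0, loc_noise_px, partner.shape)
        tracks_a.append(Track(tid, "A", frames, np.mod(na, [W, H]), frame_interval_s))
        tid += 1
        tracks_b.append(Track(tid, "B", frames, np.mod(nb, [W, H]), frame_interval_s))
        tid += 1

    truth = SyntheticTruth(
        "tracks",
        {
            "n_free_per_channel": n_free_per_channel,
            "n_pairs": n_pairs,
            "diffusion_um2_s": diffusion_um2_s,
            "tau_on_mean_s": tau_on_mean_s,
            "bound_labels": bound_labels,
            "bound_durations_s": np.array(bound_durations),
            "fov_px": list(fov_px),
        },
        seed,
    )
    return (
        TrackSet(tracks_a, fov_px, frame_interval_s),
        TrackSet(tracks_b, fov_px, frame_interval_s),
        truth,
    )


# ---------------------------------------------------------------------------
# FRET titrations
# ---------------------------------------------------------------------------


def simulate_fret(
    h_true_nm: float,
    densities_per_um2,
    R0_nm: float = 5.0,
    n_cells_per_density: int = 10,
    noise_sd: float = 0.05,
    n_config: int = 400,
    seed=None,
) -> tuple[list[FretObservation], SyntheticTruth]:
    """Per-cell FRET efficiencies across an acceptor-density titration.

    Each cell's efficiency is the Monte-Carlo mean response at
    (h_true, density) plus Gaussian noise, truncated to [0, 1].
    """
    if h_true_nm <= 0:
        raise ValueError("h_true must be > 0")
    densities = list(densities_per_um2)
    if not densities:
        raise ValueError("densities must be non-empty")
    rng = np.random.default_rng(seed)
    obs: list[FretObservation] = []
    cell = 0
    for d in densities:
        e_mean = mc_efficiency(h_true_nm, d, R0_nm, n_config, seed=rng.integers(2**31))
        for _ in range(n_cells_per_density):
            e = float(np.clip(e_mean + rng.normal(0.0, noise_sd), 0.0, 1.0))
            obs.append(FretObservation(float(d), e, cell))
            cell += 1
    truth = SyntheticTruth(
        "fret",
        {
            "h_true_nm": h_true_nm,
            "densities_per_um2": list(densities),
            "R0_nm": R0_nm,
            "n_cells_per_density": n_cells_per_density,
            "noise_sd": noise_sd,
        },
        seed,
    )
    return obs, truth
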