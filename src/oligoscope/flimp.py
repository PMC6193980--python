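"""Fluorophore localisation imaging with photobleaching (FLImP) analysis.

A FLImP measurement is the Euclidean distance between two fluorophores, each
localised with isotropic Gaussian error; the observed distance r then follows
a Rice distribution around the true separation nu with combined scale
sigma = sqrt(sigma_A^2 + sigma_B^2):

    Rice(r | nu, sigma) = (r / sigma^2) exp(-(r^2 + nu^2) / 2 sigma^2)
                          I0(r nu / sigma^2)

which reduces to a Rayleigh law at nu = 0.  This module provides

* the per-measurement posterior over nu (flat prior on nu >= 0) and its 69%
  highest-density credible interval, used both for quality filtering and for
  range-overlap classification;
* extraction of the two emitter positions from a stepwise-photobleaching
  spot movie (change-point detection on the summed-intensity trace, Gaussian
  fits to the bleach-step difference images);
* maximum-likelihood decomposition of a set of measurements into K discrete
  Rician components, with BIC model selection and bootstrap error bars;
* the range-fraction post-analysis (fraction of measurements whose 69% CI
  overlaps a query separation or interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar
from scipy.special import i0e, logsumexp

NU_MAX_NM = 60.0  # separations beyond this are unresolvable clusters, not pairs
CI_LEVEL = 0.69  # ~1-sigma credible level used throughout
MIN_SEGMENT_FRAMES = 3  # minimum bleach-segment length for change-point detection


class NotAPairError(ValueError):
    """Raised when a spot movie does not show exactly two bleach steps."""


class InsufficientDataError(ValueError):
    """Raised when a bleach segment is too short to localise an emitter."""


# ---------------------------------------------------------------------------
# Rice likelihood and single-measurement posterior
# ---------------------------------------------------------------------------


def rice_logpdf(r, nu, sigma):
    """Log density of Rice(r | nu, sigma), vectorised; stable via i0e."""
    r = np.asarray(r, dtype=float)
    nu = np.asarray(nu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    s2 = sigma**2
    x = r * nu / s2
    # log I0(x) = x + log(i0e(x))
    out = np.log(r) - np.log(s2) - (r**2 + nu**2) / (2.0 * s2) + x + np.log(i0e(x))
    return np.where(r > 0, out, -np.inf)


@dataclass(frozen=True)
class Localization:
    """A fitted emitter position with isotropic localisation uncertainty (nm)."""

    x: float
    y: float
    sigma_loc: float

    def __post_init__(self) -> None:
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be >= 0")


@dataclass(frozen=True)
class SeparationMeasurement:
    """One pairwise separation with its Rician posterior summary.

    ``sigma`` is the combined localisation scale sqrt(sigma_A^2 + sigma_B^2);
    ``ci69`` is the 69% highest-density interval on the true separation nu.
    """

    r_obs: float
    sigma: float
    ci69: tuple[float, float]
    degenerate: bool = False

    @property
    def ci_width(self) -> float:
        return self.ci69[1] - self.ci69[0]


def separation_posterior(
    a: Localization, b: Localization, grid_points: int = 2000
) -> SeparationMeasurement:
    """Posterior over the true separation of two localised emitters.

    The posterior is proportional to Rice(r_obs | nu, sigma) under a flat
    prior on nu >= 0; the 69% interval is highest-density, which correctly
    pins the lower bound at 0 for near-coincident emitters.
    """
    r_obs = float(np.hypot(a.x - b.x, a.y - b.y))
    sigma = float(np.hypot(a.sigma_loc, b.sigma_loc))
    if sigma == 0.0:
        if r_obs == 0.0:
            return SeparationMeasurement(0.0, 0.0, (0.0, 0.0), degenerate=True)
        return SeparationMeasurement(r_obs, 0.0, (r_obs, r_obs))

    nu_hi = r_obs + 8.0 * sigma
    nu = np.linspace(0.0, nu_hi, grid_points)
    logp = rice_logpdf(max(r_obs, 1e-12), nu, sigma)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    lo, hi = _hdi_from_grid(nu, p, CI_LEVEL)
    return SeparationMeasurement(r_obs, sigma, (lo, hi))


def _hdi_from_grid(x: np.ndarray, p: np.ndarray, level: float) -> tuple[float, float]:
    """Highest-density interval of a unimodal density tabulated on a grid."""
    order = np.argsort(p)[::-1]
    csum = np.cumsum(p[order])
    k = int(np.searchsorted(csum, level)) + 1
    sel = x[order[:k]]
    return float(sel.min()), float(sel.max())


# ---------------------------------------------------------------------------
# Measurement datasets
# ---------------------------------------------------------------------------

FLIMP_COLUMNS = ["r_obs_nm", "sigma_nm", "ci_lo_nm", "ci_hi_nm", "condition"]


@dataclass
class FLImPDataset:
    """A set of pairwise-separation measurements, CSV round-trippable."""

    measurements: list[SeparationMeasurement]
    condition: str = ""
    truth: dict | None = None

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def r_obs(self) -> np.ndarray:
        return np.array([m.r_obs for m in self.measurements])

    @property
    def sigma(self) -> np.ndarray:
        return np.array([m.sigma for m in self.measurements])

    @property
    def ci_widths(self) -> np.ndarray:
        return np.array([m.ci_width for m in self.measurements])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_obs_nm": self.r_obs,
                "sigma_nm": self.sigma,
                "ci_lo_nm": [m.ci69[0] for m in self.measurements],
                "ci_hi_nm": [m.ci69[1] for m in self.measurements],
                "condition": self.condition,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FLImPDataset":
        ms = [
            SeparationMeasurement(
                float(row.r_obs_nm),
                float(row.sigma_nm),
                (float(row.ci_lo_nm), float(row.ci_hi_nm)),
            )
            for row in df.itertuples()
        ]
        cond = str(df["condition"].iloc[0]) if len(df) else ""
        return cls(ms, condition=cond)


def filter_ci(dataset: FLImPDataset, ci_max_nm: float) -> FLImPDataset:
    """Retain measurements whose 69% CI width is <= ci_max_nm (inclusive)."""
    if ci_max_nm < 0:
        raise ValueError("ci_max_nm must be >= 0")
    kept = [m for m in dataset.measurements if m.ci_width <= ci_max_nm]
    return FLImPDataset(kept, condition=dataset.condition, truth=dataset.truth)


# ---------------------------------------------------------------------------
# Spot-movie emitter extraction
# ---------------------------------------------------------------------------


def _piecewise_constant_steps(trace: np.ndarray, max_steps: int = 2) -> list[int]:
    """Change points of the best piecewise-constant fit with 0..max_steps
    downward steps, chosen by a BIC-style penalty; binary segmentation with a
    minimum segment length."""
    T = trace.size
    csum = np.concatenate([[0.0], np.cumsum(trace)])
    csum2 = np.concatenate([[0.0], np.cumsum(trace**2)])

    def sse(i, j):  # segment [i, j)
        n = j - i
        s = csum[j] - csum[i]
        return (csum2[j] - csum2[i]) - s * s / n

    m = MIN_SEGMENT_FRAMES
    best: dict[int, tuple[float, list[int]]] = {0: (sse(0, T), [])}
    if T >= 2 * m:
        cands = [(sse(0, c) + sse(c, T), [c]) for c in range(m, T - m + 1)]
        best[1] = min(cands, key=lambda t: t[0])
    if T >= 3 * m:
        best2 = (np.inf, [])
        for c1 in range(m, T - 2 * m + 1):
            left = sse(0, c1)
            for c2 in range(c1 + m, T - m + 1):
                tot = left + sse(c1, c2) + sse(c2, T)
                if tot < best2[0]:
                    best2 = (tot, [c1, c2])
        best[2] = best2

    # model cost: T log(SSE/T) + 2 k log T, ties toward fewer steps
    def cost(k):
        s, _ = best[k]
        return T * np.log(max(s, 1e-300) / T) + 2.0 * k * np.log(T)

    k_best = min(best, key=lambda k: (round(cost(k), 9), k))
    return best[min(k_best, max_steps)][1]


def _fit_gaussian_spot(img: np.ndarray, pixel_size_nm: float, var_map: np.ndarray | None = None):
    """Weighted least-squares 2-D Gaussian fit; returns Localization in nm.

    ``var_map`` holds the per-pixel noise variance of ``img`` (shot noise is
    heteroscedastic, so unweighted residual-based covariances badly
    underestimate the position error at the bright centre pixels).  The
    position uncertainty is read from the weighted Gauss-Newton covariance
    (J^T W J)^-1 with absolute weights.
    """
    H, W = img.shape
    yy, xx = np.mgrid[0:H, 0:W]
    total = img.sum()
    if total <= 0:
        raise InsufficientDataError("non-positive spot image")
    if var_map is None:
        sd = np.full(img.shape, max(float(img.std()), 1e-12))
    else:
        sd = np.sqrt(np.clip(var_map, 1e-12, None))
    x0 = float((xx * img).sum() / total)
    y0 = float((yy * img).sum() / total)
    amp0 = float(img.max())
    sig0 = max(1.0, 0.2 * min(H, W) / 2)

    def model(p):
        amp, x, y, s, off = p
        return amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * s**2)) + off

    def resid(p):
        return ((model(p) - img) / sd).ravel()

    res = least_squares(
        resid,
        x0=[amp0, x0, y0, sig0, float(np.median(img))],
        bounds=([0, -1, -1, 0.3, -np.inf], [np.inf, W, H, max(H, W), np.inf]),
    )
    J = res.jac
    try:
        cov = np.linalg.inv(J.T @ J)
        sd_px = float(np.sqrt(max(0.5 * (cov[1, 1] + cov[2, 2]), 0.0)))
    except np.linalg.LinAlgError:
        sd_px = 0.0
    if var_map is None:
        # relative weights only: rescale by reduced chi-square
        dof = max(img.size - 5, 1)
        sd_px *= float(np.sqrt((res.fun @ res.fun) / dof))
    amp, x, y, sig, off = res.x
    return Localization(x * pixel_size_nm, y * pixel_size_nm, sd_px * pixel_size_nm)


def extract_two_emitter_positions(movie) -> tuple[Localization, Localization]:
    """Localise the two emitters of a stepwise-photobleaching spot movie.

    Change points are found on the summed-intensity trace.  The
    last-surviving emitter is localised from the mean image of the final
    bright segment (background subtracted); the first-bleaching emitter from
    the difference of the two bright-segment mean images, where its partner
    cancels exactly in expectation.
    """
    frames = np.asarray(movie.frames, dtype=float)
    trace = frames.sum(axis=(1, 2))
    steps = _piecewise_constant_steps(trace, max_steps=2)
    if len(steps) != 2:
        raise NotAPairError(f"expected 2 bleach steps, detected {len(steps)}")
    c1, c2 = steps
    if c1 < MIN_SEGMENT_FRAMES or (c2 - c1) < MIN_SEGMENT_FRAMES or (len(trace) - c2) < MIN_SEGMENT_FRAMES:
        raise InsufficientDataError("bleach segments shorter than the minimum length")

    seg_both = frames[:c1].mean(axis=0)
    seg_one = frames[c1:c2].mean(axis=0)
    background = frames[c2:].mean(axis=0)
    n_both, n_one, n_bg = c1, c2 - c1, len(trace) - c2

    # per-pixel shot-noise variance of each difference image, propagated
    # from the segment means (mean of n Poisson frames has var rate/n)
    rate_both = np.clip(seg_both, 0, None)
    rate_one = np.clip(seg_one, 0, None)
    rate_bg = np.clip(background, 0, None)
    var_last = rate_one / n_one + rate_bg / n_bg
    var_first = rate_both / n_both + rate_one / n_one

    img_last = seg_one - background
    img_first = seg_both - seg_one
    px = movie.pixel_size_nm
    loc_last = _fit_gaussian_spot(np.clip(img_last, 0, None), px, var_last)
    loc_first = _fit_gaussian_spot(np.clip(img_first, 0, None), px, var_first)
    return loc_first, loc_last


def measurement_from_movie(movie) -> SeparationMeasurement:
    """Convenience: movie -> two localisations -> separation posterior."""
    a, b = extract_two_emitter_positions(movie)
    return separation_posterior(a, b)


# ---------------------------------------------------------------------------
# Rician mixture decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RicianComponent:
    nu: float
    weight: float
    sd: float = np.nan
    n_measurements: float = np.nan


@dataclass
class DecompositionResult:
    """Selected mixture: K components with bootstrap SDs and the BIC table."""

    K: int
    components: list[RicianComponent]
    log_likelihood: float
    bic_table: dict[int, float]
    k_stability: float = np.nan

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "nu": [c.nu for c in self.components],
            "weight": [c.weight for c in self.components],
            "sd": [c.sd for c in self.components],
            "n_measurements": [c.n_measurements for c in self.components],
            "log_likelihood": self.log_likelihood,
            "bic_table": {str(k): v for k, v in self.bic_table.items()},
            "k_stability": self.k_stability,
        }


def _mixture_loglik(r, sigma, nu, w):
    lp = rice_logpdf(r[:, None], nu[None, :], sigma[:, None]) + np.log(w)[None, :]
    return float(logsumexp(lp, axis=1).sum())


def _em_fit(r, sigma, nu0, w0, max_iter=300, tol=1e-8):
    """EM for a K-component Rician mixture with known per-point sigma."""
    nu = nu0.copy()
    w = w0.copy()
    prev = -np.inf
    for _ in range(max_iter):
        lp = rice_logpdf(r[:, None], nu[None, :], sigma[:, None]) + np.log(
            np.clip(w, 1e-300, None)
        )
        norm = logsumexp(lp, axis=1)
        ll = float(norm.sum())
        gamma = np.exp(lp - norm[:, None])
        w = gamma.mean(axis=0)
        for k in range(nu.size):
            g = gamma[:, k]
            if g.sum() < 1e-12:
                continue

            def negq(v, g=g):
                return -float(g @ rice_logpdf(r, v, sigma))

            res = minimize_scalar(negq, bounds=(0.0, NU_MAX_NM), method="bounded")
            nu[k] = res.x
        if ll - prev < tol:
            break
        prev = ll
    return nu, w, _mixture_loglik(r, sigma, nu, np.clip(w, 1e-300, None))


def fit_mixture(dataset: FLImPDataset, K: int, restarts: int = 5, seed=None):
    """Best-of-`restarts` EM fit of a K-component Rician mixture.

    Component positions are bounded to [0, 60] nm; per-measurement sigmas are
    plugged in as known.  Returns (components, log_likelihood).
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("empty dataset")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError("K must not exceed the number of measurements")
    r = dataset.r_obs
    sigma = np.clip(dataset.sigma, 1e-6, None)
    rng = np.random.default_rng(seed)

    # quantile (k-means-like) initialisation plus random jitter per restart
    base = np.quantile(r, (np.arange(K) + 0.5) / K)
    best = None
    for i in range(max(restarts, 1)):
        if i == 0:
            nu0 = base.copy()
        else:
            nu0 = np.clip(base + rng.normal(0, max(r.std(), 1.0), K), 0, NU_MAX_NM)
        w0 = np.full(K, 1.0 / K)
        nu, w, ll = _em_fit(r, sigma, np.sort(nu0), w0)
        if best is None or ll > best[2]:
            best = (nu, w, ll)
    nu, w, ll = best
    order = np.argsort(nu)
    comps = [RicianComponent(float(nu[k]), float(w[k])) for k in order]
    return comps, ll


def _assign_counts(r, sigma, comps):
    """Hard-assign each measurement to its most responsible component."""
    nu = np.array([c.nu for c in comps])
    w = np.clip(np.array([c.weight for c in comps]), 1e-300, None)
    lp = rice_logpdf(r[:, None], nu[None, :], sigma[:, None]) + np.log(w)[None, :]
    idx = lp.argmax(axis=1)
    return np.bincount(idx, minlength=len(comps))


def select_K(
    dataset: FLImPDataset, K_max: int = 8, restarts: int = 5, seed=None
) -> DecompositionResult:
    """Choose the number of Rician components by BIC.

    BIC(K) = -2 L_hat + (2K - 1) ln n, counting K positions and K-1 free
    weights; ties are broken toward smaller K (parsimony).
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("empty dataset")
    K_max = max(1, min(K_max, n))
    rng = np.random.default_rng(seed)
    bic_table: dict[int, float] = {}
    fits = {}
    for K in range(1, K_max + 1):
        comps, ll = fit_mixture(dataset, K, restarts=restarts, seed=rng.integers(2**31))
        bic_table[K] = -2.0 * ll + (2 * K - 1) * np.log(n)
        fits[K] = (comps, ll)
    K_star = min(bic_table, key=lambda k: (bic_table[k], k))
    comps, ll = fits[K_star]
    counts = _assign_counts(dataset.r_obs, np.clip(dataset.sigma, 1e-6, None), comps)
    comps = [
        RicianComponent(c.nu, c.weight, n_measurements=float(cnt))
        for c, cnt in zip(comps, counts)
    ]
    return DecompositionResult(K_star, comps, ll, bic_table)


def bootstrap_errors(
    dataset: FLImPDataset,
    K: int,
    n_boot: int = 200,
    seed=None,
    restarts: int = 2,
    K_max_stability: int | None = None,
) -> tuple[np.ndarray, float]:
    """Bootstrap SDs of component positions and the K-stability fraction.

    Measurements are resampled with replacement; each resample is refit at K
    (positions matched to the full-data fit by nearest nu) and, for the
    stability fraction, K is reselected by BIC up to ``K_max_stability``
    (default K+1).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    n = len(dataset)
    rng = np.random.default_rng(seed)
    ref_comps, _ = fit_mixture(dataset, K, restarts=restarts, seed=rng.integers(2**31))
    ref_nu = np.array([c.nu for c in ref_comps])
    K_max = K_max_stability or (K + 1)

    boot_nu = np.full((n_boot, K), np.nan)
    k_hits = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        ds = FLImPDataset([dataset.measurements[i] for i in idx])
        comps, _ = fit_mixture(ds, K, restarts=restarts, seed=rng.integers(2**31))
        nu_b = np.array([c.nu for c in comps])
        # match each reference component to the nearest bootstrap position
        for k, target in enumerate(ref_nu):
            boot_nu[b, k] = nu_b[np.argmin(np.abs(nu_b - target))]
        sel = select_K(ds, K_max=K_max, restarts=1, seed=rng.integers(2**31))
        if sel.K == K:
            k_hits += 1
    sds = boot_nu.std(axis=0, ddof=1)
    return sds, k_hits / n_boot


def decompose(
    dataset: FLImPDataset,
    K_max: int = 8,
    n_boot: int = 200,
    restarts: int = 5,
    seed=None,
) -> DecompositionResult:
    """Full decomposition: BIC selection, then bootstrap error bars."""
    rng = np.random.default_rng(seed)
    result = select_K(dataset, K_max=K_max, restarts=restarts, seed=rng.integers(2**31))
    if len(dataset) >= 2 and n_boot >= 2:
        sds, stab = bootstrap_errors(
            dataset, result.K, n_boot=n_boot, seed=rng.integers(2**31)
        )
        result.components = [
            RicianComponent(c.nu, c.weight, sd=float(s), n_measurements=c.n_measurements)
            for c, s in zip(result.components, sds)
        ]
        result.k_stability = stab
    return result


# ---------------------------------------------------------------------------
# Range-overlap post-analysis
# ---------------------------------------------------------------------------


def range_fractions(dataset: FLImPDataset, queries: Sequence) -> list[float]:
    """Fraction of measurements whose 69% CI overlaps each query.

    A query is either a point separation (nm) or an (lo, hi) interval; a
    point counts a measurement iff it lies inside the CI, an interval iff the
    intervals intersect.  Overlap classes are not exclusive: one measurement
    may count toward several queries.
    """
    n = len(dataset)
    out = []
    for q in queries:
        if np.isscalar(q):
            lo_q = hi_q = float(q)
        else:
            lo_q, hi_q = float(q[0]), float(q[1])
            if lo_q > hi_q:
                raise ValueError("interval query must satisfy lo <= hi")
        if n == 0:
            out.append(0.0)
            continue
        hits = sum(
            1 for m in dataset.measurements if m.ci69[0] <= hi_q and lo_q <= m.ci69[1]
        )
        out.append(hits / n)
    return out
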