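"""Photobleaching image correlation spectroscopy (pbICS).

pbICS infers oligomer composition from how the apparent cluster density
changes as fluorophores are progressively photobleached: a j-mer remains a
visible cluster as long as at least one of its j fluorophores survives, so
larger oligomers lose apparent density more slowly than monomers as the
surviving intensity fraction p drops.  For a mixture with concentration c_j
of j-mers, with fluorophores bleached independently (per-fluorophore
survival p), the apparent cluster density is

    CD(p) = (sum_j j c_j)^2 p / sum_j [ j c_j + j (j-1) c_j p ]

equivalently c (E B)^2 / E B^2 summed over species with B ~ Binomial(j, p).
Cluster density itself is estimated from the zero-lag amplitude of the
normalised spatial image autocorrelation: CD = 1 / (g(0,0) pi omega^2) for a
Gaussian beam of 1/e^2 waist omega.  Composition is recovered by bounded
non-negative least squares of the measured (p, CD) curve against the model.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares, linprog

DEFAULT_J_MAX = 8


@dataclass
class BleachCurve:
    """Apparent cluster density versus surviving intensity fraction.

    ``p`` starts at 1 (round 0, no bleaching) and strictly decreases.
    """

    p: np.ndarray
    cd: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.cd = np.asarray(self.cd, dtype=float)
        if self.p.shape != self.cd.shape:
            raise ValueError("p and cd must have the same length")
        if np.any(np.diff(self.p) >= 0):
            raise ValueError("p must be strictly decreasing across rounds")
        if np.any(self.cd < 0):
            raise ValueError("cluster densities must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"p": self.p, "cd": self.cd})


@dataclass
class CompositionFit:
    """Fitted species concentrations c_j (clusters per unit area).

    The bleach curve identifies only two functionals of the concentrations
    (see :func:`fit_composition`): the total molecular density
    A = sum_j j c_j and the second factorial moment B = sum_j j(j-1) c_j.
    Both are exposed here alongside the (degenerate) per-size vector.
    """

    c: np.ndarray
    residual_norm: float
    n_curves: int = 1

    @property
    def species_fractions(self) -> np.ndarray:
        """Normalised species-number fractions f_j = c_j / sum c."""
        total = self.c.sum()
        if total <= 0:
            return np.zeros_like(self.c)
        return self.c / total

    @property
    def molecular_fractions(self) -> np.ndarray:
        """Molecule-number fractions m_j = j c_j / sum_k k c_k."""
        j = np.arange(1, self.c.size + 1)
        w = j * self.c
        return w / w.sum()

    @property
    def oligomer_fraction(self) -> float:
        """Molecule-normalised fraction in species of size >= 2.

        This functional lies partly in the curve's unidentified directions;
        it is exact for single-species data but model-dependent for
        mixtures (see :func:`fit_composition`).
        """
        return float(self.molecular_fractions[1:].sum())

    @property
    def molecular_density(self) -> float:
        """A = sum_j j c_j, the total molecule density (identified)."""
        j = np.arange(1, self.c.size + 1)
        return float((j * self.c).sum())

    @property
    def second_factorial_moment(self) -> float:
        """B = sum_j j(j-1) c_j (identified)."""
        j = np.arange(1, self.c.size + 1)
        return float((j * (j - 1) * self.c).sum())

    @property
    def mean_oligomer_size(self) -> float:
        """Molecule-weighted mean assembly size 1 + B/A (identified)."""
        return 1.0 + self.second_factorial_moment / self.molecular_density


def cd_model(c, p):
    """Apparent cluster density for concentrations c_j at survival fraction p.

    Vectorised over p.  CD(0) = 0; CD(1) = (sum j c_j)^2 / sum j^2 c_j, the
    true total cluster density when a single species is present.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    if not np.any(c > 0):
        raise ValueError("concentrations must not be all zero")
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p must lie in [0, 1]")
    j = np.arange(1, c.size + 1)
    num = (j * c).sum() ** 2 * p
    den = (j * c).sum() + np.multiply.outer(p, (j * (j - 1) * c).sum())
    return num / den


def cd_binomial_oracle(c, p):
    """Independent evaluation of the same curve via binomial survival moments:
    CD = sum_j c_j (E B_j)^2 / E B_j^2 with B_j ~ Binomial(j, p), pooled as
    (E over the cluster mixture)^2 / (second moment).  Used as a cross-check.
    """
    c = np.asarray(c, dtype=float)
    p = float(p)
    j = np.arange(1, c.size + 1)
    if p == 0.0:
        return 0.0
    eb = j * p  # E[B_j]
    eb2 = j * p * (1 - p) + (j * p) ** 2  # E[B_j^2]
    return float((c * eb).sum() ** 2 / (c * eb2).sum())


# ---------------------------------------------------------------------------
# Image-level estimators
# ---------------------------------------------------------------------------


def spatial_autocorrelation(image: np.ndarray) -> np.ndarray:
    """Normalised fluctuation autocorrelation g = <dI dI> / <I>^2 via FFT,
    zero lag at the array centre."""
    img = np.asarray(image, dtype=float)
    mean = img.mean()
    if mean <= 0:
        raise ValueError("image mean must be positive")
    d = img - mean
    F = np.fft.fft2(d)
    corr = np.fft.ifft2(F * np.conj(F)).real / d.size
    return np.fft.fftshift(corr) / mean**2


def cluster_density(image: np.ndarray, beam_waist_px: float, fit_halfwidth=None) -> float:
    """Apparent cluster density (per px^2) from the ICS autocorrelation peak.

    The central peak is fitted by a 2-D Gaussian g0 exp(-(xi^2+eta^2)/omega^2)
    excluding the zero-lag pixel (shot-noise spike); CD = 1/(g0 pi omega^2).
    Raises ValueError (QC failure) when no positive peak is found.
    """
    g = spatial_autocorrelation(image)
    H, W = g.shape
    cy, cx = H // 2, W // 2
    hw = int(fit_halfwidth or max(4, round(3 * beam_waist_px)))
    win = g[cy - hw : cy + hw + 1, cx - hw : cx + hw + 1]
    yy, xx = np.mgrid[-hw : hw + 1, -hw : hw + 1]
    mask = ~((xx == 0) & (yy == 0))
    r2 = (xx**2 + yy**2)[mask].ravel()
    z = win[mask].ravel()
    if not np.any(z > 0):
        raise ValueError("ICS QC failure: featureless image (no positive correlation)")

    def model(r2_, g0, w2):
        return g0 * np.exp(-r2_ / w2)

    try:
        popt, _ = curve_fit(
            model,
            r2,
            z,
            p0=[max(z.max(), 1e-6), beam_waist_px**2],
            bounds=([0, 0.25 * beam_waist_px**2], [np.inf, 25 * beam_waist_px**2]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise ValueError("ICS QC failure: autocorrelation peak fit did not converge") from exc
    g0, w2 = popt
    if g0 <= 0 or not np.isfinite(g0):
        raise ValueError("ICS QC failure: non-positive autocorrelation amplitude")
    return float(1.0 / (g0 * np.pi * w2))


def bleach_fraction(stack) -> np.ndarray:
    """Surviving intensity fraction p_t per bleach round.

    p_t is the background-subtracted mean intensity of round t divided by
    round 0.  The background of each image is estimated by its median, which
    is robust to the sparse bright clusters; residual cluster-tail
    contamination of the median scales with the signal and so cancels in
    the round ratio.
    """
    rounds = np.asarray(stack.rounds, dtype=float)
    vals = np.array([img.mean() - np.median(img) for img in rounds])
    if vals[0] <= 0:
        raise ValueError("round-0 background-subtracted intensity must be > 0")
    p = vals / vals[0]
    if np.any(p < 0):
        warnings.warn("negative surviving fraction clipped to 0")
        p = np.clip(p, 0.0, None)
    return p


def bleach_curve_from_stack(stack, beam_waist_px: float | None = None) -> BleachCurve:
    """Measure (p, CD) across the rounds of a photobleach image series."""
    omega = beam_waist_px if beam_waist_px is not None else stack.beam_waist_px
    p = bleach_fraction(stack)
    cd = np.array([cluster_density(img, omega) for img in stack.rounds])
    order = np.argsort(p)[::-1]
    return BleachCurve(p[order], cd[order])


# ---------------------------------------------------------------------------
# Composition fitting
# ---------------------------------------------------------------------------


def fit_composition(
    curve: BleachCurve, j_max: int = DEFAULT_J_MAX, restarts: int = 20, seed=None
) -> CompositionFit:
    """Non-negative least-squares fit of species concentrations to a curve.

    Because the model curve equals A^2 p / (A + B p) with A = sum j c_j and
    B = sum j(j-1) c_j, a single bleach curve determines only (A, B): the
    8-concentration fit has an exactly flat 6-dimensional direction.  The
    multi-start bounded least squares determines the identified (A, B); the
    reported concentration vector is then the minimum-total-cluster-density
    representative of that (A, B) (a linear program), a parsimony tie-break
    that concentrates mass on the fewest clusters consistent with the curve.
    Under it, noiseless single-species curves are recovered exactly, while
    for genuine mixtures the per-size split (and any functional touching
    c_1, such as the monomer fraction) remains model-dependent — prefer the
    identified ``molecular_density`` and ``mean_oligomer_size``.
    """
    if curve.p.size < 3:
        raise ValueError("need at least 3 curve points to fit a composition")
    rng = np.random.default_rng(seed)
    scale = max(curve.cd.max(), 1e-12)

    def resid(c):
        return cd_model(np.clip(c, 1e-12, None), curve.p) - curve.cd

    best = None
    for i in range(max(restarts, 1)):
        if i == 0:
            c0 = np.full(j_max, scale / j_max)
        else:
            c0 = scale * rng.dirichlet(np.ones(j_max))
        res = least_squares(resid, np.clip(c0, 1e-9, None), bounds=(0, np.inf))
        if best is None or res.cost < best.cost:
            best = res
    c_ls = np.clip(best.x, 0.0, None)
    j = np.arange(1, j_max + 1)
    A = float((j * c_ls).sum())
    B = float((j * (j - 1) * c_ls).sum())
    c_hat = _parsimony_representative(A, B, j_max)
    if c_hat is None:
        c_hat = c_ls
    c_hat = np.clip(c_hat, 0.0, None)
    c_hat[c_hat < 1e-10 * scale] = 0.0
    resid_final = cd_model(np.clip(c_hat, 1e-12, None), curve.p) - curve.cd
    return CompositionFit(c_hat, residual_norm=float(np.linalg.norm(resid_final)))


def _parsimony_representative(A: float, B: float, j_max: int):
    """Minimum sum(c) composition with sum j c = A and sum j(j-1) c = B."""
    if A <= 0:
        return None
    j = np.arange(1, j_max + 1)
    res = linprog(
        c=np.ones(j_max),
        A_eq=np.vstack([j, j * (j - 1)]).astype(float),
        b_eq=np.array([A, B]),
        bounds=[(0, None)] * j_max,
        method="highs",
    )
    return res.x if res.success else None


def aggregate_replicates(fits: list[CompositionFit]) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD of normalised species fractions across replicate fits.

    SD is the population SD across replicates (ddof=0, so two fits at 0 and 1
    report 0.5), the convention for the cumulative average over repeated
    bleach curves per condition.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 replicate fits to aggregate")
    fr = np.stack([f.species_fractions for f in fits])
    return fr.mean(axis=0), fr.std(axis=0, ddof=0)
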