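"""Head-to-head polymer-chain geometry and oligomer-composition bookkeeping.

Ligand-free receptor oligomers are modelled as polymer chains built by
repeating a single head-to-head extracellular interface.  Because the
nearest-neighbour separation of the outer label site (DIII) exceeds that of
the inner site (DI), the chain curves in the membrane plane; this module
represents that curvature with a two-parameter circular-arc model (repeat
spacing and turn angle per repeat) and provides the conversion between
species-number and molecule-number oligomer fractions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_J_MAX = 8  # largest oligomer size fitted (monomer..octamer)

SITE_DIII = "DIII"
SITE_DI = "DI"

MODE_INTERNAL = "internal_1to1"
MODE_END = "end_2Nto2"


@dataclass(frozen=True)
class ChainGeometry:
    """Planar arc geometry of a head-to-head chain.

    Parameters
    ----------
    repeat_spacing_nm
        Nearest-neighbour label-site distance along the chain backbone (nm).
    turn_angle_deg
        In-plane angle between successive head-to-head repeats (degrees).
        Zero gives a straight chain.
    site_offset_nm
        Radial offset of the probed site from the chain backbone (nm);
        positive offsets move the site outward (DIII-like, larger
        nearest-neighbour spacing), and the DI site sits at the mirrored
        inward offset.
    """

    repeat_spacing_nm: float = 9.0
    turn_angle_deg: float = 22.0
    site_offset_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.repeat_spacing_nm <= 0:
            raise ValueError("repeat_spacing_nm must be > 0")
        if not (0 <= abs(self.turn_angle_deg) < 180):
            raise ValueError("turn_angle_deg must satisfy 0 <= |angle| < 180")

    @property
    def arc_radius_nm(self) -> float:
        """Radius R = s / (2 sin(theta/2)) of the backbone arc (inf if straight)."""
        theta = np.deg2rad(abs(self.turn_angle_deg))
        if theta == 0:
            return np.inf
        return self.repeat_spacing_nm / (2.0 * np.sin(theta / 2.0))

    def to_json(self) -> str:
        return json.dumps(
            {
                "repeat_spacing_nm": self.repeat_spacing_nm,
                "turn_angle_deg": self.turn_angle_deg,
                "site_offset_nm": self.site_offset_nm,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ChainGeometry":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class LabelingScheme:
    """Stochastic labelling of chain sites.

    ``internal_1to1`` labels every protomer site independently with
    probability ``p_label`` (a 1:1 binder at sub-saturating concentration,
    ~20% of receptors by default).  ``end_2Nto2`` places exactly one probe
    at each chain end (2N:2 stoichiometry, as for bivalent EGF bridging),
    so each chain contributes at most one labelled pair.
    """

    mode: str = MODE_INTERNAL
    p_label: float = 0.2

    def __post_init__(self) -> None:
        if self.mode not in (MODE_INTERNAL, MODE_END):
            raise ValueError(f"unknown labelling mode {self.mode!r}")
        if not (0.0 <= self.p_label <= 1.0):
            raise ValueError("p_label must be in [0, 1]")


@dataclass
class OligomerComposition:
    """Species-number fractions f_j over oligomer sizes j = 1..J_max."""

    fractions: np.ndarray

    def __init__(self, fractions: Iterable[float]):
        f = np.asarray(list(fractions), dtype=float)
        if f.ndim != 1 or f.size < 1:
            raise ValueError("fractions must be a non-empty 1-D sequence")
        if np.any(f < -1e-12):
            raise ValueError("fractions must be non-negative")
        total = f.sum()
        if total <= 0:
            raise ValueError("fractions must not be all zero")
        if abs(total - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1 (tolerance 1e-9)")
        self.fractions = np.clip(f, 0.0, None)

    @property
    def j_max(self) -> int:
        return self.fractions.size

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(1, self.j_max + 1)

    @classmethod
    def exponential(cls, rate: float = 1.0, j_max: int = DEFAULT_J_MAX) -> "OligomerComposition":
        """Approximately exponential species distribution, f_j ∝ exp(-rate*(j-1)),
        consistent with step-wise polymerisation."""
        j = np.arange(j_max)
        f = np.exp(-rate * j)
        return cls(f / f.sum())

    def to_csv(self, path) -> None:
        pd.DataFrame({"size": self.sizes, "fraction": self.fractions}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OligomerComposition":
        df = pd.read_csv(path)
        df = df.sort_values("size")
        return cls(df["fraction"].to_numpy())


def chain_site_positions(geometry: ChainGeometry, n: int, site: str = SITE_DIII) -> np.ndarray:
    """Planar coordinates (nm) of the n label sites of an n-chain.

    Sites are placed at successive angular steps of the turn angle on a
    circular arc; a zero turn angle degenerates to a straight line with the
    repeat spacing.  ``site`` selects the outward (DIII) or inward (DI)
    radial offset of the probed epitope.

    Returns an (n, 2) array; the chord between sites i and k on the backbone
    arc equals 2 R sin(|k-i| theta / 2).
    """
    n = int(n)
    if n < 1:
        raise ValueError("chain size n must be >= 1")
    if site not in (SITE_DIII, SITE_DI):
        raise ValueError(f"unknown site {site!r}")

    offset = geometry.site_offset_nm if site == SITE_DIII else -geometry.site_offset_nm
    theta = np.deg2rad(geometry.turn_angle_deg)
    idx = np.arange(n)

    if theta == 0.0:
        # straight-chain limit: sites on a line, offset perpendicular to it
        xy = np.column_stack([idx * geometry.repeat_spacing_nm, np.full(n, offset)])
    else:
        R = geometry.arc_radius_nm
        r_site = R + offset
        if r_site <= 0:
            raise ValueError("site offset exceeds arc radius; geometry degenerate")
        ang = idx * theta
        xy = np.column_stack([r_site * np.sin(ang), R - r_site * np.cos(ang)])
    return xy - xy[0]


def pairwise_separations(
    geometry: ChainGeometry,
    n: int,
    scheme: LabelingScheme,
    seed=None,
    site: str = SITE_DIII,
) -> np.ndarray:
    """Label-label distances (nm) contributed by one n-chain under a scheme.

    Internal 1:1 labelling draws a Bernoulli(p_label) label at every site and
    reports every unordered pair of labelled sites; 2N:2 end labelling
    reports the single end-to-end chord (none for a monomer).
    """
    pos = chain_site_positions(geometry, n, site=site)
    if scheme.mode == MODE_END:
        if n < 2:
            return np.empty(0)
        return np.array([float(np.hypot(*(pos[-1] - pos[0])))])

    rng = np.random.default_rng(seed)
    labelled = np.flatnonzero(rng.random(n) < scheme.p_label)
    if labelled.size < 2:
        return np.empty(0)
    sub = pos[labelled]
    d = sub[:, None, :] - sub[None, :, :]
    dist = np.sqrt((d**2).sum(-1))
    iu = np.triu_indices(labelled.size, k=1)
    return dist[iu]


def species_to_molecular(composition: OligomerComposition) -> np.ndarray:
    """Molecule-number fractions m_j = j f_j / sum_k k f_k.

    f_j is the fraction of *species* (assemblies) of size j; m_j is the
    fraction of *molecules* residing in assemblies of size j.
    """
    f = composition.fractions
    j = composition.sizes
    w = j * f
    total = w.sum()
    if total <= 0:
        raise ValueError("composition has zero molecular mass")
    return w / total


def molecular_to_species(m: Sequence[float]) -> OligomerComposition:
    """Inverse of :func:`species_to_molecular` (up to normalisation)."""
    m = np.asarray(m, dtype=float)
    if np.any(m < -1e-12) or m.sum() <= 0:
        raise ValueError("molecular fractions must be non-negative, not all zero")
    j = np.arange(1, m.size + 1)
    f = np.clip(m, 0.0, None) / j
    return OligomerComposition(f / f.sum())


def oligomer_resident_fraction(composition: OligomerComposition) -> float:
    """Fraction of molecules residing in species of size >= 2 (dimers and larger)."""
    return float(species_to_molecular(composition)[1:].sum())
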