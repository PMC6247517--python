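"""Energy functions for toy alchemical systems.

The alchemical mutation couples two end-state potentials V1 (the reference
ligand, lambda = 0) and V2 (the mutant, lambda = 1) linearly,

    V(lambda) = (1 - lambda) V1 + lambda V2,

with two refinements standard in alchemical work and adopted here:

* the 12-6 Lennard-Jones term of perturbed (appearing/disappearing) atoms is
  replaced by a separation-shifted soft-core form that stays finite as atoms
  overlap at intermediate lambda, avoiding the end-point catastrophe;
* electrostatics of appearing atoms are switched on only after lambda > 0.1,
  and those of disappearing atoms are switched off beyond lambda > 0.9, so the
  soft-core repulsion can resolve overlaps before charges act.

Atoms are tagged ``unperturbed`` (present in both end states), ``appearing``
(present only in V2) or ``disappearing`` (present only in V1); an
appearing-disappearing pair never interacts in either end state.  External
one-body wells carry their own end-state stiffnesses and interpolate linearly
in lambda, which is how a receptor site that exists for only one end state
(e.g. a salt-bridge partner of a phosphate being deleted) is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence, Union

import numpy as np

from .constants import COULOMB_KCAL

__all__ = [
    "AlchemicalTag",
    "InteractionParams",
    "HarmonicWell",
    "FlatBottomWell",
    "AlchemicalSystem",
    "EnergyBreakdown",
    "lj_energy",
    "coulomb_energy",
    "softcore_lj_energy",
    "elec_scaling",
    "system_energy",
    "combine_lb",
]

#: Default soft-core separation-shift parameter (dimensionless).
DEFAULT_SOFTCORE_ALPHA: float = 0.5

#: Default van der Waals truncation distance, Angstrom.
DEFAULT_VDW_CUTOFF: float = 12.0


class AlchemicalTag(Enum):
    """Alchemical state of an atom: which end-state potentials it enters."""

    UNPERTURBED = "unperturbed"
    APPEARING = "appearing"
    DISAPPEARING = "disappearing"


@dataclass(frozen=True)
class InteractionParams:
    """Nonbonded parameters of one atom.

    epsilon : LJ well depth, kcal/mol (>= 0)
    sigma : LJ diameter, Angstrom (> 0)
    charge : partial charge, e
    vdw_radius : hard-sphere radius used for pore profiling, Angstrom (> 0)
    """

    epsilon: float
    sigma: float
    charge: float = 0.0
    vdw_radius: float = 1.7

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.vdw_radius <= 0:
            raise ValueError(f"vdw_radius must be > 0, got {self.vdw_radius}")


def combine_lb(a: InteractionParams, b: InteractionParams) -> tuple[float, float]:
    """Lorentz-Berthelot combining rules: arithmetic sigma, geometric epsilon."""
    return math.sqrt(a.epsilon * b.epsilon), 0.5 * (a.sigma + b.sigma)


@dataclass(frozen=True)
class HarmonicWell:
    """Per-axis harmonic restraint with end-state stiffnesses.

    The stiffness along each axis interpolates linearly in lambda between
    ``k_initial`` (state 1) and ``k_final`` (state 2); a well belonging to only
    one end state uses a zero stiffness for the other.  Energy is
    0.5 * sum_axis k_axis(lambda) * (x_axis - c_axis)^2.
    """

    k_initial: tuple[float, float, float]
    k_final: tuple[float, float, float]
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(k < 0 for k in self.k_initial) or any(k < 0 for k in self.k_final):
            raise ValueError("harmonic force constants must be >= 0")

    def stiffness(self, lam: float) -> tuple[float, float, float]:
        return tuple(
            (1.0 - lam) * k1 + lam * k2
            for k1, k2 in zip(self.k_initial, self.k_final)
        )

    @classmethod
    def isotropic(
        cls,
        k_initial: float,
        k_final: Optional[float] = None,
        center: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "HarmonicWell":
        if k_final is None:
            k_final = k_initial
        return cls((k_initial,) * 3, (k_final,) * 3, tuple(center))


@dataclass(frozen=True)
class FlatBottomWell:
    """Lambda-independent flat-bottom confinement.

    Zero inside ``radius`` of the center, harmonic (0.5 k (d - radius)^2)
    outside.  radius = 0 reduces to an isotropic harmonic well.
    """

    k: float
    radius: float
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("flat-bottom force constant must be >= 0")
        if self.radius < 0:
            raise ValueError("flat-bottom radius must be >= 0")


Well = Union[HarmonicWell, FlatBottomWell]


@dataclass
class AlchemicalSystem:
    """A toy alchemical system: particles, parameters, tags and wells.

    coordinates : (n, 3) reference coordinates, Angstrom
    params : per-atom nonbonded parameters
    tags : per-atom alchemical tags
    wells : per-atom list of external wells (may be empty)
    mobile : per-atom flag; immobile atoms are frozen at their reference
        coordinates (they still interact -- they stand in for a rigid
        receptor site)
    box : optional periodic box lengths (3,), Angstrom; minimum-image
        convention applied to pair distances when set
    cutoff : optional vdW truncation distance, Angstrom (plain truncation);
        None disables truncation (the default for toy systems, which use
        direct sums)
    alpha : soft-core shift parameter
    """

    coordinates: np.ndarray
    params: list[InteractionParams]
    tags: list[AlchemicalTag]
    wells: list[list[Well]] = field(default_factory=list)
    mobile: list[bool] = field(default_factory=list)
    box: Optional[np.ndarray] = None
    cutoff: Optional[float] = None
    alpha: float = DEFAULT_SOFTCORE_ALPHA
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        n = len(self.coordinates)
        if len(self.params) != n or len(self.tags) != n:
            raise ValueError(
                f"coordinates ({n}), params ({len(self.params)}) and tags "
                f"({len(self.tags)}) must have the same length"
            )
        if not self.wells:
            self.wells = [[] for _ in range(n)]
        if len(self.wells) != n:
            raise ValueError("wells must have one (possibly empty) list per atom")
        if not self.mobile:
            self.mobile = [True] * n
        if len(self.mobile) != n:
            raise ValueError("mobile must have one flag per atom")
        if not self.labels:
            self.labels = [f"X{i}" for i in range(n)]
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise ValueError("box lengths must be positive")
        if self.alpha <= 0:
            raise ValueError("softcore alpha must be > 0")

    @property
    def n_atoms(self) -> int:
        return len(self.coordinates)

    @property
    def mobile_indices(self) -> list[int]:
        return [i for i, m in enumerate(self.mobile) if m]

    def is_perturbed(self) -> bool:
        """True if any atom is tagged or any well is lambda-dependent."""
        if any(t is not AlchemicalTag.UNPERTURBED for t in self.tags):
            return True
        for wl in self.wells:
            for w in wl:
                if isinstance(w, HarmonicWell) and w.k_initial != w.k_final:
                    return True
        return False


@dataclass(frozen=True)
class EnergyBreakdown:
    """Exact bookkeeping decomposition: total = elec + vdw + external."""

    total: float
    elec: float
    vdw: float
    external: float


def _check_lambda(lam: float) -> None:
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")


def lj_energy(
    r: float,
    params: tuple[InteractionParams, InteractionParams],
    cutoff: Optional[float] = None,
) -> float:
    """Plain 12-6 Lennard-Jones energy of a pair at separation r.

    4 eps [(sigma/r)^12 - (sigma/r)^6] with Lorentz-Berthelot combined
    parameters; truncated to zero beyond ``cutoff`` when one is given.
    """
    if r <= 0:
        raise ValueError(f"pair distance must be positive, got {r}")
    if cutoff is not None and r > cutoff:
        return 0.0
    eps, sig = combine_lb(*params)
    x = (sig / r) ** 6
    return 4.0 * eps * (x * x - x)


def coulomb_energy(r: float, q1: float, q2: float, scale: float = 1.0) -> float:
    """Coulomb energy C q1 q2 / r, scaled by a switching factor in [0, 1]."""
    if r <= 0:
        raise ValueError(f"pair distance must be positive, got {r}")
    if not 0.0 <= scale <= 1.0:
        raise ValueError(f"scale must lie in [0, 1], got {scale}")
    return scale * COULOMB_KCAL * q1 * q2 / r


def softcore_lj_energy(
    r: float,
    lam: float,
    params: tuple[InteractionParams, InteractionParams],
    alpha: float = DEFAULT_SOFTCORE_ALPHA,
    cutoff: Optional[float] = None,
) -> float:
    """Separation-shifted soft-core 12-6 Lennard-Jones energy.

    V = 4 eps lam [ (sigma^6 / (alpha (1-lam) sigma^6 + r^6))^2
                    - sigma^6 / (alpha (1-lam) sigma^6 + r^6) ] * sigma^6-scaled

    i.e. r^6 is shifted by alpha (1-lam) sigma^6 and the whole interaction is
    scaled by lam.  Finite at r = 0 for lam < 1; identical to ``lj_energy`` at
    lam = 1; zero at lam = 0.
    """
    _check_lambda(lam)
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if r < 0:
        raise ValueError(f"pair distance must be >= 0, got {r}")
    if lam == 0.0:
        return 0.0
    if cutoff is not None and r > cutoff:
        return 0.0
    eps, sig = combine_lb(*params)
    sig6 = sig**6
    denom = alpha * (1.0 - lam) * sig6 + r**6
    if denom == 0.0:
        return math.inf
    s = sig6 / denom
    return 4.0 * eps * lam * (s * s - s)


def elec_scaling(lam: float, tag: AlchemicalTag) -> float:
    """Electrostatic switching factor for one atom at coupling lambda.

    Appearing atoms: off until lambda = 0.1, then linear to 1 at lambda = 1.
    Disappearing atoms: 1 at lambda = 0, linear to 0 at lambda = 0.9, then off.
    Unperturbed atoms: always 1.
    """
    _check_lambda(lam)
    if tag is AlchemicalTag.UNPERTURBED:
        return 1.0
    if tag is AlchemicalTag.APPEARING:
        return min(1.0, max(0.0, (lam - 0.1) / 0.9))
    # disappearing
    return min(1.0, max(0.0, 1.0 - lam / 0.9))


# ---------------------------------------------------------------------------
# compiled per-window interaction tables
# ---------------------------------------------------------------------------


def _pair_lambda_eff(t1: AlchemicalTag, t2: AlchemicalTag, lam: float) -> Optional[float]:
    """Effective vdW coupling of a pair, or None if the pair never interacts."""
    tags = {t1, t2}
    if AlchemicalTag.APPEARING in tags and AlchemicalTag.DISAPPEARING in tags:
        return None
    if AlchemicalTag.APPEARING in tags:
        return lam
    if AlchemicalTag.DISAPPEARING in tags:
        return 1.0 - lam
    return 1.0


@dataclass
class WindowContext:
    """Interaction tables of a system frozen at one lambda.

    pairs : tuples (i, j, qq, eps4, shift, sig6, cutoff2) where
        qq = C q_i q_j * elec scalings (kcal A / mol),
        eps4 = 4 eps_ij lam_eff, shift = alpha (1 - lam_eff) sigma_ij^6,
        cutoff2 = squared vdW truncation or None.
    harmonic : tuples (i, kx, ky, kz, cx, cy, cz) at this lambda.
    flat : tuples (i, k, radius, cx, cy, cz).
    """

    lam: float
    pairs: list[tuple]
    harmonic: list[tuple]
    flat: list[tuple]
    box: Optional[np.ndarray]

    def atom_terms(self, a: int):
        """Terms involving atom ``a`` (for Metropolis single-move deltas)."""
        pairs = [p for p in self.pairs if p[0] == a or p[1] == a]
        # orient so the partner index comes first in the tuple tail
        orient = [
            (p[1] if p[0] == a else p[0], p[2], p[3], p[4], p[5], p[6])
            for p in pairs
        ]
        harm = [h[1:] for h in self.harmonic if h[0] == a]
        flat = [f[1:] for f in self.flat if f[0] == a]
        return orient, harm, flat


def compile_window(system: AlchemicalSystem, lam: float) -> WindowContext:
    """Precompute pair and well coefficient tables at a fixed lambda."""
    _check_lambda(lam)
    n = system.n_atoms
    cutoff2 = None if system.cutoff is None else system.cutoff**2
    pairs: list[tuple] = []
    for i in range(n):
        pi, ti = system.params[i], system.tags[i]
        si = elec_scaling(lam, ti)
        for j in range(i + 1, n):
            pj, tj = system.params[j], system.tags[j]
            lam_eff = _pair_lambda_eff(ti, tj, lam)
            if lam_eff is None:
                continue
            eps, sig = combine_lb(pi, pj)
            sig6 = sig**6
            qq = COULOMB_KCAL * pi.charge * pj.charge * si * elec_scaling(lam, tj)
            eps4 = 4.0 * eps * lam_eff
            shift = system.alpha * (1.0 - lam_eff) * sig6
            if qq == 0.0 and eps4 == 0.0:
                continue
            pairs.append((i, j, qq, eps4, shift, sig6, cutoff2))
    harmonic: list[tuple] = []
    flat: list[tuple] = []
    for i, well_list in enumerate(system.wells):
        for w in well_list:
            if isinstance(w, HarmonicWell):
                kx, ky, kz = w.stiffness(lam)
                if kx or ky or kz:
                    harmonic.append((i, kx, ky, kz, *w.center))
            else:
                if w.k:
                    flat.append((i, w.k, w.radius, *w.center))
    return WindowContext(lam=lam, pairs=pairs, harmonic=harmonic, flat=flat, box=system.box)


def _min_image(d: np.ndarray, box: Optional[np.ndarray]) -> np.ndarray:
    if box is None:
        return d
    return d - box * np.round(d / box)


def context_energy(ctx: WindowContext, coords: np.ndarray) -> EnergyBreakdown:
    """Energy breakdown of one configuration under a compiled context."""
    coords = np.asarray(coords, dtype=float)
    elec = 0.0
    vdw = 0.0
    for (i, j, qq, eps4, shift, sig6, cutoff2) in ctx.pairs:
        d = _min_image(coords[i] - coords[j], ctx.box)
        r2 = float(d @ d)
        if qq != 0.0:
            if r2 == 0.0:
                raise ValueError(f"atoms {i} and {j} coincide with nonzero charges")
            elec += qq / math.sqrt(r2)
        if eps4 != 0.0 and (cutoff2 is None or r2 <= cutoff2):
            denom = shift + r2 * r2 * r2
            if denom == 0.0:
                vdw += math.inf
            else:
                s = sig6 / denom
                vdw += eps4 * (s * s - s)
    ext = 0.0
    for (i, kx, ky, kz, cx, cy, cz) in ctx.harmonic:
        dx, dy, dz = coords[i, 0] - cx, coords[i, 1] - cy, coords[i, 2] - cz
        ext += 0.5 * (kx * dx * dx + ky * dy * dy + kz * dz * dz)
    for (i, k, radius, cx, cy, cz) in ctx.flat:
        dx, dy, dz = coords[i, 0] - cx, coords[i, 1] - cy, coords[i, 2] - cz
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        if d > radius:
            ext += 0.5 * k * (d - radius) ** 2
    return EnergyBreakdown(total=elec + vdw + ext, elec=elec, vdw=vdw, external=ext)


def frames_energy(
    ctx: WindowContext, frames: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (elec, vdw, external) over a stack of frames (F, n, 3)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must have shape (F, n, 3)")
    F = frames.shape[0]
    elec = np.zeros(F)
    vdw = np.zeros(F)
    ext = np.zeros(F)
    for (i, j, qq, eps4, shift, sig6, cutoff2) in ctx.pairs:
        d = frames[:, i, :] - frames[:, j, :]
        if ctx.box is not None:
            d = _min_image(d, ctx.box)
        r2 = np.einsum("ij,ij->i", d, d)
        if qq != 0.0:
            elec += qq / np.sqrt(r2)
        if eps4 != 0.0:
            s = sig6 / (shift + r2 * r2 * r2)
            term = eps4 * (s * s - s)
            if cutoff2 is not None:
                term = np.where(r2 <= cutoff2, term, 0.0)
            vdw += term
    for (i, kx, ky, kz, cx, cy, cz) in ctx.harmonic:
        d = frames[:, i, :] - np.array([cx, cy, cz])
        ext += 0.5 * (kx * d[:, 0] ** 2 + ky * d[:, 1] ** 2 + kz * d[:, 2] ** 2)
    for (i, k, radius, cx, cy, cz) in ctx.flat:
        d = np.linalg.norm(frames[:, i, :] - np.array([cx, cy, cz]), axis=1)
        excess = np.maximum(0.0, d - radius)
        ext += 0.5 * k * excess**2
    return elec, vdw, ext


def system_energy(
    system: AlchemicalSystem,
    coordinates: Optional[np.ndarray] = None,
    lam: float = 0.0,
) -> EnergyBreakdown:
    """Total energy and exact (elec, vdw, external) decomposition at lambda.

    Unperturbed-unperturbed pairs are lambda-independent; pairs involving
    perturbed atoms use the soft-core vdW form and the staged electrostatic
    switching.  ``coordinates`` defaults to the system's reference coordinates.
    """
    if coordinates is None:
        coordinates = system.coordinates
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape != (system.n_atoms, 3):
        raise ValueError(
            f"coordinates shape {coordinates.shape} does not match system size "
            f"({system.n_atoms}, 3)"
        )
    return context_energy(compile_window(system, lam), coordinates)
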