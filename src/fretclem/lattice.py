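"""Geometric FRET simulation in a clathrin lattice.

A donor fluorophore on one clathrin light chain can transfer energy to
acceptor-labelled light chains bound to the surrounding heavy chains.  Each
heavy-chain binding site is in one of four states — empty, endogenous light
chain, donor-labelled (EGFP) light chain, or acceptor-labelled (ShadowY)
light chain — and only the acceptor-bearing state quenches the donor.  The
occupancy (acceptor-bearing fraction of sites) therefore fully determines
the per-site acceptor probability, and sites are treated as independent
Bernoulli draws.

For a fixed configuration of occupied sites, transfer rates to independent
acceptors add:  E = S / (1 + S) with S = sum_i (R0 / r_i)^6 over occupied
sites, r_i the donor-site distance and R0 the Förster radius (60 Å for
EGFP–ShadowY).  The expected lattice efficiency averages E over all 2^n
site configurations weighted binomially by occupancy.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "LatticeScene",
    "OccupancyModel",
    "PositionScan",
    "occupancy_fraction",
    "multi_acceptor_efficiency",
    "expected_lattice_efficiency",
    "scan_nterm_positions",
    "pentagon_sites",
]

#: Förster radius of the EGFP–ShadowY pair, Å
DEFAULT_R0_A = 60.0

#: exact enumeration refuses beyond this many sites (2^n configurations)
MAX_EXACT_SITES = 20


def pentagon_sites(radius: float = 70.0, z: float = 0.0) -> np.ndarray:
    """Reference geometry: five acceptor sites (the surrounding heavy
    chains) at the vertices of a regular pentagon of the given radius (Å),
    centered on the origin in the plane at height ``z``."""
    ang = 2.0 * np.pi * np.arange(5) / 5.0
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.full(5, float(z))])


@dataclass
class LatticeScene:
    """Donor position, acceptor site coordinates (Å) and Förster radius."""

    donor_position: np.ndarray
    acceptor_sites: np.ndarray
    R0: float = DEFAULT_R0_A
    donor_tau: float = 2.6  # ns, unquenched donor lifetime

    def __post_init__(self):
        self.donor_position = np.asarray(self.donor_position, dtype=float).reshape(3)
        self.acceptor_sites = np.atleast_2d(np.asarray(self.acceptor_sites, float))
        if self.acceptor_sites.shape[1] != 3 or len(self.acceptor_sites) == 0:
            raise InvalidParameterError("acceptor_sites must be a non-empty (n, 3)")
        if self.R0 <= 0:
            raise InvalidParameterError("R0 must be positive")
        if not (np.isfinite(self.donor_position).all()
                and np.isfinite(self.acceptor_sites).all()):
            raise InvalidParameterError("coordinates must be finite")

    @property
    def n_sites(self) -> int:
        return len(self.acceptor_sites)

    def site_distances(self) -> np.ndarray:
        """Donor-to-site distances (Å)."""
        return np.linalg.norm(self.acceptor_sites - self.donor_position, axis=1)


@dataclass(frozen=True)
class OccupancyModel:
    """Probabilities of the four heavy-chain light-chain binding states."""

    p_none: float
    p_endogenous: float
    p_egfp: float
    p_shadowy: float

    def __post_init__(self):
        probs = (self.p_none, self.p_endogenous, self.p_egfp, self.p_shadowy)
        if any(p < 0 for p in probs):
            raise InvalidParameterError("state probabilities must be >= 0")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise InvalidParameterError("state probabilities must sum to 1")

    @property
    def acceptor_occupancy(self) -> float:
        return self.p_shadowy


@dataclass(frozen=True)
class PositionScan:
    """Lateral scan of the donor (light-chain N-terminus) position.

    The N-terminus is stepped on a lateral grid (default spacing 0.6 Å)
    at a fixed axial offset above the reference plane (default 25 Å, the
    assumed N- over C-terminus height).
    """

    lateral_spacing: float = 0.6
    axial_offset: float = 25.0
    lateral_bounds: tuple[float, float] = (-30.0, 30.0)

    def __post_init__(self):
        if self.lateral_spacing <= 0:
            raise InvalidParameterError("lateral_spacing must be positive")
        lo, hi = self.lateral_bounds
        if not hi > lo:
            raise InvalidParameterError("lateral_bounds must be a non-empty box")

    def grid_1d(self) -> np.ndarray:
        lo, hi = self.lateral_bounds
        n = int(math.floor((hi - lo) / self.lateral_spacing)) + 1
        return lo + self.lateral_spacing * np.arange(n)


def occupancy_fraction(weights) -> float:
    """Acceptor-bearing fraction of heavy-chain sites.

    ``weights`` are the four state weights (counts, concentrations or
    probabilities) ordered (none, endogenous, egfp, shadowy); the result is
    shadowy / total.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (4,):
        raise InvalidParameterError("expected four state weights")
    if np.any(w < 0):
        raise InvalidParameterError("weights must be >= 0")
    total = w.sum()
    if total <= 0:
        raise InvalidParameterError("weights must not all be zero")
    return float(w[3] / total)


def multi_acceptor_efficiency(scene: LatticeScene, occupied_site_mask) -> float:
    """FRET efficiency of the donor for one configuration of occupied sites.

    Transfer rates to independent acceptors add:  E = S / (1 + S) with
    S = sum over occupied sites of (R0 / r_i)^6.  A donor coincident with
    an occupied site gives E = 1 with a degenerate-geometry warning.
    """
    mask = np.asarray(occupied_site_mask, dtype=bool)
    if mask.shape != (scene.n_sites,):
        raise InvalidParameterError(
            f"mask length {mask.shape} must match n_sites {scene.n_sites}"
        )
    if not mask.any():
        return 0.0
    r = scene.site_distances()[mask]
    if np.any(r == 0):
        warnings.warn("donor coincident with an occupied acceptor site",
                      RuntimeWarning, stacklevel=2)
        return 1.0
    S = float(np.sum((scene.R0 / r) ** 6))
    return S / (1.0 + S)


def _config_efficiencies(scene: LatticeScene) -> tuple[np.ndarray, np.ndarray]:
    """Efficiency and occupied-site count for every 2^n configuration."""
    n = scene.n_sites
    r = scene.site_distances()
    rates = (scene.R0 / np.where(r == 0, np.inf, r)) ** 6
    masks = np.array(list(itertools.product((0, 1), repeat=n)), dtype=bool)
    S = masks @ rates
    eff = S / (1.0 + S)
    eff[masks[:, r == 0].any(axis=1) if np.any(r == 0) else np.zeros(len(masks), bool)] = 1.0
    return eff, masks.sum(axis=1)


def expected_lattice_efficiency(
    scene: LatticeScene,
    occ: OccupancyModel | float,
    monte_carlo: int | None = None,
    seed: int = 0,
) -> float:
    """Occupancy-averaged FRET efficiency of the donor.

    Sites carry an acceptor independently with probability equal to the
    acceptor occupancy; the expectation enumerates all 2^n configurations
    exactly (binomial weights) and averages their efficiencies.  Monotone
    non-decreasing in occupancy.  For more than 20 sites exact enumeration
    is refused; pass ``monte_carlo=<n draws>`` instead.
    """
    p = occ.acceptor_occupancy if isinstance(occ, OccupancyModel) else float(occ)
    if not (0.0 <= p <= 1.0):
        raise InvalidParameterError("occupancy must be in [0, 1]")
    if monte_carlo is not None:
        rng = np.random.default_rng(seed)
        r = scene.site_distances()
        rates = (scene.R0 / np.where(r == 0, np.inf, r)) ** 6
        masks = rng.random((int(monte_carlo), scene.n_sites)) < p
        S = masks @ rates
        return float(np.mean(S / (1.0 + S)))
    if scene.n_sites > MAX_EXACT_SITES:
        raise InvalidParameterError(
            f"{scene.n_sites} sites exceeds exact-enumeration limit "
            f"{MAX_EXACT_SITES}; pass monte_carlo=<n draws>"
        )
    eff, k = _config_efficiencies(scene)
    n = scene.n_sites
    if p == 0.0:
        w = (k == 0).astype(float)
    elif p == 1.0:
        w = (k == n).astype(float)
    else:
        w = np.exp(k * math.log(p) + (n - k) * math.log1p(-p))
    return float(np.dot(w, eff))


def scan_nterm_positions(
    scene_template: LatticeScene,
    scan: PositionScan,
    occ: OccupancyModel | float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expected efficiency map over a lateral grid of donor positions.

    The donor (light-chain N-terminus) is placed at each (x, y) grid point
    at ``scan.axial_offset`` above the acceptor reference plane; the map
    shows how the expected lattice FRET efficiency varies with the lateral
    N-terminus position.

    Returns ``(xs, ys, eff_map)`` with ``eff_map[j, i]`` the efficiency at
    (xs[i], ys[j]).
    """
    xs = scan.grid_1d()
    ys = scan.grid_1d()
    z_plane = float(scene_template.acceptor_sites[:, 2].mean())
    eff = np.empty((len(ys), len(xs)))
    for j, y in enumerate(ys):
        for i, x in enumerate(xs):
            scene = replace(
                scene_template,
                donor_position=np.array([x, y, z_plane + scan.axial_offset]),
            )
            eff[j, i] = expected_lattice_efficiency(scene, occ)
    return xs, ys, eff
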