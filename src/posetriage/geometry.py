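"""Shared geometric primitives: van der Waals radii, deterministic sphere
point sets, and solvent-accessible surface area (SASA).

SASA uses Shrake-Rupley quadrature over a Fibonacci-spiral point set, which
is deterministic for a fixed point count (no random rotations), so repeated
runs are bit-identical.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass
from scipy.spatial import cKDTree

from .errors import ContractError, NumericError

#: Consensus van der Waals radii in Angstrom (Bondi-class table).
VDW_RADII: dict[str, float] = {
    "H": 1.10,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}

DEFAULT_VDW = 1.70
DEFAULT_PROBE = 1.4
DEFAULT_SASA_POINTS = 960


def vdw_radius(element: str) -> float:
    """Van der Waals radius for an element symbol (case-normalized)."""
    return VDW_RADII.get(element.capitalize(), DEFAULT_VDW)


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors on the sphere via the golden spiral.

    Deterministic: the same ``n`` always yields the same array.
    """
    if n < 1:
        raise ContractError("fibonacci_sphere needs n >= 1")
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class SASAResult:
    """Per-atom solvent-accessible surface areas in Angstrom^2."""

    areas: np.ndarray
    probe_radius: float
    n_points: int = DEFAULT_SASA_POINTS

    @property
    def total(self) -> float:
        return float(self.areas.sum())


def compute_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_SASA_POINTS,
) -> SASAResult:
    """Shrake-Rupley SASA over a deterministic spherical point set.

    Each atom is expanded by the probe radius; quadrature points on the
    expanded sphere count as accessible when they lie outside every
    neighbouring expanded sphere.  Total SASA of a set is the sum of the
    per-atom values.

    Raises
    ------
    NumericError
        If two atoms share (near-)coincident coordinates.
    ContractError
        If a radius is non-positive or ``n_points`` < 100.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float).reshape(-1)
    if coords.shape[0] != radii.shape[0]:
        raise ContractError("coords and radii length mismatch")
    if np.any(radii <= 0):
        raise ContractError("all radii must be positive")
    if n_points < 100:
        raise ContractError("n_points must be >= 100 for usable quadrature")

    n = coords.shape[0]
    if n == 0:
        return SASAResult(np.zeros(0), probe, n_points)

    tree = cKDTree(coords)
    close = tree.query_pairs(1e-3)
    if close:
        i, j = sorted(close)[0]
        raise NumericError(f"coincident atom coordinates: atoms {i} and {j}")

    sphere = fibonacci_sphere(n_points)
    expanded = radii + probe
    areas = np.empty(n)
    for i in range(n):
        ri = expanded[i]
        pts = coords[i] + ri * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], ri + expanded.max()) if j != i]
        if neighbors:
            nb = np.array(neighbors)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * ri * ri * frac
    return SASAResult(areas, probe, n_points)


def rigid_transform(rotation: np.ndarray, translation: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Apply ``R x + t`` to an (n, 3) coordinate array."""
    return coords @ np.asarray(rotation).T + np.asarray(translation)


def validate_rotation(rotation: np.ndarray, tol: float = 1e-6) -> None:
    """Raise ContractError unless ``rotation`` is a proper rotation matrix."""
    r = np.asarray(rotation, dtype=float)
    if r.shape != (3, 3):
        raise ContractError("rotation must be 3x3")
    if not np.allclose(r @ r.T, np.eye(3), atol=tol):
        raise ContractError("rotation is not orthonormal")
    if abs(np.linalg.det(r) - 1.0) > 1e-4:
        raise ContractError("rotation determinant must be +1")
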