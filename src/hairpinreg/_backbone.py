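"""Low-level synthetic backbone construction.

Two construction styles are used by the generators:

* dihedral-driven chains (NeRF extension with ideal bond lengths/angles)
  for extended strands and random coils, and
* direct template placement for antiparallel strand pairs, where every
  backbone atom is positioned so that cross-strand N-O hydrogen bonds land
  exactly on the requested ladder rungs and nowhere else.

Only N, CA, C, O are produced; every in-pipeline metric is backbone-driven.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

# ideal backbone internal coordinates (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANG_C_N_CA = 121.7
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_CA_C_O = 120.8

# antiparallel strand-pair template parameters (Å)
STRAND_STEP = 3.65       # along-strand CA spacing (x)
STRAND_SEP = 5.83        # inter-strand CA separation (y)
PLEAT = 0.4              # alternating CA z displacement
N_IN, C_IN, O_EXTRA = 1.00, 0.80, 1.23   # rung-side lateral offsets
N_OUT, C_OUT = 0.60, 0.55                # non-rung (away) offsets
# resulting rung N-O distance: STRAND_SEP - N_IN - (C_IN + O_EXTRA) = 2.80


def nerf_place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d given three predecessors and internal coordinates."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(dihedral),
            bond * math.sin(angle) * math.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def chain_from_dihedrals(
    phi: np.ndarray, psi: np.ndarray, omega: np.ndarray | float = 180.0
) -> dict[str, np.ndarray]:
    """Backbone coordinates for a chain with the given (phi, psi, omega).

    ``phi[0]`` and ``psi[-1]`` have no structural effect on the chain but
    ``psi[-1]`` still orients the final carbonyl.  Returns arrays of shape
    (n, 3) for N, CA, C, O.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n_res = len(phi)
    if len(psi) != n_res:
        raise ValueError("phi and psi must have equal length")
    if np.isscalar(omega) or isinstance(omega, float):
        omega = np.full(n_res, float(omega))

    n_pos = np.zeros((n_res, 3))
    ca_pos = np.zeros((n_res, 3))
    c_pos = np.zeros((n_res, 3))
    o_pos = np.zeros((n_res, 3))

    n_pos[0] = (0.0, 0.0, 0.0)
    ca_pos[0] = (BOND_N_CA, 0.0, 0.0)
    ang = math.radians(ANG_N_CA_C)
    c_pos[0] = ca_pos[0] + BOND_CA_C * np.array(
        (-math.cos(ang), math.sin(ang), 0.0)
    )
    for i in range(1, n_res):
        n_pos[i] = nerf_place(
            n_pos[i - 1], ca_pos[i - 1], c_pos[i - 1],
            BOND_C_N, ANG_CA_C_N, psi[i - 1],
        )
        ca_pos[i] = nerf_place(
            ca_pos[i - 1], c_pos[i - 1], n_pos[i],
            BOND_N_CA, ANG_C_N_CA, omega[i - 1],
        )
        c_pos[i] = nerf_place(
            c_pos[i - 1], n_pos[i], ca_pos[i],
            BOND_CA_C, ANG_N_CA_C, phi[i],
        )
    for i in range(n_res):
        o_pos[i] = nerf_place(
            n_pos[i], ca_pos[i], c_pos[i],
            BOND_C_O, ANG_CA_C_O, psi[i] - 180.0,
        )
    return {"N": n_pos, "CA": ca_pos, "C": c_pos, "O": o_pos}


@dataclass
class PlacedResidue:
    """Backbone atom positions for one residue."""

    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"N": self.n, "CA": self.ca, "C": self.c, "O": self.o}


def strand_residue(
    x: float, y: float, direction: int, rung: bool, toward: int,
    origin: np.ndarray | None = None, pleat_sign: int | None = None,
) -> PlacedResidue:
    """One residue of an ideal (flat, pleated) beta strand along x.

    ``direction`` is the chain N->C sense along x (+1/-1); ``toward`` is the
    y-sense of the partner strand.  On a ladder ``rung`` the amide and
    carbonyl point toward the partner with larger lateral offsets, so the
    intended cross-strand N-O pairs sit at 2.8 Å while every other
    cross-strand heavy-atom pair stays beyond ~4.3 Å.
    """
    base = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    if rung:
        n_off, c_off = N_IN * toward, C_IN * toward
    else:
        n_off, c_off = -N_OUT * toward, -C_OUT * toward
    if pleat_sign is None:
        pleat_sign = 1 if rung else -1
    ca = base + np.array([x, y, PLEAT * pleat_sign])
    n = base + np.array([x - 1.2 * direction, y + n_off, 0.0])
    c = base + np.array([x + 1.05 * direction, y + c_off, 0.0])
    o = c + np.array([0.0, math.copysign(O_EXTRA, n_off), 0.0])
    return PlacedResidue(n=n, ca=ca, c=c, o=o)


def solve_arc_angle(n_steps: int, chord: float, step: float,
                    tol: float = 1e-12) -> float:
    """Total subtended angle of an inscribed equal-chord polyline.

    ``n_steps`` chords of length ``step`` connect two circle points a
    straight-line distance ``chord`` apart: chord = 2R sin(theta/2) with
    step = 2R sin(theta/(2 n_steps)).  The ratio sin(theta/2) /
    sin(theta/(2 n_steps)) decreases monotonically from n_steps to 0 on
    (0, 2 pi), so bisection applies.
    """
    if chord >= n_steps * step:
        raise ValueError("not enough steps to span the chord")
    ratio = chord / step

    def f(theta: float) -> float:
        return math.sin(theta / 2) / math.sin(theta / (2 * n_steps)) - ratio

    lo, hi = 1e-9, 2 * math.pi - 1e-9
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def arc_points(
    p0: np.ndarray, p1: np.ndarray, n_points: int,
    lift: np.ndarray, step: float = 3.8,
) -> np.ndarray:
    """CA positions for ``n_points`` residues on a circular arc from p0 to p1.

    The arc lies in the plane spanned by the chord and ``lift`` (bulge
    direction); successive positions -- including the two endpoints, which
    are not returned -- are exactly ``step`` apart in a straight line.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    chord_vec = p1 - p0
    chord = float(np.linalg.norm(chord_vec))
    if chord < 1e-9:
        raise ValueError("arc endpoints coincide")
    w = chord_vec / chord
    u = np.asarray(lift, dtype=float)
    u = u - (u @ w) * w
    norm = np.linalg.norm(u)
    if norm < 1e-9:
        raise ValueError("lift direction parallel to chord")
    u /= norm

    n_steps = n_points + 1
    theta = solve_arc_angle(n_steps, chord, step)
    radius = step / (2 * math.sin(theta / (2 * n_steps)))
    mid = 0.5 * (p0 + p1)
    center = mid - radius * math.cos(theta / 2) * u

    pts = np.empty((n_points, 3))
    for k in range(1, n_steps):
        ang = math.pi / 2 + (theta / 2) * (1 - 2 * k / n_steps)
        pts[k - 1] = center + radius * (math.cos(ang) * w + math.sin(ang) * u)
    return pts


def backbone_from_ca_path(
    ca: np.ndarray,
    prev_ca: np.ndarray,
    next_ca: np.ndarray,
    outward: np.ndarray,
) -> list[PlacedResidue]:
    """Place N, C, O around loop CA positions.

    ``prev_ca``/``next_ca`` anchor the tangents at the path ends; carbonyls
    and amides point along ``outward`` (component orthogonal to the local
    tangent) so loop atoms stay clear of nearby strand hydrogen-bond
    partners.
    """
    ca = np.atleast_2d(np.asarray(ca, dtype=float))
    full = np.vstack([prev_ca, ca, next_ca])
    out: list[PlacedResidue] = []
    for k in range(1, len(full) - 1):
        t = full[k + 1] - full[k - 1]
        t /= np.linalg.norm(t)
        n_dir = np.asarray(outward, dtype=float)
        n_dir = n_dir - (n_dir @ t) * t
        nn = np.linalg.norm(n_dir)
        if nn < 1e-9:
            # tangent parallel to outward: fall back to any perpendicular
            n_dir = np.cross(t, [0.0, 0.0, 1.0])
            if np.linalg.norm(n_dir) < 1e-9:
                n_dir = np.cross(t, [0.0, 1.0, 0.0])
            nn = np.linalg.norm(n_dir)
        n_dir /= nn
        p = full[k]
        n = p - 1.2 * t + 0.7 * n_dir
        c = p + 1.05 * t + 0.7 * n_dir
        o = c + O_EXTRA * n_dir
        out.append(PlacedResidue(n=n, ca=p, c=c, o=o))
    return out
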