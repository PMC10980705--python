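"""Per-frame geometric primitives.

Backbone hydrogen-bond detection (heavy-atom N-O distance criterion),
secondary-structure assignment (Kabsch-Sander hydrogen-bond patterns plus a
dihedral rule for isolated extended strands), deterministic Shrake-Rupley
solvent-accessible surface area, and Kabsch superposition RMSD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Conformer

__all__ = [
    "HBond",
    "SASAProfile",
    "detect_backbone_hbonds",
    "assign_secondary_structure",
    "compute_sasa",
    "kabsch_rmsd",
    "reconstruct_amide_hydrogens",
    "backbone_dihedrals",
    "ATOMIC_RADII",
]

HBOND_CUTOFF = 3.5          # Å, heavy-atom N-O
MIN_SEQUENCE_SEPARATION = 2  # |donor - acceptor| >= 2

#: fixed van der Waals radii (Å) for SASA; H ignored by default
ATOMIC_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

# Kabsch-Sander electrostatic H-bond model: E = q1*q2*332*(1/rON + 1/rCH
# - 1/rOH - 1/rCN) with q1*q2 = 0.42*0.20 -> prefactor 0.084*332 = 27.888
KS_COUPLING = 27.888
KS_CUTOFF = -0.5  # kcal/mol


@dataclass(frozen=True)
class HBond:
    """Backbone amide-N (donor) to carbonyl-O (acceptor) contact."""

    donor_residue: int
    acceptor_residue: int
    distance: float

    def __post_init__(self) -> None:
        if self.donor_residue == self.acceptor_residue:
            raise ValueError("donor and acceptor must differ")


@dataclass
class SASAProfile:
    """Per-residue solvent-accessible surface area (Å²)."""

    values: np.ndarray
    probe_radius: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("SASA values must be non-negative")


def _backbone_arrays(frame: Conformer, names=("N", "O")):
    residues = frame.residue_ids
    out = {}
    for name in names:
        pos = np.empty((len(residues), 3))
        for k, res in enumerate(residues):
            if not frame.has_atom(res, name):
                raise ValueError(
                    f"frame {frame.frame_id}: residue {res} is missing "
                    f"backbone atom {name}"
                )
            pos[k] = frame.atom_position(res, name)
        out[name] = pos
    return residues, out


def detect_backbone_hbonds(
    frame: Conformer,
    cutoff: float = HBOND_CUTOFF,
    min_separation: int = MIN_SEQUENCE_SEPARATION,
    angle_filter: bool = False,
    min_angle_deg: float = 120.0,
) -> list[HBond]:
    """All donor-N / acceptor-O pairs with N-O distance <= cutoff (inclusive).

    Pairs closer than ``min_separation`` in sequence are covalent-geometry
    artifacts and excluded.  ``angle_filter`` optionally also requires the
    N-H...O angle (H reconstructed) to exceed ``min_angle_deg``; it is off by
    default because the published criterion is purely a heavy-atom distance.
    The list is sorted by (donor, acceptor).
    """
    residues, pos = _backbone_arrays(frame)
    n_pos, o_pos = pos["N"], pos["O"]
    d = np.linalg.norm(n_pos[:, None, :] - o_pos[None, :, :], axis=-1)
    res_arr = np.asarray(residues)
    sep = np.abs(res_arr[:, None] - res_arr[None, :])
    ok = (d <= cutoff) & (sep >= min_separation)

    if angle_filter:
        h_pos = reconstruct_amide_hydrogens(frame)
    bonds: list[HBond] = []
    for i, j in zip(*np.nonzero(ok)):
        donor, acceptor = int(res_arr[i]), int(res_arr[j])
        if angle_filter:
            h = h_pos.get(donor)
            if h is None:
                continue
            v1 = n_pos[i] - h
            v2 = o_pos[j] - h
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            if math.degrees(math.acos(np.clip(cosang, -1, 1))) < min_angle_deg:
                continue
        bonds.append(HBond(donor, acceptor, float(d[i, j])))
    bonds.sort(key=lambda b: (b.donor_residue, b.acceptor_residue))
    return bonds


def reconstruct_amide_hydrogens(frame: Conformer) -> dict[int, np.ndarray]:
    """Place amide H 1.0 Å from N opposing the C(i-1)-N / CA-N bisector.

    The first residue (no preceding carbonyl) and prolines get no H.
    """
    residues = frame.residue_ids
    out: dict[int, np.ndarray] = {}
    for prev, res in zip(residues[:-1], residues[1:]):
        if frame.residue_name(res) == "PRO":
            continue
        if frame.has_atom(res, "H"):
            out[res] = frame.atom_position(res, "H")
            continue
        n = frame.atom_position(res, "N")
        c_prev = frame.atom_position(prev, "C")
        ca = frame.atom_position(res, "CA")
        u = n - c_prev
        v = n - ca
        u = u / np.linalg.norm(u)
        v = v / np.linalg.norm(v)
        direction = u + v
        norm = np.linalg.norm(direction)
        if norm < 1e-8:  # degenerate, collinear geometry
            direction = u
            norm = 1.0
        out[res] = n + direction / norm
    return out


def _ks_bond_matrix(frame: Conformer) -> np.ndarray:
    """bonds[i, j]: NH of residue index i donates to CO of residue index j."""
    residues, pos = _backbone_arrays(frame, names=("N", "O", "C"))
    h_pos = reconstruct_amide_hydrogens(frame)
    n = len(residues)
    h_arr = np.zeros((n, 3))
    has_h = np.zeros(n, dtype=bool)
    for k, res in enumerate(residues):
        h = h_pos.get(res)
        if h is not None:
            h_arr[k] = h
            has_h[k] = True

    def dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
        return np.maximum(d, 1e-6)

    r_on = dist(pos["N"], pos["O"])
    r_ch = dist(h_arr, pos["C"])
    r_oh = dist(h_arr, pos["O"])
    r_cn = dist(pos["N"], pos["C"])
    energy = KS_COUPLING * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)

    res_arr = np.asarray(residues)
    sep_ok = np.abs(res_arr[:, None] - res_arr[None, :]) >= 2
    return (energy < KS_CUTOFF) & sep_ok & has_h[:, None]


def backbone_dihedrals(frame: Conformer) -> tuple[np.ndarray, np.ndarray]:
    """(phi, psi) in degrees per residue; NaN where undefined (termini)."""
    residues = frame.residue_ids
    n = len(residues)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)

    def dihedral(p0, p1, p2, p3):
        b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
        b1n = b1 / np.linalg.norm(b1)
        v = b0 - (b0 @ b1n) * b1n
        w = b2 - (b2 @ b1n) * b1n
        x = v @ w
        y = np.cross(b1n, v) @ w
        return math.degrees(math.atan2(y, x))

    for k, res in enumerate(residues):
        n_i = frame.atom_position(res, "N")
        ca_i = frame.atom_position(res, "CA")
        c_i = frame.atom_position(res, "C")
        if k > 0:
            c_prev = frame.atom_position(residues[k - 1], "C")
            phi[k] = dihedral(c_prev, n_i, ca_i, c_i)
        if k < n - 1:
            n_next = frame.atom_position(residues[k + 1], "N")
            psi[k] = dihedral(n_i, ca_i, c_i, n_next)
    return phi, psi


def _in_beta_basin(phi: float, psi: float) -> bool:
    """Broad extended/PPII basin; NaN dihedrals (termini) do not disqualify."""
    if not math.isnan(phi) and not (-180.0 <= phi <= -45.0):
        return False
    if not math.isnan(psi) and not (psi >= 45.0 or psi <= -135.0):
        return False
    return not (math.isnan(phi) and math.isnan(psi))


def assign_secondary_structure(frame: Conformer) -> str:
    """Per-residue codes over {H, G, I, E, B, T, C}.

    Helices, bridges/ladders and turns follow the Kabsch-Sander hydrogen-bond
    patterns (electrostatic energy < -0.5 kcal/mol).  Residues in runs of
    three or more extended-basin (phi, psi) pairs are additionally labelled
    "E" even without a partner strand, mirroring dihedral-aware assigners
    such as STRIDE; everything else is coil "C".
    """
    residues = frame.residue_ids
    n = len(residues)
    if n < 3:
        return "C" * n
    hb = _ks_bond_matrix(frame)

    # n-turns: CO(i) accepts NH(i+d)
    turn = {d: np.zeros(n, dtype=bool) for d in (3, 4, 5)}
    for d in (3, 4, 5):
        for i in range(n - d):
            if hb[i + d, i]:
                turn[d][i] = True

    ss = np.array(["C"] * n, dtype=object)

    # helices: two consecutive n-turns
    helix_code = {4: "H", 3: "G", 5: "I"}
    helix_mask = {4: np.zeros(n, bool), 3: np.zeros(n, bool), 5: np.zeros(n, bool)}
    for d in (4, 3, 5):
        for i in range(n - d - 1):
            if turn[d][i] and turn[d][i + 1]:
                helix_mask[d][i + 1 : i + 1 + d] = True

    # bridges
    bridge_partners: dict[int, set[int]] = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 2, n):
            anti = (hb[i, j] and hb[j, i]) or (
                0 <= i - 1 and j + 1 < n and 0 <= j - 1 and i + 1 < n
                and hb[j + 1, i - 1] and hb[i + 1, j - 1]
            )
            para = (
                0 <= i - 1 and j + 1 < n and hb[j, i - 1] and hb[j + 1, i]
            ) or (
                0 <= j - 1 and i + 1 < n and hb[i, j - 1] and hb[i + 1, j]
            )
            if anti or para:
                bridge_partners[i].add(j)
                bridge_partners[j].add(i)

    in_bridge = np.array([bool(bridge_partners[i]) for i in range(n)])
    extended = np.zeros(n, bool)
    for i in range(n):
        if not in_bridge[i]:
            continue
        for j in bridge_partners[i]:
            neigh = bridge_partners.get(i - 1, set()) | bridge_partners.get(i + 1, set())
            if {j - 1, j, j + 1} & neigh:
                extended[i] = True
                break

    # dihedral-based extended strands (isolated beta conformation)
    phi, psi = backbone_dihedrals(frame)
    basin = np.array([_in_beta_basin(phi[k], psi[k]) for k in range(n)])
    run_extended = np.zeros(n, bool)
    k = 0
    while k < n:
        if basin[k]:
            j = k
            while j < n and basin[j]:
                j += 1
            if j - k >= 3:
                run_extended[k:j] = True
            k = j
        else:
            k += 1

    # priority: H > E > B > G > I > T > C
    for i in range(n):
        if helix_mask[4][i]:
            ss[i] = "H"
        elif extended[i] or run_extended[i]:
            ss[i] = "E"
        elif in_bridge[i]:
            ss[i] = "B"
        elif helix_mask[3][i]:
            ss[i] = "G"
        elif helix_mask[5][i]:
            ss[i] = "I"
    # turns
    for d in (3, 4, 5):
        for i in range(n - d):
            if turn[d][i]:
                for k in range(i + 1, i + d):
                    if ss[k] == "C":
                        ss[k] = "T"
    return "".join(ss)


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def compute_sasa(
    frame: Conformer,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
    include_hydrogens: bool = False,
) -> SASAProfile:
    """Shrake-Rupley numerical SASA summed per residue.

    Uses a deterministic golden-spiral quadrature (no RNG) so results are
    bit-reproducible.  Hydrogens are ignored by default.
    """
    from .structure_io import _element_of

    radii = dict(ATOMIC_RADII if radii is None else radii)
    elements = []
    keep_rows = []
    for i, (_res, _rn, atom_name) in enumerate(frame.atoms):
        el = _element_of(atom_name)
        if el == "H" and not include_hydrogens:
            continue
        if el not in radii:
            raise ValueError(f"unknown element {el!r} for atom {atom_name!r}")
        elements.append(el)
        keep_rows.append(i)
    coords = frame.coords[keep_rows]
    res_of = np.array([frame.atoms[i][0] for i in keep_rows])
    rad = np.array([radii[e] for e in elements]) + probe_radius

    sphere = _golden_spiral(n_points)
    tree = cKDTree(coords)
    max_r = rad.max()
    residues = frame.residue_ids
    per_res = {res: 0.0 for res in residues}
    for a in range(len(coords)):
        pts = coords[a] + rad[a] * sphere
        neighbors = [
            b for b in tree.query_ball_point(coords[a], rad[a] + max_r)
            if b != a
        ]
        if neighbors:
            nb_idx = np.array(neighbors)
            nb_coords = coords[nb_idx]
            nb_rad = rad[nb_idx]
            d2 = ((pts[:, None, :] - nb_coords[None, :, :]) ** 2).sum(-1)
            # boundary points count as buried only against lower-index
            # neighbors, so exactly coincident spheres expose one surface
            r2 = nb_rad[None, :] ** 2
            strict = d2 < r2 * (1 - 1e-9)
            boundary = (d2 <= r2 * (1 + 1e-9)) & (nb_idx[None, :] < a)
            buried = (strict | boundary).any(axis=1)
            accessible = int((~buried).sum())
        else:
            accessible = n_points
        area = 4 * np.pi * rad[a] ** 2 * accessible / n_points
        per_res[int(res_of[a])] += area
    return SASAProfile(
        values=np.array([per_res[res] for res in residues]),
        probe_radius=probe_radius,
    )


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimal RMSD over rigid rotation+translation (Kabsch, via SVD)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate sets must share shape (N, 3); got "
                         f"{a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 points")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.diag([1.0, 1.0, sign])
    r = u @ d @ vt
    diff = a @ r - b
    return float(np.sqrt((diff**2).sum() / a.shape[0]))
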