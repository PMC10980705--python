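"""Ground-truth-labelled synthetic inputs for every analysis stage.

Generators produce geometric fixtures, not thermodynamic samples: ideal
even/odd hairpins whose cross-arm hydrogen bonds land exactly on the
requested parity set, fully extended strands, self-avoiding random coils,
k18-length chains realizing designated local-hairpin and inter-hexapeptide
pairing events, and noisy sigmoidal ThT plates.  Every construction is
validated closed-loop against the analysis stage that will consume it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _backbone as bb
from .geometry_core import detect_backbone_hbonds
from .hairpin_registry import Registry, classify_hairpin
from .kinetics_corr import logistic4
from .repeat_domain import (
    RepeatSpec,
    interhexapeptide_pairing,
    k18_default_spec,
    local_hairpin_probabilities,
    K18_SEQUENCE,
)
from .structure_io import (
    AA1TO3,
    Conformer,
    Ensemble,
    RegionMap,
    TAU295_SEQUENCE,
    make_region_map,
)

__all__ = [
    "EnsembleRecipe",
    "PlateRecipe",
    "PlateMutant",
    "build_ideal_hairpin",
    "build_extended",
    "build_coil",
    "sample_ensemble",
    "build_k18_frame",
    "simulate_tht_plate",
]


def _conformer_from_positions(
    sequence: str,
    positions: dict[int, bb.PlacedResidue] | dict[str, np.ndarray],
    frame_id: int = 0,
) -> Conformer:
    """Assemble a Conformer (internal 1-based residues) from placements."""
    atoms: list[tuple[int, str, str]] = []
    coords: list[np.ndarray] = []
    if isinstance(positions, dict) and "N" in positions:  # dihedral-chain dict
        arrays = positions
        for i, aa in enumerate(sequence, start=1):
            res_name = AA1TO3.get(aa, "UNK")
            for name in ("N", "CA", "C", "O"):
                atoms.append((i, res_name, name))
                coords.append(arrays[name][i - 1])
    else:
        for i, aa in enumerate(sequence, start=1):
            res_name = AA1TO3.get(aa, "UNK")
            placed = positions[i]
            for name, pos in placed.as_dict().items():
                atoms.append((i, res_name, name))
                coords.append(pos)
    return Conformer(frame_id=frame_id, coords=np.array(coords), atoms=atoms)


# ---------------------------------------------------------------------------
# 17-mer peptide conformers
# ---------------------------------------------------------------------------

EXTENDED_PHI, EXTENDED_PSI = -120.0, 120.0
TURN_LIFT = np.array([0.30, 0.0, 0.954])  # bulge direction for hairpin turns


def _hairpin_placements(
    author_ids: range,
    bonded: list[int],
    pairing_sum: int,
    arm_y: float = 0.0,
) -> dict[int, bb.PlacedResidue]:
    """Place an antiparallel hairpin: arm strand, turn arc, hex strand.

    ``bonded`` hexapeptide residues pair arm residue ``pairing_sum - r``
    via mutual N-O rungs; the strand alignment follows from the pairing
    sum, the turn is a circular arc with uniform ~3.8 Å CA steps.
    """
    author_min = author_ids[0]
    hex_start = min(bonded)
    partners = {b: pairing_sum - b for b in bonded}
    arm_top = partners[hex_start]
    n_turn = hex_start - arm_top - 1
    if n_turn < 1:
        raise ValueError("no residues left for the turn")
    rung_arm = set(partners.values())

    placed: dict[int, bb.PlacedResidue] = {}
    for r in range(author_min, arm_top + 1):
        placed[r] = bb.strand_residue(
            x=bb.STRAND_STEP * (r - author_min),
            y=arm_y,
            direction=+1,
            rung=r in rung_arm,
            toward=+1,
            pleat_sign=1 if r % 2 == 0 else -1,
        )
    for h in range(hex_start, author_ids[-1] + 1):
        placed[h] = bb.strand_residue(
            x=bb.STRAND_STEP * (pairing_sum - h - author_min),
            y=arm_y + bb.STRAND_SEP,
            direction=-1,
            rung=h in bonded,
            toward=-1,
            pleat_sign=1 if h % 2 == 0 else -1,
        )
    p0 = placed[arm_top].ca
    p1 = placed[hex_start].ca
    arc = bb.arc_points(p0, p1, n_turn, lift=TURN_LIFT)
    loop = bb.backbone_from_ca_path(arc, p0, p1, outward=TURN_LIFT)
    for k, r in enumerate(range(arm_top + 1, hex_start)):
        placed[r] = loop[k]
    return placed


def build_ideal_hairpin(
    sequence: str,
    regions: RegionMap | None = None,
    parity: str = "even",
    turn_center: int | None = None,
) -> Conformer:
    """Ideal antiparallel hairpin classified with the requested registry.

    Cross-arm hydrogen bonds land exactly on the even or odd parity set;
    consecutive CA-CA distances are in the ideal-strand range.  The output
    is verified against the hairpin classifier before being returned.
    """
    if regions is None:
        regions = make_region_map(sequence)
    if parity not in ("even", "odd"):
        raise ValueError(f"parity must be 'even' or 'odd', got {parity!r}")
    bonded = sorted(regions.even_set if parity == "even" else regions.odd_set)
    if len(bonded) < 2:
        raise ValueError("parity set too small for two cross-arm bonds")
    author_ids = range(regions.offset + 1, regions.offset + len(sequence) + 1)

    if turn_center is None:
        pairing_sum = min(bonded) + max(regions.n_arm) - 2
    else:
        if turn_center not in regions.turn:
            raise ValueError(
                f"turn_center {turn_center} outside turn region "
                f"{sorted(regions.turn)}"
            )
        pairing_sum = (turn_center - 1) + min(bonded)

    partners = [pairing_sum - b for b in bonded]
    if not set(partners) <= regions.n_arm:
        raise ValueError(
            f"pairing partners {sorted(partners)} not all inside the "
            f"N-arm {sorted(regions.n_arm)}"
        )
    if min(partners) - author_ids[0] < 0:
        raise ValueError("arm too short for the requested pairing")

    placed = _hairpin_placements(author_ids, bonded, pairing_sum)
    conf = _conformer_from_positions(
        sequence, {r - regions.offset: p for r, p in placed.items()}
    )

    check = classify_hairpin(conf, regions, detect_backbone_hbonds(conf))
    if check.registry.value != parity:
        raise RuntimeError(
            f"constructed hairpin classified as {check.registry.value!r} "
            f"({check.reason}); geometry parameters are inconsistent"
        )
    return conf


def build_extended(sequence: str) -> Conformer:
    """Fully extended strand (beta-region dihedrals, no internal H-bonds)."""
    n = len(sequence)
    arrays = bb.chain_from_dihedrals(
        np.full(n, EXTENDED_PHI), np.full(n, EXTENDED_PSI)
    )
    conf = _conformer_from_positions(sequence, arrays)
    if detect_backbone_hbonds(conf):
        raise RuntimeError("extended chain unexpectedly contains H-bonds")
    return conf


# coil library: sterically allowed (phi, psi) basins away from the
# extended-strand basin and the two helical cores.  Drawing from allowed
# regions only keeps 1-3 steric clashes rare; the no-3-consecutive rule for
# the polyproline-II-like basin prevents dihedral-based strand labels.
_COIL_BASINS = (
    ((-150.0, -70.0), (110.0, 170.0)),   # PPII-like (capped at runs of 2)
    ((-160.0, -55.0), (-65.0, -15.0)),   # broad alpha-region fringe
    ((55.0, 90.0), (15.0, 65.0)),        # left-handed alpha
)
_COIL_BASIN_PROBS = (0.45, 0.35, 0.20)


def build_coil(
    sequence: str,
    seed: int,
    regions: RegionMap | None = None,
    max_tries: int = 2000,
) -> Conformer:
    """Self-avoiding random coil that no classifier can mistake for beta.

    Per-residue dihedrals are drawn from sterically allowed coil basins
    (never three consecutive extended-basin residues, so no strand run can
    be assigned).  A draw is rejected when any heavy-atom pair of residues
    two or more apart comes below 2.5 Å, when any backbone hydrogen bond
    forms, or when a hexapeptide residue would not be assigned coil "C".
    Deterministic for a fixed seed.
    """
    from .geometry_core import assign_secondary_structure

    rng = np.random.default_rng(seed)
    n = len(sequence)
    if regions is not None:
        hex_internal = sorted(r - regions.offset for r in regions.hexapeptide)
    else:
        hex_internal = list(range(1, n + 1))
    for _ in range(max_tries):
        phi = np.empty(n)
        psi = np.empty(n)
        basins: list[int] = []
        for i in range(n):
            while True:
                b = int(rng.choice(len(_COIL_BASINS), p=_COIL_BASIN_PROBS))
                if b == 0 and basins[-2:] == [0, 0]:
                    continue
                break
            basins.append(b)
            (plo, phi_hi), (slo, shi) = _COIL_BASINS[b]
            phi[i] = rng.uniform(plo, phi_hi)
            psi[i] = rng.uniform(slo, shi)
        arrays = bb.chain_from_dihedrals(phi, psi)
        conf = _conformer_from_positions(sequence, arrays)
        # clash check between residues >= 2 apart
        coords = conf.coords
        res_idx = np.array([a[0] for a in conf.atoms])
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        sep = np.abs(res_idx[:, None] - res_idx[None, :])
        if (d[(sep >= 2)] < 2.5).any():
            continue
        if detect_backbone_hbonds(conf):
            continue
        ss = assign_secondary_structure(conf)
        if any(ss[i - 1] != "C" for i in hex_internal):
            continue
        if regions is not None:
            a = classify_hairpin(conf, regions, [])
            if a.registry is not Registry.NONE:
                continue
        return conf
    raise RuntimeError(
        f"could not draw a self-avoiding coil in {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# labelled ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleRecipe:
    """Recipe for a mixed ensemble with known composition."""

    sequence: str = TAU295_SEQUENCE
    composition: dict[str, float] = field(
        default_factory=lambda: {
            "even": 0.25, "odd": 0.25, "extended": 0.25, "coil": 0.25
        }
    )
    n_frames: int = 100
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition sums to {total}, not 1")
        unknown = set(self.composition) - {"even", "odd", "extended", "coil"}
        if unknown:
            raise ValueError(f"unknown composition keys {unknown}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def sample_ensemble(
    recipe: EnsembleRecipe,
    regions: RegionMap | None = None,
) -> tuple[Ensemble, list[str]]:
    """Draw a labelled ensemble according to the recipe.

    Frame types are drawn i.i.d. from the composition, Gaussian coordinate
    noise of the stated sigma is applied, and the per-frame truth labels
    are returned alongside the ensemble.
    """
    if regions is None:
        regions = make_region_map(recipe.sequence)
    rng = np.random.default_rng(recipe.seed)
    kinds = sorted(recipe.composition)
    probs = np.array([recipe.composition[k] for k in kinds])

    templates = {
        "even": build_ideal_hairpin(recipe.sequence, regions, "even"),
        "odd": build_ideal_hairpin(recipe.sequence, regions, "odd"),
        "extended": build_extended(recipe.sequence),
    }
    draws = rng.choice(len(kinds), size=recipe.n_frames, p=probs)
    conformers: list[Conformer] = []
    labels: list[str] = []
    for idx, d in enumerate(draws):
        kind = kinds[d]
        if kind == "coil":
            coil_seed = int(rng.integers(0, 2**31 - 1))
            base = build_coil(recipe.sequence, seed=coil_seed, regions=regions)
        else:
            base = templates[kind]
        coords = base.coords.copy()
        if recipe.noise_sigma > 0:
            coords = coords + rng.normal(0, recipe.noise_sigma, coords.shape)
        conformers.append(base.with_coords(coords, frame_id=idx))
        labels.append(kind)
    ensemble = Ensemble(
        conformers=conformers,
        sequence=recipe.sequence,
        numbering_offset=regions.offset,
    )
    return ensemble, labels


# ---------------------------------------------------------------------------
# k18 chains with designated events
# ---------------------------------------------------------------------------

def _normalize_events(events) -> tuple[set[int], set[tuple[int, int]]]:
    locals_: set[int] = set()
    pairs: set[tuple[int, int]] = set()
    for ev in events:
        if isinstance(ev, str) and ev.upper().startswith("H"):
            locals_.add(int(ev[1:]))
        elif isinstance(ev, tuple) and len(ev) == 2:
            i, j = sorted(int(x) for x in ev)
            if i == j:
                raise ValueError("pairing event needs two distinct segments")
            pairs.add((i, j))
        else:
            raise ValueError(f"unrecognized event {ev!r}")
    return locals_, pairs


def build_k18_frame(
    spec: RepeatSpec | None = None,
    events=(),
    sequence: str = K18_SEQUENCE,
) -> Conformer:
    """k18-length chain realizing exactly the requested beta events.

    ``events`` mixes local-hairpin labels ("H1".."H4") and inter-hexapeptide
    pairings as (i, j) tuples.  Event footprints must not overlap.  The
    realized hydrogen-bond events are verified against the repeat-domain
    statistics before the frame is returned.
    """
    if spec is None:
        spec = k18_default_spec()
    locals_, pairs = _normalize_events(events)

    # residue footprints (author numbering, inclusive)
    modules: list[tuple[int, int, tuple]] = []
    for k in sorted(locals_):
        lo, hi = spec.hexapeptides[k - 1]
        bonded = [lo, lo + 2, lo + 4]
        bonded = [b for b in bonded if b < hi]  # window is lo-1..hi-1
        pairing_sum = 2 * lo - 4
        arm_lo = pairing_sum - max(bonded)
        modules.append((arm_lo, hi, ("local", k, bonded, pairing_sum)))
    for i, j in sorted(pairs):
        lo_i, hi_i = spec.hexapeptides[i - 1]
        lo_j, hi_j = spec.hexapeptides[j - 1]
        modules.append((lo_i, hi_j, ("pair", i, j)))
    modules.sort()
    for (a0, a1, _), (b0, b1, _) in zip(modules, modules[1:]):
        if b0 <= a1:
            raise ValueError("event footprints overlap; incompatible events")

    chain_lo, chain_hi = spec.chain_start, spec.chain_end
    placed: dict[int, bb.PlacedResidue] = {}
    x_cursor = 0.0  # next free x on the main axis

    for lo, hi, payload in modules:
        origin = np.array([x_cursor, 0.0, 0.0])
        if payload[0] == "local":
            _, k, bonded, pairing_sum = payload
            sub = _hairpin_placements(
                range(lo, hi + 1), bonded, pairing_sum
            )
            for r, pr in sub.items():
                placed[r] = bb.PlacedResidue(
                    n=pr.n + origin, ca=pr.ca + origin,
                    c=pr.c + origin, o=pr.o + origin,
                )
        else:
            _, i, j = payload
            lo_i, hi_i = spec.hexapeptides[i - 1]
            lo_j, hi_j = spec.hexapeptides[j - 1]
            s2 = lo_i + hi_j
            rungs_i = {lo_i + 2 * t for t in range(3) if lo_i + 2 * t <= hi_i}
            rungs_j = {s2 - r for r in rungs_i if lo_j <= s2 - r <= hi_j}
            for r in range(lo_i, hi_i + 1):
                placed[r] = bb.strand_residue(
                    x=bb.STRAND_STEP * (r - lo_i), y=0.0,
                    direction=+1, rung=r in rungs_i, toward=+1,
                    origin=origin, pleat_sign=1 if r % 2 == 0 else -1,
                )
            for m in range(lo_j, hi_j + 1):
                placed[m] = bb.strand_residue(
                    x=bb.STRAND_STEP * (s2 - m - lo_i), y=bb.STRAND_SEP,
                    direction=-1, rung=m in rungs_j, toward=-1,
                    origin=origin, pleat_sign=1 if m % 2 == 0 else -1,
                )
            # connector between the paired strands
            n_conn = lo_j - hi_i - 1
            arc = bb.arc_points(
                placed[hi_i].ca, placed[lo_j].ca, n_conn,
                lift=np.array([0.2, 0.0, 0.98]),
            )
            loop = bb.backbone_from_ca_path(
                arc, placed[hi_i].ca, placed[lo_j].ca,
                outward=np.array([0.0, 0.0, 1.0]),
            )
            for t, r in enumerate(range(hi_i + 1, lo_j)):
                placed[r] = loop[t]
        module_xmax = max(placed[r].ca[0] for r in range(lo, hi + 1))
        x_cursor = module_xmax + 14.0

    # linkers between / around modules, laid as smooth paths
    def fill_linker(res_lo: int, res_hi: int, p_prev, p_next) -> None:
        """Place residues res_lo..res_hi between anchor CAs."""
        n = res_hi - res_lo + 1
        if n <= 0:
            return
        if p_prev is None:  # leading tail: straight line backwards
            d = np.array([-0.95, 0.0, -0.312])
            cas = np.array(
                [p_next + 3.8 * (res_hi - r + 1) * d for r in range(res_lo, res_hi + 1)]
            )
            prev_ca = cas[0] + 3.8 * d
            loop = bb.backbone_from_ca_path(
                cas, prev_ca, p_next, outward=np.array([0.0, -0.9, 0.44])
            )
        elif p_next is None:  # trailing tail: straight line forwards
            d = np.array([0.95, 0.0, -0.312])
            cas = np.array(
                [p_prev + 3.8 * (r - res_lo + 1) * d for r in range(res_lo, res_hi + 1)]
            )
            next_ca = cas[-1] + 3.8 * d
            loop = bb.backbone_from_ca_path(
                cas, p_prev, next_ca, outward=np.array([0.0, -0.9, 0.44])
            )
        else:
            arc = bb.arc_points(
                p_prev, p_next, n, lift=np.array([0.15, 0.1, 0.98])
            )
            loop = bb.backbone_from_ca_path(
                arc, p_prev, p_next, outward=np.array([0.0, 0.0, 1.0])
            )
        for t, r in enumerate(range(res_lo, res_hi + 1)):
            placed[r] = loop[t]

    if modules:
        first_lo = modules[0][0]
        fill_linker(chain_lo, first_lo - 1, None, placed[first_lo].ca)
        for (a_lo, a_hi, _), (b_lo, b_hi, _) in zip(modules, modules[1:]):
            fill_linker(
                a_hi + 1, b_lo - 1, placed[a_hi].ca, placed[b_lo].ca
            )
        last_hi = modules[-1][1]
        fill_linker(last_hi + 1, chain_hi, placed[last_hi].ca, None)
    else:
        for r in range(chain_lo, chain_hi + 1):
            placed[r] = bb.strand_residue(
                x=bb.STRAND_STEP * (r - chain_lo), y=0.0,
                direction=+1, rung=False, toward=+1,
                pleat_sign=1 if r % 2 == 0 else -1,
            )

    internal = {r - spec.offset: placed[r] for r in range(chain_lo, chain_hi + 1)}
    conf = _conformer_from_positions(sequence, internal)

    # closed-loop verification of realized events
    single = Ensemble([conf], sequence, numbering_offset=spec.offset)
    hb = [detect_backbone_hbonds(conf)]
    local = local_hairpin_probabilities(single, spec, hbonds_per_frame=hb)
    mat = interhexapeptide_pairing(
        single, spec, hbonds_per_frame=hb, include_local=False
    )
    want_local = {f"H{k}": float(k in locals_) for k in range(1, spec.n_segments + 1)}
    if local != want_local:
        raise RuntimeError(f"realized local events {local} != requested {want_local}")
    for i in range(spec.n_segments):
        for j in range(i + 1, spec.n_segments):
            want = float((i + 1, j + 1) in pairs)
            if mat.pairwise[i, j] != want:
                raise RuntimeError(
                    f"realized pairing {i+1}-{j+1} = {mat.pairwise[i, j]} "
                    f"!= requested {want}"
                )
    return conf


# ---------------------------------------------------------------------------
# synthetic ThT plates
# ---------------------------------------------------------------------------

@dataclass
class PlateMutant:
    mutant_id: str
    T_half: float | None          # hours; None = non-aggregator
    baseline: float = 100.0
    plateau: float = 2100.0
    slope: float = 0.5            # 1/h


@dataclass
class PlateRecipe:
    mutants: list[PlateMutant]
    times: np.ndarray = field(
        default_factory=lambda: np.arange(0, 100.0, 0.5)  # scans every 30 min
    )
    noise_sigma_frac: float = 0.02
    blank_level: float = 80.0
    n_replicates: int = 4
    n_blanks: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for m in self.mutants:
            if m.T_half is not None and not (
                self.times[0] <= m.T_half <= self.times[-1]
            ):
                raise ValueError(
                    f"{m.mutant_id}: T_half {m.T_half} outside the time grid"
                )


def simulate_tht_plate(recipe: PlateRecipe) -> pd.DataFrame:
    """Quadruplicate 4PL ThT wells plus blank wells, with Gaussian noise.

    Noise sigma is ``noise_sigma_frac`` times each mutant's amplitude (and
    times the blank level for blank wells).  Reproducible for fixed seed.
    """
    rng = np.random.default_rng(recipe.seed)
    t = recipe.times
    data: dict[str, np.ndarray] = {"time_h": t}
    for m in recipe.mutants:
        if m.T_half is None:
            clean = np.full_like(t, m.baseline)
            amp = m.plateau - m.baseline
        else:
            clean = logistic4(t, m.baseline, m.plateau, m.T_half, m.slope)
            amp = m.plateau - m.baseline
        for k in range(recipe.n_replicates):
            noise = rng.normal(0, recipe.noise_sigma_frac * amp, t.shape)
            data[f"{m.mutant_id}_r{k + 1}"] = recipe.blank_level + clean + noise
    for k in range(recipe.n_blanks):
        noise = rng.normal(
            0, recipe.noise_sigma_frac * recipe.blank_level, t.shape
        )
        data[f"blank_{k + 1}"] = recipe.blank_level + noise
    return pd.DataFrame(data)
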