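"""Even/odd beta-hairpin registry classification and per-frame flags.

A frame is a hairpin when the aggregation-prone C-terminal hexapeptide is
held against the N-terminal arm by cross-arm backbone hydrogen bonds in an
antiparallel arrangement.  The registry is "even" when the even-numbered
hexapeptide residues (306, 308, 310 in tau author numbering) carry the
cross-arm bonds, "odd" when the odd-numbered ones (305, 307, 309) do.
Shifting the pairing by one residue flips every side chain between the two
strand faces, which is why the two registries behave so differently in
nucleation.

Hairpin and random-coil metrics are mutually orthogonal by construction: a
frame classified as a hairpin contributes nothing to the coil count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .geometry_core import HBond
from .structure_io import Conformer, RegionMap

__all__ = ["Registry", "HairpinAssignment", "FrameFlags", "classify_hairpin",
           "frame_flags"]


class Registry(str, Enum):
    EVEN = "even"
    ODD = "odd"
    NONE = "none"


@dataclass
class HairpinAssignment:
    """Outcome of the two-criterion hairpin test for one frame."""

    registry: Registry
    pairing: dict[int, int] = field(default_factory=dict)
    support_bonds: list[HBond] = field(default_factory=list)
    span_ok: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if self.registry is not Registry.NONE:
            if not self.pairing or not self.span_ok:
                raise ValueError(
                    "a classified hairpin requires a pairing map and a "
                    "satisfied span criterion"
                )


@dataclass
class FrameFlags:
    """Per-frame counters feeding the ensemble summary."""

    is_even: bool
    is_odd: bool
    coil_count_hex: int
    all_E_hex: bool
    raw_coil_count_hex: int = 0  # pre-orthogonality count, for diagnostics

    def __post_init__(self) -> None:
        if self.is_even and self.is_odd:
            raise ValueError("a frame cannot be both even and odd")
        if not 0 <= self.coil_count_hex <= 6:
            raise ValueError("coil_count_hex must be within 0..6")


def classify_hairpin(
    frame: Conformer,
    regions: RegionMap,
    hbonds: list[HBond],
    min_parity_bonds: int = 2,
    allow_mixed: bool = False,
    span_extension: int = 1,
    span_mode: str = "span",
) -> HairpinAssignment:
    """Classify one frame as an even hairpin, odd hairpin, or neither.

    Criterion (1): the scored hexapeptide residues (306-310 by default) must
    all lie within the hairpin span -- the interval covered by the
    cross-arm-bonded hexapeptide residues, extended by ``span_extension``
    ladder positions on each side (the non-H-bonded positions flanking a
    bonded rung are still part of the antiparallel strand).  At least two
    cross-arm-bonded hexapeptide residues are required.

    Criterion (2): cross-arm contacts must be proper backbone hydrogen bonds
    (either donor orientation) between the bond-eligible hexapeptide
    residues and the N-terminal arm.

    Registry: even (odd) when the bonded hexapeptide residues are >=
    ``min_parity_bonds`` members of the even (odd) set and none of the other
    parity; mixed parity yields ``none`` unless ``allow_mixed``.  Arm
    partners must strictly decrease as the hexapeptide index increases
    (antiparallel ordering); violations yield ``none``.
    """
    internal_hex = {r - regions.offset: r for r in regions.bond_eligible_hex}
    internal_arm = {r - regions.offset: r for r in regions.n_arm}

    # cross-arm H-bonds, both donor orientations
    cross: list[HBond] = []
    partners: dict[int, dict[int, float]] = {}
    for b in hbonds:
        if b.donor_residue in internal_hex and b.acceptor_residue in internal_arm:
            h, a = b.donor_residue, b.acceptor_residue
        elif b.acceptor_residue in internal_hex and b.donor_residue in internal_arm:
            h, a = b.acceptor_residue, b.donor_residue
        else:
            continue
        cross.append(b)
        best = partners.setdefault(h, {})
        best[a] = min(best.get(a, b.distance), b.distance)

    if not partners:
        return HairpinAssignment(Registry.NONE, reason="no cross-arm bonds")
    if len(partners) < 2:
        return HairpinAssignment(
            Registry.NONE, reason="fewer than two cross-arm-bonded residues"
        )

    bonded_author = sorted(internal_hex[h] for h in partners)

    # mixed-parity bonding can never be a single registry, whatever the span
    bonded = set(bonded_author)
    n_even = len(bonded & regions.even_set)
    n_odd = len(bonded & regions.odd_set)
    if n_even and n_odd and not allow_mixed:
        return HairpinAssignment(Registry.NONE, reason="mixed registry")

    # criterion (1): span membership of the scored hexapeptide
    if span_mode == "span":
        lo = bonded_author[0] - span_extension
        hi = bonded_author[-1] + span_extension
        span_ok = all(lo <= r <= hi for r in regions.scored_hex)
    elif span_mode == "any5":
        lo = bonded_author[0] - span_extension
        hi = bonded_author[-1] + span_extension
        inside = sum(lo <= r <= hi for r in regions.hexapeptide)
        span_ok = inside >= 5
    else:
        raise ValueError(f"unknown span_mode {span_mode!r}")
    if not span_ok:
        return HairpinAssignment(
            Registry.NONE, reason="scored hexapeptide not inside hairpin span"
        )

    # antiparallel ordering: best partner strictly decreases with hex index
    pairing: dict[int, int] = {}
    for h in sorted(partners):
        best_arm = min(partners[h], key=lambda a: partners[h][a])
        pairing[internal_hex[h]] = internal_arm[best_arm]
    ordered = [pairing[r] for r in sorted(pairing)]
    if any(p2 >= p1 for p1, p2 in zip(ordered, ordered[1:])):
        return HairpinAssignment(
            Registry.NONE, reason="pairing not antiparallel"
        )

    if n_even >= min_parity_bonds and (n_odd == 0 or allow_mixed) and n_even >= n_odd:
        registry = Registry.EVEN
    elif n_odd >= min_parity_bonds and (n_even == 0 or allow_mixed) and n_odd > n_even:
        registry = Registry.ODD
    elif n_even and n_odd:
        return HairpinAssignment(Registry.NONE, reason="mixed registry")
    else:
        return HairpinAssignment(
            Registry.NONE,
            reason="fewer than two cross-arm bonds of one parity",
        )
    return HairpinAssignment(
        registry,
        pairing=pairing,
        support_bonds=cross,
        span_ok=True,
    )


def frame_flags(
    frame: Conformer,
    regions: RegionMap,
    assignment: HairpinAssignment,
    ss: str,
) -> FrameFlags:
    """Coil and beta-content counters for one frame.

    ``coil_count_hex`` counts hexapeptide residues assigned coil "C", but is
    zeroed for frames classified as hairpins so that a given fold can never
    be counted both as hairpin and as coil.  ``all_E_hex`` is true when all
    six hexapeptide residues are extended "E".
    """
    if len(ss) != frame.n_residues:
        raise ValueError(
            f"secondary-structure string length {len(ss)} does not match "
            f"{frame.n_residues} residues"
        )
    hex_internal = sorted(regions.to_internal(regions.hexapeptide))
    codes = [ss[i - 1] for i in hex_internal]
    raw_coil = sum(c == "C" for c in codes)
    is_hairpin = assignment.registry is not Registry.NONE
    return FrameFlags(
        is_even=assignment.registry is Registry.EVEN,
        is_odd=assignment.registry is Registry.ODD,
        coil_count_hex=0 if is_hairpin else raw_coil,
        all_E_hex=all(c == "E" for c in codes),
        raw_coil_count_hex=raw_coil,
    )
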