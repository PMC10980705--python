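"""Four-repeat (k18) statistics: local hairpins, inter-hexapeptide pairing,
segment beta totals and SASA differentials.

The k18 fragment of tau (residues 244-372) carries four aggregation-prone
hexapeptides, one at the start of each repeat, each preceded by a PGGG turn
motif.  Local hairpins H1-H4 form when a hexapeptide folds back onto its
N-terminal flank; long-range beta pairing forms when two hexapeptides
hydrogen-bond each other.  Both event classes are counted as frame
fractions over an ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry_core import compute_sasa, detect_backbone_hbonds
from .hairpin_registry import Registry, classify_hairpin
from .structure_io import Conformer, Ensemble, RegionMap

__all__ = [
    "RepeatSpec",
    "PairingMatrix",
    "k18_default_spec",
    "segment_region_map",
    "local_hairpin_probability",
    "local_hairpin_probabilities",
    "interhexapeptide_pairing",
    "total_beta_for_segment",
    "sasa_differential",
    "K18_SEQUENCE",
    "K18_OFFSET",
]

#: tau four-repeat fragment, author numbering 244-372 (offset +243)
K18_SEQUENCE = (
    "QTAPVPMPDLKNVKSKIGSTENLKHQPGGGK"   # R1 244-274
    "VQIINKKLDLSNVQSKCGSKDNIKHVPGGGS"   # R2 275-305
    "VQIVYKPVDLSKVTSKCGSLGNIHHKPGGGQ"   # R3 306-336
    "VEVKSEKLDFKDRVQSKIGSLDNITHVPGGG"   # R4 337-367
    "NKKIE"                             # 368-372
)
K18_OFFSET = 243


@dataclass
class RepeatSpec:
    """Residue-range layout of the four hexapeptides and their flanks.

    All ranges are inclusive (start, end) pairs in author numbering.
    """

    hexapeptides: list[tuple[int, int]]
    flanks: list[tuple[int, int]]
    pggg_motifs: list[tuple[int, int]]
    chain_start: int = 244
    chain_end: int = 372
    offset: int = K18_OFFSET

    def __post_init__(self) -> None:
        for ranges in (self.hexapeptides, self.flanks, self.pggg_motifs):
            spans = sorted(ranges)
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                if b0 <= a1:
                    raise ValueError(f"overlapping ranges {spans}")
        clipped = []
        for lo, hi in self.hexapeptides:
            if hi > self.chain_end:
                warnings.warn(
                    f"hexapeptide range {lo}-{hi} extends past the chain "
                    f"terminus {self.chain_end}; clipping",
                    stacklevel=2,
                )
                hi = self.chain_end
            clipped.append((lo, hi))
        self.hexapeptides = clipped

    @property
    def n_segments(self) -> int:
        return len(self.hexapeptides)


def k18_default_spec() -> RepeatSpec:
    """Published k18 layout: hexapeptides 1-4 after each PGGG motif."""
    return RepeatSpec(
        hexapeptides=[(275, 280), (306, 311), (337, 342), (369, 374)],
        flanks=[(264, 268), (295, 299), (325, 329), (357, 361)],
        pggg_motifs=[(270, 273), (301, 304), (332, 335), (364, 367)],
    )


@dataclass
class PairingMatrix:
    """Local hairpin probabilities H1-H4 and the 4x4 pairing matrix."""

    local: dict[str, float]
    pairwise: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        self.pairwise = np.asarray(self.pairwise, dtype=float)
        if not np.allclose(self.pairwise, self.pairwise.T):
            raise ValueError("pairwise matrix must be symmetric")
        if ((self.pairwise < 0) | (self.pairwise > 1)).any():
            raise ValueError("pairing probabilities must lie in [0, 1]")


def segment_region_map(spec: RepeatSpec, k: int) -> RegionMap:
    """RegionMap for local-hairpin classification of segment k (1-based).

    Mirrors the hexapeptide-vs-arm conventions of the 295-311 peptide: the
    bond-eligible window is [hex_start-1, hex_end-1], the scored span is
    [hex_start, hex_end-1], and the arm is the flank extended upstream to
    (but not including) the previous hexapeptide.
    """
    if not 1 <= k <= spec.n_segments:
        raise ValueError(f"segment index {k} out of range 1..{spec.n_segments}")
    lo, hi = spec.hexapeptides[k - 1]
    window = range(lo - 1, hi)
    even = frozenset(r for r in window if (r - lo) % 2 == 0)
    odd = frozenset(r for r in window if (r - lo) % 2 == 1)
    arm_lo = spec.chain_start if k == 1 else spec.hexapeptides[k - 2][1] + 1
    return RegionMap(
        hexapeptide=frozenset(range(lo, hi + 1)),
        scored_hex=frozenset(range(lo, hi)),
        even_set=even,
        odd_set=odd,
        n_arm=frozenset(range(arm_lo, lo - 1)),
        excluded_termini=frozenset({hi}),
        turn=frozenset(range(lo - 5, lo)),
        offset=spec.offset,
    )


def _frame_hbonds(ensemble: Ensemble) -> list[list]:
    return [detect_backbone_hbonds(conf) for conf in ensemble]


def local_hairpin_probabilities(
    ensemble: Ensemble,
    spec: RepeatSpec | None = None,
    hbonds_per_frame: list[list] | None = None,
) -> dict[str, float]:
    """Weighted probability of a local hairpin around each PGGG motif.

    Any registry counts as a local hairpin; parity is not restricted.
    """
    if spec is None:
        spec = k18_default_spec()
    if hbonds_per_frame is None:
        hbonds_per_frame = _frame_hbonds(ensemble)
    maps = [segment_region_map(spec, k) for k in range(1, spec.n_segments + 1)]
    w = ensemble.weights
    total = w.sum()
    out = {}
    for k, rm in enumerate(maps, start=1):
        hit = np.zeros(ensemble.n_frames)
        for idx, (conf, hb) in enumerate(zip(ensemble, hbonds_per_frame)):
            a = classify_hairpin(conf, rm, hb)
            hit[idx] = a.registry is not Registry.NONE
        out[f"H{k}"] = float((w * hit).sum() / total)
    return out


def local_hairpin_probability(
    ensemble: Ensemble, spec: RepeatSpec | None = None, k: int = 1
) -> float:
    n_seg = (spec or k18_default_spec()).n_segments
    if not 1 <= k <= n_seg:
        raise ValueError(f"segment index {k} out of range 1..{n_seg}")
    return local_hairpin_probabilities(ensemble, spec)[f"H{k}"]


def interhexapeptide_pairing(
    ensemble: Ensemble,
    spec: RepeatSpec | None = None,
    min_bonds: int = 2,
    hbonds_per_frame: list[list] | None = None,
    include_local: bool = True,
) -> PairingMatrix:
    """4x4 matrix of inter-hexapeptide beta-pairing frame probabilities.

    pairwise[i, j] is the weighted fraction of frames with at least
    ``min_bonds`` backbone hydrogen bonds between residues of hexapeptide
    i+1 and hexapeptide j+1 (either donor orientation).
    """
    if spec is None:
        spec = k18_default_spec()
    if hbonds_per_frame is None:
        hbonds_per_frame = _frame_hbonds(ensemble)
    n_seg = spec.n_segments
    members = []
    for lo, hi in spec.hexapeptides:
        members.append(frozenset(r - spec.offset for r in range(lo, hi + 1)))
    w = ensemble.weights
    total = w.sum()
    pairwise = np.zeros((n_seg, n_seg))
    for i in range(n_seg):
        for j in range(i + 1, n_seg):
            hit = np.zeros(ensemble.n_frames)
            for idx, hb in enumerate(hbonds_per_frame):
                count = sum(
                    1
                    for b in hb
                    if (b.donor_residue in members[i] and b.acceptor_residue in members[j])
                    or (b.donor_residue in members[j] and b.acceptor_residue in members[i])
                )
                hit[idx] = count >= min_bonds
            pairwise[i, j] = pairwise[j, i] = float((w * hit).sum() / total)
    local = (
        local_hairpin_probabilities(ensemble, spec, hbonds_per_frame)
        if include_local
        else {f"H{k}": 0.0 for k in range(1, n_seg + 1)}
    )
    return PairingMatrix(local=local, pairwise=pairwise, n_frames=ensemble.n_frames)


def total_beta_for_segment(local_k: float, pairwise_row: list[float]) -> float:
    """Total beta-formation probability for one hexapeptide segment.

    Sum of the local-hairpin probability and the selected inter-hexapeptide
    pairing probabilities (the caller picks which pairings to include).  A
    total above 1 is possible when events overlap within a frame and is
    only warned about.
    """
    vals = [local_k, *pairwise_row]
    for v in vals:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"probability {v} outside [0, 1]")
    total = float(sum(vals))
    if total > 1.0:
        warnings.warn(
            f"segment beta total {total:.3f} exceeds 1; component events "
            "overlap",
            stacklevel=2,
        )
    return total


def sasa_differential(
    ensemble_a: Ensemble,
    ensemble_b: Ensemble,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-residue ensemble-mean SASA difference, a minus b.

    Positive values mean ensemble a is more solvent-exposed at that
    residue.  Frame weights are honoured.
    """
    if len(ensemble_a.sequence) != len(ensemble_b.sequence):
        raise ValueError("ensembles must have equal sequence lengths")

    def mean_profile(ens: Ensemble) -> np.ndarray:
        w = ens.weights
        acc = np.zeros(len(ens.sequence))
        for conf, wi in zip(ens, w):
            acc += wi * compute_sasa(
                conf, probe_radius=probe_radius, n_points=n_points
            ).values
        return acc / w.sum()

    return mean_profile(ensemble_a) - mean_profile(ensemble_b)
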