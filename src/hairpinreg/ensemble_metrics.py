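"""Ensemble-level hairpin/coil fractions and the xHAT nucleation score.

The xHAT (cross-beta hairpin amyloid trimer) score ranks fibril-nucleation
propensity from the monomer ensemble alone:

    S_xHAT = f_odd * f_even**2

where f_even and f_odd are the ensemble fractions of even- and odd-registry
hairpins.  The cube reflects the proposed trimeric transition state built
from two even hairpins plus one registry-shifted (odd) monomer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .geometry_core import assign_secondary_structure, detect_backbone_hbonds
from .hairpin_registry import Registry, classify_hairpin, frame_flags
from .structure_io import Ensemble, RegionMap

__all__ = ["EnsembleSummary", "summarize_ensemble", "xhat_score",
           "rank_mutants", "classify_frames"]

RANK_KEYS = ("f_coil", "f_even+f_odd", "S_xHAT", "f_beta_hex")


@dataclass
class EnsembleSummary:
    mutant_id: str
    n_frames: int
    f_even: float
    f_odd: float
    f_coil: float
    f_beta_hex: float
    S_xHAT: float

    def __post_init__(self) -> None:
        for name in ("f_even", "f_odd", "f_coil", "f_beta_hex"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.f_even + self.f_odd > 1.0 + 1e-12:
            raise ValueError("f_even + f_odd exceeds 1")

    @property
    def f_hairpin(self) -> float:
        """Total hairpin content (both registries)."""
        return self.f_even + self.f_odd


def classify_frames(ensemble: Ensemble, regions: RegionMap) -> pd.DataFrame:
    """Per-frame classification table (one row per conformer).

    Columns: frame_id, weight, registry, n_cross_bonds, coil_count_hex,
    all_E_hex, reason.
    """
    rows = []
    for conf in ensemble:
        hbonds = detect_backbone_hbonds(conf)
        assignment = classify_hairpin(conf, regions, hbonds)
        ss = assign_secondary_structure(conf)
        flags = frame_flags(conf, regions, assignment, ss)
        rows.append(
            dict(
                frame_id=conf.frame_id,
                weight=conf.weight,
                registry=assignment.registry.value,
                n_cross_bonds=len(assignment.support_bonds),
                coil_count_hex=flags.coil_count_hex,
                raw_coil_count_hex=flags.raw_coil_count_hex,
                all_E_hex=flags.all_E_hex,
                reason=assignment.reason,
            )
        )
    return pd.DataFrame(rows)


def summarize_ensemble(
    ensemble: Ensemble,
    regions: RegionMap,
    mutant_id: str = "",
    frame_table: pd.DataFrame | None = None,
) -> EnsembleSummary:
    """Weighted hairpin/coil/beta fractions and xHAT score for one mutant.

    f_even/f_odd are weighted frame fractions with the respective registry;
    f_coil is the summed hexapeptide coil count divided by the normalization
    constant 6 x (total frame weight); f_beta_hex is the weighted fraction
    of frames whose six hexapeptide residues are all extended "E".
    """
    if frame_table is None:
        frame_table = classify_frames(ensemble, regions)
    w = frame_table["weight"].to_numpy(dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("total frame weight must be positive")
    even = (frame_table["registry"] == Registry.EVEN.value).to_numpy()
    odd = (frame_table["registry"] == Registry.ODD.value).to_numpy()
    coil = frame_table["coil_count_hex"].to_numpy(dtype=float)
    all_e = frame_table["all_E_hex"].to_numpy(dtype=bool)

    f_even = float(w[even].sum() / total)
    f_odd = float(w[odd].sum() / total)
    f_coil = float((w * coil).sum() / (6.0 * total))
    f_beta_hex = float(w[all_e].sum() / total)
    return EnsembleSummary(
        mutant_id=mutant_id,
        n_frames=ensemble.n_frames,
        f_even=f_even,
        f_odd=f_odd,
        f_coil=f_coil,
        f_beta_hex=f_beta_hex,
        S_xHAT=xhat_score(f_even, f_odd),
    )


def xhat_score(f_even: float, f_odd: float) -> float:
    """S_xHAT = f_odd * f_even**2 on the hairpin-fraction simplex."""
    if f_even < 0 or f_odd < 0 or f_even + f_odd > 1 + 1e-9:
        raise ValueError(
            f"(f_even={f_even}, f_odd={f_odd}) outside the simplex"
        )
    return f_odd * f_even**2


def rank_mutants(
    summaries: list[EnsembleSummary],
    key: str = "S_xHAT",
) -> pd.DataFrame:
    """Rank mutants by a structural metric, rank 1 = largest value.

    Ties receive the average of the ranks they span.  Returns a DataFrame
    with columns (mutant_id, value, rank) in input order.
    """
    if len(summaries) < 2:
        raise ValueError("ranking needs at least two summaries")
    ids = [s.mutant_id for s in summaries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate mutant ids")
    if key == "f_even+f_odd":
        values = np.array([s.f_even + s.f_odd for s in summaries])
    elif key in ("f_coil", "S_xHAT", "f_beta_hex"):
        values = np.array([getattr(s, key) for s in summaries])
    else:
        raise ValueError(f"unknown ranking key {key!r}; use one of {RANK_KEYS}")
    ranks = rankdata(-values, method="average")
    return pd.DataFrame({"mutant_id": ids, "value": values, "rank": ranks})
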