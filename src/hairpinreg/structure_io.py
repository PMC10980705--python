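"""Ensemble and metadata I/O plus residue-numbering conventions.

Conformational ensembles are ordered, weighted collections of frames
(:class:`Conformer`).  Internally residues are numbered 1..n; the numbering
used by tau structural biologists (e.g. 295-311 for the PHF6-containing
peptide) is recovered through a single additive offset, so every region
definition downstream is expressed in author numbering and converted once.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BACKBONE_ATOMS",
    "Conformer",
    "Ensemble",
    "RegionMap",
    "MutantTable",
    "make_region_map",
    "load_ensemble",
    "write_ensemble",
    "load_mutant_table",
    "TAU295_SEQUENCE",
    "TAU295_OFFSET",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: tau(295-311) peptide, author numbering 295..311 (offset +294)
TAU295_SEQUENCE = "DNIKHVPGGGSVQIVYK"
TAU295_OFFSET = 294

AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA3TO1 = {v: k for k, v in AA1TO3.items()}


@dataclass
class Conformer:
    """A single frame: coordinates plus minimal backbone topology.

    ``atoms`` holds one ``(residue_index, residue_name, atom_name)`` triple
    per row of ``coords``; residue indices are 1-based and contiguous.
    """

    frame_id: int
    coords: np.ndarray
    atoms: list[tuple[int, str, str]]
    weight: float = 1.0

    _index: dict[tuple[int, str], int] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"frame {self.frame_id}: non-finite coordinates")
        if self.weight < 0:
            raise ValueError("frame weight must be non-negative")
        self._index = {
            (res, name): i for i, (res, _, name) in enumerate(self.atoms)
        }

    @property
    def residue_ids(self) -> list[int]:
        seen: dict[int, None] = {}
        for res, _, _ in self.atoms:
            seen.setdefault(res, None)
        return list(seen)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def has_atom(self, residue: int, atom_name: str) -> bool:
        return (residue, atom_name) in self._index

    def atom_position(self, residue: int, atom_name: str) -> np.ndarray:
        try:
            return self.coords[self._index[(residue, atom_name)]]
        except KeyError:
            raise KeyError(
                f"frame {self.frame_id}: residue {residue} has no atom "
                f"{atom_name!r}"
            ) from None

    def residue_name(self, residue: int) -> str:
        for res, name, _ in self.atoms:
            if res == residue:
                return name
        raise KeyError(residue)

    def validate_backbone(self) -> None:
        """Raise if any residue lacks N, CA, C or O."""
        for res in self.residue_ids:
            for name in BACKBONE_ATOMS:
                if not self.has_atom(res, name):
                    raise ValueError(
                        f"frame {self.frame_id}: residue {res} is missing "
                        f"backbone atom {name}"
                    )

    def with_coords(self, coords: np.ndarray, frame_id: int | None = None) -> "Conformer":
        return Conformer(
            frame_id=self.frame_id if frame_id is None else frame_id,
            coords=np.asarray(coords, dtype=float),
            atoms=list(self.atoms),
            weight=self.weight,
        )


@dataclass
class Ensemble:
    """Ordered weighted collection of conformers sharing one topology."""

    conformers: list[Conformer]
    sequence: str
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("ensemble must contain at least one conformer")
        n_res = self.conformers[0].n_residues
        for c in self.conformers:
            if c.n_residues != n_res:
                raise ValueError("conformers do not share one topology")
        if n_res != len(self.sequence):
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match "
                f"{n_res} residues"
            )
        if sum(c.weight for c in self.conformers) <= 0:
            raise ValueError("sum of frame weights must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.conformers)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.conformers], dtype=float)

    def to_internal(self, author_id: int) -> int:
        return author_id - self.numbering_offset

    def to_author(self, internal_id: int) -> int:
        return internal_id + self.numbering_offset

    def __iter__(self):
        return iter(self.conformers)

    def __len__(self) -> int:
        return len(self.conformers)


@dataclass(frozen=True)
class RegionMap:
    """Named residue sets (author numbering) parameterizing all classifiers.

    ``offset`` converts author numbering to internal 1-based indices
    (internal = author - offset).
    """

    hexapeptide: frozenset[int]
    scored_hex: frozenset[int]
    even_set: frozenset[int]
    odd_set: frozenset[int]
    n_arm: frozenset[int]
    excluded_termini: frozenset[int]
    turn: frozenset[int]
    offset: int = 0

    def __post_init__(self) -> None:
        if self.even_set & self.odd_set:
            raise ValueError("even_set and odd_set overlap")
        if self.excluded_termini & (self.even_set | self.odd_set):
            raise ValueError("excluded termini appear in a parity set")

    def to_internal(self, author_ids: Iterable[int]) -> frozenset[int]:
        return frozenset(i - self.offset for i in author_ids)

    @property
    def bond_eligible_hex(self) -> frozenset[int]:
        """Hexapeptide-side residues whose cross-arm H-bonds count."""
        return (self.scored_hex | self.even_set | self.odd_set) - self.excluded_termini


def make_region_map(
    sequence: str,
    spec: str | Mapping[str, object] = "tau295_default",
    offset: int | None = None,
) -> RegionMap:
    """Build a :class:`RegionMap`, defaulting to the tau 295-311 conventions.

    The default reproduces the published regions: PHF6 hexapeptide 306-311
    (scored 306-310), even set {306, 308, 310}, odd set {305, 307, 309},
    N-terminal arm 296-304, termini 295/311 excluded, turn 301-304.
    """
    if spec == "tau295_default":
        if offset is None:
            offset = TAU295_OFFSET
        params: dict[str, object] = dict(
            hexapeptide=range(306, 312),
            scored_hex=range(306, 311),
            even_set=(306, 308, 310),
            odd_set=(305, 307, 309),
            n_arm=range(296, 305),
            excluded_termini=(295, 311),
            turn=range(301, 305),
        )
    elif isinstance(spec, Mapping):
        params = dict(spec)
        if offset is None:
            offset = int(params.pop("offset", 0))
        else:
            params.pop("offset", None)
    else:
        raise ValueError(f"unknown region spec {spec!r}")

    rm = RegionMap(
        hexapeptide=frozenset(params["hexapeptide"]),
        scored_hex=frozenset(params["scored_hex"]),
        even_set=frozenset(params["even_set"]),
        odd_set=frozenset(params["odd_set"]),
        n_arm=frozenset(params["n_arm"]),
        excluded_termini=frozenset(params["excluded_termini"]),
        turn=frozenset(params["turn"]),
        offset=offset,
    )
    n = len(sequence)
    every = (
        rm.hexapeptide | rm.scored_hex | rm.even_set | rm.odd_set
        | rm.n_arm | rm.excluded_termini | rm.turn
    )
    for author_id in every:
        internal = author_id - rm.offset
        if not 1 <= internal <= n:
            raise ValueError(
                f"residue {author_id} (internal {internal}) outside the "
                f"{n}-residue sequence"
            )
    return rm


@dataclass
class MutantTable:
    """Mutant library: id, sequence, numbering offset, optional T_1/2 (h)."""

    records: pd.DataFrame

    REQUIRED = ("mutant_id", "sequence", "numbering_offset")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.records.columns:
                raise ValueError(f"mutant table lacks column {col!r}")
        ids = self.records["mutant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate mutant_id {dup!r}")
        lengths = self.records["sequence"].str.len().unique()
        if len(lengths) > 1:
            raise ValueError("sequences in a library must share one length")
        if "experimental_T_half" in self.records.columns:
            th = self.records["experimental_T_half"]
            if (th.dropna() <= 0).any():
                raise ValueError("experimental_T_half must be positive")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, mutant_id: str) -> pd.Series:
        sel = self.records[self.records["mutant_id"] == mutant_id]
        if sel.empty:
            raise KeyError(mutant_id)
        return sel.iloc[0]


def load_mutant_table(path: str | Path) -> MutantTable:
    df = pd.read_csv(path)
    if "experimental_T_half" in df.columns:
        df["experimental_T_half"] = pd.to_numeric(
            df["experimental_T_half"], errors="coerce"
        )
    return MutantTable(df)


# ---------------------------------------------------------------------------
# PDB ensemble I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element for atom name {atom_name!r}")


def load_ensemble(
    path: str | Path,
    fmt: str = "pdb",
    numbering_offset: int | None = None,
    sequence: str | None = None,
) -> Ensemble:
    """Read a multi-model PDB into an :class:`Ensemble`.

    Every MODEL is one frame (files without MODEL records are single-frame);
    weights default to 1.  If ``numbering_offset`` is None it is inferred so
    that the file's residue numbering is preserved as author numbering.
    """
    if fmt != "pdb":
        raise ValueError(f"unsupported ensemble format {fmt!r}")
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    stack = pdb.get_structure(f)  # AtomArrayStack (models, atoms)
    if stack.stack_depth() == 0 or stack.array_length() == 0:
        raise ValueError(f"{path}: no frames found")

    res_ids_file = stack.res_id
    first = int(res_ids_file.min())
    if numbering_offset is None:
        numbering_offset = first - 1
    internal = res_ids_file - first + 1

    atoms: list[tuple[int, str, str]] = []
    for i in range(stack.array_length()):
        atoms.append(
            (int(internal[i]), str(stack.res_name[i]), str(stack.atom_name[i]))
        )

    conformers = []
    for m in range(stack.stack_depth()):
        c = Conformer(frame_id=m, coords=np.array(stack.coord[m]), atoms=atoms)
        c.validate_backbone()
        conformers.append(c)

    if sequence is None:
        seq_chars = []
        seen: set[int] = set()
        for res, name, _ in atoms:
            if res not in seen:
                seen.add(res)
                seq_chars.append(AA3TO1.get(name, "X"))
        sequence = "".join(seq_chars)

    return Ensemble(
        conformers=conformers,
        sequence=sequence,
        numbering_offset=numbering_offset,
    )


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (author numbering)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    ref = ensemble.conformers[0]
    n_atoms = len(ref.atoms)
    template = struc.AtomArray(n_atoms)
    for i, (res, res_name, atom_name) in enumerate(ref.atoms):
        template.chain_id[i] = "A"
        template.res_id[i] = ensemble.to_author(res)
        template.res_name[i] = res_name
        template.atom_name[i] = atom_name
        template.element[i] = _element_of(atom_name)
        template.hetero[i] = False

    coords = np.stack([c.coords for c in ensemble.conformers])
    stack = struc.from_template(template, coords.astype(np.float32))
    f = pdb.PDBFile()
    pdb.set_structure(f, stack)
    f.write(str(path))
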