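"""Atomic structure records and PDB input/output.

Parsing and formatting of fixed-column PDB files is delegated to `gemmi`;
this module maps gemmi structures into lightweight :class:`Atom` /
:class:`Chain` records, applies altloc/HETATM/element conventions, and
locates the per-nucleotide sample atoms (the ribose C1' carbon, whose
B-factor is the regression target).

Conventions applied on top of the raw parse:

* only the first model of multi-model files is read;
* for alternate locations, the first-listed conformer of each atom is kept;
* HETATM records are ignored unless ``include_hetatm=True``;
* the element is taken from the element column when present, otherwise
  derived from the leading letter of the atom name, and coarsened to
  {C, N, O, P, H, other};
* hydrogens are retained at parse time — removing them is
  :func:`select_heavy_atoms`'s job.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Chain",
    "StructureSet",
    "StructureError",
    "EmptyStructureError",
    "HEAVY_ELEMENTS",
    "SAMPLE_ATOM_NAMES",
    "read_structure",
    "write_structure",
    "select_heavy_atoms",
    "find_sample_atoms",
]

logger = logging.getLogger(__name__)

#: heavy elements of a ribonucleotide, in the fixed feature order
HEAVY_ELEMENTS = ("C", "N", "O", "P")

#: accepted names for the per-nucleotide sample atom, in priority order:
#: modern C1', legacy C1*, bare C1
SAMPLE_ATOM_NAMES = ("C1'", "C1*", "C1")


class StructureError(ValueError):
    """A structure file violates the parsing contract."""


class EmptyStructureError(StructureError):
    """No usable ATOM records were found."""


@dataclass(frozen=True, eq=False)  # identity equality: coords are arrays
class Atom:
    """One atomic record: identity, coordinates (Å) and B-factor (Å²)."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    coords: np.ndarray
    b_factor: float

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.isfinite(c).all():
            raise ValueError(f"atom {self.atom_name}: coords must be 3 finite reals")
        object.__setattr__(self, "coords", c)


@dataclass
class Chain:
    """An ordered list of atoms sharing one chain identifier."""

    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a in self.atoms:
            if a.chain_id != self.chain_id:
                raise ValueError(
                    f"atom chain id {a.chain_id!r} != chain {self.chain_id!r}"
                )

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class StructureSet:
    """Chains parsed from one or more source files."""

    chains: list[Chain] = field(default_factory=list)
    source: str = ""

    def __len__(self) -> int:
        return len(self.chains)

    def extend(self, other: "StructureSet") -> None:
        seen = {c.chain_id for c in self.chains}
        for ch in other.chains:
            cid = ch.chain_id
            if cid in seen:
                raise StructureError(f"duplicate chain id {cid!r} when merging")
            self.chains.append(ch)
            seen.add(cid)


def _coarse_element(gemmi_atom: gemmi.Atom) -> str:
    name = gemmi_atom.element.name.upper()
    if name in ("", "X"):
        # element column absent: fall back to the atom-name convention
        # (leading letters before any digit/prime)
        stripped = gemmi_atom.name.strip().lstrip("0123456789")
        name = stripped[:1].upper()
    if name in ("C", "N", "O", "P", "H"):
        return name
    if name == "D":  # deuterium
        return "H"
    return "other"


def read_structure(
    path, format: str = "PDB", include_hetatm: bool = False
) -> StructureSet:
    """Parse a PDB file into a :class:`StructureSet`.

    Raises :class:`EmptyStructureError` when no atom survives parsing and
    ``OSError`` when the file cannot be read.  Records with non-finite
    coordinates are skipped with a warning.
    """
    if format.upper() != "PDB":
        raise ValueError(f"unsupported structure format {format!r}")
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    chains: list[Chain] = []
    if len(st) > 0:
        model = st[0]  # first model only
        for gch in model:
            atoms: list[Atom] = []
            for res in gch:
                if not include_hetatm and res.het_flag == "H":
                    continue
                seen_names: set[str] = set()
                for ga in res:
                    if ga.name in seen_names:  # altloc duplicate: keep first
                        continue
                    xyz = (ga.pos.x, ga.pos.y, ga.pos.z)
                    if not all(math.isfinite(v) for v in xyz):
                        logger.warning(
                            "%s: skipping atom %s/%s with non-finite coordinates",
                            path.name, gch.name, ga.name,
                        )
                        continue
                    seen_names.add(ga.name)
                    atoms.append(
                        Atom(
                            chain_id=gch.name,
                            residue_index=res.seqid.num,
                            residue_name=res.name.strip(),
                            atom_name=ga.name.strip(),
                            element=_coarse_element(ga),
                            coords=np.array(xyz),
                            b_factor=float(ga.b_iso),
                        )
                    )
            if atoms:
                chains.append(Chain(gch.name, atoms))
    if not chains:
        raise EmptyStructureError(f"{path}: no ATOM records parsed")
    ids = [c.chain_id for c in chains]
    if len(set(ids)) != len(ids):
        raise StructureError(f"{path}: duplicate chain identifiers {ids}")
    return StructureSet(chains, source=str(path))


def write_structure(structures: StructureSet, path) -> None:
    """Write a :class:`StructureSet` as fixed-column PDB ATOM records.

    Coordinates are stored at 3 decimals and B-factors at 2 — the PDB
    column precision — so ``read_structure(write_structure(S))`` reproduces
    ``S`` to that precision.
    """
    for ch in structures.chains:
        for a in ch.atoms:
            if not (np.isfinite(a.coords).all() and math.isfinite(a.b_factor)):
                raise ValueError(
                    f"chain {ch.chain_id} atom {a.atom_name}: non-finite value"
                )

    st = gemmi.Structure()
    st.name = "rnaflex"
    model = gemmi.Model("1")
    for ch in structures.chains:
        gch = gemmi.Chain(ch.chain_id)
        current: gemmi.Residue | None = None
        for a in ch.atoms:
            if (
                current is None
                or current.seqid.num != a.residue_index
                or current.name != a.residue_name
            ):
                current = gemmi.Residue()
                current.name = a.residue_name
                current.seqid = gemmi.SeqId(a.residue_index, " ")
                current.het_flag = "A"
                gch.add_residue(current)
                current = gch[-1]
            ga = gemmi.Atom()
            ga.name = a.atom_name
            ga.pos = gemmi.Position(*a.coords)
            ga.occ = 1.0
            ga.b_iso = a.b_factor
            ga.element = gemmi.Element(a.element if a.element != "other" else "X")
            current.add_atom(ga)
        model.add_chain(gch)
    st.add_model(model)
    st.write_pdb(str(path))


def select_heavy_atoms(
    chain: Chain, elements: Iterable[str] = HEAVY_ELEMENTS
) -> list[Atom]:
    """Atoms of the chain whose element is in ``elements``, order preserved."""
    wanted = frozenset(elements)
    return [a for a in chain.atoms if a.element in wanted]


def find_sample_atoms(chain: Chain) -> list[Atom]:
    """The per-nucleotide C1' sample atoms of a chain, in residue order.

    Atom names C1', C1* and bare C1 are accepted, in that priority, one per
    residue.  Returns an empty list (after logging a warning) when the chain
    has none, in which case the chain is excluded from featurization.
    """
    by_residue: dict[int, dict[str, Atom]] = {}
    order: list[int] = []
    for a in chain.atoms:
        name = a.atom_name.strip()
        if name in SAMPLE_ATOM_NAMES:
            if a.residue_index not in by_residue:
                order.append(a.residue_index)
            by_residue.setdefault(a.residue_index, {})[name] = a
    found: list[Atom] = []
    for ridx in order:
        candidates = by_residue[ridx]
        for name in SAMPLE_ATOM_NAMES:
            if name in candidates:
                found.append(candidates[name])
                break
    if not found:
        logger.warning("chain %s: no C1' sample atoms found; chain excluded",
                       chain.chain_id)
    return found
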