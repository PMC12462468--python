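"""Monomeric predicted-structure models as ordered alpha-carbon traces.

Models follow the AlphaFold-DB convention for predicted structures: a
single chain numbered 1..L along the reference protein sequence, with the
per-residue confidence (pLDDT, 0-100) stored in the B-factor column.
Only the CA atom of each residue is used; pLDDT is read from the CA atom's
B-factor (AlphaFold writes identical values for every atom of a residue).

Large proteins are deposited as multiple overlapping fragments, each with
its own absolute residue numbering; :func:`select_fragment` picks the
fragment covering the most variant positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import gemmi

from mlof.errors import AmbiguityError, CoverageError, EmptyModelError, ParseError

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


@dataclass(frozen=True)
class ResidueSite:
    """One residue of a model: position, amino acid, CA coordinates, pLDDT."""

    position: int
    aa: str
    ca_xyz: tuple[float, float, float]
    plddt: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"residue position must be >= 1, got {self.position}")
        if not 0.0 <= self.plddt <= 100.0:
            raise ValueError(f"pLDDT must be in [0, 100], got {self.plddt}")


@dataclass
class StructureModel:
    """Ordered CA trace of one model fragment of one protein."""

    protein_id: str
    residues: list[ResidueSite]
    fragment_id: int = 1
    sequence: str = field(default="")

    def __post_init__(self) -> None:
        positions = [r.position for r in self.residues]
        if positions != sorted(positions):
            self.residues = sorted(self.residues, key=lambda r: r.position)
            positions = [r.position for r in self.residues]
        if len(set(positions)) != len(positions):
            raise AmbiguityError(f"{self.protein_id}: duplicate residue positions")
        if not self.sequence and self.residues:
            # reconstruct from the sites; gaps become 'X'
            length = positions[-1]
            seq = ["X"] * length
            for r in self.residues:
                seq[r.position - 1] = r.aa
            self.sequence = "".join(seq)

    @property
    def positions(self) -> list[int]:
        return [r.position for r in self.residues]

    def __len__(self) -> int:
        return len(self.residues)

    def site(self, position: int) -> ResidueSite:
        for r in self.residues:
            if r.position == position:
                return r
        raise KeyError(position)


def read_structure(path: str, protein_id: str | None = None, fragment_id: int = 1) -> StructureModel:
    """Read a PDB model into a :class:`StructureModel`.

    One ResidueSite per residue carrying a CA atom; pLDDT is taken from the
    CA atom's B-factor and positions from residue sequence numbers.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ParseError(f"cannot read structure file {path}: {exc}") from exc
    if len(st) == 0 or len(st[0]) == 0:
        raise EmptyModelError(f"{path}: no chains / ATOM records")
    chain = st[0][0]
    sites: list[ResidueSite] = []
    seen: set[int] = set()
    for res in chain:
        ca = res.find_atom("CA", "*")
        if ca is None:
            continue
        pos = res.seqid.num
        if pos in seen:
            raise AmbiguityError(f"{path}: duplicate residue number {pos}")
        seen.add(pos)
        aa = _THREE_TO_ONE.get(res.name.upper(), "X")
        sites.append(ResidueSite(pos, aa, (ca.pos.x, ca.pos.y, ca.pos.z), ca.b_iso))
    if not sites:
        raise EmptyModelError(f"{path}: no CA atoms found")
    pid = protein_id if protein_id is not None else (st.name or "UNKNOWN")
    return StructureModel(protein_id=pid, residues=sites, fragment_id=fragment_id)


def write_structure(model: StructureModel, path: str) -> None:
    """Write a CA-trace model as PDB, pLDDT in the B-factor column."""
    st = gemmi.Structure()
    st.name = model.protein_id
    md = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for site in model.residues:
        res = gemmi.Residue()
        res.name = _ONE_TO_THREE.get(site.aa, "GLY")
        res.seqid = gemmi.SeqId(site.position, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*site.ca_xyz)
        atom.occ = 1.0
        atom.b_iso = site.plddt
        res.add_atom(atom)
        chain.add_residue(res)
    md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


def select_fragment(models: Sequence[StructureModel], variants) -> StructureModel:
    """Pick the fragment covering the most distinct variant positions.

    Ties break deterministically toward the lowest fragment_id.  Raises
    :class:`CoverageError` when no fragment covers any variant position.
    """
    if not models:
        raise ValueError("no models supplied")
    pids = {m.protein_id for m in models}
    if len(pids) > 1:
        raise ValueError(f"models span multiple proteins: {sorted(pids)}")
    var_positions = {v.position for v in variants.variants}
    best = None
    best_key = None
    for m in models:
        covered = len(var_positions & set(m.positions))
        key = (-covered, m.fragment_id)
        if best_key is None or key < best_key:
            best, best_key = m, key
    if best_key is None or best_key[0] == 0:
        raise CoverageError(
            f"{models[0].protein_id}: no fragment covers any of the "
            f"{len(var_positions)} variant positions"
        )
    return best
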