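"""Coordinate I/O and the residue/atom data model.

Models are single protein chains with heavy-atom coordinates in Å.  Predicted
models carry per-residue pLDDT (AlphaFold2's 0-100 confidence) in the PDB
B-factor column; ``read_model(plddt_from_bfactor=True)`` lifts it onto the
residues.  Two numbering systems coexist and are deliberately kept apart:

* 1-based *sequence index* into the query — used by every positional API
  (windows, mutation sets, MSA columns);
* *author residue numbers* from the PDB — carried along and used only to
  match models against experimental references with missing density.

Hydrogens are dropped on read; for altloc groups only the highest-occupancy
conformer is kept, so inter-atomic distances are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Residue",
    "StructureModel",
    "read_model",
    "write_model",
    "query_sequence",
    "read_fasta",
    "write_fasta",
    "infer_element",
]


@dataclass
class Residue:
    """One amino-acid residue: author number, 3-letter name, heavy atoms.

    ``atoms`` is a list of ``(atom_name, x, y, z)`` tuples in Å; atom names
    are unique within the residue.  ``plddt`` is optional and in [0, 100].
    """

    number: int
    name: str
    atoms: list[tuple[str, float, float, float]] = field(default_factory=list)
    plddt: float | None = None

    def atom(self, name: str) -> tuple[float, float, float]:
        for aname, x, y, z in self.atoms:
            if aname == name:
                return (x, y, z)
        raise KeyError(f"residue {self.name}{self.number} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a[0] == name for a in self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([[x, y, z] for _, x, y, z in self.atoms], dtype=float)


@dataclass
class StructureModel:
    """An ordered single-chain protein model."""

    model_id: str
    residues: list[Residue]
    source_path: str | None = None

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self, positions: list[int] | None = None) -> np.ndarray:
        """Cα coordinates, (L, 3).  ``positions`` are 1-based sequence indices.

        Raises ``ValueError`` naming the residue if a Cα is missing.
        """
        if positions is None:
            positions = list(range(1, len(self.residues) + 1))
        out = np.empty((len(positions), 3), dtype=float)
        for k, pos in enumerate(positions):
            res = self.residues[pos - 1]
            try:
                out[k] = res.atom("CA")
            except KeyError:
                raise ValueError(
                    f"model {self.model_id}: residue {res.name}{res.number} "
                    f"(sequence position {pos}) lacks a CA atom required here"
                ) from None
        return out

    def plddt_array(self) -> np.ndarray:
        vals = [r.plddt for r in self.residues]
        if any(v is None for v in vals):
            missing = [r.number for r in self.residues if r.plddt is None]
            raise ValueError(
                f"model {self.model_id}: residues {missing[:5]}... lack pLDDT"
            )
        return np.array(vals, dtype=float)

    def validate(self) -> None:
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError(f"model {self.model_id}: residue numbers not strictly increasing")
        for r in self.residues:
            if not r.atoms:
                raise ValueError(f"model {self.model_id}: residue {r.name}{r.number} has no atoms")
            names = [a[0] for a in r.atoms]
            if len(names) != len(set(names)):
                raise ValueError(
                    f"model {self.model_id}: duplicate atom names in {r.name}{r.number}"
                )
            if not np.all(np.isfinite(r.coords())):
                raise ValueError(
                    f"model {self.model_id}: non-finite coordinates in {r.name}{r.number}"
                )
            if r.plddt is not None and not (0.0 <= r.plddt <= 100.0):
                raise ValueError(
                    f"model {self.model_id}: pLDDT {r.plddt} outside [0, 100] "
                    f"at {r.name}{r.number}"
                )


def infer_element(atom_name: str) -> str:
    """Element symbol from a (PDB-style) heavy-atom name, e.g. 'CA'→'C', 'OD1'→'O'."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    if stripped[:2].upper() in ("SE",):  # selenium (MSE)
        return "SE"
    return stripped[0].upper()


def _is_amino_acid(resname: str) -> bool:
    info = gemmi.find_tabulated_residue(resname)
    return info is not None and info.is_amino_acid()


def _best_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    return max(atoms, key=lambda a: (a.occ, -ord(a.altloc or "A")))


def read_model(
    path: str | Path,
    plddt_from_bfactor: bool = False,
    chain: str | None = None,
    model_id: str | None = None,
) -> StructureModel:
    """Read a PDB (or mmCIF) file into a :class:`StructureModel`.

    The first protein chain is used unless ``chain`` names one explicitly;
    additional protein chains trigger a warning.  Hydrogens and non-amino-acid
    residues (waters, ligands) are dropped; altloc groups are collapsed to the
    highest-occupancy conformer.  With ``plddt_from_bfactor`` the per-residue
    pLDDT is taken from the Cα B-factor (falling back to the residue's first
    atom when Cα is absent).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    gmodel = st[0]

    protein_chains = [
        ch for ch in gmodel if any(_is_amino_acid(res.name) for res in ch)
    ]
    if not protein_chains:
        raise ValueError(f"{path}: no protein chain found (protein-only input expected)")
    if chain is not None:
        matches = [ch for ch in protein_chains if ch.name == chain]
        if not matches:
            raise ValueError(
                f"{path}: chain {chain!r} not found; protein chains: "
                f"{[ch.name for ch in protein_chains]}"
            )
        gchain = matches[0]
    else:
        if len(protein_chains) > 1:
            warnings.warn(
                f"{path}: multiple protein chains "
                f"{[ch.name for ch in protein_chains]}; using first "
                f"({protein_chains[0].name}) — pass chain= to select",
                stacklevel=2,
            )
        gchain = protein_chains[0]

    residues: list[Residue] = []
    for gres in gchain:
        if not _is_amino_acid(gres.name):
            continue
        by_name: dict[str, list[gemmi.Atom]] = {}
        for atom in gres:
            if atom.element.is_hydrogen:
                continue
            by_name.setdefault(atom.name, []).append(atom)
        atoms = []
        bfactors = {}
        for aname, group in by_name.items():
            a = _best_altloc(group)
            atoms.append((aname, a.pos.x, a.pos.y, a.pos.z))
            bfactors[aname] = a.b_iso
        if not atoms:
            continue
        plddt = None
        if plddt_from_bfactor:
            plddt = bfactors.get("CA", next(iter(bfactors.values())))
        residues.append(
            Residue(number=gres.seqid.num, name=gres.name, atoms=atoms, plddt=plddt)
        )
    if not residues:
        raise ValueError(f"{path}: zero parseable protein residues")
    model = StructureModel(
        model_id=model_id or path.stem, residues=residues, source_path=str(path)
    )
    model.validate()
    return model


def write_model(model: StructureModel, path: str | Path, chain_name: str = "A") -> None:
    """Write a model as PDB; pLDDT (when present) goes to the B-factor column."""
    st = gemmi.Structure()
    st.name = model.model_id
    gmodel = gemmi.Model("1")
    gchain = gemmi.Chain(chain_name)
    for res in model.residues:
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.number, " ")
        for aname, x, y, z in res.atoms:
            atom = gemmi.Atom()
            atom.name = aname
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            atom.b_iso = res.plddt if res.plddt is not None else 0.0
            atom.element = gemmi.Element(infer_element(aname))
            gres.add_atom(atom)
        gchain.add_residue(gres)
    gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


_THREE_TO_ONE_EXTRA = {"MSE": "M", "SEC": "U", "PYL": "O"}


def query_sequence(model: StructureModel) -> str:
    """1-letter amino-acid sequence, in residue order; unknown residues → 'X'."""
    letters = []
    for res in model.residues:
        if res.name in _THREE_TO_ONE_EXTRA:
            letters.append(_THREE_TO_ONE_EXTRA[res.name])
            continue
        info = gemmi.find_tabulated_residue(res.name)
        if info is not None and info.is_amino_acid():
            one = info.one_letter_code.upper()
            letters.append(one if one.isalpha() else "X")
        else:
            letters.append("X")
    return "".join(letters)


def read_fasta(path: str | Path) -> tuple[str, str]:
    """First record of a FASTA file as ``(id, sequence)``."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA")
    return records[0].id, str(records[0].seq)


def write_fasta(seq_id: str, sequence: str, path: str | Path) -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=seq_id, description="")], str(path), "fasta")
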