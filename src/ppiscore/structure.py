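"""Minimal chain/residue/atom model read from PDB files.

The scored object is a multi-chain protein complex.  Parsing keeps only what
the scoring scheme needs: heavy atoms of standard amino-acid residues with
their coordinates, grouped by chain, plus the main-chain/side-chain split
that defines the three interaction modes (main-main, main-side, side-side).

Filtering rules:

* hydrogens and waters are always dropped;
* non-polymer HETATM records (ligands, ions, cofactors such as haem) are
  dropped — only the 20 canonical amino acids are scored, with
  selenomethionine (MSE) mapped to MET;
* alternate locations are resolved to the highest-occupancy conformer
  (first wins on a tie); only the first MODEL of multi-model files is read.
"""

from __future__ import annotations

import logging
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import EmptyStructureError, FormatError

logger = logging.getLogger(__name__)

#: Backbone heavy-atom names for standard residues.  Everything else
#: (including CB) counts as side chain; glycine therefore contributes
#: main-chain atoms only.
MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

MAIN_CHAIN = "main_chain"
SIDE_CHAIN = "side_chain"

#: Canonical one-letter order used for all 20x20 matrices.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
    # selenomethionine is scored as methionine
    "MSE": "M",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class Atom:
    """One heavy atom: PDB name, element symbol, position in Å."""

    name: str
    element: str
    coord: np.ndarray  # shape (3,), float64
    is_backbone: bool

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.name}: coord must be 3 finite components")
        object.__setattr__(self, "coord", coord)


@dataclass
class Residue:
    """One standard amino-acid residue with author numbering preserved."""

    chain_id: str
    seq_id: int
    icode: str
    aa: str  # one-letter code, one of AA_ORDER
    atoms: list[Atom] = field(default_factory=list)

    @property
    def label(self) -> str:
        """Author residue label, e.g. ``A:42`` or ``A:42A``."""
        return f"{self.chain_id}:{self.seq_id}{self.icode.strip()}"

    @property
    def aa3(self) -> str:
        return ONE_TO_THREE[self.aa]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    """A parsed complex: ordered chains of residues of heavy atoms."""

    id: str
    chains: list[Chain] = field(default_factory=list)

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)


def classify_atom(aa: str, atom_name: str) -> str:
    """Classify a heavy atom as ``main_chain`` or ``side_chain``.

    The main-chain set is {N, CA, C, O, OXT}; every other name — including
    CB and any nonstandard name — is side chain.  ``aa`` is accepted for
    interface symmetry but does not affect the rule.
    """
    return MAIN_CHAIN if atom_name.strip() in MAIN_CHAIN_ATOMS else SIDE_CHAIN


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; first in file order on a tie
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ:
            best = a
    return best


def _convert_residue(chain_id: str, res: gemmi.Residue) -> Residue | None:
    name = res.name.strip()
    if name in _WATER_NAMES or name not in THREE_TO_ONE:
        return None
    by_name: dict[str, list[gemmi.Atom]] = {}
    for atom in res:
        if atom.element.is_hydrogen:
            continue
        by_name.setdefault(atom.name.strip(), []).append(atom)
    atoms = []
    for atom_name, group in by_name.items():
        a = _pick_altloc(group)
        atoms.append(
            Atom(
                name=atom_name,
                element=a.element.name,
                coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                is_backbone=atom_name in MAIN_CHAIN_ATOMS,
            )
        )
    if not atoms:
        return None
    return Residue(
        chain_id=chain_id,
        seq_id=res.seqid.num,
        icode=(res.seqid.icode or " ").strip() or "",
        aa=THREE_TO_ONE[name],
        atoms=atoms,
    )


def read_structure(source: str | Path, structure_id: str | None = None) -> Structure:
    """Read a PDB file (path or PDB-format text) into a :class:`Structure`.

    Hydrogens, waters and non-polymer HETATM records are dropped, altlocs
    are resolved to the highest-occupancy conformer, and only the first
    MODEL is used.

    Raises
    ------
    FormatError
        if the source cannot be parsed as PDB.
    EmptyStructureError
        if no standard amino-acid residues remain after filtering.
    """
    try:
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            st = gemmi.read_pdb(str(source))
            label = structure_id or Path(source).stem
        else:
            st = gemmi.read_pdb_string(str(source))
            label = structure_id or (st.name or "structure")
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot parse PDB input: {exc}") from exc

    if len(st) == 0:
        raise EmptyStructureError("no ATOM records found")
    model = st[0]  # first MODEL only

    chains: list[Chain] = []
    seen_ids: set[str] = set()
    n_dropped = 0
    for gchain in model:
        cid = gchain.name.strip() or "_"
        residues = []
        for gres in gchain:
            conv = _convert_residue(cid, gres)
            if conv is None:
                n_dropped += 1
            else:
                residues.append(conv)
        if not residues:
            continue
        if cid in seen_ids:
            # gemmi may split a chain at a TER/het boundary; merge back
            self_chain = next(c for c in chains if c.chain_id == cid)
            self_chain.residues.extend(residues)
        else:
            seen_ids.add(cid)
            chains.append(Chain(chain_id=cid, residues=residues))

    if n_dropped:
        logger.debug("dropped %d non-standard/water residues", n_dropped)
    if not chains:
        raise EmptyStructureError(
            "no standard amino-acid residues remain after filtering"
        )
    return Structure(id=label, chains=chains)


def fetch_structure(pdb_id: str, cache_dir: str | Path = ".") -> Structure:
    """Download ``<pdb_id>.pdb`` from RCSB and parse it.

    Convenience helper for interactive use; requires network access and is
    never needed by the test suite or the synthetic-fixture workflow.
    """
    pdb_id = pdb_id.lower()
    if len(pdb_id) != 4 or not pdb_id.isalnum():
        raise ValueError(f"not a 4-character PDB code: {pdb_id!r}")
    path = Path(cache_dir) / f"{pdb_id}.pdb"
    if not path.exists():
        url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
        with urllib.request.urlopen(url) as resp:  # pragma: no cover - network
            path.write_bytes(resp.read())
    return read_structure(path, structure_id=pdb_id)
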