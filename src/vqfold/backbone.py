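"""Protein backbone structures: PDB I/O and the in-memory backbone model.

A backbone is the ordered list of residues with their N, CA, C, O atoms.  This
is the object every other part of the package operates on: the encoder embeds
it, the decoder reconstructs it, and all ensemble metrics compare instances of
it.  Parsing is delegated to gemmi; only the first MODEL is read (an explicit
`read_models` helper returns one structure per MODEL for ensemble analysis).
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

ATOM_NAMES = ("N", "CA", "C", "O")
N, CA, C, O = 0, 1, 2, 3

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
UNKNOWN_AA = "X"

ResidueSelector = Union[int, tuple]


class PDBParseError(ValueError):
    """Raised when no parsable backbone residues are found."""


@dataclass
class BackboneStructure:
    """Ordered residues with N/CA/C/O coordinates in Angstrom.

    coords has shape (L, 4, 3) in the atom order N, CA, C, O; atom_mask marks
    which of the four atoms are present (CA is always required).
    """

    chain_ids: list
    residue_numbers: np.ndarray
    insertion_codes: list
    amino_acids: list
    coords: np.ndarray
    atom_mask: np.ndarray

    def __post_init__(self):
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.atom_mask = np.asarray(self.atom_mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        L = len(self.chain_ids)
        if L < 2:
            raise ValueError("a backbone needs at least 2 residues")
        if self.coords.shape != (L, 4, 3):
            raise ValueError(f"coords must be ({L}, 4, 3), got {self.coords.shape}")
        if self.atom_mask.shape != (L, 4):
            raise ValueError("atom_mask must be (L, 4)")
        if not self.atom_mask[:, CA].all():
            raise ValueError("every residue must have a CA atom")
        if not np.isfinite(self.coords[self.atom_mask]).all():
            raise ValueError("present-atom coordinates must be finite")
        # residues of one chain must be contiguous and strictly ordered
        seen_chains: set = set()
        prev_chain = None
        prev_key: Optional[tuple] = None
        for cid, num, icode in zip(self.chain_ids, self.residue_numbers,
                                   self.insertion_codes):
            if cid != prev_chain:
                if cid in seen_chains:
                    raise ValueError(f"chain {cid!r} is not contiguous")
                seen_chains.add(cid)
                prev_chain, prev_key = cid, None
            key = (int(num), icode)
            if prev_key is not None and key <= prev_key:
                raise ValueError(
                    f"residues out of order in chain {cid!r}: {prev_key} -> {key}")
            prev_key = key

    def __len__(self) -> int:
        return len(self.chain_ids)

    @property
    def ca(self) -> np.ndarray:
        """CA coordinates, shape (L, 3)."""
        return self.coords[:, CA, :]

    def sequence(self) -> str:
        return "".join(self.amino_acids)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "BackboneStructure":
        """Apply a rigid motion x -> R x + t to all atoms."""
        coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return self.with_coords(coords)

    def with_coords(self, coords: np.ndarray) -> "BackboneStructure":
        return BackboneStructure(list(self.chain_ids),
                                 self.residue_numbers.copy(),
                                 list(self.insertion_codes),
                                 list(self.amino_acids),
                                 np.asarray(coords, dtype=np.float64),
                                 self.atom_mask.copy())

    def crop(self, start: int, stop: int) -> "BackboneStructure":
        sl = slice(start, stop)
        return BackboneStructure(self.chain_ids[sl],
                                 self.residue_numbers[sl],
                                 self.insertion_codes[sl],
                                 self.amino_acids[sl],
                                 self.coords[sl],
                                 self.atom_mask[sl])

    def find_residue(self, selector: ResidueSelector) -> int:
        """Index of a residue.

        Selectors: residue number (first match across chains), (chain, number)
        or (chain, number, insertion_code).
        """
        if isinstance(selector, (int, np.integer)):
            chain, number, icode = None, int(selector), None
        else:
            parts = tuple(selector)
            chain = parts[0]
            number = int(parts[1])
            icode = parts[2] if len(parts) > 2 else None
        for i in range(len(self)):
            if self.residue_numbers[i] != number:
                continue
            if chain is not None and self.chain_ids[i] != chain:
                continue
            if icode is not None and self.insertion_codes[i] != icode:
                continue
            return i
        raise KeyError(f"residue {selector!r} not found")


def _structure_from_gemmi_model(model, chains) -> Optional[BackboneStructure]:
    chain_ids, numbers, icodes, aas, coords, masks = [], [], [], [], [], []
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for res in chain:
            if res.name in ("HOH", "DOD", "WAT"):
                continue
            xyz = np.zeros((4, 3))
            mask = np.zeros(4, dtype=bool)
            for ai, aname in enumerate(ATOM_NAMES):
                best = None
                for atom in res:
                    if atom.name != aname:
                        continue
                    if best is None or atom.occ > best.occ or (
                            atom.occ == best.occ and atom.altloc == "A"):
                        best = atom
                if best is not None:
                    xyz[ai] = (best.pos.x, best.pos.y, best.pos.z)
                    mask[ai] = True
            if not mask[CA]:
                if mask.any():
                    logger.warning("dropping residue %s %s%s: no CA atom",
                                   chain.name, res.seqid.num, res.seqid.icode.strip())
                continue
            if not (mask[N] and mask[C]) and res.het_flag == "H":
                continue  # hetero ligand without a peptide backbone
            chain_ids.append(chain.name)
            numbers.append(res.seqid.num)
            icodes.append(res.seqid.icode.strip())
            aas.append(_THREE_TO_ONE.get(res.name, UNKNOWN_AA))
            coords.append(xyz)
            masks.append(mask)
    if len(chain_ids) < 2:
        return None
    return BackboneStructure(chain_ids, np.array(numbers), icodes, aas,
                             np.array(coords), np.array(masks))


def _read_gemmi(source: Union[str, os.PathLike]) -> gemmi.Structure:
    text: Optional[str] = None
    if isinstance(source, str) and ("\n" in source or source.lstrip()[:6] in
                                    ("ATOM  ", "HEADER", "MODEL ", "REMARK")):
        text = source
    elif not os.path.exists(os.fspath(source)):
        raise FileNotFoundError(f"no such file: {source!r}")
    try:
        if text is not None:
            st = gemmi.read_pdb_string(text)
        else:
            st = gemmi.read_structure(os.fspath(source))
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"could not parse PDB input: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError("input contains no models")
    return st


def read_pdb(source: Union[str, os.PathLike],
             chains: Optional[Iterable[str]] = None) -> BackboneStructure:
    """Read a backbone from PDB text or a PDB/mmCIF file (first MODEL only).

    Hetero residues without peptide backbones and all waters are skipped;
    residues without a CA atom are dropped with a warning; for alternate
    locations the highest-occupancy conformer is kept (ties: altloc 'A').
    """
    st = _read_gemmi(source)
    chains = set(chains) if chains is not None else None
    s = _structure_from_gemmi_model(st[0], chains)
    if s is None:
        raise PDBParseError("no parsable backbone residues in selection")
    return s


def read_models(source: Union[str, os.PathLike],
                chains: Optional[Iterable[str]] = None) -> list:
    """One BackboneStructure per MODEL (for multi-model ensembles)."""
    st = _read_gemmi(source)
    chains = set(chains) if chains is not None else None
    out = []
    for model in st:
        s = _structure_from_gemmi_model(model, chains)
        if s is not None:
            out.append(s)
    if not out:
        raise PDBParseError("no parsable backbone residues in any model")
    return out


def write_pdb(s: BackboneStructure, path: Optional[Union[str, os.PathLike]] = None,
              model_number: Optional[int] = None) -> str:
    """Serialize a backbone to PDB text (and optionally write it to `path`)."""
    s.validate()
    buf = io.StringIO()
    if model_number is not None:
        buf.write(f"MODEL {model_number:>8d}\n")
    serial = 1
    prev_chain = None
    for i in range(len(s)):
        cid = s.chain_ids[i]
        if prev_chain is not None and cid != prev_chain:
            buf.write("TER\n")
        prev_chain = cid
        resname = _ONE_TO_THREE.get(s.amino_acids[i], "UNK")
        for ai, aname in enumerate(ATOM_NAMES):
            if not s.atom_mask[i, ai]:
                continue
            x, y, z = s.coords[i, ai]
            icode = s.insertion_codes[i] or " "
            buf.write(
                f"ATOM  {serial:>5d}  {aname:<3s}{resname:>3s} {cid[:1]}"
                f"{int(s.residue_numbers[i]):>4d}{icode}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {aname[0]:>2s}\n")
            serial += 1
    buf.write("TER\n")
    if model_number is not None:
        buf.write("ENDMDL\n")
    else:
        buf.write("END\n")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def write_ensemble_pdb(members: Sequence[BackboneStructure],
                       path: Optional[Union[str, os.PathLike]] = None) -> str:
    """Write same-length backbones as a multi-MODEL PDB."""
    parts = [write_pdb(m, model_number=i + 1) for i, m in enumerate(members)]
    text = "".join(parts) + "END\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def ca_distance(s: BackboneStructure, res_a: ResidueSelector,
                res_b: ResidueSelector) -> float:
    """Euclidean CA-CA distance in Angstrom between two residues."""
    i = s.find_residue(res_a)
    j = s.find_residue(res_b)
    return float(np.linalg.norm(s.ca[i] - s.ca[j]))
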