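"""Reading and writing backbones, sequences and probability profiles.

PDB parsing is delegated to biotite (alternate locations resolved by
highest occupancy). Only single chains are supported; residues missing any
of N, CA, C, O are dropped with a logged warning, and common non-standard
residues (e.g. MSE) are mapped to their parent amino acid.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .alphabet import (
    AA_TO_INDEX,
    AMINO_ACIDS,
    NONSTANDARD_PARENT,
    THREE_TO_ONE,
    UNKNOWN,
    encode_sequence,
)
from .types import BackboneStructure, PartialSequence, ProbabilityProfile

logger = logging.getLogger(__name__)

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
BACKBONE_ATOMS = ("N", "CA", "C", "O")
PROFILE_HEADER = "#" + AMINO_ACIDS
ROW_SUM_TOLERANCE = 1e-3


def read_backbone(path: str | Path, chain: str) -> BackboneStructure:
    """Read one chain's backbone from a PDB file.

    Residue order follows file order; alternate locations are resolved to
    the highest-occupancy conformer. Raises ``FileNotFoundError`` for a
    missing file, ``ValueError`` when the chain is absent or no residue has
    a complete backbone.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="occupancy")
    chain_mask = atoms.chain_id == chain
    if not chain_mask.any():
        available = sorted(set(atoms.chain_id))
        raise ValueError(f"chain {chain!r} not found; file has chains {available}")
    atoms = atoms[chain_mask]

    coords = {name: [] for name in BACKBONE_ATOMS}
    numbers, letters = [], []
    for start, stop in zip(*_residue_bounds(atoms)):
        res = atoms[start:stop]
        res_name = res.res_name[0]
        one = THREE_TO_ONE.get(res_name) or NONSTANDARD_PARENT.get(res_name)
        if one is None:
            if "CA" in res.atom_name:
                logger.warning("dropping unmapped residue %s %d in chain %s",
                               res_name, int(res.res_id[0]), chain)
            continue
        positions = {}
        for atom in BACKBONE_ATOMS:
            hit = np.flatnonzero(res.atom_name == atom)
            if hit.size:
                positions[atom] = res.coord[hit[0]]
        if len(positions) < len(BACKBONE_ATOMS):
            missing = [a for a in BACKBONE_ATOMS if a not in positions]
            logger.warning("dropping residue %s %d in chain %s: missing %s",
                           res_name, int(res.res_id[0]), chain, ",".join(missing))
            continue
        for atom in BACKBONE_ATOMS:
            coords[atom].append(positions[atom])
        numbers.append(int(res.res_id[0]))
        letters.append(one)
    if not numbers:
        raise ValueError(f"chain {chain!r} has no residues with a complete backbone")
    return BackboneStructure(
        chain_id=chain,
        coords_N=np.array(coords["N"]),
        coords_CA=np.array(coords["CA"]),
        coords_C=np.array(coords["C"]),
        coords_O=np.array(coords["O"]),
        residue_numbers=np.array(numbers),
        native_sequence="".join(letters),
    )


def _residue_bounds(atoms) -> tuple[np.ndarray, np.ndarray]:
    starts = struc.get_residue_starts(atoms)
    stops = np.append(starts[1:], len(atoms))
    return starts, stops


def write_backbone(structure: BackboneStructure, path: str | Path) -> None:
    """Write a backbone-only PDB file (N, CA, C, O per residue)."""
    n = structure.n_residues
    seq = structure.native_sequence or "A" * n
    atoms = struc.AtomArray(4 * n)
    coords = np.empty((4 * n, 3))
    for i in range(n):
        for a, atom_name in enumerate(BACKBONE_ATOMS):
            idx = 4 * i + a
            atoms.chain_id[idx] = structure.chain_id
            atoms.res_id[idx] = structure.residue_numbers[i]
            atoms.res_name[idx] = ONE_TO_THREE.get(seq[i], "ALA")
            atoms.atom_name[idx] = atom_name
            atoms.element[idx] = atom_name[0]
            coords[idx] = getattr(structure, f"coords_{atom_name}")[i]
    atoms.coord = coords
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_partial_sequence(path: str | Path, expected_length: int) -> PartialSequence:
    """Read a single-record FASTA; 'X' marks unknown positions."""
    header, seq = _read_fasta(path)
    if len(seq) != expected_length:
        raise ValueError(
            f"sequence length {len(seq)} does not match expected {expected_length}")
    tokens = encode_sequence(seq, allow_unknown=True)
    return PartialSequence(tokens=tokens,
                           visible_mask=tokens != AA_TO_INDEX[UNKNOWN])


def _read_fasta(path: str | Path) -> tuple[str, str]:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith(">"):
        raise ValueError(f"{path} is not a FASTA file")
    header = lines[0][1:].strip()
    seq = "".join(line.strip() for line in lines[1:] if not line.startswith(">"))
    return header, seq.upper()


def write_design(path: str | Path, sequence: str, header: str) -> None:
    """Write a single-record FASTA, wrapped at 60 columns."""
    with open(path, "w") as fh:
        fh.write(f">{header}\n")
        for start in range(0, len(sequence), 60):
            fh.write(sequence[start:start + 60] + "\n")


def read_probability_profile(path: str | Path, expected_length: int) -> ProbabilityProfile:
    """Read an N x 20 tab-separated profile in canonical alphabet order.

    Rows whose sum deviates from 1 by at most 1e-3 are renormalized; larger
    deviations, negative entries or a wrong column count raise ValueError.
    """
    probs = np.loadtxt(path, comments="#", delimiter="\t", ndmin=2)
    if probs.shape != (expected_length, len(AMINO_ACIDS)):
        raise ValueError(
            f"profile shape {probs.shape} does not match "
            f"({expected_length}, {len(AMINO_ACIDS)})")
    if (probs < 0).any():
        raise ValueError("profile contains negative probabilities")
    sums = probs.sum(axis=1)
    bad = np.abs(sums - 1.0) > ROW_SUM_TOLERANCE
    if bad.any():
        raise ValueError(
            f"profile row {int(np.flatnonzero(bad)[0])} sums to "
            f"{sums[bad][0]:.6f}, outside 1 +/- {ROW_SUM_TOLERANCE}")
    probs = probs / sums[:, None]
    return ProbabilityProfile(probs=probs, source="base")


def write_probability_profile(path: str | Path, profile: ProbabilityProfile) -> None:
    """Write a profile as TSV with the canonical alphabet header line."""
    with open(path, "w") as fh:
        fh.write(PROFILE_HEADER + "\n")
        for row in profile.probs:
            fh.write("\t".join(f"{x:.8f}" for x in row) + "\n")
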