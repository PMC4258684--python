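"""Per-residue RMSD between two conformational states.

Structural comparison of the inactive- and active-state coordinates gives a
covariance-independent map of the allosteric network for well-folded regions:
after least-squares rigid superposition, residues whose local RMSD exceeds a
threshold (1 Angstrom, i.e. ~10% of the maximum, in the canonical use) are
the structure-based allosteric set, which can be compared with the residue
sets produced by the shift-covariance schemes.

Structures are held as plain DataFrames with columns
``residue_id, atom, x, y, z`` so that synthetic toy structures and parsed PDB
files flow through the same operations.  PDB parsing uses Biopython (first
model, first altloc; occupancies are not weighted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError

__all__ = [
    "BACKBONE_ATOMS",
    "load_structure",
    "write_pdb",
    "coordinate_rmsd",
    "superpose",
    "per_residue_rmsd",
    "threshold_structural_set",
    "SuperpositionResult",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def load_structure(
    path: str | Path, chain: str | None = None, model: int = 0
) -> pd.DataFrame:
    """Read ATOM coordinates from a PDB file into a structure table."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(Path(path).stem, str(path))
    rows = []
    mdl = list(structure)[model]
    for ch in mdl:
        if chain is not None and ch.id != chain:
            continue
        for residue in ch:
            hetflag, resseq, _ = residue.id
            if hetflag.strip():
                continue  # skip heteroatoms/water
            seen = set()
            for atom in residue:
                if atom.name in seen:
                    continue  # first altloc wins
                seen.add(atom.name)
                x, y, z = atom.coord
                rows.append(
                    {
                        "residue_id": int(resseq),
                        "atom": atom.name,
                        "x": float(x),
                        "y": float(y),
                        "z": float(z),
                    }
                )
    if not rows:
        raise DegenerateInputError(f"no ATOM records read from {path}")
    return pd.DataFrame(rows)


def write_pdb(structure: pd.DataFrame, path: str | Path, chain: str = "A") -> None:
    """Write a structure table as minimal PDB ATOM records (CA-style toys)."""
    lines = []
    for serial, (_, row) in enumerate(structure.iterrows(), start=1):
        lines.append(
            f"ATOM  {serial:5d} {row['atom']:<4s}ALA {chain}{int(row['residue_id']):4d}"
            f"    {row['x']:8.3f}{row['y']:8.3f}{row['z']:8.3f}  1.00  0.00"
            f"          {row['atom'][0]:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def coordinate_rmsd(
    a: pd.DataFrame,
    b: pd.DataFrame,
    atom_selection: Sequence[str] | None = BACKBONE_ATOMS,
) -> float:
    """Global RMSD over common selected atoms of the coordinates as given.

    No superposition is performed — use this after :func:`superpose`, or when
    the frames are already aligned.  One atom displaced by ``d`` among ``N``
    otherwise identical atoms gives exactly ``d / sqrt(N)``.
    """
    ref, mob = _common_atoms(a, b, atom_selection)
    if len(ref) == 0:
        raise DegenerateInputError("no common atoms between the structures")
    sq = ((ref.to_numpy(dtype=float) - mob.to_numpy(dtype=float)) ** 2).sum(axis=1)
    return float(np.sqrt(sq.mean()))


@dataclass
class SuperpositionResult:
    """Transformed mobile structure plus the global fit RMSD."""

    transformed: pd.DataFrame
    rmsd: float
    rotation: np.ndarray
    translation: np.ndarray


def _common_atoms(
    a: pd.DataFrame, b: pd.DataFrame, atoms: Sequence[str] | None
) -> pd.DataFrame:
    ka = a.set_index(["residue_id", "atom"])[["x", "y", "z"]]
    kb = b.set_index(["residue_id", "atom"])[["x", "y", "z"]]
    common = ka.index.intersection(kb.index)
    if atoms is not None:
        common = common[[atom in atoms for _, atom in common]]
    return ka.loc[common], kb.loc[common]


def superpose(
    a: pd.DataFrame,
    b: pd.DataFrame,
    atom_selection: Sequence[str] | None = BACKBONE_ATOMS,
) -> SuperpositionResult:
    """Least-squares rigid superposition of structure ``b`` onto ``a``.

    The rotation/translation is fitted over the common (residue, atom) pairs
    in ``atom_selection`` (default backbone N, CA, C, O; ``None`` selects all
    shared atoms) and applied to every atom of ``b``.  Returns the
    transformed structure and the global RMSD over the fitted selection.
    """
    ref, mob = _common_atoms(a, b, atom_selection)
    if len(ref) < 3:
        raise DegenerateInputError(
            f"superposition needs >= 3 common atoms, got {len(ref)}"
        )
    from Bio.SVDSuperimposer import SVDSuperimposer

    sup = SVDSuperimposer()
    sup.set(ref.to_numpy(dtype=float), mob.to_numpy(dtype=float))
    sup.run()
    rot, tran = sup.get_rotran()
    transformed = b.copy()
    coords = transformed[["x", "y", "z"]].to_numpy(dtype=float) @ rot + tran
    transformed[["x", "y", "z"]] = coords
    return SuperpositionResult(
        transformed=transformed,
        rmsd=float(sup.get_rms()),
        rotation=rot,
        translation=tran,
    )


def per_residue_rmsd(
    a: pd.DataFrame,
    b_superposed: pd.DataFrame,
    atom_selection: Sequence[str] | None = BACKBONE_ATOMS,
) -> pd.Series:
    """RMSD per common residue over the selected atoms (already superposed).

    Residues missing in either structure (or with no shared selected atoms)
    are omitted with a warning.
    """
    ref, mob = _common_atoms(a, b_superposed, atom_selection)
    if len(ref) == 0:
        raise DegenerateInputError("no common atoms between the structures")
    sq = ((ref.to_numpy(dtype=float) - mob.to_numpy(dtype=float)) ** 2).sum(axis=1)
    per_res = (
        pd.DataFrame({"residue_id": ref.index.get_level_values(0), "sq": sq})
        .groupby("residue_id")["sq"]
        .mean()
        .pow(0.5)
    )
    all_res = set(a["residue_id"]) | set(b_superposed["residue_id"])
    skipped = sorted(all_res - set(per_res.index))
    if skipped:
        warnings.warn(
            f"residues without shared selected atoms omitted: {skipped}",
            stacklevel=2,
        )
    per_res.name = "rmsd"
    return per_res


def threshold_structural_set(
    rmsd_map: pd.Series | dict,
    mode: str = "absolute",
    value: float = 1.0,
) -> frozenset:
    """Residues whose local RMSD marks a significant conformational change.

    ``absolute`` keeps residues with RMSD >= ``value`` Angstrom; the
    ``fraction_of_max`` mode keeps RMSD >= ``value * max(RMSD)``.
    """
    if value <= 0:
        raise ValueError(f"threshold value must be > 0, got {value}")
    series = pd.Series(rmsd_map, dtype=float)
    if series.empty:
        raise DegenerateInputError("empty RMSD map")
    if mode == "absolute":
        cut = value
    elif mode == "fraction_of_max":
        cut = value * float(series.max())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return frozenset(int(r) for r in series.index[series >= cut])
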