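"""File I/O: multi-model PDB ensembles and TSV tables.

PDB files are parsed with biotite (MODEL/ENDMDL records delimit
snapshots; files without MODEL records yield a single-model ensemble)
after a light line-level sanity check that reports the offending line
number for truncated ATOM records.  Tabular data uses tab-separated
files with a header row; angles are degrees on disk and radians in
memory, lengths are angstrom, rotations are stored row-major as nine
matrix entries or as four quaternion components (w, x, y, z).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .rototrans import RototransSampleSet
from .spaces import quaternion_to_matrix, validate_rotation_matrices

__all__ = [
    "read_models",
    "write_models",
    "read_angle_table",
    "write_angle_table",
    "read_vector_table",
    "write_vector_table",
    "read_transform_table",
    "write_transform_table",
    "atom_mask",
    "parse_selection",
]

_MIN_ATOM_LINE = 54  # columns through the z coordinate


def _validate_pdb_lines(path: str) -> None:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            record = line[:6].strip()
            if record in ("ATOM", "HETATM"):
                stripped = line.rstrip("\n")
                if len(stripped) < _MIN_ATOM_LINE:
                    raise ValueError(
                        f"{path}: truncated {record} record at line {lineno}"
                    )
                try:
                    for start, stop in ((30, 38), (38, 46), (46, 54)):
                        float(stripped[start:stop])
                except ValueError as err:
                    raise ValueError(
                        f"{path}: malformed coordinates at line {lineno}"
                    ) from err


def read_models(path: str):
    """Read a (multi-model) PDB file into a biotite ``AtomArrayStack``."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    _validate_pdb_lines(path)
    pdb_file = pdb.PDBFile.read(path)
    stack = pdb_file.get_structure()
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    return stack


def write_models(stack, path: str) -> None:
    """Write an ``AtomArrayStack`` as a multi-model PDB file."""
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(path)


# ---------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------

def read_angle_table(path: str) -> pd.DataFrame:
    """Long-format torsion-angle table (degrees on disk).

    Columns: residue_index, residue_type, variant, angle_name, degrees,
    model (chain_id optional).
    """
    table = pd.read_csv(path, sep="\t")
    if "degrees" not in table.columns:
        raise ValueError(f"{path}: angle tables need a 'degrees' column")
    if not np.issubdtype(table["degrees"].dtype, np.number):
        raise ValueError(f"{path}: non-numeric angle entries")
    return table


def write_angle_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_vector_table(path: str) -> np.ndarray:
    """n x d numeric table (e.g. translation vectors in angstrom)."""
    table = pd.read_csv(path, sep="\t")
    data = table.to_numpy()
    if not np.issubdtype(data.dtype, np.number):
        raise ValueError(f"{path}: non-numeric cells in vector table")
    return data.astype(float)


def write_vector_table(vectors: np.ndarray, path: str, names=None) -> None:
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if names is None:
        names = [f"v{i}" for i in range(vectors.shape[1])]
    pd.DataFrame(vectors, columns=list(names)).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


_ROT_COLS = ["r11", "r12", "r13", "r21", "r22", "r23", "r31", "r32", "r33"]
_QUAT_COLS = ["qw", "qx", "qy", "qz"]
_TRANS_COLS = ["tx", "ty", "tz"]


def read_transform_table(path: str) -> RototransSampleSet:
    """Per-snapshot rigid transforms from a TSV.

    Either nine row-major rotation entries (r11..r33) or four quaternion
    components (qw..qz), plus translation columns tx, ty, tz.
    """
    table = pd.read_csv(path, sep="\t")
    if set(_ROT_COLS) <= set(table.columns):
        rotations = table[_ROT_COLS].to_numpy(dtype=float).reshape(-1, 3, 3)
    elif set(_QUAT_COLS) <= set(table.columns):
        rotations = quaternion_to_matrix(table[_QUAT_COLS].to_numpy(dtype=float))
    else:
        raise ValueError(
            f"{path}: need rotation columns {_ROT_COLS} or quaternion columns {_QUAT_COLS}"
        )
    if not set(_TRANS_COLS) <= set(table.columns):
        raise ValueError(f"{path}: need translation columns {_TRANS_COLS}")
    validate_rotation_matrices(rotations)
    translations = table[_TRANS_COLS].to_numpy(dtype=float)
    return RototransSampleSet(rotations, translations)


def write_transform_table(samples: RototransSampleSet, path: str) -> None:
    data = np.hstack(
        [samples.rotations.reshape(-1, 9), samples.translations]
    )
    pd.DataFrame(data, columns=_ROT_COLS + _TRANS_COLS).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


# ---------------------------------------------------------------------
# atom selections
# ---------------------------------------------------------------------

def parse_selection(selection: str) -> tuple[str | None, list[int] | None, list[str] | None]:
    """Parse a 'CHAIN:RESIDS:ATOMS' selection string.

    ``RESIDS`` is a comma-separated list of ids or id ranges (``32-37``);
    empty fields select everything, e.g. ``A:32-37,245:N,CA,C`` or
    ``B::CA``.
    """
    parts = selection.split(":")
    if len(parts) != 3:
        raise ValueError(
            f"selection {selection!r} must have the form CHAIN:RESIDS:ATOMS"
        )
    chain = parts[0] or None
    res_ids: list[int] | None = None
    if parts[1]:
        res_ids = []
        for token in parts[1].split(","):
            if "-" in token.lstrip("-")[0:] and token.count("-") == 1 and not token.startswith("-"):
                lo, hi = token.split("-")
                res_ids.extend(range(int(lo), int(hi) + 1))
            else:
                res_ids.append(int(token))
    atoms = parts[2].split(",") if parts[2] else None
    return chain, res_ids, atoms


def atom_mask(atoms, selection: str) -> np.ndarray:
    """Boolean mask over an ``AtomArray`` for a selection string."""
    chain, res_ids, names = parse_selection(selection)
    mask = np.ones(atoms.array_length(), dtype=bool)
    if chain is not None:
        mask &= atoms.chain_id == chain
    if res_ids is not None:
        mask &= np.isin(atoms.res_id, res_ids)
    if names is not None:
        mask &= np.isin(atoms.atom_name, names)
    return mask
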