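"""Reading and writing PDB structures, multi-model PDB trajectories, and
TSV result tables.

PDB parsing is delegated to biotite's fixed-column reader; this module
adds the package's conventions on top: altloc resolution by highest
occupancy, exclusion of waters and other HETATM records, element
resolution against the internal mass table, and strict topology checking
across trajectory frames.
"""

from __future__ import annotations

import os
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .elements import infer_element, mass_of
from .errors import EmptyStructureError, StructureIOError, TopologyError
from .structures import Atom, ComplexModel, Trajectory

__all__ = [
    "read_pdb",
    "read_trajectory",
    "write_pdb",
    "write_trajectory",
    "write_table",
    "read_table",
]


def _atoms_from_array(arr: bst.AtomArray, *, include_hetero: bool) -> list[Atom]:
    if not include_hetero:
        arr = arr[~arr.hetero]
    atoms: list[Atom] = []
    for i in range(arr.array_length()):
        name = str(arr.atom_name[i])
        element = str(arr.element[i]).strip()
        if not element:
            element = infer_element(name)
        serial = int(arr.atom_id[i]) if "atom_id" in arr.get_annotation_categories() else i + 1
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=element,
                residue_number=int(arr.res_id[i]),
                residue_name=str(arr.res_name[i]),
                chain_id=str(arr.chain_id[i]),
                position=tuple(float(c) for c in arr.coord[i]),
                mass=mass_of(element, atom_label=f"{serial} {name}"),
            )
        )
    return atoms


def _read_pdbfile(path: str | os.PathLike) -> PDBFile:
    try:
        return PDBFile.read(str(path))
    except OSError:
        raise
    except Exception as exc:  # malformed records
        raise StructureIOError(f"cannot parse PDB file {path}: {exc}") from exc


def _model_atoms(pdbfile: PDBFile, model: int, *, include_hetero: bool) -> list[Atom]:
    with warnings.catch_warnings():
        # biotite warns when it guesses elements from atom names; that is
        # exactly our documented fallback, so stay quiet.
        warnings.simplefilter("ignore", UserWarning)
        arr = pdbfile.get_structure(
            model=model, altloc="occupancy", extra_fields=["atom_id", "occupancy"]
        )
    return _atoms_from_array(arr, include_hetero=include_hetero)


def read_pdb(
    path: str | os.PathLike,
    *,
    model_id: str | int | None = None,
    include_hetero: bool = False,
) -> ComplexModel:
    """Read a single-model PDB file into a :class:`ComplexModel`.

    Altloc duplicates are resolved by keeping the highest-occupancy
    location (ties keep the first). Waters and other HETATM records are
    excluded unless ``include_hetero`` is set. The first MODEL block is
    used if the file holds several.
    """
    pdbfile = _read_pdbfile(path)
    if pdbfile.get_model_count() == 0:
        raise EmptyStructureError(f"no ATOM records found in {path}")
    atoms = _model_atoms(pdbfile, model=1, include_hetero=include_hetero)
    if not atoms:
        raise EmptyStructureError(f"no ATOM records found in {path}")
    if model_id is None:
        model_id = os.path.splitext(os.path.basename(str(path)))[0]
    return ComplexModel(model_id=model_id, atoms=atoms)


def read_trajectory(
    path: str | os.PathLike,
    replicate_id: str,
    *,
    include_hetero: bool = False,
) -> Trajectory:
    """Read a multi-model PDB file as the frames of one MD replicate.

    Frames keep file order. Every frame must share the first frame's
    (chain, residue number, residue name, atom name) topology; a mismatch
    raises :class:`TopologyError` naming the first offending frame.
    """
    pdbfile = _read_pdbfile(path)
    n_models = pdbfile.get_model_count()
    if n_models == 0:
        raise EmptyStructureError(f"no models found in {path}")
    frames: list[ComplexModel] = []
    ref_key = None
    for m in range(1, n_models + 1):
        atoms = _model_atoms(pdbfile, model=m, include_hetero=include_hetero)
        if not atoms:
            raise EmptyStructureError(f"model {m} of {path} has no ATOM records")
        frame = ComplexModel(model_id=f"{replicate_id}:{m}", atoms=atoms)
        key = frame.topology_key()
        if ref_key is None:
            ref_key = key
        elif key != ref_key:
            raise TopologyError(
                f"trajectory {path}: frame {m} topology differs from frame 1"
            )
        frames.append(frame)
    return Trajectory(replicate_id=replicate_id, frames=frames)


def _to_atom_array(model: ComplexModel) -> bst.AtomArray:
    n = len(model.atoms)
    arr = bst.AtomArray(n)
    arr.coord = model.coords.astype(np.float32)
    arr.chain_id = np.array([a.chain_id for a in model.atoms])
    arr.res_id = np.array([a.residue_number for a in model.atoms])
    arr.res_name = np.array([a.residue_name for a in model.atoms])
    arr.atom_name = np.array([a.name for a in model.atoms])
    arr.element = np.array([a.element.upper() for a in model.atoms])
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_pdb(model: ComplexModel, path: str | os.PathLike) -> None:
    """Write a ComplexModel as a single-model PDB file."""
    pdbfile = PDBFile()
    pdbfile.set_structure(_to_atom_array(model))
    pdbfile.write(str(path))


def write_trajectory(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write a Trajectory as a multi-model PDB (MODEL/ENDMDL blocks)."""
    stack = bst.stack([_to_atom_array(f) for f in traj.frames])
    pdbfile = PDBFile()
    pdbfile.set_structure(stack)
    pdbfile.write(str(path))


#: columns rendered with 2 decimals in output tables (Å quantities)
_ANGSTROM_COLUMNS = {
    "mean",
    "sd",
    "mean_distance",
    "sd_distance",
    "pooled_mean",
    "pooled_sd",
    "distance",
    "pooled_mean_distance",
}


def write_table(
    rows: Sequence[Mapping] | pd.DataFrame,
    path: str | os.PathLike,
    *,
    float_decimals: int = 2,
) -> None:
    """Write homogeneous records as a TSV with a header row.

    Å-valued columns are rendered with 2 decimals; other floats use
    ``float_decimals``. An empty row list still produces the header when a
    DataFrame (with columns) is given, or an empty file otherwise.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df = df.copy()
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            dec = 2 if col in _ANGSTROM_COLUMNS else float_decimals
            df[col] = df[col].map(lambda v: f"{v:.{dec}f}")
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
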