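"""File formats: multi-model PDB trajectories, FASTA sequences, TSV tables.

Conformations travel as multi-model PDB (one MODEL per saved frame, three
backbone ATOM records N/CA/C per residue), energy series and reports as
TSV with ``#``-prefixed metadata headers. Coordinates survive a PDB round
trip to the format's fixed 3-decimal precision.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb
from biotite.sequence import ProteinSequence
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "write_multi_model_pdb",
    "read_multi_model_pdb",
    "write_xyz",
    "write_energy_series",
    "read_energy_series",
    "write_fasta",
    "read_fasta",
    "config_hash",
]

_ATOM_NAMES = ("N", "CA", "C")
_ELEMENTS = ("N", "C", "C")


def _atom_array(sequence: str) -> struc.AtomArray:
    n_res = len(sequence)
    arr = struc.AtomArray(3 * n_res)
    arr.chain_id = np.full(3 * n_res, "A")
    arr.res_id = np.repeat(np.arange(1, n_res + 1), 3)
    arr.res_name = np.repeat(
        [ProteinSequence.convert_letter_1to3(aa) for aa in sequence], 3)
    arr.atom_name = np.tile(_ATOM_NAMES, n_res)
    arr.element = np.tile(_ELEMENTS, n_res)
    arr.hetero = np.zeros(3 * n_res, dtype=bool)
    return arr


def write_multi_model_pdb(frames: np.ndarray, sequence: str,
                          path: str | Path) -> None:
    """Write (F, 3n, 3) backbone frames as a multi-model PDB file."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] == 0:
        raise ValueError("refusing to write an empty trajectory")
    if frames.shape[1] != 3 * len(sequence):
        raise ValueError("frame size does not match sequence length")
    template = _atom_array(sequence)
    stack = struc.from_template(template, frames)
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def read_multi_model_pdb(path: str | Path) -> tuple[np.ndarray, str]:
    """Read a multi-model PDB back into (frames, one-letter sequence)."""
    path = Path(path)
    text = path.read_text()
    if not any(line.startswith(("ATOM", "HETATM")) for line in
               text.splitlines()):
        raise ValueError(f"{path}: no ATOM records (empty trajectory?)")
    f = pdb.PDBFile.read(str(path))
    stack = f.get_structure(model=None)
    arr0 = stack[0] if isinstance(stack, struc.AtomArrayStack) else stack
    res_ids = arr0.res_id[arr0.atom_name == "CA"]
    res_names = arr0.res_name[arr0.atom_name == "CA"]
    seq = "".join(ProteinSequence.convert_letter_3to1(rn) for rn in res_names)
    if len(res_ids) * 3 != arr0.array_length():
        raise ValueError(f"{path}: expected exactly N/CA/C per residue")
    coords = stack.coord if isinstance(stack, struc.AtomArrayStack) \
        else stack.coord[None]
    return np.asarray(coords, dtype=float), seq


def write_xyz(frames: np.ndarray, path: str | Path,
              names: list[str] | None = None) -> None:
    """Plain XYZ stream (one block per frame), a lightweight alternative."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n = frames.shape[1]
    names = names or [(_ATOM_NAMES[i % 3]) for i in range(n)]
    with open(path, "w") as fh:
        for f in frames:
            fh.write(f"{n}\n\n")
            for name, (x, y, z) in zip(names, f):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def config_hash(text: str) -> str:
    """Short stable hash used to stamp outputs with their configuration."""
    return hashlib.sha1(text.encode()).hexdigest()[:12]


def write_energy_series(df: pd.DataFrame, path: str | Path,
                        metadata: dict | None = None) -> None:
    """TSV with '#'-comment metadata header (time, potential, kinetic, rg)."""
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_energy_series(path: str | Path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, meta


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
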