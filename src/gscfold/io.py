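"""Text-first file formats: BED segmentations, contact maps, XYZ, configs.

All formats are plain text for portability: BED (0-based, half-open,
column 4 = state label) for segmentations, dense TSV or upper-triangle
``i<TAB>j<TAB>value`` triplets for matrices, XYZ for sampled 3D
configurations, and flat ``key=value`` files for model constants.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import ChainModel, ChromatinAnnotation, CrumplingTable, PolymerParams
from .observables import ContactMap

__all__ = [
    "read_segmentation",
    "write_segmentation",
    "read_bed_records",
    "read_contact_map",
    "write_contact_map",
    "write_configurations",
    "read_crumpling_table",
    "write_crumpling_table",
    "write_params",
    "read_params",
]


class InputError(ValueError):
    """Malformed input file; CLI maps this to exit code 2."""


def read_bed_records(path: str | Path) -> list[tuple[int, int, str]]:
    """Parse a BED file into sorted (start, end, label) records.

    Requires integer, non-overlapping, sorted coordinates; the chromosome
    column is accepted but must be unique within one file.
    """
    recs = []
    chroms = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise InputError(f"{path}:{ln}: need 4 columns (chrom start end label)")
            chrom, start, end, label = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise InputError(f"{path}:{ln}: non-integer coordinates") from exc
            chroms.add(chrom)
            recs.append((start, end, label))
    if len(chroms) > 1:
        raise InputError(f"{path}: multiple chromosomes ({sorted(chroms)}); supply one region")
    if not recs:
        raise InputError(f"{path}: no records")
    for prev, cur in zip(recs, recs[1:]):
        if cur[0] < prev[1]:
            raise InputError(
                f"{path}: overlapping or unsorted records at {cur[0]} < {prev[1]}"
            )
    return recs


def read_segmentation(path: str | Path, bp_per_bin: int = 10_000) -> ChromatinAnnotation:
    """Read a BED segmentation into one state label per bin.

    Records must tile the region contiguously and each record length must
    respect the bin grid (use :func:`gscfold.model.build_from_segmentation`
    for majority-rule re-binning of off-grid records).
    """
    recs = read_bed_records(path)
    states: list[str] = []
    pos = recs[0][0]
    for start, end, label in recs:
        if start != pos:
            raise InputError(f"{path}: gap between {pos} and {start}")
        if (end - start) % bp_per_bin:
            raise InputError(
                f"{path}: record [{start}, {end}) is not a multiple of {bp_per_bin} bp"
            )
        states.extend([label] * ((end - start) // bp_per_bin))
        pos = end
    return ChromatinAnnotation(states)


def write_segmentation(
    annotation: ChromatinAnnotation,
    path: str | Path,
    bp_per_bin: int = 10_000,
    chrom: str = "chr",
    origin: int = 0,
) -> None:
    """Write one BED record per contiguous state block (round-trip stable)."""
    with open(path, "w") as fh:
        for start, stop, state in annotation.blocks():
            fh.write(
                f"{chrom}\t{origin + start * bp_per_bin}\t"
                f"{origin + stop * bp_per_bin}\t{state}\n"
            )


def read_contact_map(path: str | Path, fmt: str = "dense") -> ContactMap:
    """Read a contact map: dense TSV or 0-based upper-triangle triplets.

    Triplet input is symmetrised; dense input must be square and is
    averaged with its transpose.
    """
    if fmt == "dense":
        M = np.loadtxt(path, ndmin=2)
        if M.shape[0] != M.shape[1]:
            raise InputError(f"{path}: dense map must be square, got {M.shape}")
        M = 0.5 * (M + M.T)
    elif fmt == "triplet":
        df = pd.read_csv(path, sep="\t", header=None, names=["i", "j", "value"],
                         comment="#")
        if df.empty:
            raise InputError(f"{path}: empty triplet file")
        i = df["i"].to_numpy(dtype=int)
        j = df["j"].to_numpy(dtype=int)
        v = df["value"].to_numpy(dtype=float)
        if (i < 0).any() or (j < 0).any():
            raise InputError(f"{path}: negative bin indices")
        N = int(max(i.max(), j.max())) + 1
        M = np.zeros((N, N))
        M[i, j] = v
        M[j, i] = v
    else:
        raise ValueError(f"unknown contact-map format {fmt!r}")
    return ContactMap(P=M)


def write_contact_map(cmap: ContactMap, path: str | Path, fmt: str = "dense") -> None:
    if fmt == "dense":
        np.savetxt(path, cmap.P, delimiter="\t", fmt="%.8g")
    elif fmt == "triplet":
        iu = np.triu_indices(cmap.N)
        with open(path, "w") as fh:
            for i, j in zip(*iu):
                v = cmap.P[i, j]
                if v != 0:
                    fh.write(f"{i}\t{j}\t{v:.8g}\n")
    else:
        raise ValueError(f"unknown contact-map format {fmt!r}")


def write_configurations(
    coords: np.ndarray,
    path: str | Path,
    annotation: Optional[ChromatinAnnotation] = None,
) -> None:
    """Write sampled configurations as multi-frame XYZ.

    ``coords`` has shape (n_frames, N, 3); the atom label of each bead is
    its chromatin state (``M`` for an unannotated chain).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n, N, _ = coords.shape
    labels = (
        [str(s) for s in annotation.states] if annotation is not None else ["M"] * N
    )
    if len(labels) != N:
        raise ValueError("annotation length must match bead count")
    with open(path, "w") as fh:
        for f in range(n):
            fh.write(f"{N}\nframe {f}\n")
            for lab, (x, y, z) in zip(labels, coords[f]):
                fh.write(f"{lab}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def write_crumpling_table(table: CrumplingTable, path: str | Path) -> None:
    """Two-column TSV (s, U_crumpling(s))."""
    with open(path, "w") as fh:
        fh.write("s\tU_crumpling\n")
        for s in range(1, table.values.size):
            fh.write(f"{s}\t{table.values[s]:.8g}\n")


def read_crumpling_table(path: str | Path) -> CrumplingTable:
    df = pd.read_csv(path, sep="\t")
    s = df.iloc[:, 0].to_numpy(dtype=int)
    u = df.iloc[:, 1].to_numpy(dtype=float)
    vals = np.zeros(int(s.max()) + 1)
    vals[s] = u
    return CrumplingTable(values=vals)


_PARAM_FIELDS = ("N", "l", "bp_per_monomer", "k", "U_ev", "r_e", "U_ns", "r_o")


def write_params(params: PolymerParams, path: str | Path) -> None:
    """Flat key=value serialization of every chain constant (round-trip safe)."""
    with open(path, "w") as fh:
        for name in _PARAM_FIELDS:
            fh.write(f"{name}={getattr(params, name)}\n")


def read_params(path: str | Path) -> PolymerParams:
    kv = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise InputError(f"{path}:{ln}: expected key=value")
            key, val = line.split("=", 1)
            key = key.strip()
            if key not in _PARAM_FIELDS:
                raise InputError(f"{path}:{ln}: unknown key {key!r}")
            kv[key] = val.strip()
    ints = {"N", "bp_per_monomer"}
    out = {}
    for key, val in kv.items():
        if val == "None":
            out[key] = None
        elif key in ints:
            out[key] = int(val)
        else:
            out[key] = float(val)
    return PolymerParams(**out)
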