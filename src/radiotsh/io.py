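"""Readers and writers for the plain-text and imaging formats used here.

Expression matrices travel as TSV (genes in rows, samples in columns,
linear scale), marker sets as GMT, abundance/survival/feature tables as
CSV, and volumes/masks as NIfTI.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

try:  # nibabel is only needed when NIfTI I/O is actually used
    import nibabel as nib
except ImportError:  # pragma: no cover
    nib = None


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes x samples expression matrix from TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression TSV")
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample ids in expression TSV")
    return df


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path) -> dict[str, list[str]]:
    """Read marker gene sets from a GMT file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, genes = parts[0], [g for g in parts[2:] if g]
            if name in sets:
                raise ValueError(f"duplicate gene set {name!r} in GMT")
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a NIfTI volume; returns (array, voxel spacing in mm)."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), spacing


def write_nifti(volume: np.ndarray, spacing, path) -> None:
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def write_mask_nifti(mask: np.ndarray, spacing, path) -> None:
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))
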