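"""Tractogram (TCK/TRK) and scalar-map (NIfTI-1) file I/O.

Both tractogram dialects are read through :mod:`nibabel.streamlines`, which
returns coordinates in RAS world mm regardless of the on-disk convention
(TRK's voxel-corner frame is undone via the header transform).  Degenerate
streamlines — fewer than two distinct consecutive points after duplicate
removal — are dropped at load with a logged count.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import ScalarVolume, Tractogram, as_streamline

log = logging.getLogger(__name__)

__all__ = [
    "load_tractogram",
    "save_tractogram",
    "load_scalar_volume",
    "save_scalar_volume",
]


def load_tractogram(path) -> Tractogram:
    """Load a TCK or TRK file into world-mm streamlines.

    Degenerate streamlines (<2 distinct points) are removed; if all
    streamlines are degenerate an empty tractogram is returned with a
    warning.

    Raises
    ------
    ValueError
        If the file extension is not a known tractogram dialect or the
        file cannot be parsed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() not in (".tck", ".trk"):
        raise ValueError(f"unknown tractogram format: {path.suffix!r}")
    try:
        tfile = nib.streamlines.load(str(path))
    except Exception as exc:  # nibabel raises assorted header errors
        raise ValueError(f"unreadable tractogram {path}: {exc}") from exc

    streamlines = []
    n_dropped = 0
    for pts in tfile.streamlines:
        try:
            streamlines.append(as_streamline(pts))
        except ValueError:
            n_dropped += 1
    if n_dropped:
        log.warning("%s: dropped %d degenerate streamline(s)", path.name, n_dropped)
    if not streamlines and n_dropped:
        log.warning("%s: all streamlines degenerate, returning empty tractogram", path.name)
    return Tractogram(streamlines=streamlines, space_id=f"world-ras-mm:{path.name}")


def save_tractogram(t: Tractogram, path, reference: ScalarVolume | None = None) -> None:
    """Write a tractogram as TCK or TRK (chosen by extension).

    TRK needs a voxel grid in its header; ``reference`` supplies the affine
    and shape, else an identity/1-mm header is written (coordinates are in
    world mm either way).
    """
    path = Path(path)
    sl = [np.asarray(s, dtype=np.float64) for s in t.streamlines]
    nib_t = nib.streamlines.Tractogram(sl, affine_to_rasmm=np.eye(4))
    if path.suffix.lower() == ".trk":
        header = nib.streamlines.trk.TrkFile.create_empty_header()
        if reference is not None:
            header["voxel_to_rasmm"] = reference.affine.astype(np.float32)
            header["voxel_sizes"] = np.abs(np.diag(reference.affine[:3, :3])).astype(np.float32)
            header["dimensions"] = np.asarray(reference.grid.shape, dtype=np.uint16)
        else:
            header["voxel_to_rasmm"] = np.eye(4, dtype=np.float32)
            header["voxel_sizes"] = np.ones(3, dtype=np.float32)
            header["dimensions"] = np.array([1, 1, 1], dtype=np.uint16)
        nib.streamlines.save(nib_t, str(path), header=header)
    elif path.suffix.lower() == ".tck":
        nib.streamlines.save(nib_t, str(path))
    else:
        raise ValueError(f"unknown tractogram format: {path.suffix!r}")


def load_scalar_volume(path, metric_name: str = "") -> ScalarVolume:
    """Load a NIfTI scalar map (.nii/.nii.gz)."""
    img = nib.load(str(path))
    grid = np.asarray(img.dataobj, dtype=np.float64)
    if grid.ndim == 4 and grid.shape[3] == 1:
        grid = grid[..., 0]
    return ScalarVolume(grid=grid, affine=np.asarray(img.affine), metric_name=metric_name)


def save_scalar_volume(vol: ScalarVolume, path) -> None:
    """Write a scalar map as NIfTI-1 (float32 on disk)."""
    img = nib.Nifti1Image(vol.grid.astype(np.float32), vol.affine)
    nib.save(img, str(path))
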