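"""File I/O: multipage TIFF stacks with JSON sidecars, design and network
checkpoints.

PSF stacks are written one page per (depth, wavelength) pair, depth-major,
with the axes and pixel pitch in a ``.json`` sidecar next to the TIFF.
Network weights go into a compressed ``.npz`` with the architecture spec in
a JSON header entry so a checkpoint is self-describing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .metaoptic import MetaOpticDesign, UnitCellLibrary, radial_map
from .optics import PSFStack, PupilGrid
from .reconstructor import Reconstructor, ReconstructorSpec
from .autodiff import Tensor

__all__ = ["write_psf_stack", "read_psf_stack", "write_image", "read_image",
           "save_design", "load_design", "export_width_map",
           "save_checkpoint", "load_checkpoint"]


def _sidecar(path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".json")


def write_psf_stack(stack: PSFStack, path) -> None:
    """Pages ordered depth-major: page = iz * n_wavelengths + il."""
    nz, nl, h, w = stack.values.shape
    tifffile.imwrite(path, stack.values.reshape(nz * nl, h, w)
                     .astype(np.float32))
    meta = {"depths_um": list(map(float, stack.depths_um)),
            "wavelengths_nm": list(map(float, stack.wavelengths_nm)),
            "pixel_pitch_um": stack.pixel_pitch_um,
            "page_order": "depth_major"}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_psf_stack(path) -> PSFStack:
    meta = json.loads(_sidecar(path).read_text())
    pages = tifffile.imread(path).astype(np.float64)
    nz, nl = len(meta["depths_um"]), len(meta["wavelengths_nm"])
    return PSFStack(values=pages.reshape(nz, nl, *pages.shape[-2:]),
                    depths_um=meta["depths_um"],
                    wavelengths_nm=meta["wavelengths_nm"],
                    pixel_pitch_um=meta["pixel_pitch_um"])


def write_image(values: np.ndarray, path, **metadata) -> None:
    """Multichannel image as TIFF (C, H, W float32) plus JSON sidecar."""
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
    if metadata:
        _sidecar(path).write_text(json.dumps(metadata, indent=1))


def read_image(path) -> tuple:
    values = tifffile.imread(path).astype(np.float64)
    side = _sidecar(path)
    meta = json.loads(side.read_text()) if side.exists() else {}
    return values, meta


def save_design(design: MetaOpticDesign, path) -> None:
    payload = {"gamma_init_nm": design.gamma_init.tolist(),
               "delta_gamma_nm": design.delta_gamma.data.tolist(),
               "width_bounds_nm": list(design.width_bounds),
               "k_rot": design.k_rot}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_design(path) -> MetaOpticDesign:
    payload = json.loads(Path(path).read_text())
    return MetaOpticDesign(
        gamma_init=np.asarray(payload["gamma_init_nm"], dtype=np.float64),
        delta_gamma=Tensor(np.asarray(payload["delta_gamma_nm"],
                                      dtype=np.float64), requires_grad=True),
        width_bounds=tuple(payload["width_bounds_nm"]),
        k_rot=payload["k_rot"])


def export_width_map(design: MetaOpticDesign, grid: PupilGrid, path) -> None:
    """Fabrication-facing 2-D width map (nm) as 32-bit float TIFF + metadata."""
    widths = design.effective_widths_array()
    full = radial_map(widths, grid, design.k_rot) * grid.mask
    tifffile.imwrite(path, full.astype(np.float32))
    meta = {"grid_pitch_um": grid.ds_um, "k_rot": design.k_rot,
            "width_bounds_nm": list(design.width_bounds),
            "pupil_diameter_um": grid.pupil_diameter_um}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def save_checkpoint(net: Reconstructor, path) -> None:
    spec = dataclasses.asdict(net.spec)
    arrays = {f"p{i}": p.data for i, p in enumerate(net.parameters())}
    # running statistics of the normalization layers travel with the weights
    stats = {}
    for j, m in enumerate(net.modules()):
        if hasattr(m, "running_mean"):
            stats[f"rm{j}"] = m.running_mean
            stats[f"rv{j}"] = m.running_var
    np.savez_compressed(path, __spec__=json.dumps(spec), **arrays, **stats)


def load_checkpoint(path) -> Reconstructor:
    with np.load(path, allow_pickle=False) as data:
        spec_dict = json.loads(str(data["__spec__"]))
        spec_dict["widths"] = tuple(spec_dict["widths"])
        net = Reconstructor(ReconstructorSpec(**spec_dict))
        for i, p in enumerate(net.parameters()):
            p.data[...] = data[f"p{i}"]
        for j, m in enumerate(net.modules()):
            if hasattr(m, "running_mean"):
                m.running_mean = data[f"rm{j}"].copy()
                m.running_var = data[f"rv{j}"].copy()
    return net
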