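"""Reading and writing lesion stacks, volumes and cohort tables.

Contours travel as one JSON file per plaque; intensity volumes as NIfTI
(``.nii.gz``, via nibabel) or NPZ arrays, one per weighting.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import Contour, CrossSection, LesionStack

WEIGHTINGS = ("t2", "t1_pre", "t1_post")


class StackIOError(ValueError):
    pass


def stack_to_contour_dict(stack: LesionStack) -> dict:
    sections = []

    def _entry(section: CrossSection, role: str) -> dict:
        return {
            "slice_index": int(section.slice_index),
            "role": role,
            "lumen": section.lumen.vertices.tolist(),
            "outer": section.outer_wall.vertices.tolist(),
        }

    sections.append(_entry(stack.stenotic, "stenotic"))
    sections.append(_entry(stack.proximal_ref, "proximal_ref"))
    sections.append(_entry(stack.distal_ref, "distal_ref"))
    for s in stack.whole_plaque:
        if s.slice_index != stack.stenotic.slice_index:
            sections.append(_entry(s, "plaque"))
    return {
        "plaque_id": stack.plaque_id,
        "slice_spacing_mm": stack.stenotic.slice_spacing,
        "voxel_spacing_mm": stack.voxel_spacing,
        "sections": sections,
        "gray_matter_roi": stack.gray_matter_roi.tolist(),
        "muscle_roi": stack.muscle_roi.tolist(),
    }


def save_lesion_stack(
    stack: LesionStack, directory: str | Path, volume_format: str = "nii.gz"
) -> Path:
    """Write ``contours.json`` plus one volume file per weighting."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "contours.json").write_text(
        json.dumps(stack_to_contour_dict(stack), indent=1)
    )
    sp = stack.voxel_spacing
    for name in WEIGHTINGS:
        data = np.asarray(stack.volumes[name], dtype=np.float32)
        if volume_format == "npz":
            np.savez(directory / f"{name}.npz", data=data, spacing=sp)
        elif volume_format == "nii.gz":
            img = nib.Nifti1Image(data, affine=np.diag([sp, sp, sp, 1.0]))
            nib.save(img, directory / f"{name}.nii.gz")
        else:
            raise StackIOError(f"unknown volume format {volume_format!r}")
    return directory


def _load_volume(directory: Path, name: str) -> np.ndarray:
    npz = directory / f"{name}.npz"
    nii = directory / f"{name}.nii.gz"
    if npz.exists():
        return np.load(npz)["data"].astype(float)
    if nii.exists():
        return np.asarray(nib.load(nii).dataobj, dtype=float)
    raise StackIOError(f"no volume file for weighting {name!r} in {directory}")


def load_lesion_stack(directory: str | Path) -> LesionStack:
    """Load a plaque directory written by :func:`save_lesion_stack`."""
    directory = Path(directory)
    contours_path = directory / "contours.json"
    try:
        payload = json.loads(contours_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise StackIOError(f"{contours_path}: {exc}") from exc

    try:
        spacing = float(payload["slice_spacing_mm"])
        voxel_spacing = float(payload.get("voxel_spacing_mm", spacing))
        by_role: dict[str, CrossSection] = {}
        plaque_sections: list[CrossSection] = []
        for entry in payload["sections"]:
            section = CrossSection(
                slice_index=int(entry["slice_index"]),
                lumen=Contour(np.asarray(entry["lumen"], float), "lumen"),
                outer_wall=Contour(np.asarray(entry["outer"], float),
                                   "outer_wall"),
                slice_spacing=spacing,
            )
            role = entry["role"]
            if role in ("stenotic", "proximal_ref", "distal_ref"):
                by_role[role] = section
            if role in ("stenotic", "plaque"):
                plaque_sections.append(section)
        plaque_sections.sort(key=lambda s: s.slice_index)
        volumes = {name: _load_volume(directory, name) for name in WEIGHTINGS}
        return LesionStack(
            stenotic=by_role["stenotic"],
            proximal_ref=by_role["proximal_ref"],
            distal_ref=by_role["distal_ref"],
            whole_plaque=tuple(plaque_sections),
            volumes=volumes,
            gray_matter_roi=np.asarray(payload["gray_matter_roi"], int),
            muscle_roi=np.asarray(payload["muscle_roi"], int),
            voxel_spacing=voxel_spacing,
            plaque_id=str(payload.get("plaque_id", directory.name)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise StackIOError(f"{contours_path}: invalid stack schema ({exc})") \
            from exc
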