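"""Volumetric containers: tissue probability maps, atlas labels, hemisphere masks.

All volumes in one analysis share a single :class:`~ieegcoverage.grid.VolumeGrid`.
Tissue maps are per-voxel probabilities (partial-volume estimates) for gray
matter, white matter and CSF; atlas labels are integer parcel ids with a
lookup table and a per-region analysis class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import VolumeGrid

#: Analysis classes for atlas regions. Subcortical and cerebellar gray matter
#: are excluded from total gray/white quantification (their clinical use in
#: epilepsy monitoring is rare and would inflate coverage).
CLASS_ANALYSIS = "cortical-analysis"
CLASS_SUBCORTICAL = "subcortical-excluded"
CLASS_CEREBELLUM = "cerebellum-excluded"
REGION_CLASSES = (CLASS_ANALYSIS, CLASS_SUBCORTICAL, CLASS_CEREBELLUM)


@dataclass
class TissueProbabilityVolumes:
    grid: VolumeGrid
    p_gm: np.ndarray
    p_wm: np.ndarray
    p_csf: np.ndarray

    def __post_init__(self) -> None:
        for name in ("p_gm", "p_wm", "p_csf"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {self.grid.shape}")
            if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
                raise ValueError(f"{name} has values outside [0, 1]")
            setattr(self, name, np.clip(arr, 0.0, 1.0))
        total = self.p_gm + self.p_wm + self.p_csf
        if total.max() > 1 + 1e-6:
            raise ValueError("tissue probabilities exceed the unit simplex")

    def save(self, directory: str | Path, prefix: str = "") -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for tissue in ("gm", "wm", "csf"):
            p = directory / f"{prefix}p_{tissue}.nii"
            nib.save(self.grid.to_nifti(getattr(self, f"p_{tissue}")), p)
            paths[tissue] = p
        return paths

    @classmethod
    def load(cls, directory: str | Path, prefix: str = "") -> "TissueProbabilityVolumes":
        directory = Path(directory)
        imgs = {
            t: nib.load(directory / f"{prefix}p_{t}.nii") for t in ("gm", "wm", "csf")
        }
        grid = VolumeGrid.from_nifti(imgs["gm"])
        return cls(
            grid,
            np.asarray(imgs["gm"].dataobj, dtype=float),
            np.asarray(imgs["wm"].dataobj, dtype=float),
            np.asarray(imgs["csf"].dataobj, dtype=float),
        )


@dataclass
class AtlasLabels:
    """Integer parcellation on the tissue grid with name + class lookup."""

    grid: VolumeGrid
    label: np.ndarray
    lut: dict[int, str]
    region_class: dict[int, str]

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label)
        if self.label.shape != self.grid.shape:
            raise ValueError("label volume shape does not match grid")
        present = set(np.unique(self.label)) - {0}
        missing = present - set(self.lut)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from lookup table")
        unclassed = set(self.lut) - set(self.region_class)
        if unclassed:
            raise ValueError(f"regions {sorted(unclassed)} have no analysis class")
        bad = set(self.region_class.values()) - set(REGION_CLASSES)
        if bad:
            raise ValueError(f"unknown region classes {sorted(bad)}")

    def ids_of_class(self, cls_name: str) -> list[int]:
        return sorted(i for i, c in self.region_class.items() if c == cls_name)

    @property
    def analysis_ids(self) -> list[int]:
        return self.ids_of_class(CLASS_ANALYSIS)

    def mask(self, region_id: int) -> np.ndarray:
        if region_id not in self.lut:
            raise KeyError(f"unknown region id {region_id}")
        return self.label == region_id

    def exclusion_mask(self) -> np.ndarray:
        """Voxels in subcortical or cerebellar parcels (excluded from totals)."""
        excl = np.zeros(self.grid.shape, dtype=bool)
        for rid in self.ids_of_class(CLASS_SUBCORTICAL) + self.ids_of_class(
            CLASS_CEREBELLUM
        ):
            excl |= self.label == rid
        return excl

    def save(self, directory: str | Path, prefix: str = "") -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / f"{prefix}atlas.nii"
        nib.save(self.grid.to_nifti(self.label.astype(np.int16)), path)
        lut_path = directory / f"{prefix}atlas_lut.tsv"
        with open(lut_path, "w") as fh:
            fh.write("id\tname\tclass\n")
            for rid in sorted(self.lut):
                fh.write(f"{rid}\t{self.lut[rid]}\t{self.region_class[rid]}\n")
        return path

    @classmethod
    def load(cls, directory: str | Path, prefix: str = "") -> "AtlasLabels":
        directory = Path(directory)
        img = nib.load(directory / f"{prefix}atlas.nii")
        lut, region_class = {}, {}
        with open(directory / f"{prefix}atlas_lut.tsv") as fh:
            next(fh)
            for line in fh:
                rid, name, rcls = line.rstrip("\n").split("\t")
                lut[int(rid)] = name
                region_class[int(rid)] = rcls
        return cls(
            VolumeGrid.from_nifti(img),
            np.asarray(img.dataobj).astype(int),
            lut,
            region_class,
        )


@dataclass
class HemisphereMasks:
    """Disjoint left/right boolean volumes used to restrict interhemispheric
    contacts to the hemisphere they record from."""

    grid: VolumeGrid
    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=bool)
        self.right = np.asarray(self.right, dtype=bool)
        if self.left.shape != self.grid.shape or self.right.shape != self.grid.shape:
            raise ValueError("hemisphere mask shape does not match grid")
        if np.any(self.left & self.right):
            raise ValueError("hemisphere masks overlap")

    def mask_for(self, side: str) -> np.ndarray:
        if side == "left":
            return self.left
        if side == "right":
            return self.right
        raise ValueError(f"unknown hemisphere {side!r}")

    def save(self, directory: str | Path, prefix: str = "") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for side in ("left", "right"):
            nib.save(
                self.grid.to_nifti(getattr(self, side).astype(np.uint8)),
                directory / f"{prefix}hemi_{side}.nii",
            )

    @classmethod
    def load(cls, directory: str | Path, prefix: str = "") -> "HemisphereMasks":
        directory = Path(directory)
        imgs = {
            s: nib.load(directory / f"{prefix}hemi_{s}.nii") for s in ("left", "right")
        }
        return cls(
            VolumeGrid.from_nifti(imgs["left"]),
            np.asarray(imgs["left"].dataobj) > 0,
            np.asarray(imgs["right"].dataobj) > 0,
        )
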