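"""Electrode contacts, leads, and implant-class bookkeeping.

A *contact* is a single recording site; a *lead* groups the contacts of one
depth electrode or one subdural strip/grid array. Implant classes follow the
standard epilepsy-monitoring taxonomy: strips only (S), strips + grids (S+G),
strips + grids + depths (S+G+D), and depths only / SEEG (D).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

MODALITIES = ("strip", "grid", "depth")
IMPLANT_CLASSES = ("S", "S+G", "S+G+D", "D")

#: Standard contact geometries (mm): subdural contacts are flat discs,
#: depth contacts are cylinders.
SUBDURAL_DISC_DIAMETER_MM = 2.3
DEPTH_CYLINDER_HEIGHT_MM = 2.29
DEPTH_CYLINDER_DIAMETER_MM = 0.86


@dataclass(frozen=True)
class ContactGeometry:
    """Physical contact shape: ``disc(diameter)`` or ``cylinder(height, diameter)``."""

    kind: str  # "disc" | "cylinder"
    diameter_mm: float
    height_mm: float = 0.0

    @classmethod
    def subdural_disc(cls) -> "ContactGeometry":
        return cls("disc", SUBDURAL_DISC_DIAMETER_MM)

    @classmethod
    def depth_cylinder(cls) -> "ContactGeometry":
        return cls("cylinder", DEPTH_CYLINDER_DIAMETER_MM, DEPTH_CYLINDER_HEIGHT_MM)


@dataclass(frozen=True)
class Contact:
    id: str
    lead_id: str
    modality: str
    position: np.ndarray  # world mm, shape (3,)
    interhemispheric: bool = False
    geometry: ContactGeometry | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        pos = np.asarray(self.position, dtype=float).reshape(3)
        object.__setattr__(self, "position", pos)
        geom = self.geometry
        if geom is None:
            geom = (
                ContactGeometry.depth_cylinder()
                if self.modality == "depth"
                else ContactGeometry.subdural_disc()
            )
        expected = "cylinder" if self.modality == "depth" else "disc"
        if geom.kind != expected:
            raise ValueError(
                f"{self.modality} contact requires {expected} geometry, got {geom.kind}"
            )
        object.__setattr__(self, "geometry", geom)

    def moved_to(self, position: np.ndarray) -> "Contact":
        return replace(self, position=np.asarray(position, dtype=float).reshape(3))


def classify_implant(modalities: set[str]) -> str:
    """Map the set of modalities present to an implant class label."""
    has_surf = bool(modalities & {"strip", "grid"})
    has_g = "grid" in modalities
    has_d = "depth" in modalities
    if has_d and not has_surf:
        return "D"
    if has_d and has_surf:
        return "S+G+D"
    if has_g:
        return "S+G"
    if "strip" in modalities:
        return "S"
    raise ValueError(f"modality combination {sorted(modalities)} has no implant class")


@dataclass
class ElectrodeSet:
    """All contacts of one patient, with lead grouping and implant class."""

    contacts: list[Contact]
    patient_id: str = "phantom"
    implant_class: str | None = None

    def __post_init__(self) -> None:
        if self.implant_class is None:
            self.implant_class = classify_implant(self.modalities)
        elif self.implant_class not in IMPLANT_CLASSES:
            raise ValueError(f"unknown implant class {self.implant_class!r}")

    @property
    def modalities(self) -> set[str]:
        return {c.modality for c in self.contacts}

    @property
    def positions(self) -> np.ndarray:
        return np.array([c.position for c in self.contacts]).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self):
        return iter(self.contacts)

    def subset(self, modality: str) -> list[Contact]:
        return [c for c in self.contacts if c.modality == modality]

    def surface_contacts(self) -> list[Contact]:
        return [c for c in self.contacts if c.modality in ("strip", "grid")]

    def lead_contacts(self, lead_id: str) -> list[Contact]:
        return [c for c in self.contacts if c.lead_id == lead_id]

    def merged_with(self, other: "ElectrodeSet") -> "ElectrodeSet":
        return ElectrodeSet(self.contacts + other.contacts, self.patient_id, None)

    # ---- tabular I/O ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": self.patient_id,
                "contact_id": c.id,
                "lead_id": c.lead_id,
                "modality": c.modality,
                "x_mm": c.position[0],
                "y_mm": c.position[1],
                "z_mm": c.position[2],
                "interhemispheric": c.interhemispheric,
            }
            for c in self.contacts
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, implant_class: str | None = None) -> "ElectrodeSet":
        pids = df["patient_id"].unique()
        if len(pids) != 1:
            raise ValueError("electrode table must describe exactly one patient")
        contacts = [
            Contact(
                id=str(r.contact_id),
                lead_id=str(r.lead_id),
                modality=str(r.modality),
                position=np.array([r.x_mm, r.y_mm, r.z_mm]),
                interhemispheric=bool(r.interhemispheric),
            )
            for r in df.itertuples()
        ]
        return cls(contacts, patient_id=str(pids[0]), implant_class=implant_class)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ElectrodeSet":
        return cls.from_frame(pd.read_csv(path))
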