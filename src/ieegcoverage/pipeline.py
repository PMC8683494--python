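"""End-to-end orchestration: phantom/cohort -> projection -> coverage -> stats.

Stages communicate through files (NIfTI volumes, CSV tables, PLY surfaces)
so each can be rerun or inspected in isolation, and a provenance record
(config hash, seed, package versions) accompanies every cohort run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coverage import (
    NAMED_RADII_MM,
    RoiSweepConfig,
    coverage_sweep,
    region_coverage,
    regional_inclusion,
)
from .electrodes import ElectrodeSet
from .fem import (
    ConductivityTable,
    FemSourceConfig,
    build_tet_mesh,
    fem_coverage_compare,
    solve_potential,
)
from .stats import (
    PatientCoverageRecord,
    crossover_radius,
    mean_curve_by_class,
    named_radius_comparisons,
    summarize,
)
from .surface import extract_smooth_surface, project_surface_contacts, split_hemispheres
from .synthetic import CohortConfig, SyntheticPatient, generate_cohort
from .volumes import AtlasLabels, HemisphereMasks, TissueProbabilityVolumes

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of one cohort run."""

    mode: str = "synthetic"  # "synthetic" | "files"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_dir: str | None = None  # for mode="files"
    sweep: RoiSweepConfig = field(default_factory=RoiSweepConfig)
    reference_radius_mm: float = 5.0
    fem: bool = False
    fem_edge_mm: float = 1.5
    fem_contacts_per_patient: int = 2
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.mode == "files" and not self.input_dir:
            raise ValueError("mode='files' requires input_dir")

    def digest(self) -> str:
        blob = repr(self).encode()
        return hashlib.sha256(blob).hexdigest()


def _fem_for_patient(
    patient: SyntheticPatient,
    electrodes: ElectrodeSet,
    config: RunConfig,
) -> pd.DataFrame:
    """Solve FEM recording volumes for a subset of contacts (one solve per
    contact on a sub-box mesh that keeps the grounded top of the head)."""
    spec = patient.spec
    rng = np.random.default_rng(config.seed)
    contacts = list(electrodes.contacts)
    if len(contacts) > config.fem_contacts_per_patient:
        pick = rng.choice(len(contacts), config.fem_contacts_per_patient, replace=False)
        contacts = [contacts[i] for i in sorted(pick)]
    sub = ElectrodeSet(contacts, electrodes.patient_id, electrodes.implant_class)
    fields = {}
    for c in contacts:
        lo = np.maximum(c.position - 35.0, 0.0)
        hi = np.minimum(c.position + 35.0, np.asarray(spec.extent_mm))
        hi[2] = spec.extent_mm[2]  # keep the grounded vertex patch in the box
        mesh = build_tet_mesh(patient.tissue, config.fem_edge_mm, (lo, hi))
        fields[c.id] = solve_potential(
            mesh, ConductivityTable(), FemSourceConfig(), c
        )
    return fem_coverage_compare(sub, patient.tissue, fields, NAMED_RADII_MM)


def run_patient(
    patient: SyntheticPatient,
    config: RunConfig,
    out_dir: str | Path | None = None,
) -> PatientCoverageRecord:
    """Run the per-patient pipeline: project subdural contacts, split
    hemispheres when needed, sweep the RoI radii, compute region coverage,
    and (optionally) FEM volumes. Artifacts are written as they are made."""
    out = Path(out_dir) if out_dir else Path(config.out_dir) / patient.patient_id
    out.mkdir(parents=True, exist_ok=True)
    spec = patient.spec
    electrodes = patient.electrodes
    midline = spec.midline_x

    stage = "projection"
    try:
        if electrodes.surface_contacts():
            surface = extract_smooth_surface(patient.tissue.p_gm, patient.tissue.grid)
            surface.export(out / "smooth_surface.ply", encoding="ascii")
            projected = project_surface_contacts(electrodes, surface)
        else:
            projected = electrodes  # depth-only: projection is a no-op
        orig = electrodes.to_frame()
        proj = projected.to_frame()
        orig[["x_proj_mm", "y_proj_mm", "z_proj_mm"]] = proj[["x_mm", "y_mm", "z_mm"]]
        orig.to_csv(out / "electrodes.csv", index=False)

        stage = "hemispheres"
        if any(c.interhemispheric for c in projected):
            hemis = split_hemispheres(patient.tissue.p_gm, patient.tissue.grid, midline)
        else:
            hemis = patient.hemispheres

        stage = "coverage"
        curve = coverage_sweep(
            projected, patient.tissue, patient.atlas, hemis, config.sweep, midline
        )
        curve.to_csv(out / "coverage.csv")

        stage = "regions"
        regions = region_coverage(
            projected, patient.atlas, patient.tissue,
            config.reference_radius_mm, hemis, midline,
        )
        inclusion = regional_inclusion(regions)
        rt = regions.table.copy()
        rt["included"] = [inclusion[r] for r in rt.region]
        rt.insert(0, "patient_id", patient.patient_id)
        rt.to_csv(out / "regions.csv", index=False)

        dice_df = None
        if config.fem:
            stage = "fem"
            dice_df = _fem_for_patient(patient, projected, config)
            dice_df.to_csv(out / "fem_compare.csv", index=False)
    except Exception as exc:  # noqa: BLE001 - tag the failing stage
        raise StageError(stage, exc) from exc

    return PatientCoverageRecord(
        patient.patient_id, patient.implant_class, curve, regions, inclusion, dice_df
    )


def _load_patients_from_files(input_dir: str) -> list[SyntheticPatient]:
    """Load per-patient NIfTI volumes + electrode CSVs from a directory tree
    (one subdirectory per patient, files as written by the synthetic stage)."""
    from .synthetic import PhantomSpec

    root = Path(input_dir)
    patients = []
    for pdir in sorted(p for p in root.iterdir() if p.is_dir()):
        tissue = TissueProbabilityVolumes.load(pdir)
        atlas = AtlasLabels.load(pdir)
        hemis = HemisphereMasks.load(pdir)
        es = ElectrodeSet.from_csv(pdir / "electrodes.csv")
        meta = json.loads((pdir / "phantom_spec.json").read_text())
        spec = PhantomSpec(**meta)
        patients.append(
            SyntheticPatient(
                es.patient_id, es.implant_class, es, es, tissue, atlas, hemis, spec
            )
        )
    if not patients:
        raise ValueError(f"no patient directories under {input_dir}")
    return patients


def write_cohort_inputs(patients: list[SyntheticPatient], out_dir: str | Path) -> None:
    """Serialize synthetic patients to the on-disk layout the file mode reads."""
    out = Path(out_dir)
    for p in patients:
        pdir = out / p.patient_id
        pdir.mkdir(parents=True, exist_ok=True)
        p.tissue.save(pdir)
        p.atlas.save(pdir)
        p.hemispheres.save(pdir)
        p.electrodes.to_csv(pdir / "electrodes.csv")
        (pdir / "phantom_spec.json").write_text(
            json.dumps(dataclasses.asdict(p.spec), indent=1)
        )


@dataclass
class CohortResult:
    records: list[PatientCoverageRecord]
    failures: dict[str, str]
    summaries: dict[str, pd.DataFrame]
    comparisons: pd.DataFrame
    crossovers: pd.DataFrame
    provenance: dict


def run_cohort(config: RunConfig) -> CohortResult:
    """Run every patient, then the cohort statistics; patient failures are
    recorded and the cohort continues."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.mode == "synthetic":
        patients = generate_cohort(config.cohort, config.seed)
    else:
        patients = _load_patients_from_files(config.input_dir)
    if not patients:
        raise ValueError("cohort is empty")

    records, failures = [], {}
    for p in patients:
        try:
            records.append(run_patient(p, config))
        except StageError as exc:
            log.error("patient %s failed: %s", p.patient_id, exc)
            failures[p.patient_id] = str(exc)
    if not records:
        raise RuntimeError("every patient failed")

    summaries = summarize(records)
    for name, df in summaries.items():
        if not df.empty:
            df.to_csv(out / f"cohort_{name}.csv", index=False)
    swept = set(np.round(config.sweep.radii_mm, 6))
    named = tuple(r for r in config.sweep.named_radii_mm if round(r, 6) in swept)
    try:
        comparisons = named_radius_comparisons(records, named or tuple(sorted(swept)))
    except ValueError:  # every class below the 2-patient testing minimum
        log.warning("no implant class has >= 2 patients; skipping group tests")
        comparisons = pd.DataFrame()
    comparisons.to_csv(out / "cohort_comparisons.csv", index=False)

    curves = mean_curve_by_class(records, "gm", "per_contact")
    cross_rows = []
    present = list(curves.columns)
    for a in present:
        for b in present:
            if a < b:
                cross_rows.append(
                    {
                        "class_a": a,
                        "class_b": b,
                        "tissue": "gm",
                        "crossover_radius_mm": crossover_radius(curves, a, b),
                    }
                )
    crossovers = pd.DataFrame(cross_rows)
    crossovers.to_csv(out / "cohort_crossovers.csv", index=False)

    import nibabel
    import scipy

    provenance = {
        "config_sha256": config.digest(),
        "seed": config.seed,
        "n_patients": len(patients),
        "n_failed": len(failures),
        "failures": failures,
        "elapsed_s": round(time.time() - t0, 2),
        "versions": {
            "ieegcoverage": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "nibabel": nibabel.__version__,
        },
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return CohortResult(records, failures, summaries, comparisons, crossovers, provenance)


def validate_provenance(out_dir: str | Path, config: RunConfig) -> bool:
    """Re-check that outputs in a directory were produced by this config."""
    prov = json.loads((Path(out_dir) / "provenance.json").read_text())
    return prov["config_sha256"] == config.digest()
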