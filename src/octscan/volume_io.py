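"""Labeled OCT segmentation volumes: geometry contract, containers, and I/O.

A volume is a stack of B-scans indexed ``[bscan, depth, ascan]``:

* axis 0 — slow axis (B-scan index, en-face *y*); B-scan *i* sits at the
  physical position ``i * isd_um``, so the B-scan positions span the
  slow-axis field of view inclusively: ``(n_bscans - 1) * isd_um == fov_y_um``.
* axis 1 — depth (*z*), ``depth_scale_um`` µm per sample.
* axis 2 — fast axis (A-scan index, en-face *x*), pixel pitch
  ``fov_x_um / n_ascans``; after orientation normalization +x points nasal.

Voxel labels: 0 background, 1 retina (ILM→Bruch's membrane), 2 intraretinal
fluid (IRF), 3 subretinal fluid (SRF), 4 pigment epithelium detachment (PED).
One label per voxel; the pooled IRF∪SRF biomarker and the total-retina
compartment are expressed as *label sets*, so every per-biomarker operation
takes a :class:`Biomarker` argument and a future multi-mask backend only
touches this module.

Volumes are stored as NIfTI (``.nii``/``.nii.gz``) or multipage TIFF with a
mandatory JSON sidecar ``<stem>.json`` holding the geometry and clinical
metadata. Geometry always comes from the sidecar, never from container
headers, which vary by exporter.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterator, Sequence

import nibabel as nib
import numpy as np
import tifffile

from .errors import ConfigurationError, ValidationError

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_RETINA",
    "LABEL_IRF",
    "LABEL_SRF",
    "LABEL_PED",
    "Biomarker",
    "BIOMARKER_LABELS",
    "ScanGeometry",
    "SegVolume",
    "ManifestEntry",
    "CohortManifest",
    "read_volume",
    "write_volume",
    "read_manifest",
    "write_manifest",
    "load_cohort",
]

LABEL_BACKGROUND = 0
LABEL_RETINA = 1
LABEL_IRF = 2
LABEL_SRF = 3
LABEL_PED = 4

_VALID_LABELS = frozenset({0, 1, 2, 3, 4})
_LATERALITIES = ("left", "right")
_DISEASES = ("AMD", "RVO", "unknown")


class Biomarker(str, Enum):
    """Analysis compartments; ``IRF_SRF`` is the pooled exudative-activity marker."""

    IRF = "IRF"
    SRF = "SRF"
    PED = "PED"
    IRF_SRF = "IRF_SRF"
    RETINA = "retina"


#: Label codes counted for each biomarker. Total retina is the ILM→Bruch's
#: membrane compartment, so it includes intra-/subretinal fluid voxels.
BIOMARKER_LABELS: dict[Biomarker, tuple[int, ...]] = {
    Biomarker.IRF: (LABEL_IRF,),
    Biomarker.SRF: (LABEL_SRF,),
    Biomarker.PED: (LABEL_PED,),
    Biomarker.IRF_SRF: (LABEL_IRF, LABEL_SRF),
    Biomarker.RETINA: (LABEL_RETINA, LABEL_IRF, LABEL_SRF),
}

#: Fluid biomarkers in the order the analyses report them.
FLUID_BIOMARKERS = (Biomarker.IRF, Biomarker.SRF, Biomarker.IRF_SRF, Biomarker.PED)


def as_biomarker(b: "Biomarker | str") -> Biomarker:
    """Coerce a string (e.g. from the CLI) into a :class:`Biomarker`."""
    if isinstance(b, Biomarker):
        return b
    try:
        return Biomarker(b)
    except ValueError:
        try:
            return Biomarker[str(b).upper()]
        except KeyError:
            raise ValidationError(
                f"unknown biomarker {b!r}; expected one of "
                f"{[m.value for m in Biomarker]}"
            ) from None


@dataclass(frozen=True)
class ScanGeometry:
    """Physical geometry of one OCT volume.

    Parameters
    ----------
    fov_x_um, fov_y_um
        En-face field of view (fast and slow axis), µm.
    isd_um
        Interscan distance between adjacent B-scans, µm.
    n_bscans, n_ascans, n_depth
        Grid counts along slow, fast and depth axes.
    depth_scale_um
        Axial µm per depth sample.
    """

    fov_x_um: float = 6000.0
    fov_y_um: float = 6000.0
    isd_um: float = 125.0
    n_bscans: int = 49
    n_ascans: int = 480
    n_depth: int = 496
    depth_scale_um: float = 7.0

    def __post_init__(self) -> None:
        for name in ("n_bscans", "n_ascans", "n_depth"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("fov_x_um", "fov_y_um", "isd_um", "depth_scale_um"):
            if not float(getattr(self, name)) > 0:
                raise ValidationError(f"{name} must be > 0")
        span = (self.n_bscans - 1) * self.isd_um
        if abs(span - self.fov_y_um) > 1e-6 * self.fov_y_um:
            raise ValidationError(
                f"(n_bscans - 1) * isd_um = {span} must equal fov_y_um = {self.fov_y_um}"
            )

    @property
    def pitch_x_um(self) -> float:
        """En-face fast-axis pixel pitch, µm per A-scan."""
        return self.fov_x_um / self.n_ascans

    @property
    def depth_extent_um(self) -> float:
        return self.n_depth * self.depth_scale_um

    @property
    def shape(self) -> tuple[int, int, int]:
        """Expected label-array shape ``(n_bscans, n_depth, n_ascans)``."""
        return (self.n_bscans, self.n_depth, self.n_ascans)

    @property
    def bscan_positions_um(self) -> np.ndarray:
        """Slow-axis physical position of each B-scan (closed span [0, fov_y])."""
        return np.arange(self.n_bscans) * self.isd_um

    @property
    def ascan_positions_um(self) -> np.ndarray:
        """Fast-axis physical position of each A-scan column."""
        return np.arange(self.n_ascans) * self.pitch_x_um

    def to_dict(self) -> dict:
        return {
            "fov_x_um": self.fov_x_um,
            "fov_y_um": self.fov_y_um,
            "isd_um": self.isd_um,
            "n_bscans": self.n_bscans,
            "n_ascans": self.n_ascans,
            "n_depth": self.n_depth,
            "depth_scale_um": self.depth_scale_um,
        }


@dataclass
class SegVolume:
    """One eye's labeled segmentation volume plus geometry and clinical metadata.

    ``normalized`` marks a volume whose laterality has been orientation-
    normalized (left eyes mirrored so +x points nasal); it is set by
    :func:`octscan.enface.mirror_if_left` and never persisted.
    """

    labels: np.ndarray
    geometry: ScanGeometry
    eye_id: str
    laterality: str = "right"
    disease: str = "unknown"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("labels must be a 3D [bscan, depth, ascan] array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be an integer array")
        if tuple(self.labels.shape) != self.geometry.shape:
            raise ValidationError(
                f"labels shape {self.labels.shape} does not match geometry "
                f"(n_bscans, n_depth, n_ascans) = {self.geometry.shape}"
            )
        present = set(np.unique(self.labels).tolist())
        if not present <= _VALID_LABELS:
            raise ValidationError(
                f"unknown label codes {sorted(present - _VALID_LABELS)}; "
                f"allowed: {sorted(_VALID_LABELS)}"
            )
        if self.laterality not in _LATERALITIES:
            raise ValidationError(f"laterality must be one of {_LATERALITIES}")
        if self.disease not in _DISEASES:
            raise ValidationError(f"disease must be one of {_DISEASES}")

    def equals(self, other: "SegVolume") -> bool:
        return (
            np.array_equal(self.labels, other.labels)
            and self.geometry == other.geometry
            and self.eye_id == other.eye_id
            and self.laterality == other.laterality
            and self.disease == other.disease
        )


_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_TIFF_SUFFIXES = (".tif", ".tiff")


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz",) + _NIFTI_SUFFIXES + _TIFF_SUFFIXES:
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    raise ConfigurationError(
        f"unsupported container {path}; expected one of {_NIFTI_SUFFIXES + _TIFF_SUFFIXES}"
    )


def write_volume(v: SegVolume, path: "Path | str") -> None:
    """Write ``v`` as NIfTI or multipage TIFF plus its JSON geometry sidecar.

    ``read_volume(path)`` inverts this bit-exactly for labels and exactly for
    geometry and metadata. Laterality is recorded as-is: mirroring is an
    analysis step, never applied at I/O time.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    arr = v.labels.astype(np.uint8)
    if path.name.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(arr, np.eye(4)), str(path))
    else:
        tifffile.imwrite(str(path), arr)
    meta = v.geometry.to_dict()
    meta.update(
        {"laterality": v.laterality, "disease": v.disease, "eye_id": v.eye_id}
    )
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))


_GEOMETRY_KEYS = (
    "fov_x_um",
    "fov_y_um",
    "isd_um",
    "n_bscans",
    "n_ascans",
    "n_depth",
    "depth_scale_um",
)


def read_volume(path: "Path | str") -> SegVolume:
    """Read a labeled volume; geometry comes from the JSON sidecar, never the header."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not path.exists():
        raise ConfigurationError(f"volume file not found: {path}")
    if not sidecar.exists():
        raise ConfigurationError(f"missing geometry sidecar: {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"malformed sidecar {sidecar}: {exc}") from exc
    missing = [k for k in _GEOMETRY_KEYS if k not in meta]
    if missing:
        raise ConfigurationError(f"sidecar {sidecar} lacks geometry keys {missing}")
    geometry = ScanGeometry(**{k: meta[k] for k in _GEOMETRY_KEYS})
    if path.name.endswith((".nii", ".nii.gz")):
        arr = np.asanyarray(nib.load(str(path)).dataobj)
    else:
        arr = tifffile.imread(str(path))
    arr = np.asarray(arr)
    if not np.issubdtype(arr.dtype, np.integer):
        # NIfTI round-trips may promote dtype; labels are small ints by contract
        if not np.all(arr == np.round(arr)):
            raise ValidationError(f"{path}: non-integer label values")
        arr = arr.astype(np.uint8)
    return SegVolume(
        labels=arr,
        geometry=geometry,
        eye_id=str(meta.get("eye_id", path.name)),
        laterality=str(meta.get("laterality", "right")),
        disease=str(meta.get("disease", "unknown")),
    )


@dataclass(frozen=True)
class ManifestEntry:
    eye_id: str
    path: str
    laterality: str
    disease: str


@dataclass
class CohortManifest:
    """Index of one cohort: per-eye file paths plus provenance.

    ``seed`` records the generation seed for synthetic cohorts.
    """

    entries: list[ManifestEntry] = field(default_factory=list)
    provenance: str = ""
    seed: "int | None" = None

    def __post_init__(self) -> None:
        ids = [e.eye_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate eye_ids in manifest: {dupes}")


def write_manifest(m: CohortManifest, path: "Path | str") -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        if m.provenance:
            fh.write(f"# provenance: {m.provenance}\n")
        if m.seed is not None:
            fh.write(f"# seed: {m.seed}\n")
        writer = csv.writer(fh)
        writer.writerow(["eye_id", "path", "laterality", "disease"])
        for e in m.entries:
            writer.writerow([e.eye_id, e.path, e.laterality, e.disease])


def read_manifest(path: "Path | str") -> CohortManifest:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"manifest not found: {path}")
    provenance, seed, rows = "", None, []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("provenance:"):
                    provenance = body.split(":", 1)[1].strip()
                elif body.startswith("seed:"):
                    seed = int(body.split(":", 1)[1].strip())
                continue
            rows.append(line)
    reader = csv.DictReader(rows)
    if reader.fieldnames is None or set(reader.fieldnames) != {
        "eye_id",
        "path",
        "laterality",
        "disease",
    }:
        raise ConfigurationError(
            f"manifest {path} must have header eye_id,path,laterality,disease"
        )
    entries = [
        ManifestEntry(r["eye_id"], r["path"], r["laterality"], r["disease"])
        for r in reader
    ]
    return CohortManifest(entries=entries, provenance=provenance, seed=seed)


def load_cohort(
    manifest: CohortManifest, base_dir: "Path | str | None" = None
) -> Iterator[SegVolume]:
    """Yield cohort volumes one at a time (paths resolved against ``base_dir``)."""
    base = Path(base_dir) if base_dir is not None else Path(".")
    for e in manifest.entries:
        p = Path(e.path)
        if not p.is_absolute():
            p = base / p
        yield read_volume(p)
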