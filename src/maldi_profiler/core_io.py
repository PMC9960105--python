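"""Domain types and (de)serialization for MALDI-TOF profile data.

The central containers are :class:`Spectrum` (one profile trace),
:class:`SpectrumSet` (a labeled cohort for one fluid), :class:`PeakDefinition`
(one integration region on the m/z axis), :class:`PeakMatrix` (samples x peaks
quantity table) and :class:`ClassifierModel` (a trained GA/SNN/QC model).

Spectra are exchanged as two-column CSV (m/z, intensity) or read from mzML;
peak matrices as CSV with a header of centroid masses; models as versioned
JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MODEL_SCHEMA_VERSION = 1


class Fluid(str, Enum):
    SALIVA = "saliva"
    GCF = "gcf"


class Label(str, Enum):
    CONTROL = "control"
    FOA = "foa"
    IN = "in"
    UNKNOWN = "unknown"


class QuantityMode(str, Enum):
    AREA = "area"
    INTENSITY = "intensity"


class SpectrumError(ValueError):
    """Raised for malformed or degenerate spectral inputs."""


class ModelIOError(ValueError):
    """Raised when a serialized model cannot be read back."""


@dataclass
class Spectrum:
    """One profile trace: ascending m/z grid plus nonnegative intensities.

    Parameters
    ----------
    mz : array-like
        Strictly increasing mass-to-charge values (Da/e), length >= 2.
    intensity : array-like
        Nonnegative, finite intensities (arbitrary units), same length as mz.
    sample_id : str
        Opaque sample identifier.
    fluid : Fluid
        Body fluid of origin (saliva or gingival crevicular fluid).
    label : Label
        Class label (control / foa / in / unknown).
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    fluid: Fluid = Fluid.SALIVA
    label: Label = Label.UNKNOWN

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.fluid = Fluid(self.fluid)
        self.label = Label(self.label)
        self.validate()

    def validate(self) -> None:
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumError("mz and intensity must be one-dimensional")
        if len(self.mz) != len(self.intensity):
            raise SpectrumError(
                f"length mismatch: {len(self.mz)} m/z values vs "
                f"{len(self.intensity)} intensities"
            )
        if len(self.mz) < 2:
            raise SpectrumError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(self.mz)) or not np.all(np.isfinite(self.intensity)):
            raise SpectrumError("non-finite values in spectrum")
        if np.any(np.diff(self.mz) <= 0):
            raise SpectrumError("m/z grid must be strictly increasing")
        if np.any(self.intensity < 0):
            raise SpectrumError("negative intensities")

    def __len__(self) -> int:
        return len(self.mz)

    def replace(self, **kwargs) -> "Spectrum":
        """Return a copy with some fields replaced."""
        data = dict(
            mz=self.mz,
            intensity=self.intensity,
            sample_id=self.sample_id,
            fluid=self.fluid,
            label=self.label,
        )
        data.update(kwargs)
        return Spectrum(**data)


@dataclass
class SpectrumSet:
    """An ordered, labeled cohort of spectra sharing one fluid."""

    spectra: list
    fluid: Fluid
    class_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fluid = Fluid(self.fluid)
        self.spectra = list(self.spectra)
        for s in self.spectra:
            if s.fluid != self.fluid:
                raise SpectrumError(
                    f"spectrum {s.sample_id!r} has fluid {s.fluid.value}, "
                    f"set is {self.fluid.value}"
                )
        present = []
        for s in self.spectra:
            if s.label.value not in present:
                present.append(s.label.value)
        if not self.class_names:
            self.class_names = present
        else:
            missing = [c for c in present if c not in self.class_names]
            if missing:
                raise SpectrumError(f"labels {missing} absent from class_names")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def labels(self) -> list:
        return [s.label.value for s in self.spectra]

    @property
    def sample_ids(self) -> list:
        return [s.sample_id for s in self.spectra]


@dataclass
class PeakDefinition:
    """One integration region on the m/z axis.

    ``index`` is the 1-based rank of the peak by centroid mass within its
    peak list; ``snr_at_pick`` records the signal-to-noise ratio observed when
    the peak was accepted on the total average spectrum.
    """

    centroid_mz: float
    left_mz: float
    right_mz: float
    snr_at_pick: float = float("nan")
    index: int = 0

    def __post_init__(self) -> None:
        if not (self.left_mz < self.centroid_mz < self.right_mz):
            raise ValueError(
                f"peak bounds must satisfy left < centroid < right, got "
                f"({self.left_mz}, {self.centroid_mz}, {self.right_mz})"
            )


@dataclass
class PeakMatrix:
    """Samples x peaks table of integrated areas or maximal intensities."""

    values: np.ndarray
    peaks: list
    sample_ids: list
    labels: list
    quantity_mode: QuantityMode = QuantityMode.AREA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.quantity_mode = QuantityMode(self.quantity_mode)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, p = self.values.shape
        if p != len(self.peaks):
            raise ValueError(f"{p} columns but {len(self.peaks)} peak definitions")
        if n != len(self.sample_ids) or n != len(self.labels):
            raise ValueError("row metadata length mismatch")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("missing or non-finite entries in peak matrix")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.values.shape[1]

    @property
    def class_names(self) -> list:
        seen = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def centroids(self) -> np.ndarray:
        return np.array([p.centroid_mz for p in self.peaks])

    def subset_rows(self, rows: Sequence[int]) -> "PeakMatrix":
        rows = list(rows)
        return PeakMatrix(
            values=self.values[rows],
            peaks=self.peaks,
            sample_ids=[self.sample_ids[i] for i in rows],
            labels=[self.labels[i] for i in rows],
            quantity_mode=self.quantity_mode,
        )


@dataclass
class ClassifierModel:
    """A trained peak-panel classifier (GA, SNN or QC).

    ``peak_indices`` are 0-based column indices into the training peak matrix;
    ``params`` holds the type-specific fitted state (kNN exemplars for GA,
    prototypes for SNN, class means and peak weights for QC) in
    JSON-serializable form.
    """

    model_type: str
    peak_indices: list
    params: dict
    class_names: list

    def __post_init__(self) -> None:
        if self.model_type not in ("GA", "SNN", "QC"):
            raise ValueError(f"unknown model type {self.model_type!r}")
        if not self.peak_indices:
            raise ValueError("peak_indices must be nonempty")
        if len(set(self.peak_indices)) != len(self.peak_indices):
            raise ValueError("peak_indices must be unique")
        self.peak_indices = [int(i) for i in self.peak_indices]


# ---------------------------------------------------------------------------
# Spectrum readers / writers
# ---------------------------------------------------------------------------

def read_spectrum_csv(
    path,
    sample_id: str = "",
    fluid: Fluid = Fluid.SALIVA,
    label: Label = Label.UNKNOWN,
) -> Spectrum:
    """Read a two-column (m/z, intensity) text file into a Spectrum.

    Accepts comma-, tab- or whitespace-delimited numeric rows with an optional
    single header line.  Rows are sorted by m/z and duplicate m/z values are
    averaged so the returned grid is strictly increasing.
    """
    path = Path(path)
    mzs, ys = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").replace("\t", " ").split()
            if len(parts) < 2:
                raise SpectrumError(f"{path.name}:{lineno}: expected two columns")
            try:
                m, y = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:  # tolerate one header line
                    continue
                raise SpectrumError(
                    f"{path.name}:{lineno}: non-numeric row {line!r}"
                ) from None
            mzs.append(m)
            ys.append(y)
    if len(mzs) < 2:
        raise SpectrumError(f"{path.name}: fewer than 2 data points")
    mz = np.array(mzs)
    y = np.array(ys)
    order = np.argsort(mz, kind="stable")
    mz, y = mz[order], y[order]
    uniq, inverse = np.unique(mz, return_inverse=True)
    if len(uniq) < len(mz):
        sums = np.bincount(inverse, weights=y)
        counts = np.bincount(inverse)
        y = sums / counts
        mz = uniq
    if len(mz) < 2:
        raise SpectrumError(f"{path.name}: fewer than 2 distinct m/z values")
    return Spectrum(mz=mz, intensity=y, sample_id=sample_id or path.stem,
                    fluid=fluid, label=label)


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    """Write a spectrum as two-column CSV with full float precision."""
    arr = np.column_stack([spectrum.mz, spectrum.intensity])
    np.savetxt(path, arr, delimiter=",", fmt="%.17g", header="mz,intensity",
               comments="")


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"
# PSI-MS controlled-vocabulary accessions used by the minimal reader
_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _decode_binary_array(bda) -> tuple:
    """Decode one <binaryDataArray>: returns (kind, values) where kind is
    'mz', 'intensity' or None."""
    import base64
    import zlib as _zlib

    accs = {cv.get("accession") for cv in bda.iter(f"{_MZML_NS}cvParam")}
    kind = "mz" if _ACC_MZ_ARRAY in accs else (
        "intensity" if _ACC_INT_ARRAY in accs else None)
    node = bda.find(f"{_MZML_NS}binary")
    raw = base64.b64decode(node.text or "")
    if _ACC_ZLIB in accs:
        raw = _zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in accs else "<f8"
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path, fluid: Fluid = Fluid.SALIVA,
              label: Label = Label.UNKNOWN) -> SpectrumSet:
    """Read all MS1 spectra from an mzML file into a SpectrumSet.

    A deliberately narrow mzML reader (well-formed mzML 1.1, 32/64-bit
    float arrays, optional zlib compression) built on the standard-library
    XML parser.  Sample ids are taken from the native spectrum ids.
    Centroided spectra are accepted with a warning (downstream smoothing
    assumes profile data).  Duplicate m/z values within one spectrum are
    averaged.
    """
    import xml.etree.ElementTree as ET

    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise SpectrumError(f"{path}: malformed mzML: {exc}") from exc
    spectra = []
    for sp in tree.iter(f"{_MZML_NS}spectrum"):
        level = 1
        centroided = False
        for cv in sp.findall(f"{_MZML_NS}cvParam"):
            if cv.get("accession") == _ACC_MS_LEVEL:
                level = int(cv.get("value", "1"))
            elif cv.get("accession") == _ACC_CENTROID:
                centroided = True
        if level != 1:
            continue
        if centroided:
            warnings.warn(f"spectrum {sp.get('id')!r} is centroided; "
                          "accepted as-is", stacklevel=2)
        mz = y = None
        for bda in sp.iter(f"{_MZML_NS}binaryDataArray"):
            kind, values = _decode_binary_array(bda)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                y = values
        if mz is None or y is None or len(mz) != len(y):
            raise SpectrumError(
                f"{path}: spectrum {sp.get('id')!r} lacks matching "
                "m/z / intensity arrays")
        order = np.argsort(mz, kind="stable")
        mz, y = mz[order], y[order]
        uniq, inverse = np.unique(mz, return_inverse=True)
        if len(uniq) < len(mz):
            y = np.bincount(inverse, weights=y) / np.bincount(inverse)
            mz = uniq
        spectra.append(Spectrum(mz=mz, intensity=np.clip(y, 0, None),
                                sample_id=str(sp.get("id", "")),
                                fluid=fluid, label=label))
    if not spectra:
        raise SpectrumError(f"{path}: no spectra")
    return SpectrumSet(spectra=spectra, fluid=fluid)


# ---------------------------------------------------------------------------
# Peak list and matrix CSV
# ---------------------------------------------------------------------------

def write_peaks_csv(peaks: Iterable[PeakDefinition], path) -> None:
    df = pd.DataFrame(
        [(p.index, p.centroid_mz, p.left_mz, p.right_mz, p.snr_at_pick)
         for p in peaks],
        columns=["index", "centroid_mz", "left_mz", "right_mz", "snr_at_pick"],
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_peaks_csv(path) -> list:
    df = pd.read_csv(path)
    return [
        PeakDefinition(centroid_mz=row.centroid_mz, left_mz=row.left_mz,
                       right_mz=row.right_mz, snr_at_pick=row.snr_at_pick,
                       index=int(row.index))
        for row in df.itertuples(index=False)
    ]


def write_peak_matrix_csv(matrix: PeakMatrix, path) -> None:
    """Write a peak matrix as CSV: sample_id, label, then one column per
    centroid m/z."""
    cols = [f"{p.centroid_mz:.17g}" for p in matrix.peaks]
    df = pd.DataFrame(matrix.values, columns=cols)
    df.insert(0, "label", matrix.labels)
    df.insert(0, "sample_id", matrix.sample_ids)
    df.to_csv(path, index=False, float_format="%.17g")


def read_peak_matrix_csv(path, peaks: list | None = None,
                         quantity_mode: QuantityMode = QuantityMode.AREA
                         ) -> PeakMatrix:
    """Read a peak matrix CSV.

    If ``peaks`` is not given, minimal PeakDefinitions are reconstructed from
    the centroid header (bounds set to +-0.5 Da around the centroid).
    """
    df = pd.read_csv(path)
    value_cols = [c for c in df.columns if c not in ("sample_id", "label")]
    centroids = [float(c) for c in value_cols]
    if peaks is None:
        peaks = [PeakDefinition(centroid_mz=c, left_mz=c - 0.5, right_mz=c + 0.5,
                                index=i + 1)
                 for i, c in enumerate(centroids)]
    else:
        stored = np.array([p.centroid_mz for p in peaks])
        if len(stored) != len(centroids) or not np.allclose(stored, centroids):
            raise ValueError("peak definitions do not match matrix header")
    return PeakMatrix(
        values=df[value_cols].to_numpy(dtype=float),
        peaks=peaks,
        sample_ids=[str(s) for s in df["sample_id"]],
        labels=[str(l) for l in df["label"]],
        quantity_mode=quantity_mode,
    )


# ---------------------------------------------------------------------------
# Model JSON
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_model(model: ClassifierModel, path) -> None:
    """Serialize a trained model to versioned JSON."""
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "model_type": model.model_type,
        "peak_indices": list(model.peak_indices),
        "class_names": list(model.class_names),
        "params": _jsonable(model.params),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> ClassifierModel:
    """Load a model saved by :func:`save_model`; predictions round-trip
    bit-for-bit because all fitted arrays are stored at full precision."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelIOError(f"{path}: corrupt or truncated model file: {exc}")
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise ModelIOError(f"{path}: not a model file")
    if doc["schema_version"] != MODEL_SCHEMA_VERSION:
        raise ModelIOError(
            f"{path}: schema version {doc['schema_version']} unsupported "
            f"(expected {MODEL_SCHEMA_VERSION})")
    return ClassifierModel(
        model_type=doc["model_type"],
        peak_indices=doc["peak_indices"],
        params=doc["params"],
        class_names=doc["class_names"],
    )
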