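"""CT preprocessing and per-patient embedding extraction.

One CT examination per patient is reduced to a single fixed-length vector:

1. **Series selection** — among the series of an examination, keep the largest
   non-scout 3D volume (slice count first, then in-plane resolution).
2. **Slice sampling** — 32 axial slices at evenly spaced intervals along the
   cranio-caudal axis.
3. **Lung windowing** — linear HU display mapping (level -600, width 1500)
   into [0, 1].
4. **Slice preparation** — bilinear resize to 224x224, channel triplication.
5. **Feature extraction** — a frozen convolutional-style feature extractor
   maps each slice to a 512-vector; slice vectors are average-pooled into the
   patient embedding.

The extractor is pluggable (`FeatureExtractor` protocol).  The shipped
extractor is a fixed-seed Gaussian random projection of block-pooled slices —
a frozen deterministic map that exercises the full pipeline contract without
pretrained weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from skimage.transform import resize as _sk_resize

from .simulate import CTVolume

__all__ = [
    "SeriesMetadata",
    "PatientEmbedding",
    "FeatureExtractor",
    "RandomProjectionExtractor",
    "NoDiagnosticSeriesError",
    "select_representative_series",
    "sample_slice_indices",
    "apply_lung_window",
    "prepare_slice",
    "embed_patient",
    "load_nifti",
    "load_dicom_series",
]


class NoDiagnosticSeriesError(ValueError):
    """Raised when an examination contains no eligible diagnostic series."""


@dataclass(frozen=True)
class SeriesMetadata:
    series_id: str
    n_slices: int
    in_plane_rows: int
    in_plane_cols: int
    is_scout: bool = False

    def __post_init__(self) -> None:
        if self.n_slices < 1 or self.in_plane_rows < 1 or self.in_plane_cols < 1:
            raise ValueError("n_slices, rows and cols must all be >= 1")


@dataclass
class PatientEmbedding:
    patient_id: str
    vector: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float).ravel()
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("embedding contains non-finite components")


@runtime_checkable
class FeatureExtractor(Protocol):
    """A frozen map from batches of 224x224x3 images to fixed-length vectors."""

    output_dim: int

    def apply(self, batch: np.ndarray) -> np.ndarray:  # (n, 224, 224, 3) -> (n, output_dim)
        ...


def select_representative_series(candidates: Sequence[SeriesMetadata]) -> SeriesMetadata:
    """Pick the single representative diagnostic series of an examination.

    Scout views and single-slice series are excluded; among the rest the
    series maximizing (slice count, in-plane resolution) wins, with the
    lexicographically smallest series id breaking exact ties.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    eligible = [c for c in candidates if not c.is_scout and c.n_slices >= 2]
    if not eligible:
        raise NoDiagnosticSeriesError(
            "no diagnostic series: all candidates are scout views or single-slice"
        )
    return min(
        eligible,
        key=lambda c: (-c.n_slices, -(c.in_plane_rows * c.in_plane_cols), c.series_id),
    )


def sample_slice_indices(n_available: int, n_target: int = 32) -> list[int]:
    """Indices of ``n_target`` evenly spaced slices over ``[0, n_available-1]``.

    Endpoints are always included (for ``n_available >= 2``), maximizing
    cranio-caudal coverage; positions are rounded half-to-even.  When the
    volume has fewer slices than requested, indices repeat.
    """
    if n_available < 1 or n_target < 1:
        raise ValueError("n_available and n_target must both be >= 1")
    if n_available < n_target:
        warnings.warn(
            f"volume has only {n_available} slices; sampling {n_target} with repetition",
            stacklevel=2,
        )
    idx = np.rint(np.linspace(0.0, n_available - 1.0, n_target)).astype(int)
    return idx.tolist()


def apply_lung_window(
    slice_hu: np.ndarray, level: float = -600.0, width: float = 1500.0
) -> np.ndarray:
    """Linear lung-window mapping of HU values into [0, 1].

    ``level - width/2`` maps to 0, ``level + width/2`` to 1; values outside
    the window are clipped.  Monotone nondecreasing in the input.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    arr = np.asarray(slice_hu, dtype=float)
    return np.clip((arr - (level - width / 2.0)) / width, 0.0, 1.0)


def prepare_slice(
    slice01: np.ndarray,
    out_size: int = 224,
    channel_mean: Sequence[float] | None = None,
    channel_std: Sequence[float] | None = None,
) -> np.ndarray:
    """Bilinear-resize a windowed slice to ``out_size`` square and triplicate
    channels; optional per-channel standardization with extractor-declared
    constants."""
    arr = np.asarray(slice01, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("prepare_slice expects a nonempty 2D array")
    resized = _sk_resize(
        arr, (out_size, out_size), order=1, mode="edge", anti_aliasing=True,
        preserve_range=True,
    )
    img = np.repeat(resized[:, :, None], 3, axis=2)
    if channel_mean is not None:
        img = img - np.asarray(channel_mean, dtype=float)[None, None, :]
    if channel_std is not None:
        img = img / np.asarray(channel_std, dtype=float)[None, None, :]
    if not np.all(np.isfinite(img)):
        raise ValueError("prepared slice contains non-finite values")
    return img


class RandomProjectionExtractor:
    """Frozen Gaussian random-projection feature extractor.

    Each channel of the input is average-pooled to a ``pool_grid`` x
    ``pool_grid`` grid, flattened, and projected to ``output_dim`` components
    with a fixed-seed Gaussian matrix scaled by 1/sqrt(fan-in).  Deterministic
    given ``seed``; serves as a frozen stand-in for a pretrained convolutional
    backbone in the pipeline contract.
    """

    def __init__(self, output_dim: int = 512, seed: int = 7, pool_grid: int = 8) -> None:
        self.output_dim = int(output_dim)
        self.seed = int(seed)
        self.pool_grid = int(pool_grid)
        self._proj: np.ndarray | None = None
        self.channel_mean = None
        self.channel_std = None

    def _projection(self, in_dim: int) -> np.ndarray:
        if self._proj is None or self._proj.shape[0] != in_dim:
            rng = np.random.default_rng(self.seed)
            self._proj = rng.standard_normal((in_dim, self.output_dim)) / np.sqrt(in_dim)
        return self._proj

    @staticmethod
    def _block_pool(batch: np.ndarray, grid: int) -> np.ndarray:
        n, h, w, c = batch.shape
        bh, bw = h // grid, w // grid
        trimmed = batch[:, : bh * grid, : bw * grid, :]
        pooled = trimmed.reshape(n, grid, bh, grid, bw, c).mean(axis=(2, 4))
        return pooled.reshape(n, -1)

    def apply(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=float)
        if batch.ndim == 3:
            batch = batch[None]
        if batch.ndim != 4:
            raise ValueError("extractor expects a (n, H, W, 3) batch")
        flat = self._block_pool(batch, self.pool_grid)
        return flat @ self._projection(flat.shape[1])


def embed_patient(
    volume: CTVolume,
    extractor: FeatureExtractor,
    patient_id: str = "",
    n_slices: int = 32,
) -> PatientEmbedding:
    """Map one CT volume to a single patient embedding.

    Slices are sampled evenly, lung-windowed, prepared, passed through the
    extractor, and average-pooled componentwise across slices.
    """
    indices = sample_slice_indices(volume.n_slices, n_slices)
    prepared = []
    for i in indices:
        try:
            windowed = apply_lung_window(volume.voxels[i])
            prepared.append(
                prepare_slice(
                    windowed,
                    channel_mean=getattr(extractor, "channel_mean", None),
                    channel_std=getattr(extractor, "channel_std", None),
                )
            )
        except Exception as exc:  # re-raise with slice context
            raise RuntimeError(f"slice {i}: {exc}") from exc
    try:
        slice_vecs = extractor.apply(np.stack(prepared))
    except Exception as exc:
        raise RuntimeError(f"feature extraction failed on sampled slices {indices}: {exc}") from exc
    vector = np.asarray(slice_vecs, dtype=float).mean(axis=0)
    if vector.shape[0] != extractor.output_dim:
        raise ValueError(
            f"extractor returned {vector.shape[0]} components, declared {extractor.output_dim}"
        )
    return PatientEmbedding(patient_id=patient_id, vector=vector)


def load_nifti(path: str | Path) -> CTVolume:
    """Read a NIfTI volume (assumed already in HU) as (slice, row, col)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    # NIfTI stores (x, y, z); reorder so axis 0 runs cranio-caudally.
    vox = np.transpose(data, (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    return CTVolume(np.clip(vox, -1024.0, 3071.0), spacing=(zooms[2], zooms[1], zooms[0]))


def _is_scout(ds) -> bool:
    image_type = [str(t).upper() for t in getattr(ds, "ImageType", [])]
    return "LOCALIZER" in image_type or "SCOUT" in image_type


def load_dicom_series(directory: str | Path) -> CTVolume:
    """Read a DICOM directory, select the representative series, and stack it
    into an HU volume (rescale slope/intercept applied)."""
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.rglob("*") if p.is_file())
    series: dict[str, list] = {}
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        series.setdefault(str(getattr(ds, "SeriesInstanceUID", "unknown")), []).append(ds)
    if not series:
        raise ValueError(f"no readable DICOM files under {directory}")

    metas = []
    for sid, slices in series.items():
        first = slices[0]
        metas.append(
            SeriesMetadata(
                series_id=sid,
                n_slices=len(slices),
                in_plane_rows=int(getattr(first, "Rows", 1)),
                in_plane_cols=int(getattr(first, "Columns", 1)),
                is_scout=any(_is_scout(ds) for ds in slices),
            )
        )
    selected = select_representative_series(metas)
    slices = series[selected.series_id]

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices = sorted(slices, key=sort_key)
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    vox = np.clip(np.stack(planes), -1024.0, 3071.0)

    first = slices[0]
    pixel_spacing = getattr(first, "PixelSpacing", [1.0, 1.0])
    slice_thickness = float(getattr(first, "SliceThickness", 1.0))
    return CTVolume(vox, spacing=(slice_thickness, float(pixel_spacing[0]), float(pixel_spacing[1])))
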