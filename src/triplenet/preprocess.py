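"""Volume reading, spherical-ROI extraction and temporal preprocessing.

The stages mirror a standard seed-based resting-state workflow on data
already in MNI space: discard the first volumes (scanner equilibration),
average the BOLD signal over a 3 mm sphere around each node, remove the
linear trend, and band-pass to 0.01-0.08 Hz with an ideal
frequency-domain filter (DC removed, band edges inclusive).

Detrend and the filter are linear maps, so applying them to the node
average is identical to averaging filtered voxels; this package extracts
first because it is far cheaper.  Sphere membership is decided by
voxel-centre Euclidean distance in millimetre space through the NIfTI
affine (closed ball), so anisotropic grids are handled correctly.  An
empty sphere raises instead of silently yielding an empty mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import scipy.signal

from .atlas import NetworkAtlas, NodeSpec

__all__ = [
    "SubjectSeries",
    "mni_to_voxel",
    "sphere_mask",
    "extract_node_series",
    "discard_initial_volumes",
    "detrend_linear",
    "bandpass_filter",
    "preprocess_series",
    "extract_cohort",
    "read_series_cohort",
    "write_series_cohort",
]

logger = logging.getLogger(__name__)

DEFAULT_DISCARD = 10
DEFAULT_LOW_HZ = 0.01
DEFAULT_HIGH_HZ = 0.08


@dataclass
class SubjectSeries:
    """One subject's node-by-time signal matrix.

    ``data`` has shape ``(n_nodes, n_timepoints)`` with rows ordered as
    ``node_names`` (which follows the atlas).
    """

    subject_id: str
    group: str
    data: np.ndarray
    tr_seconds: float
    node_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"subject {self.subject_id!r}: data must be 2-D (nodes x time)")
        if self.data.shape[0] != len(self.node_names):
            raise ValueError(
                f"subject {self.subject_id!r}: {self.data.shape[0]} rows but "
                f"{len(self.node_names)} node names"
            )
        if not np.isfinite(self.data).all():
            raise ValueError(f"subject {self.subject_id!r}: non-finite values in series")
        if not self.tr_seconds > 0:
            raise ValueError(f"subject {self.subject_id!r}: tr_seconds must be > 0")
        self.node_names = tuple(self.node_names)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Time-by-node table with node names as columns."""
        return pd.DataFrame(self.data.T, columns=list(self.node_names))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        subject_id: str,
        group: str,
        tr_seconds: float,
        atlas: NetworkAtlas | None = None,
    ) -> "SubjectSeries":
        df = pd.read_csv(path, sep="\t")
        if atlas is not None:
            missing = set(atlas.names) - set(df.columns)
            if missing:
                raise ValueError(f"{path}: missing node columns {sorted(missing)}")
            df = df[list(atlas.names)]
        return cls(subject_id, group, df.to_numpy().T, tr_seconds, tuple(df.columns))


# ---------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------

def mni_to_voxel(coord_mm: Sequence[float], affine: np.ndarray) -> np.ndarray:
    """Map an MNI mm coordinate to continuous 0-based voxel indices.

    Applies the inverse of the NIfTI voxel-to-mm ``affine``; no rounding.
    """
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    hom = np.append(np.asarray(coord_mm, dtype=float), 1.0)
    try:
        vox = np.linalg.solve(affine, hom)
    except np.linalg.LinAlgError as exc:
        raise ValueError("affine is singular") from exc
    return vox[:3]


def sphere_mask(node: NodeSpec, affine: np.ndarray, shape: Sequence[int]) -> np.ndarray:
    """In-bounds voxels whose centre lies within ``node.radius`` mm of the node.

    Distance is Euclidean in millimetre space through ``affine`` (closed
    ball, boundary included).  Returns an ``(k, 3)`` integer index array.
    An empty mask raises ``ValueError`` naming the node — possible with
    thick slices when the radius is smaller than the voxel spacing.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) < 3 or any(s <= 0 for s in shape[:3]):
        raise ValueError(f"shape must have 3 positive spatial dims, got {shape}")
    affine = np.asarray(affine, dtype=float)
    centre_vox = mni_to_voxel(node.coords, affine)
    inv3 = np.linalg.inv(affine)[:3, :3]
    # bounding box in voxel space: |Δvox_k| <= ||row_k(A^-1)|| * radius
    half = node.radius * np.linalg.norm(inv3, axis=1) + 1.0
    lo = np.maximum(np.ceil(centre_vox - half).astype(int), 0)
    hi = np.minimum(np.floor(centre_vox + half).astype(int), np.array(shape[:3]) - 1)
    if np.any(lo > hi):
        raise ValueError(
            f"node {node.name!r}: sphere of radius {node.radius} mm at "
            f"{tuple(node.coords)} contains no voxel centre on this grid"
        )
    axes = [np.arange(lo[k], hi[k] + 1) for k in range(3)]
    vox = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    mm = vox @ affine[:3, :3].T + affine[:3, 3]
    dist = np.linalg.norm(mm - node.coords, axis=1)
    mask = vox[dist <= node.radius + 1e-9]
    if mask.size == 0:
        raise ValueError(
            f"node {node.name!r}: sphere of radius {node.radius} mm at "
            f"{tuple(node.coords)} contains no voxel centre on this grid"
        )
    return mask


def extract_node_series(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Arithmetic mean over mask voxels at each time point.

    ``volume`` is 4-D ``(x, y, z, t)``; ``mask`` is ``(k, 3)`` voxel indices.
    """
    volume = np.asarray(volume)
    if volume.ndim != 4:
        raise ValueError(f"volume must be 4-D, got ndim={volume.ndim}")
    mask = np.asarray(mask, dtype=int)
    if mask.ndim != 2 or mask.shape[1] != 3 or mask.shape[0] == 0:
        raise ValueError("mask must be a non-empty (k, 3) index array")
    if np.any(mask < 0) or np.any(mask >= np.array(volume.shape[:3])):
        raise ValueError("mask contains out-of-bounds voxel indices")
    return volume[mask[:, 0], mask[:, 1], mask[:, 2], :].mean(axis=0)


# ---------------------------------------------------------------------
# temporal preprocessing
# ---------------------------------------------------------------------

def discard_initial_volumes(data: np.ndarray, k: int = DEFAULT_DISCARD) -> np.ndarray:
    """Drop the first ``k`` time points (last axis) for scanner equilibration."""
    data = np.asarray(data)
    if k < 0:
        raise ValueError(f"discard count must be >= 0, got {k}")
    n_time = data.shape[-1]
    if k >= n_time:
        raise ValueError(f"cannot discard {k} of {n_time} time points")
    return data[..., k:]


def detrend_linear(series: np.ndarray, tr_seconds: float | None = None) -> np.ndarray:
    """Remove the least-squares linear trend (and hence the mean) over time.

    Operates along the last axis; ``tr_seconds`` is accepted for interface
    symmetry but the result is invariant to the time scale.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 3:
        raise ValueError(f"need at least 3 time points to detrend, got {series.shape[-1]}")
    return scipy.signal.detrend(series, axis=-1, type="linear")


def bandpass_filter(
    series: np.ndarray,
    tr_seconds: float,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
) -> np.ndarray:
    """Ideal frequency-domain band-pass along the last axis.

    Discrete-Fourier coefficients with frequency in ``[low_hz, high_hz]``
    (inclusive) are retained; everything else, including the
    zero-frequency term, is zeroed.  This is a projection, hence
    idempotent.  Requires ``0 <= low < high < Nyquist`` where Nyquist is
    ``1 / (2 * tr_seconds)``.
    """
    series = np.asarray(series, dtype=float)
    if not tr_seconds > 0:
        raise ValueError(f"tr_seconds must be > 0, got {tr_seconds}")
    nyquist = 0.5 / tr_seconds
    if not 0 <= low_hz < high_hz:
        raise ValueError(f"need 0 <= low < high, got low={low_hz}, high={high_hz}")
    if high_hz >= nyquist:
        raise ValueError(
            f"high cutoff {high_hz} Hz must be below Nyquist {nyquist} Hz (TR={tr_seconds}s)"
        )
    n = series.shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    keep = (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12) & (freqs > 0)
    spec = np.fft.rfft(series, axis=-1) * keep
    return np.fft.irfft(spec, n=n, axis=-1)


def preprocess_series(
    data: np.ndarray,
    tr_seconds: float,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
) -> np.ndarray:
    """Detrend then band-pass a node-by-time matrix."""
    return bandpass_filter(detrend_linear(data), tr_seconds, low_hz, high_hz)


# ---------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------

def _read_manifest(manifest: str | Path) -> tuple[pd.DataFrame, Path]:
    manifest = Path(manifest)
    df = pd.read_csv(manifest, sep="\t")
    required = {"subject_id", "group", "file"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{manifest}: manifest missing columns {sorted(missing)}")
    return df, manifest.parent


def extract_cohort(
    manifest: str | Path,
    atlas: NetworkAtlas,
    tr_seconds: float = 2.0,
    discard: int = DEFAULT_DISCARD,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
) -> list[SubjectSeries]:
    """Extract preprocessed node series from a cohort of NIfTI volumes.

    The manifest is a TSV with columns ``subject_id``, ``group``,
    ``file`` (paths relative to the manifest).  Per subject the pipeline
    is: discard first ``discard`` volumes -> mean over each node sphere
    -> linear detrend -> ideal band-pass.  A TR in the NIfTI header that
    disagrees with ``tr_seconds`` is logged; the configured value wins.
    """
    rows, base = _read_manifest(manifest)
    cohort: list[SubjectSeries] = []
    for rec in rows.itertuples(index=False):
        path = Path(rec.file)
        if not path.is_absolute():
            path = base / path
        if not path.exists():
            raise FileNotFoundError(f"subject {rec.subject_id!r}: volume file not found: {path}")
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"subject {rec.subject_id!r}: expected 4-D volume, got {data.ndim}-D")
        zooms = img.header.get_zooms()
        if len(zooms) >= 4 and zooms[3] > 0 and not np.isclose(zooms[3], tr_seconds):
            logger.warning(
                "subject %s: header TR %.3fs != configured TR %.3fs; using configured value",
                rec.subject_id, zooms[3], tr_seconds,
            )
        try:
            data = discard_initial_volumes(data, discard)
            series = np.empty((len(atlas), data.shape[-1]))
            for i, node in enumerate(atlas):
                mask = sphere_mask(node, img.affine, data.shape[:3])
                logger.debug("subject %s node %s: %d voxels", rec.subject_id, node.name, len(mask))
                series[i] = extract_node_series(data, mask)
            series = preprocess_series(series, tr_seconds, low_hz, high_hz)
        except ValueError as exc:
            raise ValueError(f"subject {rec.subject_id!r}: {exc}") from exc
        flat = np.isclose(series.var(axis=1), 0.0)
        if flat.any():
            logger.warning(
                "subject %s: zero-variance node series after preprocessing: %s",
                rec.subject_id, [atlas.names[i] for i in np.flatnonzero(flat)],
            )
        cohort.append(SubjectSeries(str(rec.subject_id), str(rec.group), series, tr_seconds, atlas.names))
    return cohort


def read_series_cohort(
    manifest: str | Path,
    atlas: NetworkAtlas,
    tr_seconds: float = 2.0,
    preprocess: bool = False,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
) -> list[SubjectSeries]:
    """Load pre-extracted node-by-time TSV tables listed in a manifest."""
    rows, base = _read_manifest(manifest)
    cohort = []
    for rec in rows.itertuples(index=False):
        path = Path(rec.file)
        if not path.is_absolute():
            path = base / path
        if not path.exists():
            raise FileNotFoundError(f"subject {rec.subject_id!r}: series file not found: {path}")
        subj = SubjectSeries.from_tsv(path, str(rec.subject_id), str(rec.group), tr_seconds, atlas)
        if preprocess:
            subj.data = preprocess_series(subj.data, tr_seconds, low_hz, high_hz)
        cohort.append(subj)
    return cohort


def write_series_cohort(cohort: Sequence[SubjectSeries], out_dir: str | Path) -> Path:
    """Write per-subject TSVs plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for subj in cohort:
        fname = f"{subj.subject_id}.tsv"
        subj.to_tsv(out_dir / fname)
        records.append({"subject_id": subj.subject_id, "group": subj.group, "file": fname})
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(records).to_csv(manifest, sep="\t", index=False)
    return manifest
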