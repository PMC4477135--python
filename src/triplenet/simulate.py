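"""Synthetic two-group BOLD-like cohorts with plantable network effects.

The generator emulates the statistical structure the degree analysis
assumes: per subject, 11 node time series with a block-structured
correlation matrix (higher within each network than between networks),
lag-1 temporal autocorrelation, and additive measurement noise.  Group
effects are planted directly on the target correlations of the affected
group: raising every edge incident to the right anterior insula
("rAI"), and lowering every DMN x CEN cross-edge — the two directional
findings the degree pipeline is meant to detect.

Construction contract per subject: draw independent Gaussian
innovations per node, apply a unit-variance AR(1) recursion in time,
mix across nodes with the Cholesky factor of the target correlation
matrix, then add white noise.  Temporal filtering happens before
spatial mixing, so at ``noise_sd = 0`` the expected inter-node Pearson
correlation equals the target exactly.  Targets that the planted
effects push outside the positive-definite cone are repaired by
eigenvalue clipping followed by re-normalisation to unit diagonal.

A rendering helper paints each node's series into its sphere of voxels
on a synthetic MNI grid, enabling end-to-end tests of volume
extraction without real scans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import scipy.signal

from .atlas import NetworkAtlas
from .preprocess import SubjectSeries, sphere_mask

__all__ = [
    "SimulationConfig",
    "CorrelationTarget",
    "GROUP_CONTROL",
    "GROUP_AFFECTED",
    "build_target_correlation",
    "repair_correlation",
    "simulate_subject_series",
    "simulate_cohort",
    "atlas_grid",
    "render_synthetic_volume",
    "write_volume_cohort",
]

GROUP_CONTROL = "control"
GROUP_AFFECTED = "affected"

#: node whose incident edges receive the planted coupling increase
RAI_NODE = "rAI"
#: network pair whose cross-edges receive the planted decrease
EFFECT_PAIR = ("DMN", "CEN")


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults reproduce the emulated study design: 16 subjects per
    group, 230 retained time points at TR = 2 s, within-network
    correlation 0.5 against a 0.1 between-network baseline, a +0.25
    increase on rAI-incident edges and a -0.3 decrease on DMN x CEN
    edges in the affected group.  ``ar_phi`` (default 0.3) is the lag-1
    autocorrelation of each latent node series and ``noise_sd``
    (default 0.2, relative to unit signal variance) the white
    measurement-noise scale.
    """

    n_per_group: int = 16
    n_timepoints: int = 230
    tr_seconds: float = 2.0
    within_network_r: float = 0.5
    between_network_r: float = 0.1
    rai_effect: float = 0.25
    dmn_cen_effect: float = 0.3
    ar_phi: float = 0.3
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError(f"n_per_group must be >= 2, got {self.n_per_group}")
        if self.n_timepoints < 3:
            raise ValueError(f"n_timepoints must be >= 3, got {self.n_timepoints}")
        if not self.tr_seconds > 0:
            raise ValueError(f"tr_seconds must be > 0, got {self.tr_seconds}")
        for name in ("within_network_r", "between_network_r", "rai_effect", "dmn_cen_effect"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1), got {v}")
        if not 0.0 <= self.ar_phi < 1.0:
            raise ValueError(f"ar_phi must lie in [0, 1), got {self.ar_phi}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def null(self) -> "SimulationConfig":
        """Copy with both planted group effects removed."""
        cfg = asdict(self)
        cfg.update(rai_effect=0.0, dmn_cen_effect=0.0)
        return SimulationConfig(**cfg)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class CorrelationTarget:
    """Per-group target correlation matrices in atlas node order."""

    node_names: tuple[str, ...]
    matrices: dict[str, np.ndarray]
    max_repair_delta: dict[str, float] = field(default_factory=dict)

    def matrix(self, group: str) -> np.ndarray:
        if group not in self.matrices:
            raise KeyError(f"unknown group {group!r}; have {sorted(self.matrices)}")
        return self.matrices[group]


def repair_correlation(mat: np.ndarray, floor: float = 1e-6, max_iter: int = 100) -> np.ndarray:
    """Nearest-style positive-definite repair of a correlation matrix.

    Eigenvalues are clipped at ``floor`` and the matrix re-normalised to
    unit diagonal, iterating until the smallest eigenvalue is positive.
    """
    out = np.array(mat, dtype=float)
    for _ in range(max_iter):
        w, v = np.linalg.eigh(out)
        if w.min() > 0 and np.allclose(np.diag(out), 1.0):
            return out
        w = np.clip(w, floor, None)
        out = (v * w) @ v.T
        scale = np.sqrt(np.diag(out))
        out = out / np.outer(scale, scale)
        out = (out + out.T) / 2.0
        np.fill_diagonal(out, 1.0)
    if np.linalg.eigvalsh(out).min() <= 0:
        raise ValueError("positive-definite repair failed to converge")
    return out


def build_target_correlation(atlas: NetworkAtlas, config: SimulationConfig) -> CorrelationTarget:
    """Block-structured group targets with the planted effects applied.

    The control matrix has ``within_network_r`` on within-network cells
    and ``between_network_r`` elsewhere; the affected matrix adds
    ``rai_effect`` to every rAI-incident cell and subtracts
    ``dmn_cen_effect`` on every DMN x CEN cell.  Both are clipped into
    (-0.999, 0.999) and repaired to positive definite.
    """
    if len(atlas.networks) < 2:
        raise ValueError("atlas must partition nodes into at least 2 networks")
    n = len(atlas)
    nets = [node.network for node in atlas]
    same = np.array([[a == b for b in nets] for a in nets])
    base = np.where(same, config.within_network_r, config.between_network_r).astype(float)
    np.fill_diagonal(base, 1.0)

    affected = base.copy()
    if config.rai_effect != 0.0:
        if RAI_NODE not in atlas.names:
            raise ValueError(
                f"rai_effect is {config.rai_effect} but atlas has no node named {RAI_NODE!r}"
            )
        k = atlas.index(RAI_NODE)
        affected[k, :] += config.rai_effect
        affected[:, k] += config.rai_effect
        affected[k, k] = 1.0
    if config.dmn_cen_effect != 0.0:
        m_name, n_name = EFFECT_PAIR
        missing = [x for x in EFFECT_PAIR if x not in atlas.networks]
        if missing:
            raise ValueError(
                f"dmn_cen_effect is {config.dmn_cen_effect} but atlas lacks networks {missing}"
            )
        rows = atlas.network_indices(m_name)
        cols = atlas.network_indices(n_name)
        affected[np.ix_(rows, cols)] -= config.dmn_cen_effect
        affected[np.ix_(cols, rows)] -= config.dmn_cen_effect

    matrices: dict[str, np.ndarray] = {}
    deltas: dict[str, float] = {}
    for label, raw in ((GROUP_CONTROL, base), (GROUP_AFFECTED, affected)):
        clipped = np.clip(raw, -0.999, 0.999)
        np.fill_diagonal(clipped, 1.0)
        repaired = repair_correlation(clipped)
        matrices[label] = repaired
        deltas[label] = float(np.abs(repaired - clipped).max())
    return CorrelationTarget(tuple(atlas.names), matrices, deltas)


def _unit_ar1(innovations: np.ndarray, phi: float) -> np.ndarray:
    """Unit-stationary-variance AR(1) series from unit-variance innovations."""
    if phi == 0.0:
        return innovations
    scaled = innovations * np.sqrt(1.0 - phi * phi)
    scaled[..., 0] = innovations[..., 0]  # stationary start
    return scipy.signal.lfilter([1.0], [1.0, -phi], scaled, axis=-1)


def simulate_subject_series(
    target: np.ndarray,
    config: SimulationConfig,
    subject_seed: int | np.random.SeedSequence,
    subject_id: str = "sim",
    group: str = GROUP_CONTROL,
    node_names: Sequence[str] | None = None,
) -> SubjectSeries:
    """One subject's node-by-time matrix realising a target correlation.

    Deterministic for a fixed ``subject_seed``.  ``target`` must be the
    positive-definite correlation matrix of the subject's group.
    """
    target = np.asarray(target, dtype=float)
    n_nodes = target.shape[0]
    if target.shape != (n_nodes, n_nodes):
        raise ValueError(f"target must be square, got {target.shape}")
    try:
        chol = np.linalg.cholesky(target)
    except np.linalg.LinAlgError as exc:
        raise ValueError("target correlation matrix is not positive definite") from exc
    rng = np.random.default_rng(subject_seed)
    innovations = rng.standard_normal((n_nodes, config.n_timepoints))
    latent = _unit_ar1(innovations, config.ar_phi)
    mixed = chol @ latent
    if config.noise_sd > 0:
        mixed = mixed + config.noise_sd * rng.standard_normal(mixed.shape)
    if node_names is None:
        node_names = tuple(f"node{i}" for i in range(n_nodes))
    return SubjectSeries(subject_id, group, mixed, config.tr_seconds, tuple(node_names))


def simulate_cohort(atlas: NetworkAtlas, config: SimulationConfig) -> list[SubjectSeries]:
    """Two-group cohort of ``2 * n_per_group`` subjects, control first.

    Per-subject seeds are spawned deterministically from ``config.seed``,
    so the whole cohort is reproducible bit-for-bit.
    """
    target = build_target_correlation(atlas, config)
    seeds = np.random.SeedSequence(config.seed).spawn(2 * config.n_per_group)
    width = len(str(config.n_per_group))
    cohort: list[SubjectSeries] = []
    k = 0
    for group in (GROUP_CONTROL, GROUP_AFFECTED):
        for i in range(config.n_per_group):
            cohort.append(
                simulate_subject_series(
                    target.matrix(group),
                    config,
                    seeds[k],
                    subject_id=f"{group}_{i + 1:0{width}d}",
                    group=group,
                    node_names=atlas.names,
                )
            )
            k += 1
    return cohort


# ---------------------------------------------------------------------
# synthetic volumes
# ---------------------------------------------------------------------

def atlas_grid(
    atlas: NetworkAtlas, voxel_size_mm: float = 2.0, margin_mm: float = 8.0
) -> tuple[tuple[int, int, int], np.ndarray]:
    """Axis-aligned MNI grid (shape, affine) covering all atlas spheres."""
    if not voxel_size_mm > 0:
        raise ValueError(f"voxel size must be > 0, got {voxel_size_mm}")
    coords = np.array([node.coords for node in atlas])
    radii = np.array([node.radius for node in atlas])
    lo = (coords - radii[:, None]).min(axis=0) - margin_mm
    hi = (coords + radii[:, None]).max(axis=0) + margin_mm
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / voxel_size_mm)) + 1 for k in range(3))
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = lo
    return shape, affine


def render_synthetic_volume(
    series: SubjectSeries,
    atlas: NetworkAtlas,
    shape: Sequence[int] | None = None,
    affine: np.ndarray | None = None,
    background_noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paint node series into their spheres on a synthetic 4-D volume.

    Every voxel of a node's sphere carries that node's series verbatim;
    all remaining voxels hold seeded Gaussian noise of scale
    ``background_noise_sd``.  Overlapping spheres raise (distinct nodes
    must own disjoint voxels).  Returns ``(data, affine)`` with data of
    shape ``shape + (n_timepoints,)``.
    """
    if (shape is None) != (affine is None):
        raise ValueError("provide both shape and affine, or neither")
    if shape is None:
        shape, affine = atlas_grid(atlas)
    shape = tuple(int(s) for s in shape)
    affine = np.asarray(affine, dtype=float)
    if background_noise_sd < 0:
        raise ValueError("background_noise_sd must be >= 0")
    n_time = series.n_timepoints
    rng = np.random.default_rng(seed)
    if background_noise_sd > 0:
        data = rng.normal(0.0, background_noise_sd, size=shape + (n_time,))
    else:
        data = np.zeros(shape + (n_time,))
    owner = np.full(shape, -1, dtype=int)
    for i, node in enumerate(atlas):
        mask = sphere_mask(node, affine, shape)  # raises naming the node if empty
        prior = owner[mask[:, 0], mask[:, 1], mask[:, 2]]
        clash = prior[prior >= 0]
        if clash.size:
            other = atlas.names[int(clash[0])]
            raise ValueError(
                f"spheres of nodes {other!r} and {node.name!r} overlap on this grid"
            )
        owner[mask[:, 0], mask[:, 1], mask[:, 2]] = i
        data[mask[:, 0], mask[:, 1], mask[:, 2], :] = series.data[series.node_names.index(node.name)]
    return data, affine


def write_volume_cohort(
    cohort: Sequence[SubjectSeries],
    atlas: NetworkAtlas,
    out_dir: str | Path,
    voxel_size_mm: float = 2.0,
    background_noise_sd: float = 0.0,
    seed: int = 0,
) -> Path:
    """Render each subject to NIfTI-1 and write a volume manifest."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shape, affine = atlas_grid(atlas, voxel_size_mm=voxel_size_mm)
    seeds = np.random.SeedSequence(seed).spawn(len(cohort))
    records = []
    for subj, sseed in zip(cohort, seeds):
        data, aff = render_synthetic_volume(
            subj, atlas, shape, affine, background_noise_sd=background_noise_sd, seed=sseed
        )
        img = nib.Nifti1Image(data.astype(np.float32), aff)
        zooms = (voxel_size_mm,) * 3 + (subj.tr_seconds,)
        img.header.set_zooms(zooms)
        fname = f"{subj.subject_id}.nii"
        nib.save(img, str(out_dir / fname))
        records.append({"subject_id": subj.subject_id, "group": subj.group, "file": fname})
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(records).to_csv(manifest, sep="\t", index=False)
    return manifest
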