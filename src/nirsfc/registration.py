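"""Geometric co-registration: landmark affine, scalp/cortex projection, labelling.

The production pipeline uses the bundled channel->ROI fixture; this module
implements the geometric path that produces such an assignment: fit a 12-dof
affine from the five cranial landmarks (Nasion, Inion, LPA, RPA, Cz), snap each
channel to the scalp mesh, project it to the nearest grey-matter vertex, and
label it by the dominant anatomical label among cortex vertices within a
12.5 mm sphere, requiring at least 25% overlap.

Real MRI template meshes are out of scope; tests run on programmatically
generated labelled sphere/ellipsoid meshes (synthetic stand-ins for the
template surfaces).  Units are mm throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import trimesh
from scipy.spatial import cKDTree

LANDMARK_NAMES = ("Nasion", "Inion", "LPA", "RPA", "Cz")


@dataclass(frozen=True)
class RegistrationParams:
    """Sphere radius (mm) and minimum label-overlap fraction for channel labelling."""

    sphere_radius_mm: float = 12.5
    min_overlap_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.sphere_radius_mm <= 0:
            raise ValueError("sphere_radius_mm must be > 0")
        if not 0 < self.min_overlap_fraction <= 1:
            raise ValueError("min_overlap_fraction must be in (0, 1]")


@dataclass
class HeadSurface:
    """Landmarks plus scalp and labelled cortex meshes (mm)."""

    landmarks: dict[str, np.ndarray]
    scalp_mesh: trimesh.Trimesh
    cortex_mesh: trimesh.Trimesh
    cortex_labels: np.ndarray  # per-vertex anatomical label (object/str array)

    def __post_init__(self) -> None:
        missing = set(LANDMARK_NAMES) - set(self.landmarks)
        if missing:
            raise ValueError(f"missing landmarks: {sorted(missing)}")
        if len(self.cortex_labels) != len(self.cortex_mesh.vertices):
            raise ValueError("cortex_labels must cover every cortex vertex")


@dataclass(frozen=True)
class AffineTransform:
    """x -> A @ x + b, with the RMS residual of the fit."""

    linear: np.ndarray      # (3, 3)
    translation: np.ndarray  # (3,)
    residual_rms: float = 0.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.linear.T + self.translation


def fit_landmark_affine(
    source_landmarks: Mapping[str, Sequence[float]],
    target_landmarks: Mapping[str, Sequence[float]],
) -> AffineTransform:
    """Least-squares 12-dof affine mapping source landmarks onto target landmarks.

    Both sides must carry the same five named points.  Exact (zero residual)
    whenever the correspondence is generated by an affine map, since five generic
    points over-determine the 12 parameters by one correspondence.
    """
    names = sorted(source_landmarks)
    if sorted(target_landmarks) != names:
        raise ValueError("source and target landmark names differ")
    src = np.array([source_landmarks[n] for n in names], dtype=float)
    tgt = np.array([target_landmarks[n] for n in names], dtype=float)
    if src.shape[0] < 4:
        raise ValueError("need at least 4 landmark correspondences")
    # homogeneous design: [x y z 1] @ M = target, M is (4, 3)
    design = np.hstack([src, np.ones((src.shape[0], 1))])
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError("degenerate landmark geometry: points are coplanar or coincident")
    sol, *_ = np.linalg.lstsq(design, tgt, rcond=None)
    linear = sol[:3].T
    translation = sol[3]
    resid = design @ sol - tgt
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineTransform(linear=linear, translation=translation, residual_rms=rms)


def _nearest_vertex(point: np.ndarray, mesh: trimesh.Trimesh) -> int:
    verts = np.asarray(mesh.vertices)
    if verts.size == 0:
        raise ValueError("mesh has no vertices")
    d2 = np.sum((verts - np.asarray(point, dtype=float)) ** 2, axis=1)
    return int(np.argmin(d2))  # argmin takes the lowest index on ties


def project_channel_to_cortex(channel_point: Sequence[float], head: HeadSurface) -> np.ndarray:
    """Snap a channel to the nearest scalp vertex, then to the nearest cortex vertex."""
    p = np.asarray(channel_point, dtype=float)
    scalp_idx = _nearest_vertex(p, head.scalp_mesh)
    scalp_point = np.asarray(head.scalp_mesh.vertices)[scalp_idx]
    cortex_idx = _nearest_vertex(scalp_point, head.cortex_mesh)
    return np.asarray(head.cortex_mesh.vertices)[cortex_idx].copy()


def label_channel(
    cortex_point: Sequence[float],
    head: HeadSurface,
    params: RegistrationParams = RegistrationParams(),
) -> str | None:
    """Dominant anatomical label within the sphere, if it covers >= the overlap fraction.

    Overlap is measured as the vertex-count fraction per label among cortex
    vertices inside the sphere.  Ties break by larger fraction, then
    lexicographically smaller label.  Returns None when no vertex lies within
    the radius or no label reaches the threshold.
    """
    verts = np.asarray(head.cortex_mesh.vertices)
    tree = cKDTree(verts)
    idx = tree.query_ball_point(np.asarray(cortex_point, dtype=float), params.sphere_radius_mm)
    if not idx:
        return None
    labels = np.asarray(head.cortex_labels)[idx]
    uniq, counts = np.unique(labels, return_counts=True)
    fractions = counts / len(idx)
    order = sorted(range(len(uniq)), key=lambda i: (-fractions[i], str(uniq[i])))
    best = order[0]
    if fractions[best] >= params.min_overlap_fraction:
        return str(uniq[best])
    return None


def label_all_channels(
    channel_points: Mapping[int, Sequence[float]],
    head: HeadSurface,
    params: RegistrationParams = RegistrationParams(),
) -> dict[int, str]:
    """Project and label every channel; unlabelled channels get 'unknown'."""
    out = {}
    for cid, point in channel_points.items():
        cortex_pt = project_channel_to_cortex(point, head)
        out[cid] = label_channel(cortex_pt, head, params) or "unknown"
    return out


def make_labeled_sphere_head(
    radius_mm: float = 80.0,
    cortex_radius_mm: float = 70.0,
    subdivisions: int = 3,
    patch_labels: Sequence[str] = ("A", "B", "C", "D"),
) -> HeadSurface:
    """Synthetic head: concentric icospheres with longitude-sector cortex labels.

    A stand-in for segmented MRI template surfaces, used by tests and the
    optional registration path demo.
    """
    scalp = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius_mm)
    cortex = trimesh.creation.icosphere(subdivisions=subdivisions, radius=cortex_radius_mm)
    verts = np.asarray(cortex.vertices)
    theta = np.mod(np.arctan2(verts[:, 1], verts[:, 0]), 2 * np.pi)
    sector = np.floor(theta / (2 * np.pi / len(patch_labels))).astype(int)
    labels = np.array([patch_labels[s] for s in sector], dtype=object)
    landmarks = {
        "Nasion": np.array([radius_mm, 0.0, 0.0]),
        "Inion": np.array([-radius_mm, 0.0, 0.0]),
        "RPA": np.array([0.0, -radius_mm, 0.0]),
        "LPA": np.array([0.0, radius_mm, 0.0]),
        "Cz": np.array([0.0, 0.0, radius_mm]),
    }
    return HeadSurface(landmarks=landmarks, scalp_mesh=scalp, cortex_mesh=cortex,
                       cortex_labels=labels)


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    mesh.export(str(path))  # format from extension (.off / .ply)


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    loaded = trimesh.load_mesh(str(path))
    if not isinstance(loaded, trimesh.Trimesh):
        raise ValueError(f"{path} did not contain a single triangular mesh")
    return loaded
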