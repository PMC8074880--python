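"""Landmark I/O, generalized Procrustes superimposition and PCA morphospace.

Jaw shape is captured as 33 ordered 2-D points per specimen: 7 fixed
landmarks followed by 26 semilandmarks along the jaw outline, digitised in
lateral view (anterior to the right, dorsal up). Left-side configurations
are mirrored to the right before analysis. Generalized Procrustes analysis
(GPA) removes translation, scale and orientation; the residual coordinates
are pure shape and are ordinated by PCA into a morphospace.

Semilandmarks are treated as fixed points during superimposition by default;
an optional mode slides them along their local curve tangent towards the
consensus, for sensitivity analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "N_LANDMARKS",
    "N_FIXED",
    "LandmarkSet",
    "AlignedShapes",
    "Morphospace",
    "TpsParseError",
    "DegenerateShapeError",
    "read_tps",
    "write_tps",
    "mirror_to_right",
    "centroid_size",
    "gpa_align",
    "procrustes_distance",
    "pca_embed",
]

N_LANDMARKS = 33
N_FIXED = 7


class TpsParseError(ValueError):
    """Malformed TPS file (bad block structure or landmark count)."""


class DegenerateShapeError(ValueError):
    """A configuration with zero centroid size (all points coincident)."""


@dataclass
class LandmarkSet:
    """One specimen's raw landmark configuration.

    ``points`` is an (n_points, 2) array; fixed landmarks first, then
    semilandmarks. ``metadata`` carries through epoch/clade/diet labels.
    """

    taxon: str
    points: np.ndarray
    side: str = "right"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError(f"{self.taxon}: points must be (k, 2)")
        if not np.isfinite(self.points).all():
            raise ValueError(f"{self.taxon}: non-finite coordinates")
        if self.side not in ("right", "left"):
            raise ValueError(f"{self.taxon}: side must be 'right' or 'left'")


@dataclass
class AlignedShapes:
    """Procrustes-superimposed configurations.

    Each aligned shape is centred at the origin with unit centroid size;
    ``consensus`` is the coordinate-wise mean shape. ``centroid_sizes`` holds
    the pre-scaling size of each specimen.
    """

    taxa: list[str]
    coords: np.ndarray          # (n, k, 2)
    centroid_sizes: np.ndarray  # (n,)
    consensus: np.ndarray       # (k, 2)
    iterations: int
    converged: bool
    metadata: list[dict] = field(default_factory=list)

    @property
    def n_shapes(self) -> int:
        return self.coords.shape[0]

    def flat(self) -> np.ndarray:
        """Flattened (n, 2k) coordinate matrix (x1, y1, x2, y2, ...)."""
        return self.coords.reshape(self.n_shapes, -1)


@dataclass
class Morphospace:
    """PCA ordination of aligned shapes.

    ``scores`` (n × axes) are projections onto the principal axes,
    ``explained`` the per-axis proportion of total variance, ``loadings``
    (axes × 2k) the axis directions in flattened coordinate space.
    """

    scores: np.ndarray
    explained: np.ndarray
    loadings: np.ndarray
    mean: np.ndarray
    eigenvalues: np.ndarray
    taxa: list[str] = field(default_factory=list)

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]

    def project(self, flat_coords: np.ndarray) -> np.ndarray:
        """Project flattened aligned coordinates into this morphospace."""
        flat_coords = np.atleast_2d(np.asarray(flat_coords, dtype=float))
        return (flat_coords - self.mean) @ self.loadings.T


# ---------------------------------------------------------------------------
# TPS input/output

_TPS_KEY = re.compile(r"^\s*([A-Z]+)\s*=\s*(.*?)\s*$")


def read_tps(path: str | Path, expected_landmarks: Optional[int] = N_LANDMARKS,
             ) -> list[LandmarkSet]:
    """Read landmark configurations from a TPS file.

    Honours LM=, ID=, IMAGE= and SCALE= records; SCALE is applied
    multiplicatively to the coordinates when present. With the default strict
    mode every block must contain exactly ``expected_landmarks`` points; pass
    ``expected_landmarks=None`` to accept any count.
    """
    blocks: list[LandmarkSet] = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    i, block_index = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _TPS_KEY.match(line)
        if not m or m.group(1) != "LM":
            raise TpsParseError(f"{path}: block {block_index}: expected LM=<k>, got {line!r}")
        try:
            k = int(m.group(2))
        except ValueError:
            raise TpsParseError(f"{path}: block {block_index}: bad LM count {m.group(2)!r}")
        i += 1
        pts = np.empty((k, 2))
        for j in range(k):
            if i >= len(lines):
                raise TpsParseError(
                    f"{path}: block {block_index}: truncated after {j} of {k} points")
            parts = lines[i].split()
            if len(parts) != 2:
                raise TpsParseError(
                    f"{path}: block {block_index}: bad coordinate line {lines[i]!r}")
            try:
                pts[j] = [float(parts[0]), float(parts[1])]
            except ValueError:
                raise TpsParseError(
                    f"{path}: block {block_index}: non-numeric coordinates {lines[i]!r}")
            i += 1
        taxon, scale, meta = f"specimen_{block_index}", None, {}
        while i < len(lines):
            mm = _TPS_KEY.match(lines[i].strip())
            if mm is None or mm.group(1) == "LM":
                break
            key, val = mm.group(1), mm.group(2)
            if key == "ID":
                taxon = val
            elif key == "IMAGE":
                meta["image"] = val
            elif key == "SCALE":
                scale = float(val)
            else:
                meta[key.lower()] = val
            i += 1
        if expected_landmarks is not None and k != expected_landmarks:
            raise TpsParseError(
                f"{path}: block {block_index} ({taxon}): expected "
                f"{expected_landmarks} landmarks, found {k}")
        if scale is not None:
            pts = pts * scale
        blocks.append(LandmarkSet(taxon=taxon, points=pts, metadata=meta))
        block_index += 1
    return blocks


def write_tps(path: str | Path, shapes: Sequence[LandmarkSet]) -> None:
    """Write configurations to TPS (LM=, coordinates to 6 decimals, ID=,
    IMAGE= when present)."""
    out = []
    for ls in shapes:
        out.append(f"LM={len(ls.points)}")
        for x, y in ls.points:
            out.append(f"{x:.6f} {y:.6f}")
        if "image" in ls.metadata:
            out.append(f"IMAGE={ls.metadata['image']}")
        out.append(f"ID={ls.taxon}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Superimposition

def mirror_to_right(ls: LandmarkSet) -> LandmarkSet:
    """Reflect left-side configurations about the vertical axis (x-negation)
    and relabel them right; right-side inputs are returned unchanged."""
    if ls.side == "right":
        return ls
    pts = ls.points.copy()
    pts[:, 0] = -pts[:, 0]
    return LandmarkSet(taxon=ls.taxon, points=pts, side="right",
                       metadata=dict(ls.metadata))


def centroid_size(points: np.ndarray) -> float:
    """Square root of summed squared distances of landmarks to their centroid."""
    pts = np.asarray(points, dtype=float)
    centred = pts - pts.mean(axis=0)
    return float(np.sqrt((centred ** 2).sum()))


def _optimal_rotation(shape: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (det = +1) minimising ||shape @ R − target||_F."""
    h = shape.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def _slide_semilandmarks(coords: np.ndarray, consensus: np.ndarray,
                         fixed: int) -> np.ndarray:
    """Move each semilandmark along its local curve tangent towards the
    consensus (projection of the residual onto the tangent direction)."""
    out = coords.copy()
    k = coords.shape[0]
    for i in range(fixed, k):
        lo = i - 1 if i > 0 else i
        hi = i + 1 if i < k - 1 else i
        tangent = coords[hi] - coords[lo]
        norm = np.linalg.norm(tangent)
        if norm < 1e-12:
            continue
        tangent /= norm
        out[i] = coords[i] + tangent * float((consensus[i] - coords[i]) @ tangent)
    return out


def _canonical_orientation(coords: np.ndarray) -> np.ndarray:
    """Rotate the whole aligned sample into a canonical frame.

    GPA fixes shapes only up to one global rotation (inherited from the
    orientation of the first input). Rotating so the consensus' principal
    axis lies along x — with the landmark of largest |x| on the positive
    side — removes that arbitrariness, making the output invariant under
    rigid motions of the inputs. Only proper rotations are used.
    """
    consensus = coords.mean(axis=0)
    _, evecs = np.linalg.eigh(consensus.T @ consensus)
    rot = evecs[:, ::-1]  # major axis first
    if np.linalg.det(rot) < 0:
        rot[:, 1] = -rot[:, 1]
    out = coords @ rot
    cons = consensus @ rot
    j = int(np.argmax(np.abs(cons[:, 0])))
    if cons[j, 0] < 0:
        out = -out  # 180-degree rotation (det +1 in 2-D)
    return out


def gpa_align(shapes: Sequence[LandmarkSet], tol: float = 1e-10,
              max_iter: int = 100, slide: bool = False) -> AlignedShapes:
    """Generalized Procrustes analysis.

    Iteratively translates each configuration's centroid to the origin,
    scales to unit centroid size, rotates (rotation only — reflections are
    never introduced) onto the current consensus, and updates the consensus,
    until its root-mean-square change falls below ``tol`` or ``max_iter``
    passes. Deterministic given input order.
    """
    if len(shapes) < 2:
        raise ValueError("GPA requires at least 2 shapes")
    k = shapes[0].points.shape[0]
    for ls in shapes:
        if ls.points.shape[0] != k:
            raise ValueError(
                f"{ls.taxon}: landmark count {ls.points.shape[0]} differs from {k}")
    sizes = np.empty(len(shapes))
    coords = np.empty((len(shapes), k, 2))
    for idx, ls in enumerate(shapes):
        cs = centroid_size(ls.points)
        if cs < 1e-12:
            raise DegenerateShapeError(
                f"{ls.taxon}: zero centroid size (all landmarks coincident)")
        sizes[idx] = cs
        coords[idx] = (ls.points - ls.points.mean(axis=0)) / cs

    consensus = coords[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for idx in range(len(shapes)):
            coords[idx] = coords[idx] @ _optimal_rotation(coords[idx], consensus)
            if slide:
                slid = _slide_semilandmarks(coords[idx], consensus, N_FIXED)
                slid -= slid.mean(axis=0)
                cs = np.sqrt((slid ** 2).sum())
                coords[idx] = slid / cs
        new_consensus = coords.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= np.sqrt((new_consensus ** 2).sum())
        change = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    # final pass so every shape is optimally rotated to the final consensus
    for idx in range(len(shapes)):
        coords[idx] = coords[idx] @ _optimal_rotation(coords[idx], consensus)
    coords = _canonical_orientation(coords)
    return AlignedShapes(
        taxa=[ls.taxon for ls in shapes],
        coords=coords,
        centroid_sizes=sizes,
        consensus=coords.mean(axis=0),
        iterations=iterations,
        converged=converged,
        metadata=[dict(ls.metadata) for ls in shapes],
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root summed squared distance between two configurations after
    centring, unit-size scaling and optimal rotation of ``a`` onto ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = (a - a.mean(axis=0)) / centroid_size(a)
    b = (b - b.mean(axis=0)) / centroid_size(b)
    a = a @ _optimal_rotation(a, b)
    return float(np.sqrt(((a - b) ** 2).sum()))


# ---------------------------------------------------------------------------
# Morphospace

def pca_embed(aligned: AlignedShapes, n_axes: Optional[int] = None,
              eig_tol: float = 1e-12) -> Morphospace:
    """PCA of the flattened aligned coordinates.

    Axes are ordered by decreasing eigenvalue; by default all axes with
    eigenvalue above ``eig_tol`` are retained. The sign of each axis is fixed
    so its largest-magnitude loading is positive, making runs comparable.
    """
    if aligned.n_shapes < 3:
        raise ValueError("PCA requires at least 3 shapes")
    x = aligned.flat()
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = s ** 2 / (aligned.n_shapes - 1)
    keep = eigenvalues > eig_tol
    if n_axes is not None:
        keep &= np.arange(eigenvalues.size) < n_axes
    u, s, vt = u[:, keep], s[keep], vt[keep]
    eigenvalues = eigenvalues[keep]
    # deterministic sign: largest-magnitude loading on each axis is positive
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    total_var = float(xc.var(axis=0, ddof=1).sum())
    explained = eigenvalues / total_var if total_var > 0 else np.zeros_like(eigenvalues)
    return Morphospace(
        scores=u * s,
        explained=explained,
        loadings=vt,
        mean=mean,
        eigenvalues=eigenvalues,
        taxa=list(aligned.taxa),
    )
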