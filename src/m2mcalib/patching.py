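"""Depth-stratified patch extraction and patch-level z-score normalization.

A 2080 x 256 frame yields 81 patches of 200 axial samples x 26 scan lines:
the first 540 axial samples are skipped, the axial start advances by 100
samples (so consecutive axial zones overlap by half a patch), and the
lateral start advances by 26 lines (exact tiling from column 0).  Each
patch carries its axial-zone identity 0-8 (0 = shallowest) and, for
classification phantoms, the class label.

Z-score normalization is patchwise and elementwise: a *mean patch* and a
*standard-deviation patch* (population convention, divide by N) are
computed across a patch collection and applied as
``(x - mean_patch) / std_patch``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import GeometryError
from .rf_io import RFDataset, RFFrame

__all__ = [
    "PatchGridConfig",
    "Patch",
    "NormalizationStats",
    "extract_patches",
    "extract_patches_dataset",
    "patches_to_arrays",
    "compute_zscore_stats",
    "apply_zscore",
    "split_train_val",
    "PatchZScore",
]


@dataclass(frozen=True)
class PatchGridConfig:
    """Geometry of the patch grid (defaults give the 81-patch layout)."""

    axial_skip: int = 540
    patch_axial: int = 200
    patch_lateral: int = 26
    axial_step: int = 100
    lateral_step: int = 26
    n_axial_positions: int = 9
    n_lateral_positions: int = 9

    @property
    def n_patches(self) -> int:
        return self.n_axial_positions * self.n_lateral_positions

    def required_shape(self) -> Tuple[int, int]:
        """Minimum (n_axial, n_lateral) frame shape this grid needs."""
        ax = self.axial_skip + (self.n_axial_positions - 1) * self.axial_step + self.patch_axial
        lat = (self.n_lateral_positions - 1) * self.lateral_step + self.patch_lateral
        return ax, lat

    def validate(self, n_axial: int, n_lateral: int) -> None:
        req_ax, req_lat = self.required_shape()
        if n_axial < req_ax or n_lateral < req_lat:
            raise GeometryError(
                f"frame of shape ({n_axial}, {n_lateral}) too small for patch "
                f"grid requiring ({req_ax}, {req_lat})"
            )


@dataclass
class Patch:
    """One RF sub-array with its axial-zone identity and optional label."""

    data: np.ndarray
    axial_zone: int
    class_label: Optional[int] = None
    #: (machine_id, phantom_id, frame_index, lateral_position)
    source: Tuple[str, str, int, int] = ("", "", -1, -1)


@dataclass
class NormalizationStats:
    """Elementwise mean / std patches for z-score normalization."""

    mean_patch: np.ndarray
    std_patch: np.ndarray
    n_source_patches: int
    source_tag: str = ""


def extract_patches(frame: RFFrame, grid: PatchGridConfig = PatchGridConfig()) -> List[Patch]:
    """Extract the full patch grid from one frame.

    Patch (i, j) covers axial rows
    ``[axial_skip + i*axial_step, axial_skip + i*axial_step + patch_axial)``
    and lateral columns
    ``[j*lateral_step, j*lateral_step + patch_lateral)``; ``axial_zone = i``.
    """
    grid.validate(frame.n_axial, frame.n_lateral)
    m = frame.meta
    out: List[Patch] = []
    for i in range(grid.n_axial_positions):
        r0 = grid.axial_skip + i * grid.axial_step
        for j in range(grid.n_lateral_positions):
            c0 = j * grid.lateral_step
            out.append(
                Patch(
                    data=frame.samples[r0 : r0 + grid.patch_axial, c0 : c0 + grid.patch_lateral],
                    axial_zone=i,
                    class_label=m.class_label,
                    source=(m.machine_id, m.phantom_id, m.frame_index, j),
                )
            )
    return out


def extract_patches_dataset(
    ds: RFDataset, grid: PatchGridConfig = PatchGridConfig(), dtype=np.float32
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized patch extraction over a dataset.

    Returns ``(X, zones, labels)`` with ``X`` of shape
    ``(n_frames * n_patches, patch_axial, patch_lateral)``; ``labels`` is -1
    where the frame carries no class label.
    """
    xs, zs, ys = [], [], []
    for fr in ds:
        grid.validate(fr.n_axial, fr.n_lateral)
        s = fr.samples
        for i in range(grid.n_axial_positions):
            r0 = grid.axial_skip + i * grid.axial_step
            band = s[r0 : r0 + grid.patch_axial]
            for j in range(grid.n_lateral_positions):
                c0 = j * grid.lateral_step
                xs.append(band[:, c0 : c0 + grid.patch_lateral])
                zs.append(i)
        lbl = fr.meta.class_label
        ys.extend([-1 if lbl is None else lbl] * grid.n_patches)
    X = np.asarray(np.stack(xs), dtype=dtype)
    return X, np.asarray(zs, dtype=np.int64), np.asarray(ys, dtype=np.int64)


def patches_to_arrays(patches: Sequence[Patch], dtype=np.float32):
    """Stack a patch list into ``(X, zones, labels)`` arrays."""
    X = np.stack([np.asarray(p.data, dtype=dtype) for p in patches])
    zones = np.asarray([p.axial_zone for p in patches], dtype=np.int64)
    labels = np.asarray(
        [-1 if p.class_label is None else p.class_label for p in patches],
        dtype=np.int64,
    )
    return X, zones, labels


def _as_stack(patches) -> np.ndarray:
    """Accept a list of Patch or an (N, H, W) array; return the (N, H, W) stack."""
    if isinstance(patches, np.ndarray):
        if patches.ndim != 3:
            raise ValueError("patch array must have shape (n, axial, lateral)")
        return patches
    if len(patches) == 0:
        raise ValueError("empty patch collection")
    return np.stack([np.asarray(p.data) for p in patches])


def compute_zscore_stats(patches, source_tag: str = "") -> NormalizationStats:
    """Elementwise mean/std patches over a collection (population std).

    The std patch is floored at ``1e-12`` times the mean absolute amplitude
    so that identical patches cannot produce a division blow-up downstream.
    """
    X = _as_stack(patches)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 patches to compute statistics")
    mean = X.mean(axis=0, dtype=np.float64)
    std = X.std(axis=0, dtype=np.float64)  # population convention (ddof=0)
    scale = float(np.abs(X).mean())
    eps = 1e-12 * (scale if scale > 0 else 1.0)
    std = np.maximum(std, eps)
    return NormalizationStats(
        mean_patch=mean, std_patch=std, n_source_patches=X.shape[0], source_tag=source_tag
    )


def apply_zscore(patches, stats: NormalizationStats):
    """Apply ``(x - mean_patch) / std_patch`` elementwise.

    Accepts and returns the same container kind as given (list of Patch in,
    list of Patch out with labels/zones preserved; array in, array out).
    """
    if isinstance(patches, np.ndarray):
        if patches.shape[1:] != stats.mean_patch.shape:
            raise ValueError(
                f"patch shape {patches.shape[1:]} does not match stats shape "
                f"{stats.mean_patch.shape}"
            )
        return ((patches - stats.mean_patch) / stats.std_patch).astype(
            patches.dtype, copy=False
        )
    out = []
    for p in patches:
        if p.data.shape != stats.mean_patch.shape:
            raise ValueError(
                f"patch shape {p.data.shape} does not match stats shape "
                f"{stats.mean_patch.shape}"
            )
        out.append(
            Patch(
                data=(p.data - stats.mean_patch) / stats.std_patch,
                axial_zone=p.axial_zone,
                class_label=p.class_label,
                source=p.source,
            )
        )
    return out


def split_train_val(
    patches,
    ratio: Tuple[int, int] = (4, 1),
    seed: int = 0,
    zones: Optional[np.ndarray] = None,
    labels: Optional[np.ndarray] = None,
):
    """Uniform random train/validation partition, stratified by
    (class_label, axial_zone) so both sets represent every cell.

    With a list of Patch the two patch lists are returned; with an
    ``(N, H, W)`` array (plus ``zones``/``labels``) two index arrays are
    returned.  Reproducible under ``seed``.
    """
    array_mode = isinstance(patches, np.ndarray)
    if array_mode:
        n = patches.shape[0]
        z = np.zeros(n, dtype=np.int64) if zones is None else np.asarray(zones)
        y = np.zeros(n, dtype=np.int64) if labels is None else np.asarray(labels)
    else:
        n = len(patches)
        z = np.asarray([p.axial_zone for p in patches])
        y = np.asarray([-1 if p.class_label is None else p.class_label for p in patches])
    if n < 5:
        raise ValueError("need at least 5 patches to split 4:1")
    num, den = ratio[0], ratio[0] + ratio[1]
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    # Iterate cells in sorted order for determinism.
    cells = sorted(set(zip(y.tolist(), z.tolist())))
    for cy, cz in cells:
        idx = np.flatnonzero((y == cy) & (z == cz))
        idx = idx[rng.permutation(idx.size)]
        k = int(round(idx.size * num / den))
        k = min(max(k, 0), idx.size)
        train_idx.append(idx[:k])
        val_idx.append(idx[k:])
    train_idx = np.sort(np.concatenate(train_idx))
    val_idx = np.sort(np.concatenate(val_idx))
    if array_mode:
        return train_idx, val_idx
    return [patches[i] for i in train_idx], [patches[i] for i in val_idx]


class PatchZScore(BaseEstimator, TransformerMixin):
    """Sklearn-style patchwise z-score transformer.

    ``fit`` learns an elementwise mean patch and std patch (population
    convention, epsilon-floored) from an ``(N, H, W)`` stack; ``transform``
    standardizes any stack of the same patch shape.

    Attributes
    ----------
    mean_ : ndarray of shape (H, W)
    std_ : ndarray of shape (H, W)
    n_samples_seen_ : int
    """

    def __init__(self, source_tag: str = ""):
        self.source_tag = source_tag

    def fit(self, X, y=None):
        stats = compute_zscore_stats(_as_stack(X), source_tag=self.source_tag)
        self.mean_ = stats.mean_patch
        self.std_ = stats.std_patch
        self.n_samples_seen_ = stats.n_source_patches
        return self

    def transform(self, X):
        stats = self.stats_
        return apply_zscore(X if isinstance(X, np.ndarray) else _as_stack(X), stats)

    @property
    def stats_(self) -> NormalizationStats:
        if not hasattr(self, "mean_"):
            raise AttributeError("PatchZScore is not fitted")
        return NormalizationStats(
            mean_patch=self.mean_,
            std_patch=self.std_,
            n_source_patches=self.n_samples_seen_,
            source_tag=self.source_tag,
        )
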