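"""Quantification of synovial tissue volume (STV) from contrast-enhanced MRI.

Given a postcontrast T1-weighted fat-suppressed volume, a binary synovium
segmentation, a co-registered precontrast volume and a two-compartment
intensity model (mean fluid intensity ``m_f``, mean enhancing-synovium
intensity ``m_s``), each non-cartilage segmented voxel is split into a
synovial-tissue fraction ``P = (I - m_f) / (m_s - m_f)``, truncated to
[0, 1], and a fluid fraction ``1 - P``.  Volumes are fraction sums times
the physical voxel volume.  Cartilage inside the segmented space is removed
by thresholding the precontrast channel (Otsu by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
from skimage.filters import threshold_otsu


class InvalidModelError(ValueError):
    """The two-compartment intensity model is degenerate (m_s <= m_f)."""


class EstimationError(RuntimeError):
    """Automatic intensity-model estimation failed (e.g. unimodal region)."""


class ShapeMismatchError(ValueError):
    """Grids that must be co-registered do not share a shape/affine."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageVolume:
    """A 3-D scalar intensity grid with physical voxel spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3 or vox.size == 0:
            raise ValueError(f"expected a non-empty 3-D grid, got shape {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise ValueError("intensities must be finite")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive mm values, got {spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape


@dataclass(frozen=True)
class VoxelMask:
    """A boolean grid sharing its companion volume's shape."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got shape {m.shape}")
        object.__setattr__(self, "mask", m.astype(bool))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape

    def count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class IntensityModel:
    """Mean fluid (m_f) and mean synovial-tissue (m_s) intensities.

    On postcontrast T1W-FS images enhancing synovium is brighter than
    fluid, so ``m_s > m_f`` is an invariant.
    """

    m_f: float
    m_s: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.m_f) and np.isfinite(self.m_s)):
            raise InvalidModelError("m_f and m_s must be finite")
        if self.m_s <= self.m_f:
            raise InvalidModelError(
                f"degenerate model: m_s ({self.m_s}) must exceed m_f ({self.m_f})"
            )


@dataclass(frozen=True)
class CompartmentVolumes:
    """Per-scan compartment volumes in mm^3.

    Invariant: ``stv_mm3 + fluid_mm3 + cartilage_mm3 == segmented_mm3``
    (each non-cartilage segmented voxel is partitioned exactly into a
    tissue fraction and a fluid fraction).
    """

    stv_mm3: float
    fluid_mm3: float
    cartilage_mm3: float
    segmented_mm3: float

    def __post_init__(self) -> None:
        for name in ("stv_mm3", "fluid_mm3", "cartilage_mm3", "segmented_mm3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        total = self.stv_mm3 + self.fluid_mm3 + self.cartilage_mm3
        if not np.isclose(total, self.segmented_mm3, rtol=1e-6, atol=1e-9):
            raise ValueError(
                "conservation violated: stv + fluid + cartilage = "
                f"{total} != segmented {self.segmented_mm3}"
            )


def _require_same_shape(*grids) -> None:
    shapes = {tuple(g.shape) for g in grids}
    if len(shapes) > 1:
        raise ShapeMismatchError(f"grids are not co-registered: shapes {shapes}")


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def voxel_fraction(intensity, model: IntensityModel):
    """Synovial-tissue fraction of a voxel under the linear mixture model.

    ``P = (I - m_f) / (m_s - m_f)`` truncated to [0, 1]; applies
    elementwise when ``intensity`` is an array.
    """
    intensity = np.asarray(intensity, dtype=float)
    frac = (intensity - model.m_f) / (model.m_s - model.m_f)
    out = np.clip(frac, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def cartilage_mask(
    precontrast: ImageVolume,
    segmentation: VoxelMask,
    threshold: float | None = None,
) -> tuple[VoxelMask, float]:
    """Identify cartilage inside the segmented space by precontrast thresholding.

    Cartilage is bright on the precontrast water-selective scan.  If
    ``threshold`` is None, Otsu's method on the precontrast intensities
    restricted to the segmented region picks it automatically.

    Returns the cartilage mask (a subset of ``segmentation``) and the
    threshold actually used.
    """
    _require_same_shape(precontrast.voxels, segmentation.mask)
    if segmentation.count() == 0:
        raise ValueError("segmentation mask is empty")
    region = precontrast.voxels[segmentation.mask]
    if threshold is None:
        if np.ptp(region) == 0:
            # uniform region: nothing to separate, no cartilage
            return VoxelMask(np.zeros(segmentation.shape, dtype=bool)), float(region[0])
        threshold = float(threshold_otsu(region))
    cart = segmentation.mask & (precontrast.voxels > threshold)
    return VoxelMask(cart), float(threshold)


def compute_volumes(
    postcontrast: ImageVolume,
    segmentation: VoxelMask,
    cartilage: VoxelMask,
    model: IntensityModel,
) -> CompartmentVolumes:
    """Partition the segmented space into synovial tissue, fluid and cartilage.

    Non-cartilage segmented voxels contribute ``P * v`` to STV and
    ``(1 - P) * v`` to fluid where ``v`` is the physical voxel volume;
    cartilage voxels are excluded whole.
    """
    _require_same_shape(postcontrast.voxels, segmentation.mask, cartilage.mask)
    if np.any(cartilage.mask & ~segmentation.mask):
        raise ValueError("cartilage mask is not a subset of the segmentation")
    v = postcontrast.voxel_volume_mm3
    soft = segmentation.mask & ~cartilage.mask
    frac = voxel_fraction(postcontrast.voxels[soft], model)
    stv = float(np.sum(frac) * v)
    fluid = float(np.sum(1.0 - frac) * v)
    cart = cartilage.count() * v
    seg = segmentation.count() * v
    # close the partition identity exactly against float summation error
    fluid = seg - cart - stv
    return CompartmentVolumes(stv_mm3=stv, fluid_mm3=fluid,
                              cartilage_mm3=cart, segmented_mm3=seg)


def estimate_intensity_means(
    postcontrast: ImageVolume,
    segmentation: VoxelMask,
    cartilage: VoxelMask | None = None,
    *,
    model: IntensityModel | None = None,
    min_separation_sd: float = 2.0,
    random_state: int = 0,
) -> IntensityModel:
    """Estimate (m_f, m_s) from the non-cartilage segmented intensities.

    Fits a two-component Gaussian mixture and assigns the lower mean to
    fluid.  A user-supplied ``model`` is passed through unchanged.  If the
    region is degenerate or the two fitted means are closer than
    ``min_separation_sd`` pooled standard deviations the estimation fails
    loudly rather than guessing.
    """
    if model is not None:
        return model
    from sklearn.mixture import GaussianMixture

    _require_same_shape(postcontrast.voxels, segmentation.mask)
    soft = segmentation.mask
    if cartilage is not None:
        _require_same_shape(segmentation.mask, cartilage.mask)
        soft = soft & ~cartilage.mask
    vals = postcontrast.voxels[soft].reshape(-1, 1)
    if vals.size < 10 or np.ptp(vals) == 0:
        raise EstimationError(
            "segmented region is degenerate (constant or too few intensities); "
            "supply m_f and m_s explicitly"
        )
    gm = GaussianMixture(n_components=2, n_init=3, random_state=random_state)
    gm.fit(vals)
    means = np.sort(gm.means_.ravel())
    pooled_sd = float(np.sqrt(gm.covariances_.ravel().mean()))
    if pooled_sd == 0 or (means[1] - means[0]) < min_separation_sd * pooled_sd:
        raise EstimationError(
            "intensity distribution appears unimodal; two-compartment means "
            "cannot be estimated — supply m_f and m_s explicitly"
        )
    return IntensityModel(m_f=float(means[0]), m_s=float(means[1]))


# ---------------------------------------------------------------------------
# NIfTI / CSV plumbing
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> ImageVolume:
    """Load a 3-D NIfTI volume; voxel spacing is taken from the header."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D data, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: header voxel spacing is missing or invalid: {zooms}")
    return ImageVolume(voxels=data, spacing=tuple(float(z) for z in zooms),
                       affine=np.asarray(img.affine))


def read_mask(path: str | Path) -> VoxelMask:
    """Load a NIfTI mask; any nonzero voxel is treated as True."""
    vol = read_volume(path)
    return VoxelMask(vol.voxels != 0)


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.voxels.astype(np.float32), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: VoxelMask, path: str | Path,
               spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
               affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8),
                          np.eye(4) if affine is None else affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def write_report(volumes: CompartmentVolumes, path: str | Path, *,
                 scan_id: str = "scan", model: IntensityModel | None = None,
                 threshold: float | None = None) -> None:
    """Write a one-row CSV quantification report."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["scan_id", "stv_mm3", "fluid_mm3", "cartilage_mm3",
                    "segmented_mm3", "m_f", "m_s", "threshold"])
        w.writerow([
            scan_id,
            repr(volumes.stv_mm3), repr(volumes.fluid_mm3),
            repr(volumes.cartilage_mm3), repr(volumes.segmented_mm3),
            "" if model is None else repr(model.m_f),
            "" if model is None else repr(model.m_s),
            "" if threshold is None else repr(threshold),
        ])


def quantify_scan(
    postcontrast: ImageVolume,
    precontrast: ImageVolume,
    segmentation: VoxelMask,
    *,
    model: IntensityModel | None = None,
    cartilage_threshold: float | None = None,
) -> tuple[CompartmentVolumes, IntensityModel, float]:
    """End-to-end quantification of one scan.

    Cartilage is removed by precontrast thresholding, the intensity model
    estimated (unless supplied), and compartment volumes computed.
    Returns (volumes, model used, cartilage threshold used).
    """
    _require_same_shape(postcontrast.voxels, precontrast.voxels, segmentation.mask)
    cart, thr = cartilage_mask(precontrast, segmentation, cartilage_threshold)
    mdl = estimate_intensity_means(postcontrast, segmentation, cart, model=model)
    vols = compute_volumes(postcontrast, segmentation, cart, mdl)
    return vols, mdl, thr
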