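"""Paired pre/postcontrast knee phantoms with exact compartment ground truth.

The phantom is deliberately schematic: an ellipsoidal synovial shell
wrapped around an ellipsoidal fluid pool, plus a box-shaped cartilage
plate, all inside one segmented space.  Exact ground-truth volumes are the
point — they let the partial-volume quantification be validated without
any real MRI.  Intensities per channel are compartment means plus iid
Gaussian noise; an optional mixing mode linearly blends tissue and fluid
intensities in voxels straddling their interface (by supersampled
sub-voxel occupancy) to exercise the partial-volume model.

Labels: 0 background, 1 synovial tissue, 2 fluid, 3 cartilage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging import ImageVolume, VoxelMask, write_volume, write_mask

LBL_BACKGROUND, LBL_TISSUE, LBL_FLUID, LBL_CARTILAGE = 0, 1, 2, 3


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and noise of one synthetic knee phantom."""

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # ellipsoid semi-axes in voxel units, centred in the grid; the default
    # split puts roughly equal volume in the synovial shell and the fluid
    # pool, mirroring the near-equal tissue/fluid volumes seen in vivo
    outer_semiaxes: tuple[float, float, float] = (18.0, 16.0, 15.0)
    inner_semiaxes: tuple[float, float, float] = (14.3, 12.7, 11.9)
    # cartilage plate: half-extent of a box inside the fluid pool
    plate_half: tuple[float, float, float] = (7.0, 6.0, 2.0)
    # postcontrast channel: synovium enhances, fluid stays dark
    post_tissue_mean: float = 300.0
    post_fluid_mean: float = 100.0
    post_cartilage_mean: float = 60.0
    post_background_mean: float = 20.0
    # precontrast channel: cartilage bright, soft compartments dark
    pre_cartilage_mean: float = 200.0
    pre_soft_mean: float = 50.0
    pre_background_mean: float = 20.0
    post_noise_sd: float = 0.0
    pre_noise_sd: float = 0.0
    partial_volume_mixing: bool = False
    supersample: int = 3
    seed: int = 0


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth compartment volumes (mm^3) and the voxel label grid."""

    stv_mm3: float
    fluid_mm3: float
    cartilage_mm3: float
    segmented_mm3: float
    labels: np.ndarray = field(repr=False)
    tissue_fraction: np.ndarray | None = field(default=None, repr=False)


def _ellipsoid_inside(coords, center, semiaxes):
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _box_inside(coords, center, half):
    x, y, z = coords
    cx, cy, cz = center
    hx, hy, hz = half
    return (np.abs(x - cx) <= hx) & (np.abs(y - cy) <= hy) & (np.abs(z - cz) <= hz)


def _labels_at(coords, spec: PhantomSpec, center):
    """Compartment label for arbitrary (possibly sub-voxel) coordinates."""
    outer = _ellipsoid_inside(coords, center, spec.outer_semiaxes)
    inner = _ellipsoid_inside(coords, center, spec.inner_semiaxes)
    plate = _box_inside(coords, center, spec.plate_half) & inner
    lbl = np.zeros(outer.shape, dtype=np.uint8)
    lbl[outer & ~inner] = LBL_TISSUE
    lbl[inner & ~plate] = LBL_FLUID
    lbl[plate] = LBL_CARTILAGE
    return lbl


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[ImageVolume, ImageVolume, VoxelMask, PhantomTruth]:
    """Build (postcontrast, precontrast, segmentation, truth) for one phantom.

    Deterministic under a fixed ``spec.seed``.  In mixing mode, voxels on
    the tissue–fluid interface get intensity ``f*m_tissue + (1-f)*m_fluid``
    where ``f`` is the tissue share of the voxel's sub-voxel occupancy, and
    the ground-truth STV is the corresponding occupancy sum.
    """
    shape = spec.shape
    center = tuple((s - 1) / 2.0 for s in shape)
    for ax, (semi, n) in enumerate(zip(spec.outer_semiaxes, shape)):
        if semi >= (n - 1) / 2.0:
            raise ValueError(
                f"outer semi-axis {semi} along axis {ax} does not fit grid of size {n}"
            )
    idx = np.indices(shape, dtype=float)
    labels = _labels_at(idx, spec, center)
    seg = labels != LBL_BACKGROUND
    vv = float(np.prod(spec.spacing))

    counts = np.bincount(labels.ravel(), minlength=4)
    cartilage_mm3 = counts[LBL_CARTILAGE] * vv
    segmented_mm3 = int(seg.sum()) * vv

    tissue_frac = None
    if spec.partial_volume_mixing:
        # supersample voxels on the tissue/fluid interface to get occupancies
        s = spec.supersample
        offsets = (np.arange(s) + 0.5) / s - 0.5
        soft = seg & (labels != LBL_CARTILAGE)
        boundary = soft & _has_neighbour_pair(labels)
        bx, by, bz = np.nonzero(boundary)
        f = labels[boundary].astype(float)
        f = np.where(f == LBL_TISSUE, 1.0, 0.0)
        if bx.size:
            tissue_hits = np.zeros(bx.size)
            fluid_hits = np.zeros(bx.size)
            for ox in offsets:
                for oy in offsets:
                    for oz in offsets:
                        sub = (bx + ox, by + oy, bz + oz)
                        l = _labels_at(sub, spec, center)
                        tissue_hits += l == LBL_TISSUE
                        fluid_hits += l == LBL_FLUID
            # mask voxels are counted whole: renormalise tissue vs fluid
            denom = tissue_hits + fluid_hits
            f = np.where(denom > 0, tissue_hits / np.maximum(denom, 1), f)
        tissue_frac = np.zeros(shape)
        tissue_frac[labels == LBL_TISSUE] = 1.0
        tissue_frac[boundary] = f
        tissue_frac[~soft] = 0.0
        stv_mm3 = float(tissue_frac[soft].sum() * vv)
    else:
        stv_mm3 = counts[LBL_TISSUE] * vv
    fluid_mm3 = segmented_mm3 - cartilage_mm3 - stv_mm3

    rng = np.random.default_rng(spec.seed)
    post = np.full(shape, spec.post_background_mean)
    pre = np.full(shape, spec.pre_background_mean)
    if spec.partial_volume_mixing:
        soft = seg & (labels != LBL_CARTILAGE)
        post[soft] = (spec.post_tissue_mean * tissue_frac[soft]
                      + spec.post_fluid_mean * (1.0 - tissue_frac[soft]))
    else:
        post[labels == LBL_TISSUE] = spec.post_tissue_mean
        post[labels == LBL_FLUID] = spec.post_fluid_mean
    post[labels == LBL_CARTILAGE] = spec.post_cartilage_mean
    pre[seg] = spec.pre_soft_mean
    pre[labels == LBL_CARTILAGE] = spec.pre_cartilage_mean
    if spec.post_noise_sd > 0:
        post = post + rng.normal(0.0, spec.post_noise_sd, shape)
    if spec.pre_noise_sd > 0:
        pre = pre + rng.normal(0.0, spec.pre_noise_sd, shape)

    truth = PhantomTruth(stv_mm3=stv_mm3, fluid_mm3=fluid_mm3,
                         cartilage_mm3=cartilage_mm3, segmented_mm3=segmented_mm3,
                         labels=labels, tissue_fraction=tissue_frac)
    mk = lambda a: ImageVolume(voxels=a, spacing=spec.spacing)
    return mk(post), mk(pre), VoxelMask(seg), truth


def _has_neighbour_pair(labels: np.ndarray) -> np.ndarray:
    """Voxels with a 6-neighbour of the other soft compartment."""
    tissue = labels == LBL_TISSUE
    fluid = labels == LBL_FLUID
    st = ndimage.generate_binary_structure(3, 1)
    near_fluid = ndimage.binary_dilation(fluid, st)
    near_tissue = ndimage.binary_dilation(tissue, st)
    return (tissue & near_fluid) | (fluid & near_tissue)


def perturb_segmentation(mask: VoxelMask, boundary_flip_rate: float,
                         seed: int = 0) -> VoxelMask:
    """Flip boundary voxels at the given rate, emulating re-segmentation.

    The boundary is the one-voxel inner rim plus the one-voxel outer rim of
    the mask (6-connectivity); interior and far-field voxels never change,
    which mimics intra-observer variability concentrated at the contour.
    """
    if not 0.0 <= boundary_flip_rate <= 1.0:
        raise ValueError("boundary_flip_rate must be in [0, 1]")
    m = mask.mask
    st = ndimage.generate_binary_structure(3, 1)
    inner = m & ~ndimage.binary_erosion(m, st)
    outer = ndimage.binary_dilation(m, st) & ~m
    boundary = inner | outer
    rng = np.random.default_rng(seed)
    flip = boundary & (rng.random(m.shape) < boundary_flip_rate)
    return VoxelMask(np.where(flip, ~m, m))


def write_phantom(out_dir: str | Path, spec: PhantomSpec) -> None:
    """Generate a phantom and write NIfTI channels plus a JSON truth file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    post, pre, seg, truth = generate_phantom(spec)
    write_volume(post, out / "postcontrast.nii.gz")
    write_volume(pre, out / "precontrast.nii.gz")
    write_mask(seg, out / "segmentation.nii.gz", spacing=spec.spacing)
    payload = {
        "spec": asdict(spec),
        "truth": {
            "stv_mm3": truth.stv_mm3,
            "fluid_mm3": truth.fluid_mm3,
            "cartilage_mm3": truth.cartilage_mm3,
            "segmented_mm3": truth.segmented_mm3,
        },
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=2))
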