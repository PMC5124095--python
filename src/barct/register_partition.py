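"""Rigid pre/post alignment and the voxel-level functional-group partition.

The pre-deployment scan (59.51 µm pitch) and post-deployment scan
(64.23 µm pitch) of a block sit on different grids in different poses.
This module aligns the post scan to the pre-scan frame (rigid transform,
trilinear resampling) and classifies every voxel of the pre-scan grid by
set algebra over four binary masks:

* ``pre_mask`` / ``post_mask`` — carbonate voxels of each scan;
* ``pre_hull`` / ``post_hull`` — the block *including* its internal void
  space, built by morphological closing (sealing tunnel apertures) and
  flood-filling cavities not connected to the outside.

The partition is then:

* accretion          = ``post_mask ∖ pre_hull``       (new material on the surface)
* grazed             = ``pre_hull ∖ post_hull``       (external volume lost)
* macroboring_void   = ``(post_hull ∖ post_mask) ∩ pre_hull``  (internal voids)
* original_remaining = ``post_mask ∩ pre_hull``
* background         = everything else

which makes ``|pre_hull| = remaining + macroboring + grazed`` an exact
identity, asserted on every run.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume_io import Volume3D

__all__ = [
    "RigidTransform",
    "LabelVolume",
    "LABEL_CODES",
    "register_rigid",
    "resample_to",
    "threshold_carbonate",
    "solid_hull",
    "partition_voxels",
]

LABEL_CODES = {
    "background": 0,
    "original_remaining": 1,
    "accretion": 2,
    "macroboring_void": 3,
    "grazed": 4,
}

#: Default closing radius used to seal borer-tunnel apertures when
#: defining the solid hull. 400 µm covers typical annelid apertures while
#: keeping the bridging limit (2r) below the width of realistic grazing
#: scars, which must stay open to the exterior.
DEFAULT_CLOSING_RADIUS_UM = 400.0


@dataclass
class RigidTransform:
    """A rigid (Euler) map from fixed-frame physical points to the moving frame.

    Applying it with :func:`resample_to` pulls the moving volume onto the
    fixed grid. Translation is stored in µm; rotation as XYZ Euler angles
    in degrees about ``center_um``.
    """

    translation_um: tuple[float, float, float]
    rotation_deg: tuple[float, float, float]
    center_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    fit_metric: float = float("nan")

    def to_sitk(self) -> sitk.Euler3DTransform:
        t = sitk.Euler3DTransform()
        t.SetCenter([float(c) for c in self.center_um])
        t.SetRotation(*[float(np.deg2rad(a)) for a in self.rotation_deg])
        t.SetTranslation([float(v) for v in self.translation_um])
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Euler3DTransform, fit_metric: float = float("nan")) -> "RigidTransform":
        ang = np.rad2deg([t.GetAngleX(), t.GetAngleY(), t.GetAngleZ()])
        return cls(
            translation_um=tuple(float(v) for v in t.GetTranslation()),
            rotation_deg=tuple(float(a) for a in ang),
            center_um=tuple(float(c) for c in t.GetCenter()),
            fit_metric=fit_metric,
        )

    def inverse(self) -> "RigidTransform":
        inv = sitk.Euler3DTransform(self.to_sitk().GetInverse())
        return RigidTransform.from_sitk(inv, self.fit_metric)

    def apply_to_points(self, pts_um: np.ndarray) -> np.ndarray:
        t = self.to_sitk()
        return np.array([t.TransformPoint(tuple(float(x) for x in p)) for p in np.atleast_2d(pts_um)])


@dataclass
class LabelVolume:
    """Per-voxel classification of the pre-scan grid (uint8 codes)."""

    labels: np.ndarray
    pitch_um: float
    legend: dict[str, int] = field(default_factory=lambda: dict(LABEL_CODES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.pitch_um <= 0:
            raise ValueError("pitch must be positive")

    @property
    def voxel_volume_cm3(self) -> float:
        return float((self.pitch_um * 1e-4) ** 3)

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.legend[name]

    def counts(self) -> dict[str, int]:
        return {name: int(np.count_nonzero(self.labels == code)) for name, code in self.legend.items()}

    def volume_cm3(self, name: str) -> float:
        return self.counts()[name] * self.voxel_volume_cm3

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.labels.T))
        img.SetSpacing((self.pitch_um,) * 3)
        sitk.WriteImage(img, str(path))
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(self.legend, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "LabelVolume":
        path = Path(path)
        img = sitk.ReadImage(str(path))
        legend = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(sitk.GetArrayFromImage(img).T, float(img.GetSpacing()[0]), legend)


# ---------------------------------------------------------------------------
# thresholding

def threshold_carbonate(
    vol: Volume3D, method: str = "otsu", value: float | None = None
) -> np.ndarray:
    """Binary mask of carbonate voxels.

    ``otsu`` picks the threshold maximizing between-class variance; if the
    histogram is effectively unimodal (between-class variance explains
    < 75% of the total — the value a lone Gaussian cannot reach only when
    two real modes exist) a warning is raised and the explicit ``value``
    is used instead (empty mask if none was given).

    ``fraction`` places the threshold at ``value`` of the way from the
    background mode to the carbonate mode (class medians of the Otsu
    split). A midpoint threshold systematically marks partial-volume
    voxels in concave corners as solid, biasing the grazing signal; a
    slightly higher cut (default 0.6) trims them while staying well
    clear of tunnel walls.
    """
    vals = vol.values
    if method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding requires a value")
        return vals > value
    if method == "fraction":
        frac = 0.6 if value is None else float(value)
        if not (0.0 < frac < 1.0):
            raise ValueError("fraction threshold must lie in (0, 1)")
        split = threshold_carbonate(vol, "otsu")
        if not split.any() or split.all():
            return split
        lo_mode = float(np.median(vals[~split]))
        hi_mode = float(np.median(vals[split]))
        return vals > lo_mode + frac * (hi_mode - lo_mode)
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    if np.ptp(vals) == 0:
        warnings.warn("constant volume: no carbonate mode found; returning empty mask")
        return np.zeros(vals.shape, dtype=bool)
    t = float(threshold_otsu(vals))
    hi = vals > t
    frac = hi.mean()
    total_var = vals.var()
    if 0 < frac < 1 and total_var > 0:
        mu_hi, mu_lo = vals[hi].mean(), vals[~hi].mean()
        between = frac * (1 - frac) * (mu_hi - mu_lo) ** 2
        separation = between / total_var
    else:
        separation = 0.0
    if separation < 0.75:
        warnings.warn(
            f"histogram looks unimodal (between-class variance fraction {separation:.2f}); "
            "falling back to fixed threshold"
        )
        if value is not None:
            return vals > value
        return np.zeros(vals.shape, dtype=bool)
    return hi


# ---------------------------------------------------------------------------
# hulls

def solid_hull(mask: np.ndarray, closing_radius_um: float, pitch_um: float) -> np.ndarray:
    """The block plus its internal voids.

    Morphological closing with a ball of the given physical radius seals
    tunnel apertures, then cavities not connected to the grid boundary
    are flood-filled. Closing is implemented with two Euclidean distance
    transforms (exact for a ball, and much faster than an explicit
    structuring element at these radii).

    A ball closing also deposits fillets in the concave corners of wide
    surface depressions (grazing scars), which are *not* internal void
    space. Closing additions are therefore filtered by geodesic depth:
    a filled tunnel reaches deeper than twice the closing radius from
    the open exterior (measured through non-solid space), while corner
    fillets are confined to a shallow shell. Only deep-reaching
    components are kept, so tunnels shorter than ~2× the closing radius
    are treated as surface relief rather than borings.
    """
    if closing_radius_um < 0:
        raise ValueError("closing radius must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    r = closing_radius_um / pitch_um
    base = ndimage.binary_fill_holes(mask)
    if r <= 0 or not mask.any():
        return base
    # pad so the dilated band never touches the array edge (erosion
    # would otherwise leave a spurious rim with no background beyond it)
    p = int(np.ceil(r)) + 1
    work = np.pad(mask, p)
    dilated = ndimage.distance_transform_edt(~work) <= r
    closed = ndimage.distance_transform_edt(dilated) > r
    closed = closed[p:-p, p:-p, p:-p] | mask

    additions = closed & ~base
    if not additions.any():
        return base
    st = ndimage.generate_binary_structure(3, 1)
    # breadth-first front from the open exterior through non-solid space;
    # anything it reaches within ~2r of the closed surface is shallow relief
    depth_limit = int(np.ceil(2 * r))
    shallow = ndimage.binary_dilation(
        ~closed, st, iterations=depth_limit, mask=~base
    )
    deep = additions & ~shallow
    if not deep.any():
        return base
    # grow back from the deep cores through the additions so tunnel
    # throats are retained, without re-absorbing surface fillets that a
    # tunnel mouth may touch (e.g. a boring that enters a grazing scar)
    keep = ndimage.binary_dilation(deep, st, iterations=depth_limit, mask=additions)
    return ndimage.binary_fill_holes(base | keep)


# ---------------------------------------------------------------------------
# registration / resampling

def _registration_image(vol: Volume3D, smooth_sigma_vox: float = 1.0) -> sitk.Image:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mask = threshold_carbonate(vol)
    if not mask.any():
        raise ValueError("no dominant solid object found to register")
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.T.astype(np.float32)))
    img.SetSpacing((vol.pitch_um,) * 3)
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    return sitk.SmoothingRecursiveGaussian(img, smooth_sigma_vox * vol.pitch_um)


def register_rigid(
    moving: Volume3D,
    fixed: Volume3D,
    max_iter: int = 200,
    min_correlation: float = 0.5,
    fixed_mask: np.ndarray | None = None,
    init: RigidTransform | None = None,
) -> RigidTransform:
    """Recover the rigid transform aligning ``moving`` onto ``fixed``.

    Normalized cross-correlation between lightly blurred attenuation
    volumes (the skeleton's internal density structure anchors the fit,
    so surface changes between scans bias it far less than a mask-overlap
    metric would), optimized over an Euler transform with a
    multi-resolution pyramid and two initializations (geometric and
    moments-centred); deterministic — full metric sampling, no random
    seeds. Correlation is invariant to the affine attenuation–density
    relation, so differing scan sessions need no intensity calibration.

    ``fixed_mask`` restricts the metric to a region of the fixed grid
    (used to exclude voxels that changed between scans when refining);
    ``init`` warm-starts from a previous estimate instead of the
    centred initializations.
    """
    f_img = _registration_image(fixed)
    m_img = _registration_image(moving)
    mask_img = None
    if fixed_mask is not None:
        mask_img = sitk.GetImageFromArray(
            np.ascontiguousarray(np.asarray(fixed_mask, np.uint8).T)
        )
        mask_img.CopyInformation(f_img)

    def _run(init_mode) -> tuple[float, sitk.Euler3DTransform] | None:
        if isinstance(init_mode, sitk.Euler3DTransform):
            start = init_mode
        else:
            start = sitk.Euler3DTransform(
                sitk.CenteredTransformInitializer(
                    f_img, m_img, sitk.Euler3DTransform(), init_mode
                )
            )
        reg = sitk.ImageRegistrationMethod()
        if mask_img is not None:
            reg.SetMetricFixedMask(mask_img)
        reg.SetMetricAsCorrelation()
        reg.SetMetricSamplingStrategy(reg.NONE)
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=1.0,
            minStep=1e-3,
            numberOfIterations=max_iter,
            relaxationFactor=0.6,
            gradientMagnitudeTolerance=1e-7,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        if isinstance(init_mode, sitk.Euler3DTransform):
            reg.SetShrinkFactorsPerLevel([4, 2])
            reg.SetSmoothingSigmasPerLevel([1.5, 0.5])
        else:
            reg.SetShrinkFactorsPerLevel([8, 4, 2])
            reg.SetSmoothingSigmasPerLevel([3.0, 1.5, 0.5])
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        reg.SetInitialTransform(sitk.Euler3DTransform(start), inPlace=False)
        try:
            result = reg.Execute(f_img, m_img)
        except RuntimeError:
            return None
        comp = sitk.CompositeTransform(result)
        euler = comp.GetNthTransform(comp.GetNumberOfTransforms() - 1).Downcast()
        return reg.GetMetricValue(), sitk.Euler3DTransform(euler)

    if init is not None:
        best = _run(init.to_sitk())
    else:
        # geometric initialization almost always suffices for near-cuboid
        # blocks; fall back to a moments start only when correlation is poor
        best = _run(sitk.CenteredTransformInitializerFilter.GEOMETRY)
        if best is None or -best[0] < min_correlation:
            alt = _run(sitk.CenteredTransformInitializerFilter.MOMENTS)
            if alt is not None and (best is None or alt[0] < best[0]):
                best = alt
    if best is None:
        raise RuntimeError("rigid registration failed from every initialization")
    metric, tfm = best
    if -metric < min_correlation:
        raise RuntimeError(
            f"registration found no overlap (mask correlation {-metric:.3f} < "
            f"{min_correlation}); are these scans of the same object?"
        )
    return RigidTransform.from_sitk(tfm, fit_metric=float(-metric))


def resample_to(
    vol: Volume3D,
    transform: RigidTransform | None,
    target: Volume3D,
    background: float | None = None,
) -> Volume3D:
    """Pull ``vol`` onto ``target``'s grid/pitch through a rigid transform.

    Trilinear interpolation; voxels mapping outside ``vol`` take the
    ``background`` value (default: the minimum of ``vol``).
    """
    bg = float(np.min(vol.values)) if background is None else float(background)
    tfm = transform.to_sitk() if transform is not None else sitk.Euler3DTransform()
    out = sitk.Resample(vol.to_sitk(), target.to_sitk(), tfm, sitk.sitkLinear, bg)
    return Volume3D(
        sitk.GetArrayFromImage(out).T.copy(),
        target.pitch_um,
        target.origin,
        {**vol.metadata, "resampled": True},
    )


def _remove_films(mask: np.ndarray, k: int) -> np.ndarray:
    """Drop sub-voxel interpolation films while keeping genuine features whole.

    An opening (erosion then dilation by ``k``) finds feature cores; the
    result is the raw mask restricted to a ``k+1`` neighbourhood of those
    cores. Films thinner than ``k+1`` voxels have no core and vanish;
    features with a core keep their full raw extent, including locally
    thin boundary voxels the plain opening would clip.
    """
    st = ndimage.generate_binary_structure(3, 1)
    core = ndimage.binary_erosion(mask, st, iterations=k)
    if not core.any():
        return np.zeros_like(mask)
    near_core = ndimage.binary_dilation(core, st, iterations=2 * k + 1)
    return mask & near_core


# ---------------------------------------------------------------------------
# partition

def partition_voxels(
    pre_mask: np.ndarray,
    post_mask: np.ndarray,
    pre_hull: np.ndarray,
    post_hull: np.ndarray,
    pitch_um: float = 1.0,
    min_feature_voxels: int = 0,
) -> LabelVolume:
    """Classify every voxel of the registered pre-scan grid.

    All four masks must live on the same grid. Raises if the pre mask is
    empty; asserts label disjointness/exhaustiveness and the hull
    conservation identity on every call.

    ``min_feature_voxels`` > 0 applies a morphological opening of that
    radius to the change labels (accretion, macroboring, grazed):
    interpolated sub-voxel films along block faces — partial-volume
    artefacts of resampling between scan pitches, not resolvable features
    — are removed, while features thicker than ``2·min_feature_voxels+1``
    survive. Voxels freed inside the pre hull return to
    ``original_remaining`` so the conservation identity still holds
    exactly.
    """
    pre_mask, post_mask = np.asarray(pre_mask, bool), np.asarray(post_mask, bool)
    pre_hull, post_hull = np.asarray(pre_hull, bool), np.asarray(post_hull, bool)
    if not pre_mask.any():
        raise ValueError("pre-scan mask is empty; nothing to partition")
    if not (pre_mask.shape == post_mask.shape == pre_hull.shape == post_hull.shape):
        raise ValueError("all masks must share the registered pre-scan grid")

    labels = np.zeros(pre_mask.shape, dtype=np.uint8)
    accretion = post_mask & ~pre_hull
    grazed = pre_hull & ~post_hull
    macro = post_hull & ~post_mask & pre_hull
    remaining = post_mask & pre_hull

    if min_feature_voxels > 0:
        accretion = _remove_films(accretion, min_feature_voxels)
        macro2 = _remove_films(macro, min_feature_voxels)
        grazed2 = _remove_films(grazed, min_feature_voxels)
        remaining = remaining | ((macro | grazed) & ~(macro2 | grazed2))
        macro, grazed = macro2, grazed2
    labels[remaining] = LABEL_CODES["original_remaining"]
    labels[accretion] = LABEL_CODES["accretion"]
    labels[macro] = LABEL_CODES["macroboring_void"]
    labels[grazed] = LABEL_CODES["grazed"]

    out = LabelVolume(labels, pitch_um)
    counts = out.counts()
    assert sum(counts.values()) == labels.size, "labels must be exhaustive"
    n_hull = int(pre_hull.sum())
    conserved = counts["original_remaining"] + counts["macroboring_void"] + counts["grazed"]
    assert conserved == n_hull, (
        f"hull conservation violated: {conserved} != |pre_hull| = {n_hull}"
    )
    return out
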