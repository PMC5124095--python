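"""Synthetic inputs with known ground truth.

Real deployments of bioerosion accretion replicates (BARs) — small blocks
of cleaned *Porites* skeleton bolted to the reef — leave no ground truth:
the true borehole volumes, grazed volumes, and accreted crusts are
unknown. This module therefore fabricates every input the pipeline
consumes with exact, voxel-counted truth:

* paired pre/post micro-CT attenuation volumes of a carbonate block with
  imposed surface accretion patches, internal macroborer tunnels, grazed
  (externally scraped) regions and a bulk density loss standing in for
  microboring — plus a rigid pre→post misalignment, a change of voxel
  pitch between scan sessions, and additive scanner noise;
* phantom scans of known-density aragonite standards for densitometry;
* closed-chamber incubation records (total alkalinity and O₂ before and
  after light/dark runs, with paired blank chambers);
* pH-response tables emulating field scatter around a linear predictor.

Defaults mirror the deployed blocks: 5 × 2 × 1 cm of skeletal carbonate
(bulk density 1.4 g cm⁻³, typical for massive *Porites*), pre-scan pitch
59.51 µm, post-scan pitch 64.23 µm. Ground-truth volumes are recorded on
the pre-scan grid before noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import SimpleITK as sitk

from .incubation_chem import SEAWATER_DENSITY_KG_L, IncubationRecord
from .volume_io import Volume3D

__all__ = [
    "AccretionPatch",
    "Borehole",
    "GrazedRegion",
    "BarSimSpec",
    "GroundTruth",
    "make_phantom_set",
    "make_bar_pair",
    "make_incubation_set",
    "make_ph_response_table",
]

_FACES = {"x-": (0, -1), "x+": (0, +1), "y-": (1, -1), "y+": (1, +1), "z-": (2, -1), "z+": (2, +1)}

# Session calibration used to map density to attenuation units (the
# generator's "scanner"): density = DEFAULT_CAL_SLOPE·attn + DEFAULT_CAL_INTERCEPT.
DEFAULT_CAL_SLOPE = 0.01
DEFAULT_CAL_INTERCEPT = 0.5


@dataclass(frozen=True)
class AccretionPatch:
    """A slab of new carbonate (CCA crust, tube worm, coral recruit) on a face."""

    face: str = "z+"
    center: tuple[float, float] = (0.5, 0.5)   # fractional position on the face
    size: tuple[float, float] = (0.3, 0.3)     # fractional extent of the face
    thickness_voxels: int = 4
    density_gcc: float = 1.6

    def __post_init__(self) -> None:
        if self.face not in _FACES:
            raise ValueError(f"unknown face {self.face!r}")
        if self.face == "z-":
            raise ValueError("accretion is restricted to exposed faces (base is epoxied)")
        if self.thickness_voxels <= 0 or self.density_gcc <= 0:
            raise ValueError("patch thickness and density must be positive")


@dataclass(frozen=True)
class Borehole:
    """A capsule-shaped macroborer tunnel (annelid-like) entering from a face."""

    face: str = "z+"
    entry: tuple[float, float] = (0.5, 0.5)    # fractional position on the face
    direction: tuple[float, float, float] | None = None  # default: inward normal
    radius_um: float = 200.0
    length_um: float = 3000.0

    def __post_init__(self) -> None:
        if self.face not in _FACES:
            raise ValueError(f"unknown face {self.face!r}")
        if self.radius_um <= 50.0:
            # tunnels ≤ 100 µm across are microboring by definition and are
            # modelled as bulk density loss, not resolved voids
            raise ValueError("macroborer tunnel radius must exceed 50 µm")
        if self.length_um <= 0:
            raise ValueError("tunnel length must be positive")


@dataclass(frozen=True)
class GrazedRegion:
    """External substrate removal (parrotfish/urchin scraping) on a face."""

    face: str = "z+"
    depth_voxels: int = 3
    footprint: tuple[float, float, float, float] = (0.0, 1.0, 0.0, 1.0)  # u0,u1,v0,v1

    def __post_init__(self) -> None:
        if self.face not in _FACES:
            raise ValueError(f"unknown face {self.face!r}")
        if self.depth_voxels <= 0:
            raise ValueError("grazing depth must be positive")
        u0, u1, v0, v1 = self.footprint
        if not (0 <= u0 < u1 <= 1 and 0 <= v0 < v1 <= 1):
            raise ValueError("footprint must be a non-empty fractional window")


@dataclass
class BarSimSpec:
    """Full description of one simulated BAR pair.

    ``rigid_offset`` is ``(translation_voxels, rotation_deg)``: the rigid
    motion (in post-grid voxels / degrees about the block centre) applied
    to the post scan before resampling to ``post_pitch_um``. Noise is
    additive Gaussian on attenuation, applied after resampling — it is a
    scanner property, not a property of the block.
    """

    block_dims_cm: tuple[float, float, float] = (5.0, 2.0, 1.0)
    pre_pitch_um: float = 59.51
    post_pitch_um: float = 64.23
    base_density_gcc: float = 1.4
    accretion_patches: list[AccretionPatch] = field(default_factory=list)
    boreholes: list[Borehole] = field(default_factory=list)
    grazed_regions: list[GrazedRegion] = field(default_factory=list)
    microboring_density_drop_frac: float = 0.0
    rigid_offset: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (0.0, 0.0, 0.0),
        (0.0, 0.0, 0.0),
    )
    noise_sd: float = 3.0
    texture_sd: float = 7.0          # attenuation units; intra-block density texture
    texture_sigma_voxels: float = 5.0
    seed: int = 0
    margin_voxels: int = 8
    background_attenuation: float = 20.0
    cal_slope: float = DEFAULT_CAL_SLOPE
    cal_intercept: float = DEFAULT_CAL_INTERCEPT

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.block_dims_cm):
            raise ValueError("block dimensions must be positive")
        if self.pre_pitch_um <= 0 or self.post_pitch_um <= 0:
            raise ValueError("voxel pitches must be positive")
        if not (0.0 <= self.microboring_density_drop_frac < 1.0):
            raise ValueError("density drop fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.margin_voxels < 2:
            raise ValueError("need a ≥2-voxel background margin around the block")

    # --- derived geometry (pre grid, voxel units) ---

    @property
    def block_voxels(self) -> tuple[int, int, int]:
        return tuple(
            int(round(d * 1e4 / self.pre_pitch_um)) for d in self.block_dims_cm
        )  # type: ignore[return-value]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        m = self.margin_voxels
        return tuple(n + 2 * m for n in self.block_voxels)  # type: ignore[return-value]

    def attenuation_of(self, density_gcc: float) -> float:
        return (density_gcc - self.cal_intercept) / self.cal_slope


@dataclass
class GroundTruth:
    """Exact voxel-counted truth recorded on the pre-scan grid before noise."""

    accretion_volume_cm3: float
    macroboring_volume_cm3: float
    grazing_volume_cm3: float
    microboring_mass_loss_g: float
    remaining_volume_cm3: float
    initial_surface_area_cm2: float
    accretion_voxels: int
    macroboring_voxels: int
    grazing_voxels: int
    remaining_voxels: int
    block_voxels: int
    translation_post_voxels: tuple[float, float, float]
    rotation_deg: tuple[float, float, float]
    rotation_center_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name in ("accretion", "macroboring", "grazing"):
            if getattr(self, f"{name}_volume_cm3") < 0:
                raise ValueError(f"{name} volume cannot be negative")


# ---------------------------------------------------------------------------
# phantoms

def make_phantom_set(
    densities_gcc: Sequence[float],
    slope: float = DEFAULT_CAL_SLOPE,
    intercept: float = DEFAULT_CAL_INTERCEPT,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int, int] = (24, 24, 24),
    pitch_um: float = 59.51,
) -> list[tuple[Volume3D, float]]:
    """Scans of aragonite density standards: (attenuation volume, known density).

    Mean attenuation of each phantom is ``(density − intercept) / slope``
    plus zero-mean Gaussian noise.
    """
    densities = [float(d) for d in densities_gcc]
    if len(densities) < 2:
        raise ValueError("need at least two phantom densities (calibration is underdetermined)")
    if any(d <= 0 for d in densities):
        raise ValueError("phantom densities must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for d in densities:
        attn = np.full(shape, (d - intercept) / slope, dtype=float)
        if noise_sd > 0:
            attn += rng.normal(0.0, noise_sd, size=shape)
        out.append((Volume3D(attn, pitch_um, metadata={"phantom_density_gcc": d}), d))
    return out


# ---------------------------------------------------------------------------
# BAR pair

def _face_window(
    n: tuple[int, int, int], face: str, center: tuple[float, float], size: tuple[float, float]
) -> tuple[int, tuple[int, int], tuple[int, int]]:
    """Integer (u, v) index window on a block face given fractional center/size."""
    axis, _ = _FACES[face]
    ua, va = [a for a in range(3) if a != axis]
    win = []
    for a, c, s in zip((ua, va), center, size):
        half = 0.5 * s * n[a]
        lo = int(round((c * n[a]) - half))
        hi = int(round((c * n[a]) + half))
        if lo < 0 or hi > n[a] or hi <= lo:
            raise ValueError(f"face window [{lo},{hi}) outside block axis of size {n[a]}")
        win.append((lo, hi))
    return axis, win[0], win[1]


def _capsule_mask(shape: tuple[int, int, int], p0: np.ndarray, p1: np.ndarray, r: float) -> np.ndarray:
    """Boolean mask of voxels within distance r (voxel units) of segment p0→p1."""
    lo = np.floor(np.minimum(p0, p1) - r - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + r + 1).astype(int)
    if np.any(lo < 0) or np.any(hi > np.asarray(shape)):
        raise ValueError("borehole extends outside the simulation grid")
    mask = np.zeros(shape, dtype=bool)
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    pts = np.stack([g.astype(float) for g in grids], axis=-1)
    d = p1 - p0
    L2 = float(d @ d)
    t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0) if L2 > 0 else np.zeros(pts.shape[:-1])
    nearest = p0 + t[..., None] * d
    dist2 = np.sum((pts - nearest) ** 2, axis=-1)
    mask[tuple(slice(a, b) for a, b in zip(lo, hi))] = dist2 <= r * r
    return mask


def make_bar_pair(spec: BarSimSpec) -> tuple[Volume3D, Volume3D, GroundTruth]:
    """Simulate one deployed BAR: (pre scan, post scan, ground truth).

    The pre scan is the clean block. The post scan has accretion added,
    tunnels carved, grazed regions removed and the bulk density drop
    applied to remaining original carbonate, then the rigid offset,
    resampling to the post pitch, and scanner noise.
    """
    n = spec.block_voxels
    m = spec.margin_voxels
    shape = spec.grid_shape
    rng = np.random.default_rng(spec.seed)

    block = np.zeros(shape, dtype=bool)
    block[m : m + n[0], m : m + n[1], m : m + n[2]] = True

    # grazed: slabs removed inward from a face
    grazed = np.zeros(shape, dtype=bool)
    for g in spec.grazed_regions:
        axis, sign = _FACES[g.face]
        ua, uw, vw = _face_window(n, g.face, _fw_center(g.footprint), _fw_size(g.footprint))
        if g.depth_voxels > n[axis]:
            raise ValueError("grazed region deeper than the block")
        sl = [slice(m + uw[0], m + uw[1]), slice(m + vw[0], m + vw[1])]
        depth = (
            slice(m + n[axis] - g.depth_voxels, m + n[axis])
            if sign > 0
            else slice(m, m + g.depth_voxels)
        )
        sl.insert(axis, depth)
        grazed[tuple(sl)] = True
    grazed &= block

    # boreholes: capsules entering from a face, carved from what grazing left
    bored = np.zeros(shape, dtype=bool)
    for b in spec.boreholes:
        axis, sign = _FACES[b.face]
        ua, va = [a for a in range(3) if a != axis]
        p0 = np.empty(3)
        p0[axis] = (m + n[axis] - 0.5) if sign > 0 else (m - 0.5)
        p0[ua] = m + b.entry[0] * n[ua]
        p0[va] = m + b.entry[1] * n[va]
        direction = np.asarray(
            b.direction if b.direction is not None else _inward_normal(axis, sign), dtype=float
        )
        nrm = np.linalg.norm(direction)
        if nrm == 0:
            raise ValueError("borehole direction cannot be the zero vector")
        direction /= nrm
        p1 = p0 + direction * (b.length_um / spec.pre_pitch_um)
        bored |= _capsule_mask(shape, p0, p1, b.radius_um / spec.pre_pitch_um)
    bored &= block
    bored &= ~grazed

    remaining = block & ~grazed & ~bored

    # accretion: slabs sitting on (outside) a face
    accretion = np.zeros(shape, dtype=bool)
    accretion_density = np.zeros(shape, dtype=float)
    for p in spec.accretion_patches:
        axis, sign = _FACES[p.face]
        ua, uw, vw = _face_window(n, p.face, p.center, p.size)
        if sign > 0:
            depth = slice(m + n[axis], m + n[axis] + p.thickness_voxels)
            if depth.stop > shape[axis]:
                raise ValueError("accretion patch extends outside the simulation grid")
        else:
            depth = slice(m - p.thickness_voxels, m)
            if depth.start < 0:
                raise ValueError("accretion patch extends outside the simulation grid")
        sl = [slice(m + uw[0], m + uw[1]), slice(m + vw[0], m + vw[1])]
        sl.insert(axis, depth)
        accretion[tuple(sl)] = True
        accretion_density[tuple(sl)] = p.density_gcc
    if np.any(accretion & block):
        raise ValueError("accretion patches must be disjoint from the original block")

    bg = spec.background_attenuation
    atten_block = spec.attenuation_of(spec.base_density_gcc)
    if atten_block <= bg:
        raise ValueError("carbonate attenuation must exceed background for thresholding")

    # intra-block density texture: coral skeleton is porous, and the
    # resulting attenuation structure is what anchors rigid registration
    # in real scans; the field is laid down on the pre grid so it moves
    # rigidly with the block
    if spec.texture_sd > 0:
        from scipy.ndimage import gaussian_filter

        raw = rng.standard_normal(shape)
        tex = gaussian_filter(raw, spec.texture_sigma_voxels)
        # zero mean and stated spread over the block itself, so the block's
        # mean density is exactly base_density_gcc
        tex -= tex[block].mean()
        tex *= spec.texture_sd / tex[block].std()
        # the deployed cores are cleaned, unbored solid skeleton: bound the
        # excursions so density variation never mimics resolvable porosity
        np.clip(tex, -2.5 * spec.texture_sd, 2.5 * spec.texture_sd, out=tex)
    else:
        tex = np.zeros(shape)

    atten_pre_block = atten_block + tex  # per-voxel pre attenuation of carbonate
    density_pre = spec.cal_slope * atten_pre_block + spec.cal_intercept

    pre = np.full(shape, bg, dtype=float)
    pre[block] = atten_pre_block[block]

    drop = spec.microboring_density_drop_frac
    modified = np.full(shape, bg, dtype=float)
    modified[remaining] = (density_pre[remaining] * (1.0 - drop) - spec.cal_intercept) / spec.cal_slope
    modified[accretion] = (accretion_density[accretion] - spec.cal_intercept) / spec.cal_slope

    vv = (spec.pre_pitch_um * 1e-4) ** 3
    pitch_cm = spec.pre_pitch_um * 1e-4
    sa = (n[0] * n[1] + 2 * n[0] * n[2] + 2 * n[1] * n[2]) * pitch_cm**2  # base (z-) excluded
    truth = GroundTruth(
        accretion_volume_cm3=int(accretion.sum()) * vv,
        macroboring_volume_cm3=int(bored.sum()) * vv,
        grazing_volume_cm3=int(grazed.sum()) * vv,
        microboring_mass_loss_g=float(drop * density_pre[remaining].sum() * vv),
        remaining_volume_cm3=int(remaining.sum()) * vv,
        initial_surface_area_cm2=sa,
        accretion_voxels=int(accretion.sum()),
        macroboring_voxels=int(bored.sum()),
        grazing_voxels=int(grazed.sum()),
        remaining_voxels=int(remaining.sum()),
        block_voxels=int(block.sum()),
        translation_post_voxels=tuple(float(t) for t in spec.rigid_offset[0]),
        rotation_deg=tuple(float(r) for r in spec.rigid_offset[1]),
        rotation_center_um=tuple((mm + nn / 2.0) * spec.pre_pitch_um for mm, nn in zip((m,) * 3, n)),
    )

    # rigid offset + resample to the post pitch (trilinear), then noise
    mod_vol = Volume3D(modified, spec.pre_pitch_um)
    translation_um = np.asarray(spec.rigid_offset[0], dtype=float) * spec.post_pitch_um
    rot_rad = np.deg2rad(np.asarray(spec.rigid_offset[1], dtype=float))
    tfm = sitk.Euler3DTransform()
    tfm.SetCenter(truth.rotation_center_um)
    tfm.SetRotation(*[float(a) for a in rot_rad])
    tfm.SetTranslation([float(t) for t in translation_um])

    # pad the post field of view so the offset block (and anything grown
    # on it) is never clipped by the scanner frame
    max_t = float(np.max(np.abs(spec.rigid_offset[0])))
    max_rot_rad = float(np.max(np.abs(rot_rad)))
    pad = int(np.ceil(max_t + max_rot_rad * max(shape) / 2.0)) + 2
    post_shape = tuple(
        int(np.ceil(s * spec.pre_pitch_um / spec.post_pitch_um)) + 2 * pad for s in shape
    )
    ref = sitk.Image(post_shape, sitk.sitkFloat64)
    ref.SetSpacing((spec.post_pitch_um,) * 3)
    ref.SetOrigin((-pad * spec.post_pitch_um,) * 3)
    post_img = sitk.Resample(mod_vol.to_sitk(), ref, tfm, sitk.sitkLinear, float(bg))
    post_vals = sitk.GetArrayFromImage(post_img).T.copy()

    if spec.noise_sd > 0:
        pre = pre + rng.normal(0.0, spec.noise_sd, size=pre.shape)
        post_vals = post_vals + rng.normal(0.0, spec.noise_sd, size=post_vals.shape)

    pre_vol = Volume3D(pre, spec.pre_pitch_um, metadata={"scan": "pre"})
    post_vol = Volume3D(
        post_vals, spec.post_pitch_um, origin=tuple(ref.GetOrigin()), metadata={"scan": "post"}
    )
    return pre_vol, post_vol, truth


def _fw_center(fp: tuple[float, float, float, float]) -> tuple[float, float]:
    return ((fp[0] + fp[1]) / 2.0, (fp[2] + fp[3]) / 2.0)


def _fw_size(fp: tuple[float, float, float, float]) -> tuple[float, float]:
    return (fp[1] - fp[0], fp[3] - fp[2])


def _inward_normal(axis: int, sign: int) -> tuple[float, float, float]:
    v = [0.0, 0.0, 0.0]
    v[axis] = -float(sign)
    return tuple(v)  # type: ignore[return-value]


def make_batch_specs(
    n: int = 10,
    seed: int = 0,
    block_dims_cm: tuple[float, float, float] = (1.2, 0.6, 0.36),
    pre_pitch_um: float = 59.51,
    post_pitch_um: float = 64.23,
    noise_sd: float = 3.0,
) -> list[BarSimSpec]:
    """A batch of varied block specifications for a simulated deployment.

    Each block carries one accretion patch, one grazed scar and one to
    three macroborer tunnels on distinct faces, a bulk density drop of
    3–12%, and a rigid pre→post offset of up to 5 voxels translation and
    ±1.5° rotation per axis — the misalignment scale of repositioning a
    small block in a scanner. Feature sizes stay at or above three voxels
    so every imposed signal is resolvable at the scan pitches. The block
    is simulated at reduced physical size (default ~1.2 × 0.6 × 0.36 cm)
    at the true scan pitches, keeping voxel-scale feature geometry
    realistic at tractable grid sizes.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        patch_face = str(rng.choice(["z+", "y+", "y-"]))
        graze_face = str(rng.choice([f for f in ("z+", "x+", "x-") if f != patch_face]))
        n_holes = int(rng.integers(1, 4))
        holes = [
            Borehole(
                face=str(rng.choice(["x+", "x-", "y+", "y-"])),
                entry=(float(rng.uniform(0.3, 0.7)), float(rng.uniform(0.3, 0.7))),
                radius_um=float(rng.uniform(180.0, 280.0)),
                length_um=float(rng.uniform(2500.0, 4000.0)),
            )
            for _ in range(n_holes)
        ]
        u0, v0 = rng.uniform(0.05, 0.35, size=2)
        du, dv = rng.uniform(0.3, 0.55, size=2)
        specs.append(
            BarSimSpec(
                block_dims_cm=block_dims_cm,
                pre_pitch_um=pre_pitch_um,
                post_pitch_um=post_pitch_um,
                accretion_patches=[
                    AccretionPatch(
                        face=patch_face,
                        center=(float(rng.uniform(0.3, 0.7)), float(rng.uniform(0.3, 0.7))),
                        size=(float(rng.uniform(0.2, 0.35)), float(rng.uniform(0.2, 0.35))),
                        thickness_voxels=int(rng.integers(3, 7)),
                        density_gcc=float(rng.uniform(1.5, 1.8)),
                    )
                ],
                boreholes=holes,
                grazed_regions=[
                    GrazedRegion(
                        face=graze_face,
                        depth_voxels=int(rng.integers(3, 6)),
                        footprint=(
                            float(u0),
                            float(min(u0 + du, 0.95)),
                            float(v0),
                            float(min(v0 + dv, 0.95)),
                        ),
                    )
                ],
                microboring_density_drop_frac=float(rng.uniform(0.03, 0.12)),
                rigid_offset=(
                    tuple(float(t) for t in rng.uniform(-5.0, 5.0, size=3)),
                    tuple(float(a) for a in rng.uniform(-1.5, 1.5, size=3)),
                ),
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# incubations

def make_incubation_set(
    true_light_rate: float,
    true_dark_rate: float,
    true_photo: float,
    true_resp: float,
    chamber_volume_l: float = 0.640,
    surface_area_cm2: float = 30.0,
    durations_min: tuple[float, float] = (80.0, 140.0),
    blank_drift: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    treatment_ph: float = 7.8,
    at_initial: float = 2300.0,
    o2_initial: float = 6.5,
    o2_blank_drift: float = 0.0,
    o2_noise_sd: float | None = None,
    n_blanks: int = 2,
    seawater_density_kg_l: float = SEAWATER_DENSITY_KG_L,
    chamber_prefix: str = "ch",
) -> list[IncubationRecord]:
    """Closed-chamber incubation records that invert to the given true rates.

    ``true_light_rate``/``true_dark_rate`` are calcification in
    µmol CaCO₃ cm⁻² h⁻¹ (positive = alkalinity drawdown); ``true_photo``
    is net photosynthesis and ``true_resp`` dark O₂ consumption, both in
    µg O₂ cm⁻² min⁻¹ (positive magnitudes). ``blank_drift`` is the A_T
    change (µmol kg⁻¹ per run) common to every chamber, removed by blank
    correction. Two blank chambers accompany each phase, matching the
    field protocol.
    """
    if surface_area_cm2 <= 0:
        raise ValueError("surface area must be positive")
    if chamber_volume_l <= 0:
        raise ValueError("chamber volume must be positive")
    if any(d <= 0 for d in durations_min):
        raise ValueError("durations must be positive")
    rng = np.random.default_rng(seed)
    o2_sd = noise_sd / 100.0 if o2_noise_sd is None else o2_noise_sd
    mass_kg = chamber_volume_l * seawater_density_kg_l
    records: list[IncubationRecord] = []
    for phase, dur_min, g_rate, o2_rate in (
        ("light", durations_min[0], true_light_rate, true_photo),
        ("dark", durations_min[1], true_dark_rate, -true_resp),
    ):
        dur_h = dur_min / 60.0
        # alkalinity drops 2 µmol per µmol CaCO₃ precipitated
        d_at = -2.0 * g_rate * surface_area_cm2 * dur_h / mass_kg + blank_drift
        d_o2 = o2_rate * surface_area_cm2 * dur_min / (1000.0 * chamber_volume_l) + o2_blank_drift
        records.append(
            IncubationRecord(
                chamber_id=f"{chamber_prefix}_{phase}",
                is_blank=False,
                phase=phase,
                at_initial=at_initial,
                at_final=at_initial + d_at + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0),
                o2_initial=o2_initial,
                o2_final=o2_initial + d_o2 + (rng.normal(0, o2_sd) if o2_sd > 0 else 0.0),
                chamber_volume_l=chamber_volume_l,
                duration_min=dur_min,
                surface_area_cm2=surface_area_cm2,
                treatment_ph=treatment_ph,
                seawater_density_kg_l=seawater_density_kg_l,
            )
        )
        for k in range(n_blanks):
            records.append(
                IncubationRecord(
                    chamber_id=f"{chamber_prefix}_{phase}_blank{k}",
                    is_blank=True,
                    phase=phase,
                    at_initial=at_initial,
                    at_final=at_initial
                    + blank_drift
                    + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0),
                    o2_initial=o2_initial,
                    o2_final=o2_initial
                    + o2_blank_drift
                    + (rng.normal(0, o2_sd) if o2_sd > 0 else 0.0),
                    chamber_volume_l=chamber_volume_l,
                    duration_min=dur_min,
                    surface_area_cm2=None,
                    treatment_ph=treatment_ph,
                    seawater_density_kg_l=seawater_density_kg_l,
                )
            )
    return records


# ---------------------------------------------------------------------------
# pH response tables

def make_ph_response_table(
    intercept: float,
    slope: float,
    n: int,
    ph_range: tuple[float, float] = (7.4, 8.1),
    noise_sd: float = 0.0,
    family: str = "gaussian",
    seed: int = 0,
):
    """Scatter of (pH, response) around the line ``intercept + slope·pH``.

    ``family='gaussian'`` adds Normal noise; ``family='gamma'`` draws from
    a Gamma distribution with that mean and standard deviation
    ``noise_sd`` (the mean must then be strictly positive — shift the
    responses first if it is not).
    """
    import pandas as pd

    if n < 3:
        raise ValueError("need at least three observations")
    lo, hi = ph_range
    if not (7.0 <= lo < hi <= 8.3):
        raise ValueError("pH range must lie within [7.0, 8.3]")
    if family not in ("gaussian", "gamma"):
        raise ValueError(f"unknown family {family!r}")
    rng = np.random.default_rng(seed)
    ph = rng.uniform(lo, hi, size=n)
    mu = intercept + slope * ph
    if family == "gaussian":
        y = mu + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)
    else:
        if np.any(mu <= 0):
            raise ValueError(
                "gamma responses require a strictly positive mean; "
                "shift the response scale before generating"
            )
        if noise_sd > 0:
            shape_k = (mu / noise_sd) ** 2
            y = rng.gamma(shape_k, scale=mu / shape_k)
        else:
            y = mu
    return pd.DataFrame({"ph": ph, "response": y})
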