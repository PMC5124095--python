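"""Volume containers, file I/O, and densitometry calibration.

Micro-CT reconstructions are 3-D grids of X-ray attenuation. Physical
interpretation requires two pieces of metadata carried with every volume:
the (isotropic) voxel pitch in micrometres and the physical position of
voxel (0, 0, 0). Attenuation is converted to calcium-carbonate density
through a linear calibration fitted to scans of aragonite phantoms of
known density.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import SimpleITK as sitk
import tifffile
from scipy import stats

__all__ = [
    "Volume3D",
    "CalibrationCurve",
    "read_volume",
    "write_volume",
    "fit_densitometry",
    "attenuation_to_density",
]


@dataclass
class Volume3D:
    """A 3-D scalar attenuation grid with physical metadata.

    ``values`` is indexed ``[x, y, z]``; ``pitch_um`` is the isotropic
    voxel edge length; ``origin`` is the physical position (µm) of the
    centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    pitch_um: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("volume must be a non-empty 3-D grid")
        if not np.isfinite(self.pitch_um) or self.pitch_um <= 0:
            raise ValueError(f"voxel pitch must be positive, got {self.pitch_um}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attenuation values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm³ (pitch in µm → cm via 1e-4)."""
        return float((self.pitch_um * 1e-4) ** 3)

    def to_sitk(self) -> sitk.Image:
        """SimpleITK image (x-fastest memory order) with physical spacing in µm."""
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.values.T))
        img.SetSpacing((self.pitch_um,) * 3)
        img.SetOrigin(tuple(float(o) for o in self.origin))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, metadata: dict | None = None) -> "Volume3D":
        sp = img.GetSpacing()
        if not np.allclose(sp, sp[0], rtol=1e-6):
            raise ValueError(f"anisotropic pitch {sp}; resample to isotropic first")
        arr = sitk.GetArrayFromImage(img).T
        return cls(arr, float(sp[0]), tuple(img.GetOrigin()), metadata or {})


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear attenuation → CaCO₃ density map: density = slope·attn + intercept."""

    slope: float          # g cm⁻³ per attenuation unit
    intercept: float      # g cm⁻³
    r_squared: float
    n_phantoms: int

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive (denser ⇒ more attenuating)")
        if self.n_phantoms < 2:
            raise ValueError("calibration needs at least two phantoms")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(vol: Volume3D, path: str | Path, format: str | None = None) -> Path:
    """Write a volume as a multi-page TIFF stack (+ JSON sidecar) or NRRD.

    The format is inferred from the extension when not given. TIFF cannot
    carry the voxel pitch natively, so it is written to ``<path>.json``;
    NRRD stores spacing in its header.
    """
    path = Path(path)
    fmt = format or ("nrrd" if path.suffix.lower() == ".nrrd" else "tiff")
    if fmt == "tiff":
        # pages along z so each page is one reconstructed slice
        tifffile.imwrite(path, np.ascontiguousarray(np.moveaxis(vol.values, 2, 0)))
        meta = {
            "pitch_um": vol.pitch_um,
            "origin_um": list(vol.origin),
            "axes_order": "zyx-pages",
            **{k: v for k, v in vol.metadata.items() if isinstance(v, (str, int, float))},
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    elif fmt == "nrrd":
        sitk.WriteImage(vol.to_sitk(), str(path))
    else:
        raise ValueError(f"unknown volume format {fmt!r}")
    return path


def read_volume(path: str | Path, format: str | None = None) -> Volume3D:
    """Read a TIFF stack (with JSON pitch sidecar) or NRRD volume.

    A TIFF without its sidecar is rejected: a scan without a voxel pitch
    is not a physical object.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("nrrd" if path.suffix.lower() == ".nrrd" else "tiff")
    if fmt == "tiff":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(
                f"{path} has no pitch metadata ({sidecar.name} missing); "
                "volumes are physical objects and require a voxel pitch"
            )
        meta = json.loads(sidecar.read_text())
        if "pitch_um" not in meta:
            raise ValueError(f"{sidecar} lacks required key 'pitch_um'")
        arr = np.moveaxis(tifffile.imread(path), 0, 2)
        origin = tuple(meta.get("origin_um", (0.0, 0.0, 0.0)))
        extra = {k: v for k, v in meta.items() if k not in ("pitch_um", "origin_um", "axes_order")}
        return Volume3D(arr, float(meta["pitch_um"]), origin, extra)
    if fmt == "nrrd":
        return Volume3D.from_sitk(sitk.ReadImage(str(path)))
    raise ValueError(f"unknown volume format {fmt!r}")


def fit_densitometry(
    phantoms: Sequence[tuple[float, float]] | "np.ndarray",
) -> CalibrationCurve:
    """Least-squares line density = slope·attenuation + intercept.

    Parameters
    ----------
    phantoms
        Sequence of ``(mean_attenuation, known_density_gcc)`` pairs, one
        per phantom scan.
    """
    arr = np.asarray(phantoms, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (attenuation, density) phantom pairs")
    attn, dens = arr[:, 0], arr[:, 1]
    if np.ptp(attn) == 0:
        raise ValueError("phantom attenuations are identical; calibration fit is singular")
    res = stats.linregress(attn, dens)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_phantoms=len(attn),
    )


def attenuation_to_density(vol: Volume3D, cal: CalibrationCurve, clamp: bool = True) -> Volume3D:
    """Voxelwise affine map of attenuation to density (g cm⁻³).

    Background noise can map below zero; density is physical, so negative
    values are clamped to 0 by default.
    """
    dens = cal.slope * vol.values.astype(float) + cal.intercept
    if clamp:
        np.maximum(dens, 0.0, out=dens)
    return Volume3D(dens, vol.pitch_um, vol.origin, {**vol.metadata, "units": "g_cm3"})
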