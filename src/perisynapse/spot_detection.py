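"""3D stack preprocessing and anisotropic puncta detection.

Reproduces a super-resolution confocal quantification workflow: thick stacks
are split into sub-stacks under 30 μm to limit top-to-bottom attenuation, a
1 μm-scale background is subtracted, per-plane brightness is equalised, and
puncta of a nominal 0.3 × 0.3 × 0.6 μm (x/y/z diameter) spot model are
detected with a multiscale anisotropic Laplacian-of-Gaussian blob detector.
Detection thresholds are calibrated on the top 10 μm of each stack only, then
applied stack-wide, so depth-dependent gradients cannot bias the cutoff.

Default voxel geometry is the super-resolution mode of the acquisition this
emulates: x = y = 0.043 μm/voxel, z = 0.185 μm/voxel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from pathlib import Path

from scipy import ndimage

SR_VOXEL_SIZE = (0.185, 0.043, 0.043)  # (z, y, x) μm/voxel


@dataclass
class ImageStack:
    """A single-channel 3D stack with voxel calibration.

    ``voxels`` is indexed (z, y, x); ``voxel_size`` is μm/voxel in the same
    order.  ``z_offset`` keeps coordinates global after sub-stack splitting.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = SR_VOXEL_SIZE
    channel: str = ""
    z_offset: float = 0.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D (z, y, x) array, got ndim={self.voxels.ndim}")
        if not all(v > 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be strictly positive, got {self.voxel_size}")

    @property
    def depth_um(self) -> float:
        return self.voxels.shape[0] * self.voxel_size[0]


@dataclass
class PunctumSet:
    """Detected or simulated 3D point objects of one channel."""

    channel: str
    table: pd.DataFrame  # punctum_id, x_um, y_um, z_um, r_xy_um, r_z_um, intensity

    COLUMNS = ["punctum_id", "x_um", "y_um", "z_um", "r_xy_um", "r_z_um", "intensity"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"puncta table missing columns {missing}")
        if self.table["punctum_id"].duplicated().any():
            raise ValueError("punctum ids must be unique")
        if len(self.table) and not (self.table[["r_xy_um", "r_z_um"]] > 0).all().all():
            raise ValueError("punctum radii must be > 0")

    def __len__(self) -> int:
        return len(self.table)

    def centers(self) -> np.ndarray:
        """(n, 3) centers in μm, ordered (x, y, z)."""
        return self.table[["x_um", "y_um", "z_um"]].to_numpy(float)

    @classmethod
    def from_records(cls, channel: str, records: list[dict]) -> "PunctumSet":
        df = pd.DataFrame(records, columns=cls.COLUMNS)
        return cls(channel=channel, table=df)


@dataclass(frozen=True)
class DetectionThresholds:
    """Per-scale robust response statistics calibrated from the top of a stack.

    Each LoG scale's response is z-scored by its own (median, robust σ) before
    scales are combined, so small scales — whose white-noise response is much
    broader — cannot flood the detector.  ``k`` is the floor in robust σ units.
    """

    scale_medians: tuple[float, ...]
    scale_sigmas: tuple[float, ...]
    k: float
    calibration_depth_um: float


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def trim_stack(stack: ImageStack, max_depth: float = 30.0) -> list[ImageStack]:
    """Split a stack into the fewest sub-stacks each strictly under ``max_depth`` μm.

    Concatenating the sub-stacks reproduces the input voxel-for-voxel; each
    carries a ``z_offset`` so downstream coordinates stay global.
    """
    nz = stack.voxels.shape[0]
    if nz == 0:
        raise ValueError("stack has zero depth")
    depth = stack.depth_um
    n_sub = int(depth // max_depth) + 1  # smallest n with depth / n < max_depth
    bounds = np.linspace(0, nz, n_sub + 1).round().astype(int)
    out = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        out.append(
            ImageStack(
                voxels=stack.voxels[lo:hi],
                voxel_size=stack.voxel_size,
                channel=stack.channel,
                z_offset=stack.z_offset + lo * stack.voxel_size[0],
            )
        )
    return out


def subtract_background(stack: ImageStack, radius: float = 1.0) -> ImageStack:
    """Remove large-scale background estimated at a ``radius`` μm scale.

    The background is a wide Gaussian estimate (σ = radius per axis, in
    anisotropic voxel units); the result is clipped at zero, so constant
    images map to all-zeros and narrow puncta survive nearly unattenuated.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    sigma_vox = tuple(radius / v for v in stack.voxel_size)
    if any(s < 1.0 for s in sigma_vox):
        raise ValueError(
            f"background radius {radius} μm is below one voxel for voxel size {stack.voxel_size}"
        )
    img = stack.voxels.astype(np.float64)
    background = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="reflect")
    return replace(stack, voxels=np.clip(img - background, 0.0, None))


def normalize_layers(stack: ImageStack, percentile: float = 99.5) -> ImageStack:
    """Equalise per-plane brightness against a stack-wide reference.

    Each z-plane is rescaled so its ``percentile`` brightness matches the
    median of that statistic across planes — a monotone, per-plane gain that
    removes depth attenuation.  Planes with no intensity spread pass through
    unchanged with a warning.
    """
    img = stack.voxels.astype(np.float64)
    stats = np.array([np.percentile(p, percentile) for p in img])
    usable = stats > 0
    if not usable.any():
        warnings.warn("all planes empty; normalize_layers is a no-op", stacklevel=2)
        return replace(stack, voxels=img)
    reference = float(np.median(stats[usable]))
    out = np.empty_like(img)
    for i, plane in enumerate(img):
        if usable[i]:
            out[i] = plane * (reference / stats[i])
        else:
            warnings.warn(f"plane {i} has no intensity spread; passed through", stacklevel=2)
            out[i] = plane
    return replace(stack, voxels=out)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _log_scales(expected_diameter_xy: float, expected_diameter_z: float, size_adaptive: bool):
    """Anisotropic LoG σ triplets (μm) bracketing the expected spot size."""
    # blob of radius r maximises scale-normalised LoG response near σ = r/√3
    base = np.array(
        [expected_diameter_z / 2, expected_diameter_xy / 2, expected_diameter_xy / 2]
    ) / math.sqrt(3.0)
    factors = (0.75, 1.0, 1.5) if size_adaptive else (1.0,)
    return [tuple(base * f) for f in factors]


def _log_response(img: np.ndarray, sigma_um, voxel_size) -> np.ndarray:
    sigma_vox = tuple(s / v for s, v in zip(sigma_um, voxel_size))
    # scale-normalised: multiply by mean σ² (in μm²) for cross-scale comparability
    norm = float(np.mean(np.square(sigma_um)))
    return -norm * ndimage.gaussian_laplace(img, sigma=sigma_vox, mode="reflect")


def calibrate_threshold(
    stack: ImageStack,
    top_depth: float = 10.0,
    k: float = 10.0,
    expected_diameter_xy: float = 0.3,
    expected_diameter_z: float = 0.6,
    size_adaptive: bool = True,
) -> DetectionThresholds:
    """Calibrate per-scale response statistics from the top ``top_depth`` μm only.

    For every LoG scale the median and MAD-based robust σ of the response over
    the calibration slab are recorded; detection floors each scale's z-scored
    response at ``k``.  The default k = 10 sits above the extreme-value range
    of the preprocessed noise field — zero-clipping after background
    subtraction and per-plane gain equalisation stretch the robust-z noise
    tail to ≈ 7–8 over typical stack volumes — while matched-scale responses
    of puncta at the nominal spot size reach z ≳ 20 even at SNR 5.
    Statistics come from the calibration slab alone and are applied stack-wide,
    so intensity gradients deeper in the tissue cannot bias the cutoff.
    """
    n_top = int(round(top_depth / stack.voxel_size[0]))
    if stack.depth_um < top_depth:
        warnings.warn(
            f"stack depth {stack.depth_um:.1f} μm < calibration depth {top_depth} μm; "
            "using the full stack",
            stacklevel=2,
        )
        n_top = stack.voxels.shape[0]
    top = stack.voxels[:n_top].astype(np.float64)
    meds, sigmas = [], []
    for s in _log_scales(expected_diameter_xy, expected_diameter_z, size_adaptive):
        resp = _log_response(top, s, stack.voxel_size)
        med = float(np.median(resp))
        mad = float(np.median(np.abs(resp - med)))
        meds.append(med)
        sigmas.append(max(1.4826 * mad, 1e-12))
    return DetectionThresholds(
        scale_medians=tuple(meds),
        scale_sigmas=tuple(sigmas),
        k=k,
        calibration_depth_um=top_depth,
    )


def detect_spots(
    stack: ImageStack,
    thresholds: DetectionThresholds,
    expected_diameter_xy: float = 0.3,
    expected_diameter_z: float = 0.6,
    size_adaptive: bool = True,
) -> PunctumSet:
    """Detect puncta with a multiscale anisotropic LoG blob detector.

    Local maxima of the scale-normalised LoG response above the calibrated
    floor become candidate puncta; non-maximum suppression removes detections
    within one expected radius (anisotropic metric) of a stronger one.
    Centers are intensity-weighted centroids in global μm coordinates; radii
    come from the best-responding scale when ``size_adaptive``.
    """
    img = stack.voxels.astype(np.float64)
    if not np.any(img):
        return PunctumSet.from_records(stack.channel, [])
    scales = _log_scales(expected_diameter_xy, expected_diameter_z, size_adaptive)
    if len(scales) != len(thresholds.scale_sigmas):
        raise ValueError("thresholds were calibrated with a different scale set")
    responses = np.stack(
        [
            (_log_response(img, s, stack.voxel_size) - m) / sg
            for s, m, sg in zip(scales, thresholds.scale_medians, thresholds.scale_sigmas)
        ]
    )
    best_scale = responses.argmax(axis=0)
    resp = responses.max(axis=0)

    # local maxima within a footprint of about one expected radius
    fp = tuple(
        max(3, 2 * int(round((d / 2) / v)) + 1)
        for d, v in zip((expected_diameter_z, expected_diameter_xy, expected_diameter_xy), stack.voxel_size)
    )
    local_max = resp == ndimage.maximum_filter(resp, size=fp, mode="reflect")
    cand = np.argwhere(local_max & (resp > thresholds.k))
    if len(cand) == 0:
        return PunctumSet.from_records(stack.channel, [])
    strengths = resp[tuple(cand.T)]
    order = np.argsort(-strengths, kind="stable")
    cand = cand[order]
    strengths = strengths[order]

    # NMS in an anisotropic metric scaled by the expected radii
    r_axes = np.array(
        [expected_diameter_z / 2, expected_diameter_xy / 2, expected_diameter_xy / 2]
    )
    pos_um = cand * np.array(stack.voxel_size)
    scaled = pos_um / r_axes
    keep: list[int] = []
    for i in range(len(cand)):
        ok = True
        for j in keep:
            if np.sum((scaled[i] - scaled[j]) ** 2) < 1.0:
                ok = False
                break
        if ok:
            keep.append(i)

    records = []
    vz, vy, vx = stack.voxel_size
    half = tuple(max(1, int(round(r / v))) for r, v in zip(r_axes, stack.voxel_size))
    for pid, i in enumerate(keep, start=1):
        z0, y0, x0 = cand[i]
        sl = tuple(
            slice(max(0, c - h), min(s, c + h + 1))
            for c, h, s in zip((z0, y0, x0), half, img.shape)
        )
        patch = img[sl]
        w = np.clip(patch, 0, None)
        if w.sum() <= 0:
            w = np.ones_like(patch)
        zz, yy, xx = np.mgrid[sl]
        cz = float((w * zz).sum() / w.sum())
        cy = float((w * yy).sum() / w.sum())
        cx = float((w * xx).sum() / w.sum())
        s = scales[best_scale[z0, y0, x0]]
        records.append(
            {
                "punctum_id": pid,
                "x_um": cx * vx,
                "y_um": cy * vy,
                "z_um": cz * vz + stack.z_offset,
                "r_xy_um": s[1] * math.sqrt(3.0),
                "r_z_um": s[0] * math.sqrt(3.0),
                "intensity": float(img[z0, y0, x0]),
            }
        )
    return PunctumSet.from_records(stack.channel, records)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_stack(path: str | Path, voxel_size=None, channel: str = "") -> ImageStack:
    """Read a (OME-)TIFF stack; voxel size from OME metadata unless overridden."""
    import tifffile

    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        voxels = tf.asarray()
        if voxel_size is None:
            voxel_size = _voxel_size_from_ome(tf) or SR_VOXEL_SIZE
    if voxels.ndim == 2:
        voxels = voxels[None]
    return ImageStack(voxels=voxels, voxel_size=tuple(voxel_size), channel=channel or path.stem)


def _voxel_size_from_ome(tf) -> tuple[float, float, float] | None:
    try:
        ome = tf.ome_metadata
        if not ome:
            return None
        import re

        m = {
            axis: float(re.search(rf'PhysicalSize{axis}="([\d.eE+-]+)"', ome).group(1))
            for axis in "ZYX"
        }
        return (m["Z"], m["Y"], m["X"])
    except (AttributeError, TypeError):
        return None


def write_stack(stack: ImageStack, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(
        str(path),
        stack.voxels.astype(np.float32),
        metadata={
            "axes": "ZYX",
            "PhysicalSizeZ": stack.voxel_size[0],
            "PhysicalSizeY": stack.voxel_size[1],
            "PhysicalSizeX": stack.voxel_size[2],
        },
    )


def write_puncta(puncta: PunctumSet, path: str | Path) -> None:
    """Write the puncta TSV dialect (deterministic float formatting)."""
    df = puncta.table.copy()
    df.insert(1, "channel", puncta.channel)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_puncta(path: str | Path, channel: str | None = None) -> PunctumSet:
    df = pd.read_csv(path, sep="\t")
    ch = channel or (str(df["channel"].iloc[0]) if "channel" in df and len(df) else "")
    return PunctumSet(channel=ch, table=df[PunctumSet.COLUMNS].copy())
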