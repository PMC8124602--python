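"""Synthetic depth scenes: parametric pig bodies on a weighing platform.

The body is a lofted solid of semi-elliptical cross-sections along the
body axis: a shoulder section (width SW, apex height SH plus any vertical
head displacement) and a hip section (width HW, apex HH), cosine-blended
between and tapered beyond, with head and tail appendages extending past
the ear-root/tail-root extent BL. All six labels are therefore
geometrically meaningful and the solid's volume has a closed quadrature
form, giving the weight model BW = density * volume * (1 + eps) and an
independent oracle for the renderer.

Depths are in mm (pixel value = camera-to-surface distance); body sizes in
cm; weights in kg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from pigdepth.units import CAMERA_DISTANCE_MM, cm_to_mm

__all__ = [
    "PigPhenotype",
    "SceneConfig",
    "DepthImage",
    "REFERENCE_DIMS_CM",
    "phenotype_from_latent",
    "sample_phenotype",
    "expected_mean_bw",
    "solid_volume_cm3",
    "render_depth",
    "rendered_volume_mm3",
    "generate_dataset",
]

#: Reference body dimensions at latent size 1.0: (BL, SW, SH, HW, HH) in cm.
REFERENCE_DIMS_CM = (100.0, 32.0, 55.0, 34.0, 57.0)

# Axial layout, as fractions of BL / taper factors. The cosine blends have
# zero slope at segment ends, so the apex height over the whole body is
# exactly max(shoulder apex, hip apex).
_F_SHOULDER = 0.25   # shoulder section position along BL
_F_HIP = 0.78        # hip section position along BL
_F_FRONT = 0.75      # size factor at the ear root relative to the shoulder
_F_REAR = 0.85       # size factor at the tail root relative to the hip
_F_SNOUT = 0.12      # size factor at the snout tip relative to the front
_F_TAIL_END = 0.08   # size factor at the tail tip relative to the rear
_HEAD_LEN = 0.28     # head appendage length as fraction of BL
_TAIL_LEN = 0.10     # tail appendage length as fraction of BL

_FIT_MARGIN_MM = 10.0


@dataclass(frozen=True)
class PigPhenotype:
    """Simulator ground truth: morphometry plus posture.

    Morphometry (cm/kg) deterministically yields the label vector; posture
    (yaw, lateral offset, vertical head displacement, spine bend) only
    changes how the body appears in the image.
    """

    body_length_cm: float
    shoulder_width_cm: float
    shoulder_height_cm: float
    hip_width_cm: float
    hip_height_cm: float
    body_weight_kg: float
    yaw_deg: float = 0.0
    lateral_offset_cm: float = 0.0
    head_pitch_cm: float = 0.0
    bend_deg: float = 0.0

    def __post_init__(self):
        for name in (
            "body_length_cm",
            "shoulder_width_cm",
            "shoulder_height_cm",
            "hip_width_cm",
            "hip_height_cm",
            "body_weight_kg",
        ):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if abs(self.head_pitch_cm) > 4.0 + 1e-9:
            raise ValueError(
                f"head_pitch_cm must be within +/-4 cm, got {self.head_pitch_cm}"
            )

    def labels(self, mode: str = "as-imaged") -> np.ndarray:
        """Label vector [BW, SW, SH, HW, HH, BL].

        ``mode='as-imaged'`` reports the shoulder apex as rendered (SH plus
        head displacement); ``'at-rest'`` reports the measured-at-rest SH.
        """
        if mode not in ("as-imaged", "at-rest"):
            raise ValueError(f"unknown label mode {mode!r}")
        sh = self.shoulder_height_cm
        if mode == "as-imaged":
            sh = sh + self.head_pitch_cm
        return np.array(
            [
                self.body_weight_kg,
                self.shoulder_width_cm,
                sh,
                self.hip_width_cm,
                self.hip_height_cm,
                self.body_length_cm,
            ]
        )


@dataclass(frozen=True)
class SceneConfig:
    camera_distance_mm: float = CAMERA_DISTANCE_MM
    image_height_px: int = 720
    image_width_px: int = 1280
    platform_length_m: float = 1.5
    platform_width_m: float = 0.5
    mm_per_pixel: float | None = None  # default: platform length / image width
    depth_noise_std_mm: float = 2.0
    include_limit_bars: bool = False
    weight_range_kg: tuple[float, float] = (16.5, 117.0)
    label_mode: str = "as-imaged"
    tissue_density_g_cm3: float = 1.0
    bw_noise_sigma: float = 0.03
    dim_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.image_height_px < 64 or self.image_width_px < 64:
            raise ValueError("image dimensions must be >= 64 pixels")
        if self.camera_distance_mm <= 0:
            raise ValueError("camera_distance_mm must be positive")
        if self.label_mode not in ("as-imaged", "at-rest"):
            raise ValueError(f"unknown label_mode {self.label_mode!r}")
        lo, hi = self.weight_range_kg
        if not (0 < lo < hi < 200):
            raise ValueError(
                f"weight_range_kg must satisfy 0 < min < max < 200, got {self.weight_range_kg}"
            )

    @property
    def scale_mm_per_px(self) -> float:
        if self.mm_per_pixel is not None:
            return self.mm_per_pixel
        return self.platform_length_m * 1000.0 / self.image_width_px


@dataclass(frozen=True)
class DepthImage:
    """Camera-to-surface distances in mm (uint16 grid) plus the
    millisecond acquisition timestamp (the file-naming key)."""

    data: np.ndarray
    timestamp_ms: int = 0


def _blend(t: np.ndarray) -> np.ndarray:
    """C1 cosine ramp from 0 to 1 on [0, 1], zero slope at both ends."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(t, 0.0, 1.0)))


def _axial_value(s_mm, bl_mm, front_val, rear_val):
    """Evaluate one lofted profile (half-width or apex height, mm) along the
    body axis. s=0 is the ear root, s=bl the tail root."""
    s = np.asarray(s_mm, dtype=float)
    lh, lt = _HEAD_LEN * bl_mm, _TAIL_LEN * bl_mm
    s_sh, s_hip = _F_SHOULDER * bl_mm, _F_HIP * bl_mm
    out = np.zeros_like(s)

    m = (s >= -lh) & (s < 0)
    f = _F_SNOUT + (_F_FRONT - _F_SNOUT) * _blend((s[m] + lh) / lh)
    out[m] = f * front_val

    m = (s >= 0) & (s < s_sh)
    f = _F_FRONT + (1.0 - _F_FRONT) * _blend(s[m] / s_sh)
    out[m] = f * front_val

    m = (s >= s_sh) & (s < s_hip)
    w = _blend((s[m] - s_sh) / (s_hip - s_sh))
    out[m] = front_val + (rear_val - front_val) * w

    m = (s >= s_hip) & (s <= bl_mm)
    f = 1.0 + (_F_REAR - 1.0) * _blend((s[m] - s_hip) / (bl_mm - s_hip))
    out[m] = f * rear_val

    m = (s > bl_mm) & (s <= bl_mm + lt)
    f = _F_REAR + (_F_TAIL_END - 1.0) * _F_REAR * _blend((s[m] - bl_mm) / lt)
    out[m] = f * rear_val
    return out


def _profiles(phenotype: PigPhenotype, s_mm, as_imaged: bool = True):
    """(half_width_mm, apex_height_mm) of the solid at axial positions s."""
    bl = cm_to_mm(phenotype.body_length_cm)
    sh = phenotype.shoulder_height_cm
    if as_imaged:
        sh = sh + phenotype.head_pitch_cm
    a = _axial_value(
        s_mm, bl, cm_to_mm(phenotype.shoulder_width_cm) / 2.0,
        cm_to_mm(phenotype.hip_width_cm) / 2.0,
    )
    h = _axial_value(s_mm, bl, cm_to_mm(sh), cm_to_mm(phenotype.hip_height_cm))
    return a, h


def solid_volume_cm3(phenotype: PigPhenotype, as_imaged: bool = True) -> float:
    """Volume of the lofted solid by composite-Simpson quadrature of the
    semi-elliptical cross-section area (pi/2 * half_width * apex_height)."""
    bl = cm_to_mm(phenotype.body_length_cm)
    lo, hi = -_HEAD_LEN * bl, bl + _TAIL_LEN * bl
    n = 8192  # even; quadrature error is negligible at this density
    s = np.linspace(lo, hi, n + 1)
    a, h = _profiles(phenotype, s, as_imaged)
    area = 0.5 * np.pi * a * h  # mm^2
    w = np.ones(n + 1)
    w[1:-1:2], w[2:-1:2] = 4.0, 2.0
    step = (hi - lo) / n
    vol_mm3 = float(np.sum(w * area) * step / 3.0)
    return vol_mm3 / 1000.0


_REFERENCE_VOLUME_CM3: float | None = None


def _reference_volume_cm3() -> float:
    global _REFERENCE_VOLUME_CM3
    if _REFERENCE_VOLUME_CM3 is None:
        bl, sw, sh, hw, hh = REFERENCE_DIMS_CM
        ref = PigPhenotype(bl, sw, sh, hw, hh, body_weight_kg=1.0)
        _REFERENCE_VOLUME_CM3 = solid_volume_cm3(ref, as_imaged=False)
    return _REFERENCE_VOLUME_CM3


def phenotype_from_latent(
    latent: float,
    density_g_cm3: float = 1.0,
    head_pitch_cm: float = 0.0,
    yaw_deg: float = 0.0,
    lateral_offset_cm: float = 0.0,
    bend_deg: float = 0.0,
    dim_factors=(1.0, 1.0, 1.0, 1.0, 1.0),
    bw_factor: float = 1.0,
) -> PigPhenotype:
    """Deterministic phenotype at a given latent size scalar.

    Dimensions scale linearly with ``latent`` (times per-dimension
    factors); weight is density * at-rest solid volume * bw_factor, so with
    all factors at 1 the weight scales with the cube of the latent size.
    """
    if latent <= 0:
        raise ValueError(f"latent must be > 0, got {latent}")
    bl0, sw0, sh0, hw0, hh0 = REFERENCE_DIMS_CM
    fbl, fsw, fsh, fhw, fhh = dim_factors
    dims = dict(
        body_length_cm=bl0 * latent * fbl,
        shoulder_width_cm=sw0 * latent * fsw,
        shoulder_height_cm=sh0 * latent * fsh,
        hip_width_cm=hw0 * latent * fhw,
        hip_height_cm=hh0 * latent * fhh,
    )
    probe = PigPhenotype(body_weight_kg=1.0, head_pitch_cm=head_pitch_cm, **dims)
    bw = density_g_cm3 * solid_volume_cm3(probe, as_imaged=False) / 1000.0 * bw_factor
    return PigPhenotype(
        body_weight_kg=bw,
        yaw_deg=yaw_deg,
        lateral_offset_cm=lateral_offset_cm,
        head_pitch_cm=head_pitch_cm,
        bend_deg=bend_deg,
        **dims,
    )


def expected_mean_bw(weight_range_kg=(16.5, 117.0)) -> float:
    """Closed-form mean body weight of the sampling law: the nominal weight
    is uniform on the margin-trimmed range (symmetric trim), and every
    noise factor has unit mean, so the mean is the range midpoint."""
    lo, hi = weight_range_kg
    return 0.5 * (lo + hi)


def _bend_deviation_mm(phenotype: PigPhenotype) -> float:
    total_len = cm_to_mm(phenotype.body_length_cm) * (1 + _HEAD_LEN + _TAIL_LEN)
    return math.tan(math.radians(abs(phenotype.bend_deg))) * total_len / 4.0


def _centerline_offset_mm(phenotype: PigPhenotype, s_mm) -> np.ndarray:
    """Lateral centre-line deviation (spine bend): a zero-mean parabola in
    the normalized axial coordinate. Shear along y preserves volume."""
    bl = cm_to_mm(phenotype.body_length_cm)
    lo = -_HEAD_LEN * bl
    total = bl * (1 + _HEAD_LEN + _TAIL_LEN)
    d = math.tan(math.radians(phenotype.bend_deg)) * total / 4.0
    t = (np.asarray(s_mm, dtype=float) - lo) / total
    return d * ((2.0 * t - 1.0) ** 2 - 1.0 / 3.0)


def _footprint_halfspan_mm(phenotype: PigPhenotype) -> tuple[float, float]:
    """(half-length, half-width) of the body's axis-aligned bounding box in
    the body frame, about its axial midpoint."""
    bl = cm_to_mm(phenotype.body_length_cm)
    half_len = bl * (1 + _HEAD_LEN + _TAIL_LEN) / 2.0
    a_max = cm_to_mm(max(phenotype.shoulder_width_cm, phenotype.hip_width_cm)) / 2.0
    half_wid = a_max + _bend_deviation_mm(phenotype)
    return half_len, half_wid


def _check_platform_fit(phenotype: PigPhenotype, config: SceneConfig) -> None:
    half_len, half_wid = _footprint_halfspan_mm(phenotype)
    th = math.radians(phenotype.yaw_deg)
    ext_x = abs(math.cos(th)) * half_len + abs(math.sin(th)) * half_wid
    ext_y = abs(math.sin(th)) * half_len + abs(math.cos(th)) * half_wid
    plat_l = config.platform_length_m * 1000.0
    plat_w = config.platform_width_m * 1000.0
    off = cm_to_mm(phenotype.lateral_offset_cm)
    if ext_x > plat_l / 2.0 - _FIT_MARGIN_MM:
        raise ValueError(
            f"phenotype exceeds platform_length_m={config.platform_length_m}: "
            f"needs {2 * ext_x / 1000.0:.3f} m along the platform"
        )
    if abs(off) + ext_y > plat_w / 2.0 - _FIT_MARGIN_MM:
        raise ValueError(
            f"phenotype exceeds platform_width_m={config.platform_width_m}: "
            f"needs {2 * (abs(off) + ext_y) / 1000.0:.3f} m across the platform"
        )


def _clamp_pose(phenotype: PigPhenotype, config: SceneConfig) -> PigPhenotype:
    """Shrink yaw / lateral offset / bend toward zero until the body fits
    the platform (deterministic)."""
    p = phenotype
    for _ in range(60):
        try:
            _check_platform_fit(p, config)
            return p
        except ValueError:
            p = replace(
                p,
                yaw_deg=p.yaw_deg * 0.8,
                lateral_offset_cm=p.lateral_offset_cm * 0.8,
                bend_deg=p.bend_deg * 0.8,
            )
    return replace(p, yaw_deg=0.0, lateral_offset_cm=0.0, bend_deg=0.0)


def sample_phenotype(
    weight_range_kg=(16.5, 117.0),
    rng_seed=0,
    density_g_cm3: float = 1.0,
    bw_noise_sigma: float = 0.03,
    dim_noise: float = 0.05,
    config: SceneConfig | None = None,
) -> PigPhenotype:
    """Draw one phenotype.

    A nominal weight is uniform on the symmetrically trimmed weight range;
    the latent size is its cube root through the reference volume; the five
    body dimensions get independent bounded relative noise (unit mean); the
    weight is density * at-rest volume * (1 + eps), eps ~ N(0, sigma^2)
    truncated at 3 sigma. Draws falling outside the weight range are
    rejected and redrawn. The pose is clamped so the body fits the
    platform. Identical seeds give identical phenotypes.
    """
    lo, hi = weight_range_kg
    if not (0 < lo < hi) or hi >= 200:
        raise ValueError(
            f"weight_range_kg must satisfy 0 < min < max < 200, got {weight_range_kg}"
        )
    if not (math.isfinite(density_g_cm3) and density_g_cm3 > 0):
        raise ValueError(f"density_g_cm3 must be finite and > 0, got {density_g_cm3}")
    if config is None:
        config = SceneConfig()
    rng = np.random.default_rng(rng_seed)
    margin = 0.15 * (hi - lo)
    v0 = _reference_volume_cm3()
    for _ in range(1000):
        bw_nom = rng.uniform(lo + margin, hi - margin)
        latent = (bw_nom * 1000.0 / (density_g_cm3 * v0)) ** (1.0 / 3.0)
        dim_factors = 1.0 + rng.uniform(-dim_noise, dim_noise, size=5)
        head_pitch = rng.uniform(-4.0, 4.0)
        yaw = rng.uniform(-6.0, 6.0)
        offset = rng.uniform(-2.5, 2.5)
        bend = rng.uniform(-12.0, 12.0)
        if bw_noise_sigma > 0:
            eps = float(
                np.clip(rng.normal(0.0, bw_noise_sigma), -3 * bw_noise_sigma, 3 * bw_noise_sigma)
            )
        else:
            eps = 0.0
        p = phenotype_from_latent(
            latent,
            density_g_cm3=density_g_cm3,
            head_pitch_cm=head_pitch,
            yaw_deg=yaw,
            lateral_offset_cm=offset,
            bend_deg=bend,
            dim_factors=tuple(dim_factors),
            bw_factor=1.0 + eps,
        )
        if lo <= p.body_weight_kg <= hi:
            return _clamp_pose(p, config)
    raise RuntimeError("failed to sample a phenotype within the weight range")


def render_depth(
    phenotype: PigPhenotype | None,
    config: SceneConfig,
    rng: np.random.Generator | None = None,
    timestamp_ms: int = 0,
) -> DepthImage:
    """Render the scene as a depth image.

    Covered pixels read camera_distance - surface_height; uncovered pixels
    read exactly camera_distance (``phenotype=None`` renders the empty
    platform). Gaussian depth noise (if configured) is added last over the
    whole frame, then values are clipped to [0, camera_distance] and
    quantized to whole mm (uint16).
    """
    if phenotype is None:
        cam = config.camera_distance_mm
        shape = (config.image_height_px, config.image_width_px)
        depth = np.full(shape, cam, dtype=float)
        if config.depth_noise_std_mm > 0:
            if rng is None:
                rng = np.random.default_rng(config.seed)
            depth += rng.normal(0.0, config.depth_noise_std_mm, shape)
        data = np.floor(np.clip(depth, 0.0, cam) + 0.5).astype(np.uint16)
        return DepthImage(data=data, timestamp_ms=timestamp_ms)
    _check_platform_fit(phenotype, config)
    cam = config.camera_distance_mm
    max_h = cm_to_mm(
        max(
            phenotype.shoulder_height_cm + phenotype.head_pitch_cm,
            phenotype.hip_height_cm,
        )
    )
    if max_h >= cam:
        raise ValueError(
            f"body apex ({max_h} mm) reaches the camera plane ({cam} mm)"
        )
    mpp = config.scale_mm_per_px
    h_px, w_px = config.image_height_px, config.image_width_px
    # pixel centres at half-integer offsets; row 0 = top, x along the length
    x = (np.arange(w_px) + 0.5) * mpp
    y = (np.arange(h_px) + 0.5) * mpp
    xx, yy = np.meshgrid(x, y)

    cx = w_px * mpp / 2.0
    cy = h_px * mpp / 2.0 + cm_to_mm(phenotype.lateral_offset_cm)
    th = math.radians(phenotype.yaw_deg)
    dx, dy = xx - cx, yy - cy
    bl = cm_to_mm(phenotype.body_length_cm)
    half_len = bl * (1 + _HEAD_LEN + _TAIL_LEN) / 2.0
    # body frame: s along the spine with s=0 at the ear root, body midpoint
    # at the platform centre
    s = math.cos(th) * dx + math.sin(th) * dy + (half_len - _HEAD_LEN * bl)
    yb = -math.sin(th) * dx + math.cos(th) * dy

    a, h = _profiles(phenotype, s, as_imaged=True)
    y_rel = yb - _centerline_offset_mm(phenotype, s)
    covered = (a > 0) & (np.abs(y_rel) < a)
    height = np.zeros_like(a)
    with np.errstate(invalid="ignore"):
        height[covered] = h[covered] * np.sqrt(
            1.0 - (y_rel[covered] / a[covered]) ** 2
        )

    if config.include_limit_bars:
        bar_half = config.platform_width_m * 1000.0 / 2.0
        bar_w, bar_h = 20.0, 300.0
        for edge in (cy - cm_to_mm(phenotype.lateral_offset_cm) - bar_half,
                     cy - cm_to_mm(phenotype.lateral_offset_cm) + bar_half):
            in_bar = np.abs(yy - edge) < bar_w / 2.0
            height = np.where(in_bar, np.maximum(height, bar_h), height)

    depth = cam - height
    if config.depth_noise_std_mm > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        depth = depth + rng.normal(0.0, config.depth_noise_std_mm, depth.shape)
    depth = np.clip(depth, 0.0, cam)
    data = np.floor(depth + 0.5).astype(np.uint16)
    return DepthImage(data=data, timestamp_ms=timestamp_ms)


def rendered_volume_mm3(image: DepthImage | np.ndarray, config: SceneConfig) -> float:
    """Pixel-area-weighted integral of (camera_distance - depth)."""
    data = image.data if isinstance(image, DepthImage) else np.asarray(image)
    mpp = config.scale_mm_per_px
    return float(
        np.sum(config.camera_distance_mm - data.astype(np.float64)) * mpp * mpp
    )


def generate_dataset(
    n: int, config: SceneConfig = SceneConfig(), seed: int = 0
) -> list[tuple[DepthImage, np.ndarray]]:
    """Generate n i.i.d. (DepthImage, label-vector) pairs.

    Labels are ordered as LABEL_NAMES = [BW, SW, SH, HW, HH, BL]; the SH
    label follows ``config.label_mode``. Timestamps step by the nominal
    0.2 s scale-reading interval. Fully determined by (config, seed).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    root = np.random.SeedSequence(seed)
    children = root.spawn(n)
    base_ms = 1_600_000_000_000
    out = []
    for i, child in enumerate(children):
        pheno_seed, noise_seed = child.spawn(2)
        p = sample_phenotype(
            config.weight_range_kg,
            rng_seed=pheno_seed,
            density_g_cm3=config.tissue_density_g_cm3,
            bw_noise_sigma=config.bw_noise_sigma,
            dim_noise=config.dim_noise,
            config=config,
        )
        img = render_depth(
            p,
            config,
            rng=np.random.default_rng(noise_seed),
            timestamp_ms=base_ms + 200 * i,
        )
        out.append((img, p.labels(config.label_mode)))
    return out
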