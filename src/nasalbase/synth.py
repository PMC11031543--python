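"""Parametric renderer of basal-view nasal-base images.

Emulates the imaging conditions of a clinical basal-view photograph at
desk scale: two dark elliptical nostril openings, a central columella
band, alar lobules, and a lightly textured skin background.  Every
render carries the exact 18-landmark annotation implied by its
parameters, and a 9-component asymmetry vector perturbs the left/right
measurement pairs so that the i-th geometry ratio equals exp(v_i) by
construction.

All randomness is seeded; the same parameters always produce a
bit-identical image and landmark set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon
from skimage.transform import resize

from .boxes import ground_truth_box
from .sample import AnnotatedImage, save_sample
from .schema import DEFAULT_SCHEMA, LandmarkSet

__all__ = [
    "NoseParams",
    "AsymmetryVector",
    "render_nasal_base",
    "embed_in_face",
    "generate_samples",
    "generate_dataset",
]

_SUPER = 4  # supersampling factor for anti-aliased shape rasterization

_NOSTRIL_COLOR = np.array([38.0, 26.0, 26.0])
_ASYM_CAP = 0.8


@dataclass(frozen=True)
class AsymmetryVector:
    """Per-measurement left/right log-ratio perturbations.

    Component i makes geometry feature i equal exp(v[i]); v = 0 is a
    perfectly symmetric nasal base.  Magnitudes are capped so rendered
    anatomy stays plausible.
    """

    v: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=float)
        if v.shape != (9,) or not np.all(np.isfinite(v)):
            raise ValueError("asymmetry vector must be 9 finite reals")
        if np.any(np.abs(v) > _ASYM_CAP):
            raise ValueError(f"asymmetry components must lie within +/-{_ASYM_CAP}")
        object.__setattr__(self, "v", v)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.v))


@dataclass(frozen=True)
class NoseParams:
    """Full parameterization of one rendered nasal base.

    Lengths are pixels, angles degrees from the columellar axis.  The
    default values describe a symmetric nasal base occupying roughly
    the central 60% of a 256 x 256 canvas.
    """

    canvas: tuple[int, int] = (256, 256)
    center: tuple[float, float] = (128.0, 128.0)
    overall_scale: float = 70.0
    nostril_axis_angle_l: float = 18.0
    nostril_axis_angle_r: float = 18.0
    nostril_width_l: float = 21.0
    nostril_width_r: float = 21.0
    nostril_height_l: float = 43.0
    nostril_height_r: float = 43.0
    midalar_width_l: float = 36.4
    midalar_width_r: float = 36.4
    ala_thickness_l: float = 10.5
    ala_thickness_r: float = 10.5
    columella_apex_width_l: float = 7.0
    columella_apex_width_r: float = 7.0
    columella_base_width_l: float = 8.4
    columella_base_width_r: float = 8.4
    alare_offset_l: float = 50.4
    alare_offset_r: float = 50.4
    subalare_offset_l: float = 22.4
    subalare_offset_r: float = 22.4
    skin_tone: tuple[int, int, int] = (224, 172, 150)
    background: tuple[int, int, int] = (224, 172, 150)
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nostril_axis_angle_l", "nostril_axis_angle_r"):
            a = getattr(self, name)
            if not 0 < a < 180:
                raise ValueError(f"{name} must be in (0, 180)")
        for name, val in self.__dict__.items():
            if name.endswith(("_l", "_r")) and "angle" not in name and val <= 0:
                raise ValueError(f"{name} must be positive")

    def with_asymmetry(self, asym: AsymmetryVector) -> "NoseParams":
        """Split each measurement pair multiplicatively: left x exp(v/2),
        right x exp(-v/2), so feature i becomes exp(v_i) exactly."""
        v = asym.v
        pairs = [
            ("nostril_axis_angle", 0),
            ("midalar_width", 1),
            ("subalare_offset", 2),
            ("alare_offset", 3),
            ("columella_apex_width", 4),
            ("columella_base_width", 5),
            ("nostril_width", 6),
            ("nostril_height", 7),
            ("ala_thickness", 8),
        ]
        changes = {}
        for stem, i in pairs:
            base_l = getattr(self, f"{stem}_l")
            base_r = getattr(self, f"{stem}_r")
            changes[f"{stem}_l"] = base_l * float(np.exp(v[i] / 2))
            changes[f"{stem}_r"] = base_r * float(np.exp(-v[i] / 2))
        return replace(self, **changes)


def _landmarks_from_params(p: NoseParams) -> dict[str, np.ndarray]:
    """Exact landmark coordinates implied by the parameters (upright frame,
    columellar axis vertical through the canvas center)."""
    cx, cy = p.center
    s = p.overall_scale
    pts: dict[str, np.ndarray] = {
        "pronasale": np.array([cx, cy - 0.80 * s]),
        "subnasale": np.array([cx, cy + 0.55 * s]),
    }
    y_nostril = cy - 0.05 * s
    for side, sign in (("l", -1.0), ("r", 1.0)):
        a = np.radians(getattr(p, f"nostril_axis_angle_{side}"))
        w = getattr(p, f"nostril_width_{side}")
        h = getattr(p, f"nostril_height_{side}")
        cb = getattr(p, f"columella_base_width_{side}")
        # long axis points toward pronasale, tilted laterally by the axis angle
        u = np.array([-sign * np.sin(a), -np.cos(a)])
        # medial normal: the perpendicular of u that points toward the midline
        n_medial = np.array([-u[1], u[0]])
        if n_medial[0] * sign > 0:
            n_medial = -n_medial
        center = np.array(
            [cx + sign * (cb + (w / 2) * abs(n_medial[0])), y_nostril]
        )
        # medial point sits exactly at distance cb from the (vertical) axis
        pts[f"nostril_apex_{side}"] = center + u * (h / 2)
        pts[f"nostril_base_{side}"] = center - u * (h / 2)
        pts[f"nostril_medial_{side}"] = center + n_medial * (w / 2)
        pts[f"columella_apex_{side}"] = np.array(
            [cx + sign * getattr(p, f"columella_apex_width_{side}"), cy - 0.45 * s]
        )
        m = getattr(p, f"midalar_width_{side}")
        t = getattr(p, f"ala_thickness_{side}")
        pts[f"midalar_{side}"] = np.array([cx + sign * m, y_nostril])
        pts[f"ala_outer_{side}"] = np.array([cx + sign * (m + t), y_nostril])
        pts[f"alare_{side}"] = np.array(
            [cx + sign * getattr(p, f"alare_offset_{side}"), cy + 0.10 * s]
        )
        pts[f"subalare_{side}"] = np.array(
            [cx + sign * getattr(p, f"subalare_offset_{side}"), cy + 0.42 * s]
        )
    return pts


def _nostril_frames(p: NoseParams) -> dict[str, tuple[np.ndarray, np.ndarray, float, float]]:
    """(center, long-axis unit, semi-major, semi-minor) per nostril side."""
    pts = _landmarks_from_params(p)
    out = {}
    for side in ("l", "r"):
        apex, base = pts[f"nostril_apex_{side}"], pts[f"nostril_base_{side}"]
        center = (apex + base) / 2
        u = apex - base
        h = float(np.linalg.norm(u))
        u = u / h
        w = getattr(p, f"nostril_width_{side}")
        out[side] = (center, u, h / 2, w / 2)
    return out


def _blend_patch(canvas: np.ndarray, alpha_super: np.ndarray, color: np.ndarray,
                 y0: int, x0: int) -> None:
    """Downsample a supersampled alpha patch (block mean) and alpha-blend
    ``color`` into the canvas at base-pixel offset (y0, x0)."""
    S = _SUPER
    hb, wb = alpha_super.shape[0] // S, alpha_super.shape[1] // S
    a = alpha_super.reshape(hb, S, wb, S).mean(axis=(1, 3))
    region = canvas[y0:y0 + hb, x0:x0 + wb]
    region *= (1 - a)[..., None]
    region += a[..., None] * color


def _ellipse_patch(canvas: np.ndarray, center: np.ndarray, u: np.ndarray,
                   a: float, b: float, color: np.ndarray) -> None:
    """Anti-aliased rotated-ellipse fill, rasterized only inside its
    base-pixel bounding box."""
    H, W = canvas.shape[:2]
    S = _SUPER
    cx, cy = center
    r = max(a, b)
    x0, x1 = max(0, int(cx - r) - 1), min(W, int(np.ceil(cx + r)) + 1)
    y0, y1 = max(0, int(cy - r) - 1), min(H, int(np.ceil(cy + r)) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = (np.arange((x1 - x0) * S) + 0.5) / S + x0 - cx
    ys = (np.arange((y1 - y0) * S) + 0.5) / S + y0 - cy
    lon = np.multiply.outer(ys * u[1], np.ones_like(xs)) + np.multiply.outer(np.ones_like(ys), xs * u[0])
    lat = np.multiply.outer(ys * u[0], np.ones_like(xs)) - np.multiply.outer(np.ones_like(ys), xs * u[1])
    mask = ((lon / a) ** 2 + (lat / b) ** 2 <= 1.0).astype(float)
    _blend_patch(canvas, mask, np.asarray(color, float), y0, x0)


def _polygon_patch(canvas: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                   color: np.ndarray) -> None:
    """Anti-aliased polygon fill restricted to the polygon's bounding box."""
    H, W = canvas.shape[:2]
    S = _SUPER
    x0 = max(0, int(np.floor(xs.min())) - 1)
    y0 = max(0, int(np.floor(ys.min())) - 1)
    x1 = min(W, int(np.ceil(xs.max())) + 1)
    y1 = min(H, int(np.ceil(ys.max())) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    alpha = np.zeros(((y1 - y0) * S, (x1 - x0) * S), dtype=float)
    rr, cc = draw_polygon((ys - y0) * S, (xs - x0) * S, shape=alpha.shape)
    alpha[rr, cc] = 1.0
    _blend_patch(canvas, alpha, np.asarray(color, float), y0, x0)


def render_nasal_base(params: NoseParams) -> AnnotatedImage:
    """Render one nasal-base image with exact landmark annotations.

    Deterministic given ``params`` (including its seed, which drives only
    the skin texture).  Raises if the implied shapes leave the canvas.
    """
    W, H = params.canvas
    pts = _landmarks_from_params(params)
    all_pts = np.stack(list(pts.values()))
    margin = params.overall_scale * 0.12
    if (all_pts[:, 0].min() < margin or all_pts[:, 0].max() > W - margin
            or all_pts[:, 1].min() < margin or all_pts[:, 1].max() > H - margin):
        raise ValueError("rendered nasal base does not fit inside the canvas")

    skin = np.array(params.skin_tone, dtype=float)
    canvas = np.ones((H, W, 3), dtype=float) * np.array(params.background, float)
    frames = _nostril_frames(params)
    cx, cy = params.center
    s = params.overall_scale

    def ellipse_layer(center, u, a, b, color):
        _ellipse_patch(canvas, np.asarray(center, float), np.asarray(u, float),
                       a, b, np.asarray(color, float))

    # alar lobules; every landmark-bearing parameter leaves a visible trace,
    # as real anatomical landmarks sit on observable structure
    dark_skin = skin * 0.84
    for side, sign in (("l", -1.0), ("r", 1.0)):
        m = getattr(params, f"midalar_width_{side}")
        t = getattr(params, f"ala_thickness_{side}")
        al = getattr(params, f"alare_offset_{side}")
        sb = getattr(params, f"subalare_offset_{side}")
        # lateral bulge whose extreme lateral point is exactly the alare
        rx = 0.38 * al
        ellipse_layer((cx + sign * (al - rx), cy + 0.10 * s), (1.0, 0.0),
                      rx, 0.26 * s, dark_skin)
        center, u, a, b = frames[side]
        ellipse_layer(center, u, a + 0.8 * t, b + t, dark_skin)
        # alar rim between the midalar point (inner) and ala outer edge
        ellipse_layer((cx + sign * (m + t / 2), cy - 0.05 * s), (1.0, 0.0),
                      t / 2, 0.32 * s, skin * 0.74)
        # alar-facial groove marking the subalare
        ellipse_layer((cx + sign * sb, cy + 0.42 * s), (1.0, 0.0),
                      0.10 * s, 0.05 * s, skin * 0.74)

    # columella band between the nostrils, slightly lighter than skin
    ca_l = getattr(params, "columella_apex_width_l")
    ca_r = getattr(params, "columella_apex_width_r")
    cb_l = getattr(params, "columella_base_width_l")
    cb_r = getattr(params, "columella_base_width_r")
    y_top, y_bot = cy - 0.45 * s, cy + 0.35 * s
    band_x = np.array([cx - ca_l, cx + ca_r, cx + cb_r, cx - cb_l])
    band_y = np.array([y_top, y_top, y_bot, y_bot])
    _polygon_patch(canvas, band_x, band_y, skin * 1.06)

    # nostril openings (dark)
    for side in ("l", "r"):
        center, u, a, b = frames[side]
        ellipse_layer(center, u, a, b, _NOSTRIL_COLOR)

    # subtle seeded skin texture
    rng = np.random.default_rng(params.seed)
    noise = gaussian_filter(rng.normal(0, params.noise_sigma * 3, (H, W)), 1.5)
    canvas += noise[..., None]
    image = np.clip(np.round(canvas), 0, 255).astype(np.uint8)

    schema = DEFAULT_SCHEMA
    lms = LandmarkSet(
        image_id=f"synth_{params.seed}",
        points=np.array([pts[n] for n in schema.names]),
        frame="whole_image",
        frame_size=(W, H),
        schema=schema,
    )
    return AnnotatedImage(image=image, landmarks=lms).with_box()


def embed_in_face(
    nasal: AnnotatedImage,
    face_canvas: tuple[int, int] = (512, 512),
    placement_seed: int = 0,
    offset: tuple[int, int] | None = None,
    scale: float | None = None,
    pad: float = 0.15,
) -> AnnotatedImage:
    """Paste a nasal-base render at a seeded random position and scale on a
    larger textured background, transforming landmarks and the ground-truth
    box accordingly."""
    W, H = face_canvas
    h0, w0 = nasal.image.shape[:2]
    rng = np.random.default_rng(placement_seed)
    if scale is None:
        scale = float(rng.uniform(0.8, 1.25))
    out_h, out_w = int(round(h0 * scale)), int(round(w0 * scale))
    if out_h > H or out_w > W:
        raise ValueError("scaled nasal-base image exceeds the face canvas")
    sy, sx = out_h / h0, out_w / w0
    if offset is None:
        dx = int(rng.integers(0, W - out_w + 1))
        dy = int(rng.integers(0, H - out_h + 1))
    else:
        dx, dy = offset
        if dx < 0 or dy < 0 or dx + out_w > W or dy + out_h > H:
            raise ValueError("placement pushes the nasal base outside the canvas")

    tone = np.array(nasal.image[2, 2], dtype=float)
    canvas = np.ones((H, W, 3), dtype=float) * tone
    # blotchy skin-like texture (built at quarter resolution) so that
    # localization is not a trivial threshold
    hq, wq = H // 4, W // 4
    blotch = np.zeros((hq, wq))
    yy, xx = np.ogrid[:hq, :wq]
    for _ in range(8):
        by, bx = rng.uniform(0, hq), rng.uniform(0, wq)
        amp = rng.uniform(-14, 14)
        sig = rng.uniform(5, 15)
        blotch += amp * np.exp(-(((yy - by) ** 2 + (xx - bx) ** 2) / (2 * sig**2)))
    blotch += gaussian_filter(rng.normal(0, 18, (hq, wq)), 0.8)
    texture = resize(blotch, (H, W), anti_aliasing=False)
    canvas += texture[..., None]

    if (out_h, out_w) == (h0, w0):
        patch = nasal.image.astype(float)
    else:
        patch = resize(nasal.image.astype(float), (out_h, out_w, 3),
                       anti_aliasing=True, preserve_range=True)
    # feathered paste: no hard square seam for the detector to latch onto
    fy = np.clip(np.minimum(np.arange(out_h), out_h - 1 - np.arange(out_h))
                 / max(1, int(0.12 * out_h)), 0, 1)
    fx = np.clip(np.minimum(np.arange(out_w), out_w - 1 - np.arange(out_w))
                 / max(1, int(0.12 * out_w)), 0, 1)
    feather = np.outer(fy, fx)[..., None]
    region = canvas[dy:dy + out_h, dx:dx + out_w]
    canvas[dy:dy + out_h, dx:dx + out_w] = feather * patch + (1 - feather) * region
    image = np.clip(np.round(canvas), 0, 255).astype(np.uint8)

    pts = nasal.landmarks.points * np.array([sx, sy]) + np.array([dx, dy], float)
    lms = nasal.landmarks.with_points(pts, frame="whole_image", frame_size=(W, H))
    out = AnnotatedImage(image=image, landmarks=lms)
    return out.with_box(pad=pad)


def sample_asymmetry(rng: np.random.Generator, spread: float) -> AsymmetryVector:
    v = np.clip(rng.normal(0.0, spread, 9), -_ASYM_CAP, _ASYM_CAP)
    return AsymmetryVector(v)


def generate_samples(
    n: int,
    asymmetry_spread: float = 0.3,
    seed: int = 0,
    embed: bool = False,
    face_canvas: tuple[int, int] = (512, 512),
) -> list[tuple[AnnotatedImage, AsymmetryVector]]:
    """Render ``n`` seeded samples with asymmetry vectors drawn from a
    zero-mean normal of the given spread (components capped)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        asym = sample_asymmetry(rng, asymmetry_spread)
        params = NoseParams(seed=int(rng.integers(0, 2**31 - 1))).with_asymmetry(asym)
        sample = render_nasal_base(params)
        sample.landmarks.image_id = f"synth_{seed:04d}_{k:04d}"
        if embed:
            sample = embed_in_face(
                sample, face_canvas, placement_seed=int(rng.integers(0, 2**31 - 1))
            )
        out.append((sample, asym))
    return out


def generate_dataset(
    n: int,
    asymmetry_spread: float,
    seed: int,
    out_dir: str | Path,
    embed: bool = False,
) -> pd.DataFrame:
    """Write ``n`` image/annotation pairs plus a manifest CSV listing each
    image's asymmetry norm and its SSIM symmetry ground truth."""
    from .symmetry import ssim_ground_truth  # local import: avoids cycle at load

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample, asym in generate_samples(n, asymmetry_spread, seed, embed=embed):
        save_sample(sample, out_dir)
        rows.append({
            "image_id": sample.image_id,
            "asymmetry_norm": asym.norm,
            "ssim": ssim_ground_truth(sample),
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
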