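"""Synthetic longitudinal sheep-face cohorts with independent identity and age factors.

Real longitudinal sheep-face datasets are rarely public, so this module renders
a controlled stand-in: each individual owns a fixed facial geometry (eye
spacing, nose placement — the eye–nose triangle), a fixed coat pattern and a
fixed base coat colour, while age (in months, 1–12) drives a saturating head
growth curve, a gradual pelage-lightness drift and a late-onset fur texture.
Lighting gain/bias, in-plane rotation and sensor noise are nuisance factors.
Identity factors are drawn independently of age by construction, which is what
makes the downstream decoupling experiments interpretable.

All rendering is deterministic given the seeds carried in the parameter
objects, so every image is reproducible bit-for-bit.
"""

from __future__ import annotations

import colorsys
import dataclasses
import math
from pathlib import Path

import numpy as np
from scipy import ndimage

# -- parameter bounds ---------------------------------------------------
EYE_SPACING_RANGE = (0.35, 0.60)      # fraction of head width
NOSE_DX_RANGE = (-0.08, 0.08)         # fraction of head half-width
NOSE_DY_RANGE = (0.25, 0.45)          # fraction of head half-height, below centre
N_MARKINGS = 4
MIN_IMAGE_SIDE = 16


@dataclasses.dataclass(frozen=True)
class IdentityParams:
    """Facial factors that stay constant for an individual across all ages."""

    eye_spacing: float
    nose_offset: tuple[float, float]
    coat_seed: int
    marking_code: int
    base_hue: float

    def __post_init__(self):
        lo, hi = EYE_SPACING_RANGE
        if not lo <= self.eye_spacing <= hi:
            raise ValueError("eye_spacing out of bounds")
        if not NOSE_DX_RANGE[0] <= self.nose_offset[0] <= NOSE_DX_RANGE[1]:
            raise ValueError("nose_offset x out of bounds")
        if not NOSE_DY_RANGE[0] <= self.nose_offset[1] <= NOSE_DY_RANGE[1]:
            raise ValueError("nose_offset y out of bounds")
        if not 0 <= self.marking_code < N_MARKINGS:
            raise ValueError("unknown marking_code")
        if not 0.0 <= self.base_hue <= 1.0:
            raise ValueError("base_hue out of [0,1]")


@dataclasses.dataclass(frozen=True)
class GrowthModel:
    """Saturating head-growth curve plus late-onset fur texture.

    ``scale(age) = s_max * (1 - exp(-age / tau))``; with the default
    ``tau = 2.5`` months about 80% of growth is complete by month 4, matching
    the rapid early change and later stabilization of lamb faces.  Fur texture
    amplitude is ``fur_gain * max(0, age - fur_onset)``: zero before
    ``fur_onset`` (default month 8), growing linearly afterwards.
    """

    s_max: float = 1.0
    tau: float = 2.5
    fur_onset: float = 8.0
    fur_gain: float = 0.035
    lightness_drift: float = 0.018   # coat value change per month around month 6

    def __post_init__(self):
        if self.s_max <= 0:
            raise ValueError("s_max must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.fur_gain < 0:
            raise ValueError("fur_gain must be nonnegative")


@dataclasses.dataclass(frozen=True)
class NuisanceParams:
    """Photometric and geometric nuisance applied after rendering."""

    gain: float = 1.0
    bias: float = 0.0
    rotation_deg: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


@dataclasses.dataclass(frozen=True)
class AugmentPolicy:
    """Ranges for the four-way augmentation (original kept as the first copy)."""

    gain_range: float = 0.20       # multiplicative luminance jitter, +-20%
    bias_range: float = 0.10       # additive contrast offset
    noise_sigma: float = 0.02      # injected Gaussian noise
    rotation_deg: float = 15.0     # random in-plane rotation, +- degrees
    multiplier: int = 4            # images out per image in


@dataclasses.dataclass
class LabeledFaceImage:
    pixels: np.ndarray              # (3, H, W) float32 in [0, 1]
    sheep_id: str
    age_months: int
    box: tuple[int, int, int, int]  # (x, y, w, h) in pixels
    nuisance: NuisanceParams
    origin: str = "original"

    def validate(self) -> None:
        if not 1 <= self.age_months <= 12:
            raise ValueError("age_months out of [1, 12]")
        if self.pixels.ndim != 3 or self.pixels.shape[0] != 3:
            raise ValueError("pixels must be (3, H, W)")
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixels must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixels must lie in [0, 1]")
        x, y, w, h = self.box
        _, H, W = self.pixels.shape
        if x < 0 or y < 0 or w < 0 or h < 0 or x + w > W or y + h > H:
            raise ValueError("box must lie inside the image")


@dataclasses.dataclass(frozen=True)
class ManifestRecord:
    path: str
    sheep_id: str
    age_months: int
    box: tuple[int, int, int, int]
    split: str
    origin: str = "original"


AGE_WINDOWS = {"train": (1, 4), "val": (5, 8), "test": (9, 12)}
ID_SPLIT_FRACTIONS = {"train": 44 / 55, "val": 5 / 55, "test": 6 / 55}


@dataclasses.dataclass
class DatasetManifest:
    records: list[ManifestRecord]
    protocol: str  # "age_based" | "id_based"

    def __post_init__(self):
        self.validate()

    @property
    def counts(self) -> dict[str, int]:
        c = {"train": 0, "val": 0, "test": 0}
        for r in self.records:
            c[r.split] += 1
        return c

    def split_records(self, split: str) -> list[ManifestRecord]:
        return [r for r in self.records if r.split == split]

    def validate(self) -> None:
        if self.protocol not in ("age_based", "id_based"):
            raise ValueError(f"unknown protocol: {self.protocol}")
        for r in self.records:
            if r.split not in AGE_WINDOWS:
                raise ValueError(f"unknown split: {r.split}")
            if not 1 <= r.age_months <= 12:
                raise ValueError("age out of range")
        if self.protocol == "age_based":
            for r in self.records:
                lo, hi = AGE_WINDOWS[r.split]
                if not lo <= r.age_months <= hi:
                    raise ValueError(
                        f"age-based split violation: age {r.age_months} in {r.split}")
        else:
            ids = {s: {r.sheep_id for r in self.records if r.split == s}
                   for s in AGE_WINDOWS}
            for a in ("train", "val", "test"):
                for b in ("train", "val", "test"):
                    if a < b and ids[a] & ids[b]:
                        raise ValueError("id-based split violation: shared individual")


# -- identity and growth -----------------------------------------------

def make_identity(seed: int) -> IdentityParams:
    """Draw per-individual facial factors; a pure function of ``seed``."""
    rng = np.random.default_rng(seed)
    return IdentityParams(
        eye_spacing=float(rng.uniform(*EYE_SPACING_RANGE)),
        nose_offset=(float(rng.uniform(*NOSE_DX_RANGE)),
                     float(rng.uniform(*NOSE_DY_RANGE))),
        coat_seed=int(rng.integers(2 ** 31)),
        marking_code=int(rng.integers(N_MARKINGS)),
        base_hue=float(rng.uniform(0.0, 1.0)),
    )


def growth_scale(age_months: float, g: GrowthModel) -> float:
    """Head scale at ``age_months``: ``s_max * (1 - exp(-age/tau))``."""
    if g.tau <= 0:
        raise ValueError("tau must be positive")
    if age_months < 0:
        raise ValueError("age must be nonnegative")
    return g.s_max * (1.0 - math.exp(-age_months / g.tau))


def _smooth_field(seed: int, grid: int, sigma: float) -> np.ndarray:
    field = np.random.default_rng(seed).standard_normal((grid, grid))
    field = ndimage.gaussian_filter(field, sigma, mode="wrap")
    return field / (np.abs(field).max() + 1e-9)


def _bandpass_field(seed: int, grid: int) -> np.ndarray:
    """Band-pass texture: difference of two Gaussian smoothings."""
    raw = np.random.default_rng(seed).standard_normal((grid, grid))
    field = (ndimage.gaussian_filter(raw, 0.8, mode="wrap")
             - ndimage.gaussian_filter(raw, 2.5, mode="wrap"))
    return field / (np.abs(field).max() + 1e-9)


def _sample_field(field: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    g = field.shape[0]
    gi = (v + 1.0) / 2.0 * (g - 1)
    gj = (u + 1.0) / 2.0 * (g - 1)
    return ndimage.map_coordinates(field, [gi.ravel(), gj.ravel()],
                                   order=1, mode="wrap").reshape(u.shape)


def render_face(identity: IdentityParams, age_months: int,
                nuisance: NuisanceParams, size: tuple[int, int] = (64, 64),
                g: GrowthModel | None = None,
                sheep_id: str = "sheep000") -> LabeledFaceImage:
    """Render one face; deterministic given all arguments.

    The head is an axis-aligned ellipse scaled by the growth curve; the
    eye–nose triangle, coat pattern and marking are placed in head-local
    coordinates, so they scale with the head but keep their identity-specific
    geometry.  Nuisance (rotation, gain/bias, noise) is applied last.
    """
    g = g or GrowthModel()
    H, W = size
    if min(H, W) < MIN_IMAGE_SIDE:
        raise ValueError("image too small to place facial landmarks")
    if not 1 <= age_months <= 12:
        raise ValueError("age_months out of [1, 12]")

    gs = growth_scale(age_months, g) / g.s_max
    cx, cy = (W - 1) / 2.0, (H - 1) / 2.0
    ax = 0.46 * W * gs            # head half-width in px
    ay = 0.48 * H * gs            # head half-height in px

    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    u = (xx - cx) / ax            # head-local coords in [-1, 1] on the head
    v = (yy - cy) / ay
    rr = u * u + v * v
    mask = np.clip((1.0 - rr) / 0.12, 0.0, 1.0)   # antialiased ellipse edge

    # base coat colour; value drifts linearly with age (pelage maturation)
    val = float(np.clip(0.55 + g.lightness_drift * (age_months - 6), 0.05, 0.95))
    coat = np.array(colorsys.hsv_to_rgb(identity.base_hue, 0.30, val))

    img = np.empty((H, W, 3))
    bg = 0.70 + 0.08 * (yy / max(H - 1, 1) - 0.5)  # plain gradient background
    img[:] = bg[..., None]

    head = np.broadcast_to(coat, (H, W, 3)).copy()
    # identity coat pattern, fixed in head-local coordinates
    coat_tex = _sample_field(_smooth_field(identity.coat_seed, 24, 1.5), u, v)
    head += 0.07 * coat_tex[..., None]

    # identity marking
    m = identity.marking_code
    if m == 1:      # facial blaze
        blaze = np.clip((0.14 - np.abs(u)) / 0.05, 0, 1)
        head += 0.16 * blaze[..., None]
    elif m == 2:    # forehead patch
        patch = np.clip((1 - ((u / 0.30) ** 2 + ((v + 0.45) / 0.22) ** 2)) / 0.3, 0, 1)
        head -= 0.14 * patch[..., None]
    elif m == 3:    # cheek patch near the left eye
        ex = -identity.eye_spacing
        patch = np.clip((1 - (((u - ex) / 0.28) ** 2 + ((v + 0.10) / 0.24) ** 2)) / 0.3,
                        0, 1)
        head -= 0.12 * patch[..., None]

    # late-onset fur texture (age-driven amplitude, identity-linked pattern)
    fur_amp = g.fur_gain * max(0.0, age_months - g.fur_onset)
    if fur_amp > 0:
        fur_tex = _sample_field(_bandpass_field(identity.coat_seed + 1000, 48), u, v)
        head += fur_amp * fur_tex[..., None]

    # eye-nose triangle
    ex = identity.eye_spacing      # eyes at +-eye_spacing * ax from centre
    for sx in (-ex, ex):
        eye = np.clip((1 - (((u - sx) / 0.105) ** 2 + ((v + 0.25) / 0.085) ** 2)) / 0.25,
                      0, 1)
        head = head * (1 - eye[..., None]) + eye[..., None] * np.array([0.06, 0.05, 0.05])
    ndx, ndy = identity.nose_offset
    nose = np.clip((1 - (((u - ndx) / 0.14) ** 2 + ((v - ndy) / 0.11) ** 2)) / 0.25, 0, 1)
    head = head * (1 - nose[..., None]) + nose[..., None] * np.array([0.13, 0.08, 0.08])

    img = img * (1 - mask[..., None]) + head * mask[..., None]
    img = np.clip(img, 0.0, 1.0)

    # nuisance: rotate, photometric, noise
    theta = nuisance.rotation_deg
    if theta:
        img = ndimage.rotate(img, theta, axes=(1, 0), reshape=False,
                             order=1, mode="nearest")
    img = nuisance.gain * img + nuisance.bias
    if nuisance.noise_sigma > 0:
        rng = np.random.default_rng(nuisance.seed)
        img = img + rng.normal(0.0, nuisance.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    box = _ellipse_box(cx, cy, ax, ay, theta, H, W)
    face = LabeledFaceImage(pixels=np.ascontiguousarray(img.transpose(2, 0, 1)),
                            sheep_id=sheep_id, age_months=age_months,
                            box=box, nuisance=nuisance, origin="original")
    face.validate()
    return face


def _ellipse_box(cx, cy, ax, ay, theta_deg, H, W) -> tuple[int, int, int, int]:
    """Tight axis-aligned bounding box of the (rotated) head ellipse."""
    t = math.radians(theta_deg)
    hw = math.sqrt((ax * math.cos(t)) ** 2 + (ay * math.sin(t)) ** 2)
    hh = math.sqrt((ax * math.sin(t)) ** 2 + (ay * math.cos(t)) ** 2)
    x0 = max(0, int(math.floor(cx - hw)))
    y0 = max(0, int(math.floor(cy - hh)))
    x1 = min(W, int(math.ceil(cx + hw)) + 1)
    y1 = min(H, int(math.ceil(cy + hh)) + 1)
    return (x0, y0, x1 - x0, y1 - y0)


def _rotate_box(box, theta_deg, H, W) -> tuple[int, int, int, int]:
    x, y, w, h = box
    cx, cy = (W - 1) / 2.0, (H - 1) / 2.0
    t = math.radians(-theta_deg)  # image rotated by +theta => content rotates -theta
    corners = np.array([[x, y], [x + w, y], [x, y + h], [x + w, y + h]], float)
    rel = corners - [cx, cy]
    rot = rel @ np.array([[math.cos(t), math.sin(t)], [-math.sin(t), math.cos(t)]])
    pts = rot + [cx, cy]
    x0 = max(0, int(math.floor(pts[:, 0].min())))
    y0 = max(0, int(math.floor(pts[:, 1].min())))
    x1 = min(W, int(math.ceil(pts[:, 0].max())))
    y1 = min(H, int(math.ceil(pts[:, 1].max())))
    return (x0, y0, x1 - x0, y1 - y0)


def augment_image(img: LabeledFaceImage, policy: AugmentPolicy | None = None,
                  seed: int = 0) -> list[LabeledFaceImage]:
    """Expand one image into ``policy.multiplier`` images.

    The output is the original plus a photometric-jittered, a noise-injected
    and a rotated variant (in that order); identity and age labels are kept.
    Deterministic given ``seed``.
    """
    policy = policy or AugmentPolicy()
    rng = np.random.default_rng(seed)
    _, H, W = img.pixels.shape
    out = [img]

    variants = ["photometric", "noise", "rotation"]
    # repeat the variant cycle if a multiplier larger than 4 is configured
    for i in range(policy.multiplier - 1):
        kind = variants[i % len(variants)]
        px = img.pixels.astype(np.float64)
        box = img.box
        if kind == "photometric":
            gain = 1.0 + rng.uniform(-policy.gain_range, policy.gain_range)
            bias = rng.uniform(-policy.bias_range, policy.bias_range)
            px = gain * px + bias
        elif kind == "noise":
            px = px + rng.normal(0.0, policy.noise_sigma, size=px.shape)
        else:
            theta = rng.uniform(-policy.rotation_deg, policy.rotation_deg)
            if theta:
                px = ndimage.rotate(px, theta, axes=(2, 1), reshape=False,
                                    order=1, mode="nearest")
                box = _rotate_box(box, theta, H, W)
        aug = LabeledFaceImage(
            pixels=np.clip(px, 0.0, 1.0).astype(np.float32),
            sheep_id=img.sheep_id, age_months=img.age_months, box=box,
            nuisance=img.nuisance, origin="augmented")
        aug.validate()
        out.append(aug)
    return out


# -- cohort generation --------------------------------------------------

def assign_id_splits(ids: list[str], rng: np.random.Generator) -> dict[str, str]:
    """Partition individuals into train/val/test with ~44:5:6 proportions."""
    n = len(ids)
    if n < 3:
        raise ValueError("id-based protocol needs at least 3 individuals")
    order = list(rng.permutation(ids))
    n_val = max(1, round(n * ID_SPLIT_FRACTIONS["val"]))
    n_test = max(1, round(n * ID_SPLIT_FRACTIONS["test"]))
    n_train = n - n_val - n_test
    assignment = {}
    for i, sid in enumerate(order):
        if i < n_train:
            assignment[sid] = "train"
        elif i < n_train + n_val:
            assignment[sid] = "val"
        else:
            assignment[sid] = "test"
    return assignment


def _age_split(age: int) -> str:
    for split, (lo, hi) in AGE_WINDOWS.items():
        if lo <= age <= hi:
            return split
    raise ValueError(f"age {age} outside 1-12")


def generate_cohort(n_ids: int, ages=None, reps_per_cell: int = 8,
                    protocol: str = "age_based", augment_train: bool = False,
                    seed: int = 0, size: tuple[int, int] = (64, 64),
                    growth: GrowthModel | None = None,
                    policy: AugmentPolicy | None = None,
                    ) -> tuple[list[LabeledFaceImage], list[ManifestRecord]]:
    """Render a full cohort in memory; the workhorse behind ``generate_dataset``."""
    if protocol not in ("age_based", "id_based"):
        raise ValueError(f"unknown protocol: {protocol}")
    ages = list(ages) if ages is not None else list(range(1, 13))
    if not ages:
        raise ValueError("empty age list")
    growth = growth or GrowthModel()
    root = np.random.SeedSequence(seed)
    id_seeds, nuis_seed, split_seed, aug_seed = root.spawn(4)
    id_seed_vals = id_seeds.generate_state(n_ids)
    identities = [make_identity(int(s)) for s in id_seed_vals]
    sheep_ids = [f"sheep{i:03d}" for i in range(n_ids)]

    if protocol == "id_based":
        id_split = assign_id_splits(
            sheep_ids, np.random.default_rng(split_seed.generate_state(1)[0]))

    nrng = np.random.default_rng(nuis_seed.generate_state(1)[0])
    arng = np.random.default_rng(aug_seed.generate_state(1)[0])
    images: list[LabeledFaceImage] = []
    records: list[ManifestRecord] = []
    for sid, ident in zip(sheep_ids, identities):
        for age in ages:
            for rep in range(reps_per_cell):
                nuis = NuisanceParams(
                    gain=float(nrng.uniform(0.85, 1.15)),
                    bias=float(nrng.uniform(-0.08, 0.08)),
                    rotation_deg=float(nrng.uniform(-12.0, 12.0)),
                    noise_sigma=float(nrng.uniform(0.005, 0.02)),
                    seed=int(nrng.integers(2 ** 31)),
                )
                face = render_face(ident, age, nuis, size=size, g=growth,
                                   sheep_id=sid)
                split = _age_split(age) if protocol == "age_based" else id_split[sid]
                group = [face]
                if augment_train and split == "train":
                    group = augment_image(face, policy, int(arng.integers(2 ** 31)))
                for k, im in enumerate(group):
                    path = f"images/{sid}_m{age:02d}_r{rep}_{k}.png"
                    images.append(im)
                    records.append(ManifestRecord(
                        path=path, sheep_id=sid, age_months=age, box=im.box,
                        split=split, origin=im.origin))
    return images, records


def generate_dataset(n_ids: int, ages=None, reps_per_cell: int = 8,
                     protocol: str = "age_based", augment_train: bool = False,
                     seed: int = 0, out_dir: str | Path = ".",
                     size: tuple[int, int] = (64, 64),
                     growth: GrowthModel | None = None,
                     policy: AugmentPolicy | None = None) -> DatasetManifest:
    """Render a cohort, write PNGs and CSV/JSONL manifests under ``out_dir``."""
    from . import manifest_io

    images, records = generate_cohort(
        n_ids, ages, reps_per_cell, protocol, augment_train, seed, size,
        growth, policy)
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    for img, rec in zip(images, records):
        save_png(img.pixels, out_dir / rec.path)
    manifest = DatasetManifest(records=records, protocol=protocol)
    manifest_io.write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def save_png(pixels: np.ndarray, path: str | Path) -> None:
    from PIL import Image

    arr = np.clip(np.round(pixels.transpose(1, 2, 0) * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def load_png(path: str | Path) -> np.ndarray:
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.float32) / 255.0
    return np.ascontiguousarray(arr.transpose(2, 0, 1))
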