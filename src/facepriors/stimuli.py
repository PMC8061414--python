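"""Face-in-noise stimulus synthesis.

Stimuli are built in a fixed three-stage degradation pipeline on a white
450x450 canvas: (1) a basic noise pattern of randomly placed black circles,
(2) multiplicative ("speckle") noise, (3) either a Gaussian blur or additive
Gaussian noise, followed by a linear contrast reduction into [0.1, 0.9].
Target stimuli receive a procedural face template, blended into the pattern
between stages 2 and 3 so the final degradation acts on face and noise alike.

All intensities are floats in [0, 1]; 8-bit quantisation happens only at PNG
export.  Every operation is deterministic given a seeded
:class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError

STAGE_CIRCLES = "circles"
STAGE_SPECKLE = "speckle"
STAGE_FACE = "face_embed"
STAGE_BLUR = "stage3_blur"
STAGE_NOISE = "stage3_additive_noise"
STAGE_CONTRAST = "contrast"


@dataclass(frozen=True)
class StimulusSpec:
    """Generation parameters for one stimulus set.

    Defaults follow the original design: 1000 black circles with diameters
    drawn uniformly from 1-15 px on a 450 px white square, speckle variance 2,
    stage-3 variance 10, contrast compressed to [0.1, 0.9], and a 40 target /
    60 noise split over 20 distinct face identities.
    """

    image_size: int = 450
    n_circles: int = 1000
    circle_diameter_range: tuple[int, int] = (1, 15)
    speckle_variance: float = 2.0
    stage3_mode: str = "blur"  # "blur" | "additive_noise"
    stage3_variance: float = 10.0
    contrast_out_range: tuple[float, float] = (0.1, 0.9)
    n_targets: int = 40
    n_noise: int = 60
    n_distinct_faces: int = 20
    face_size: int = 150
    blend_mode: str = "multiply"  # "multiply" | "replace"
    seed: Optional[int] = None

    def validate(self) -> None:
        lo, hi = self.circle_diameter_range
        clo, chi = self.contrast_out_range
        if self.image_size <= 0:
            raise ValidationError("image_size must be positive")
        if self.n_circles < 0:
            raise ValidationError("n_circles must be >= 0")
        if not (1 <= lo <= hi):
            raise ValidationError("circle_diameter_range must satisfy 1 <= low <= high")
        if self.speckle_variance < 0:
            raise ValidationError("speckle_variance must be >= 0")
        if self.stage3_mode not in ("blur", "additive_noise"):
            raise ValidationError(f"unknown stage3_mode {self.stage3_mode!r}")
        if self.stage3_variance < 0:
            raise ValidationError("stage3_variance must be >= 0")
        if not (0.0 <= clo < chi <= 1.0):
            raise ValidationError("contrast_out_range must be an increasing pair inside [0, 1]")
        if self.n_targets < 0 or self.n_noise < 0:
            raise ValidationError("stimulus counts must be >= 0")
        if self.n_targets > 0 and self.n_distinct_faces <= 0:
            raise ValidationError("n_distinct_faces must be positive when targets are requested")
        if self.face_size >= self.image_size:
            raise ValidationError("face_size must be smaller than image_size")
        if self.blend_mode not in ("multiply", "replace"):
            raise ValidationError(f"unknown blend_mode {self.blend_mode!r}")


@dataclass
class StimulusImage:
    """A single stimulus: pixel grid plus ground-truth annotations.

    ``face_position`` is the (row, col) of the template's top-left corner,
    0-based, present iff ``has_face``.  ``provenance`` records the pipeline
    stages applied, in order.
    """

    pixels: np.ndarray
    has_face: bool = False
    face_position: Optional[tuple[int, int]] = None
    face_id: Optional[int] = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError("pixels must be a 2-D grid")
        if np.nanmin(self.pixels) < 0 or np.nanmax(self.pixels) > 1:
            raise ValidationError("intensities must lie in [0, 1]")
        if self.has_face != (self.face_position is not None):
            raise ValidationError("face_position must be present iff has_face")


def generate_noise_pattern(spec: StimulusSpec, rng: np.random.Generator) -> StimulusImage:
    """Stage 1: black circles on a white canvas.

    Circle centres are uniform over the canvas (discs may clip at the
    borders); diameters are uniform integers over ``circle_diameter_range``.
    """
    spec.validate()
    n = spec.image_size
    img = np.ones((n, n), dtype=float)
    lo, hi = spec.circle_diameter_range
    centers = rng.uniform(0, n, size=(spec.n_circles, 2))
    diameters = rng.integers(lo, hi + 1, size=spec.n_circles)
    for (cy, cx), d in zip(centers, diameters):
        r = d / 2.0
        y0, y1 = max(0, int(np.floor(cy - r))), min(n, int(np.ceil(cy + r)) + 1)
        x0, x1 = max(0, int(np.floor(cx - r))), min(n, int(np.ceil(cx + r)) + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.ogrid[y0:y1, x0:x1]
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        img[y0:y1, x0:x1][mask] = 0.0
    return StimulusImage(pixels=img, provenance=[STAGE_CIRCLES])


def apply_speckle(image: StimulusImage, variance: float, rng: np.random.Generator) -> StimulusImage:
    """Stage 2: multiplicative noise J = I + n*I.

    ``n`` is i.i.d. zero-mean uniform with the given variance (uniform on
    [-sqrt(3v), sqrt(3v)]); the result is clipped to [0, 1].  An all-black
    image is a fixed point, and variance 0 is the identity.
    """
    if variance < 0:
        raise ValidationError("speckle variance must be >= 0")
    pix = image.pixels
    if variance > 0:
        half = np.sqrt(3.0 * variance)
        noise = rng.uniform(-half, half, size=pix.shape)
        pix = np.clip(pix + noise * pix, 0.0, 1.0)
    return StimulusImage(pixels=pix.copy(), has_face=image.has_face,
                         face_position=image.face_position, face_id=image.face_id,
                         provenance=image.provenance + [STAGE_SPECKLE])


def apply_stage3(image: StimulusImage, spec: StimulusSpec, rng: np.random.Generator) -> StimulusImage:
    """Stage 3: Gaussian blur (default) or additive Gaussian noise.

    Blur convolves with an isotropic Gaussian kernel of variance
    ``stage3_variance`` px^2 (sigma = sqrt(variance)) with reflective
    boundaries; the alternative mode adds zero-mean Gaussian noise of that
    variance per pixel and clips.
    """
    spec.validate()
    pix = image.pixels
    if spec.stage3_mode == "blur":
        sigma = float(np.sqrt(spec.stage3_variance))
        out = ndimage.gaussian_filter(pix, sigma=sigma, mode="reflect") if sigma > 0 else pix.copy()
        out = np.clip(out, 0.0, 1.0)
        stage = STAGE_BLUR
    else:
        out = np.clip(pix + rng.normal(0.0, np.sqrt(spec.stage3_variance), size=pix.shape), 0.0, 1.0)
        stage = STAGE_NOISE
    return StimulusImage(pixels=out, has_face=image.has_face,
                         face_position=image.face_position, face_id=image.face_id,
                         provenance=image.provenance + [stage])


def adjust_contrast(image: StimulusImage, out_range: tuple[float, float]) -> StimulusImage:
    """Final stage: linear map of [0, 1] onto [low, high]."""
    lo, hi = out_range
    if not (0.0 <= lo < hi <= 1.0):
        raise ValidationError("contrast out_range must be an increasing pair inside [0, 1]")
    pix = lo + image.pixels * (hi - lo)
    return StimulusImage(pixels=pix, has_face=image.has_face,
                         face_position=image.face_position, face_id=image.face_id,
                         provenance=image.provenance + [STAGE_CONTRAST])


def _soft_ellipse(yy, xx, cy, cx, ry, rx, softness=1.5):
    """Smooth-edged ellipse membership in [0, 1]."""
    d = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
    return np.clip((1.0 - d) / (softness / max(ry, rx)) + 0.5, 0.0, 1.0)


def make_face_template(face_id: int, size: int) -> np.ndarray:
    """Procedural grayscale upright face on a white background.

    An oval head with smooth shading, two eyes with brows, a nose and a
    mouth; ``face_id`` deterministically perturbs the geometry so distinct
    ids give visibly distinct faces.  Background is exactly 1.0 so a
    multiplicative blend leaves the surrounding noise untouched.
    """
    if size < 32:
        raise ValidationError("face template size must be >= 32 px")
    g = np.random.default_rng(int(face_id) % (2**31))
    yy, xx = np.mgrid[0:size, 0:size].astype(float) / (size - 1)

    head_ry = 0.40 + 0.06 * g.uniform(-1, 1)
    head_rx = 0.30 + 0.05 * g.uniform(-1, 1)
    eye_dx = 0.12 + 0.03 * g.uniform(-1, 1)
    eye_y = 0.42 + 0.03 * g.uniform(-1, 1)
    eye_r = 0.035 + 0.012 * g.uniform(-1, 1)
    mouth_w = 0.12 + 0.04 * g.uniform(-1, 1)
    mouth_y = 0.70 + 0.03 * g.uniform(-1, 1)
    nose_len = 0.12 + 0.03 * g.uniform(-1, 1)
    skin = 0.78 + 0.08 * g.uniform(-1, 1)

    img = np.ones((size, size), dtype=float)
    head = _soft_ellipse(yy, xx, 0.5, 0.5, head_ry, head_rx, softness=0.02)
    # gentle top-lit shading across the head
    shade = skin * (1.0 - 0.25 * (yy - 0.2) * head)
    img = img * (1 - head) + shade * head

    for sx in (-1, 1):
        ex = 0.5 + sx * eye_dx
        eye = _soft_ellipse(yy, xx, eye_y, ex, eye_r, eye_r * 1.5, softness=0.01)
        img = img * (1 - eye) + 0.12 * eye
        brow = _soft_ellipse(yy, xx, eye_y - 0.07, ex, 0.012, eye_r * 1.9, softness=0.01)
        img = img * (1 - brow) + 0.35 * brow

    nose = _soft_ellipse(yy, xx, eye_y + nose_len, 0.5, nose_len * 0.55, 0.018, softness=0.01)
    img = img * (1 - nose) + 0.45 * nose
    mouth = _soft_ellipse(yy, xx, mouth_y, 0.5, 0.022, mouth_w, softness=0.01)
    img = img * (1 - mouth) + 0.25 * mouth
    return np.clip(img, 0.0, 1.0)


def embed_face(image: StimulusImage, template: np.ndarray, position: tuple[int, int],
               face_id: int, mode: str = "multiply") -> StimulusImage:
    """Blend a face template into a noise pattern at (row, col).

    ``multiply`` multiplies template and pattern so circle noise overlays the
    face; ``replace`` overwrites the region with the template.
    """
    r, c = position
    fs = template.shape[0]
    n = image.pixels.shape[0]
    if not (0 <= r <= n - fs and 0 <= c <= n - fs):
        raise ValidationError("face must lie fully inside the canvas")
    pix = image.pixels.copy()
    if mode == "multiply":
        pix[r:r + fs, c:c + fs] *= template
    elif mode == "replace":
        pix[r:r + fs, c:c + fs] = template
    else:
        raise ValidationError(f"unknown blend mode {mode!r}")
    return StimulusImage(pixels=np.clip(pix, 0.0, 1.0), has_face=True,
                         face_position=(int(r), int(c)), face_id=int(face_id),
                         provenance=image.provenance + [STAGE_FACE])


def generate_stimulus_set(spec: StimulusSpec, rng: Optional[np.random.Generator] = None) -> list[StimulusImage]:
    """Build the full stimulus set (default 40 targets + 60 noise), shuffled.

    Targets receive a face template (identities cycled over
    ``n_distinct_faces``) after the speckle stage and before stage 3, at a
    uniform-random position fully inside the canvas.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    templates = [make_face_template(i, spec.face_size) for i in range(spec.n_distinct_faces)]
    stimuli: list[StimulusImage] = []
    flags = [True] * spec.n_targets + [False] * spec.n_noise
    face_ids = [i % spec.n_distinct_faces for i in range(spec.n_targets)]
    k = 0
    for has_face in flags:
        img = generate_noise_pattern(spec, rng)
        img = apply_speckle(img, spec.speckle_variance, rng)
        if has_face:
            hi = spec.image_size - spec.face_size
            pos = (int(rng.integers(0, hi + 1)), int(rng.integers(0, hi + 1)))
            img = embed_face(img, templates[face_ids[k]], pos, face_ids[k], mode=spec.blend_mode)
            k += 1
        img = apply_stage3(img, spec, rng)
        img = adjust_contrast(img, spec.contrast_out_range)
        stimuli.append(img)
    order = rng.permutation(len(stimuli))
    return [stimuli[i] for i in order]


def stimulus_manifest(stimuli: Sequence[StimulusImage], seed: Optional[int] = None) -> pd.DataFrame:
    """Ground-truth manifest: one row per stimulus."""
    rows = []
    for i, s in enumerate(stimuli):
        r, c = s.face_position if s.face_position is not None else (None, None)
        rows.append(dict(stimulus_id=i, has_face=int(s.has_face),
                         face_id=s.face_id, face_row=r, face_col=c, seed=seed))
    return pd.DataFrame(rows)


def export_stimulus_set(stimuli: Sequence[StimulusImage], out_dir: str | Path,
                        seed: Optional[int] = None) -> Path:
    """Write 8-bit grayscale PNGs plus a CSV manifest; returns the manifest path."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(stimuli):
        arr = np.round(s.pixels * 255.0).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out / f"stimulus_{i:03d}.png")
    manifest = stimulus_manifest(stimuli, seed=seed)
    path = out / "manifest.csv"
    manifest.to_csv(path, index=False)
    return path
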