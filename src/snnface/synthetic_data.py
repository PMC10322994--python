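"""Synthetic face-like imagery and synthetic unit-response populations.

The photographic face databases the models were designed around are
access-restricted, so every pipeline stage here runs on procedurally drawn
faces: anti-aliased ellipse/arc primitives (face outline, eyes, brows, mouth)
on the uniform gray-128 canvas, with class-conditioned geometry and
per-identity jitter.  The seven expression classes differ in mouth curvature
and opening, brow angle and raise, and eye aperture; the "happy" and
"surprised" classes receive the largest geometric deviations and
"sad"/"neutral" the smallest, mirroring which expressions shallow networks
find easiest and hardest.  Faces carry class information at several spatial
scales: coarse blob layout (low SF) and sharp part edges (high SF).

The module also synthesizes FC1-like SF tuning curves with a planted
reference-frame mix λ (0 = object-based, 1 = retina-based), used to validate
the peak-shift machinery: a unit built with mix λ has expected peak shift λ.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np
from PIL import Image, ImageDraw

from .sf_analysis import TuningRecord, make_tuning_record
from .stimuli import CANVAS, EXPRESSIONS, LabeledImageSet, center_sf_grid

_SS = 3  # supersampling factor for anti-aliased rendering


@dataclass(frozen=True)
class SyntheticFaceSpec:
    """Explicit geometry of one rendered face (all lengths in canvas px)."""

    expression: str
    identity: int
    face_rx: float = 62.0
    face_ry: float = 82.0
    face_gray: float = 190.0
    eye_dx: float = 26.0
    eye_y: float = 75.0
    eye_scale: float = 1.0
    brow_angle: float = 0.0  # radians; positive = inner ends raised
    brow_raise: float = 0.0  # px above default brow height
    mouth_y: float = 133.0
    mouth_w: float = 40.0
    mouth_open: float = 5.0  # band thickness, px
    mouth_curve: float = 0.0  # px; positive = corners raised (smile)


#: Class-conditional mean deviations from the neutral geometry.
_CLASS_MEANS: dict[str, dict[str, float]] = {
    "neutral": {},
    "happy": {"mouth_curve": 14.0, "mouth_open": 9.0, "mouth_w": 54.0},
    "sad": {"mouth_curve": -9.0, "mouth_open": 4.0, "brow_angle": 0.35, "eye_scale": 0.92},
    "angry": {"mouth_curve": -5.0, "brow_angle": -0.55, "eye_scale": 0.85, "brow_raise": -4.0},
    "fearful": {
        "mouth_open": 14.0,
        "eye_scale": 1.22,
        "brow_raise": 6.0,
        "brow_angle": 0.25,
        "mouth_w": 34.0,
        "mouth_curve": -3.0,
    },
    "disgusted": {
        "mouth_curve": -12.0,
        "mouth_open": 8.0,
        "brow_angle": -0.25,
        "eye_scale": 0.8,
        "mouth_w": 44.0,
    },
    "surprised": {"mouth_open": 24.0, "eye_scale": 1.45, "brow_raise": 9.0, "mouth_w": 26.0},
}

#: Identity-level jitter SDs (stable across a given individual's expressions).
_IDENTITY_JITTER = {
    "face_rx": 4.0,
    "face_ry": 4.0,
    "face_gray": 8.0,
    "eye_dx": 1.5,
    "eye_y": 2.0,
    "mouth_y": 2.0,
    "mouth_w": 3.0,
    "eye_scale": 0.05,
}

#: Expression-rendering jitter SDs (vary per identity × class).
_EXPRESSION_JITTER = {
    "mouth_curve": 1.5,
    "mouth_open": 1.2,
    "brow_angle": 0.05,
    "brow_raise": 1.0,
    "eye_scale": 0.04,
}

#: Geometry fields a linear read-out can use to separate the classes.
FEATURE_FIELDS = ("mouth_curve", "mouth_open", "mouth_w", "brow_angle", "brow_raise", "eye_scale")


def sample_face_spec(expression: str, identity: int, seed: int = 0) -> SyntheticFaceSpec:
    """Deterministic class-conditioned geometry for (expression, identity)."""
    if expression not in EXPRESSIONS:
        raise ValueError(f"unknown expression {expression!r}")
    base = {f.name: f.default for f in fields(SyntheticFaceSpec) if f.name not in
            ("expression", "identity")}
    base.update(_CLASS_MEANS[expression])
    id_rng = np.random.default_rng([seed, identity])
    for key in sorted(_IDENTITY_JITTER):
        base[key] += id_rng.normal(0.0, _IDENTITY_JITTER[key])
    ex_rng = np.random.default_rng([seed, identity, EXPRESSIONS.index(expression)])
    for key in sorted(_EXPRESSION_JITTER):
        base[key] += ex_rng.normal(0.0, _EXPRESSION_JITTER[key])
    return SyntheticFaceSpec(expression=expression, identity=identity, **base)


def geometry_features(spec: SyntheticFaceSpec) -> np.ndarray:
    return np.array([getattr(spec, f) for f in FEATURE_FIELDS], np.float64)


def generate_face_image(spec: SyntheticFaceSpec) -> np.ndarray:
    """Render a spec to a 198×198 uint8 image on the gray-128 background."""
    s = _SS
    cx = cy = CANVAS * s / 2.0
    im = Image.new("L", (CANVAS * s, CANVAS * s), 128)
    draw = ImageDraw.Draw(im)

    def ellipse(x, y, rx, ry, value):
        draw.ellipse(
            [(x - rx) * 1.0, (y - ry) * 1.0, (x + rx) * 1.0, (y + ry) * 1.0], fill=value
        )

    # face outline
    ellipse(cx, cy, spec.face_rx * s, spec.face_ry * s, int(round(spec.face_gray)))
    # eyes
    ex = spec.eye_dx * s
    ey = spec.eye_y * s
    erx = 9.0 * spec.eye_scale * s
    ery = 5.5 * spec.eye_scale * s
    ellipse(cx - ex, ey, erx, ery, 45)
    ellipse(cx + ex, ey, erx, ery, 45)
    # brows: straight bars above the eyes, rotated by brow_angle
    brow_y = ey - (14.0 + spec.brow_raise) * s
    half = 11.0 * s
    thick = 2.2 * s
    for side in (-1, 1):
        bx = cx + side * ex
        # inner end toward the nose; positive angle raises the inner end
        inner = -side
        dx = half * np.cos(spec.brow_angle)
        dy = half * np.sin(spec.brow_angle) * inner
        draw.line(
            [(bx - dx, brow_y + dy), (bx + dx, brow_y - dy)], fill=50, width=int(round(thick))
        )
    # mouth: curved band, corners displaced upward for positive curvature
    mw = spec.mouth_w * s
    my = spec.mouth_y * s
    xs = np.linspace(-mw / 2, mw / 2, 25)
    center_line = my + spec.mouth_curve * s * (1.0 - (2.0 * xs / mw) ** 2)
    t = max(spec.mouth_open * s, 1.5 * s)
    upper = [(cx + x, y - t / 2) for x, y in zip(xs, center_line)]
    lower = [(cx + x, y + t / 2) for x, y in zip(xs[::-1], center_line[::-1])]
    draw.polygon(upper + lower, fill=50)

    out = im.resize((CANVAS, CANVAS), Image.BILINEAR)
    return np.asarray(out, np.uint8)


def generate_dataset(n_individuals: int, seed: int = 0) -> LabeledImageSet:
    """7 × n_individuals base face images as a labeled, splittable set."""
    if n_individuals < 3:
        raise ValueError("need at least 3 individuals")
    images, expr, ident = [], [], []
    for identity in range(n_individuals):
        for expression in EXPRESSIONS:
            spec = sample_face_spec(expression, identity, seed)
            images.append(generate_face_image(spec))
            expr.append(expression)
            ident.append(identity)
    return LabeledImageSet.from_base(np.stack(images), expr, ident)


def separability_check(n_per_class: int = 100, seed: int = 0) -> float:
    """Held-out accuracy of a linear read-out on the geometry parameters.

    A multinomial logistic classifier (plain gradient descent) is fit on half
    the draws and scored on the other half; the class-conditional parameter
    distributions are built to keep this above 0.95.
    """
    feats, labels = [], []
    for c, expression in enumerate(EXPRESSIONS):
        for identity in range(n_per_class):
            feats.append(geometry_features(sample_face_spec(expression, identity, seed)))
            labels.append(c)
    X = np.asarray(feats)
    y = np.asarray(labels)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    X = np.column_stack([X, np.ones(len(X))])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(X))
    half = len(X) // 2
    tr, te = order[:half], order[half:]
    k = len(EXPRESSIONS)
    onehot = np.eye(k)[y[tr]]
    W = np.zeros((X.shape[1], k))
    for _ in range(500):  # softmax regression; full-batch GD converges easily here
        z = X[tr] @ W
        z -= z.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        W -= 0.5 * X[tr].T @ (p - onehot) / len(tr)
    pred = (X[te] @ W).argmax(axis=1)
    return float((pred == y[te]).mean())


# ---------------------------------------------------------------------------
# Synthetic SF-tuned units
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticUnitSpec:
    """A planted FC1-like unit with reference-frame mix λ.

    λ = 0 gives pure object-based tuning (size-invariant preferred SF);
    λ = 1 gives pure retina-based tuning (preferred object-based SF scales
    inversely with stimulus size).  The expected peak shift equals λ.
    """

    lam: float
    preferred_sf: float = 8.0  # cycles/object, mid-grid
    bandwidth_octaves: float = 1.0
    noise_sd: float = 0.0
    amplitude: float = 1.0


def synthetic_unit_curve(
    spec: SyntheticUnitSpec,
    size: int,
    grid: Optional[np.ndarray] = None,
    rng=None,
    ref_size: int = CANVAS,
) -> np.ndarray:
    """Gaussian tuning in log2 SF under the planted reference-frame mix.

    The unit responds to ``c · (ref_size/size)^λ`` — the object-based probe SF
    mapped toward retinal units by λ — so its object-based peak sits at
    ``preferred · (size/ref_size)^λ`` and the peak shift between sizes s1 > s2
    is exactly λ·log2(s1/s2)/log2(s1/s2) = λ.
    """
    grid = center_sf_grid() if grid is None else np.asarray(grid)
    eff = grid * (ref_size / size) ** spec.lam
    resp = spec.amplitude * np.exp(
        -((np.log2(eff) - np.log2(spec.preferred_sf)) ** 2)
        / (2.0 * spec.bandwidth_octaves**2)
    )
    if spec.noise_sd > 0:
        if rng is None:
            raise ValueError("noise requires an rng")
        resp = resp + rng.normal(0.0, spec.noise_sd, size=resp.shape)
    return resp


def generate_synthetic_unit_responses(
    spec: SyntheticUnitSpec,
    grid: Optional[np.ndarray] = None,
    sizes: tuple[int, int] = (CANVAS, CANVAS // 2),
    seed: int = 0,
    unit: int = 0,
    expression: str = "neutral",
) -> tuple[TuningRecord, TuningRecord]:
    """(large, small) TuningRecords for one planted unit."""
    grid = center_sf_grid() if grid is None else np.asarray(grid)
    rng = np.random.default_rng(seed)
    large_size, small_size = max(sizes), min(sizes)
    recs = []
    for size in (large_size, small_size):
        resp = synthetic_unit_curve(spec, size, grid, rng)
        recs.append(make_tuning_record(resp, unit, expression, size, grid))
    return recs[0], recs[1]


def generate_unit_population(
    lams: Sequence[float],
    n_units: int,
    noise_sd: float = 0.1,
    preferred_sf: float = 8.0,
    bandwidth_octaves: float = 1.0,
    seed: int = 0,
) -> list[tuple[TuningRecord, TuningRecord]]:
    """n_units record pairs per planted λ value (λ cycled over units)."""
    out = []
    for u in range(n_units):
        lam = lams[u % len(lams)]
        spec = SyntheticUnitSpec(
            lam=lam,
            preferred_sf=preferred_sf,
            bandwidth_octaves=bandwidth_octaves,
            noise_sd=noise_sd,
        )
        out.append(generate_synthetic_unit_responses(spec, seed=seed + u, unit=u))
    return out
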