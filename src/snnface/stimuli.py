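"""Image preparation: augmentation, splits, network inputs, SF probe stimuli.

Face images live on a 198×198 canvas with a uniform gray background (value
128).  Augmentation expands each base image 70-fold (7 sizes × 5 positions ×
2 horizontal flips); splitting is identity-stratified so no individual's
images leak between train/validation/test.

Bandpass probe stimuli for the spatial-frequency analysis are built in the
polar Fourier domain: the amplitude spectrum of a face image is flattened to
unity (phase preserved) and multiplied by a Gaussian in log2 radial frequency
with SD 2.4 octaves, centered on the requested object-based SF
(cycles per face-image width) and with peak amplitude inversely proportional
to the center SF so total luminance contrast is balanced across center SFs.
A size-s stimulus is the filtered s×s face pasted centered on the gray
198×198 canvas, so stimuli of sizes 198 and 99 share the same object-based
passband while their retina-based passbands differ by one octave.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

CANVAS = 198
GRAY = 128.0
NETWORK_INPUT = 227

AUGMENT_SIZES = (28, 56, 85, 113, 141, 170, 198)
#: (dx, dy) pixel displacements: center and the four diagonals, 10 px each way.
AUGMENT_POSITIONS = (
    ("center", 0, 0),
    ("left-top", -10, -10),
    ("right-top", 10, -10),
    ("left-bottom", -10, 10),
    ("right-bottom", 10, 10),
)
AUGMENT_FLIPS = (False, True)
AUGMENT_FACTOR = len(AUGMENT_SIZES) * len(AUGMENT_POSITIONS) * len(AUGMENT_FLIPS)  # 70

EXPRESSIONS = ("angry", "disgusted", "fearful", "happy", "sad", "surprised", "neutral")

BANDWIDTH_OCTAVES = 2.4
#: Global contrast gain of the bandpass filter; the peak amplitude of the
#: spectral Gaussian is BANDPASS_GAIN / center_sf.  The value puts the pixel
#: standard deviation of low-SF probes near 30 gray levels on the 0-255 scale.
BANDPASS_GAIN = 400.0


def _resize(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of a 2-D float array via PIL."""
    if image.shape[0] == image.shape[1] == size:
        return np.asarray(image, np.float32)
    im = Image.fromarray(np.asarray(image, np.float32), mode="F")
    return np.asarray(im.resize((size, size), Image.BILINEAR), np.float32)


# ---------------------------------------------------------------------------
# Labeled image sets
# ---------------------------------------------------------------------------


class LabeledImageSet:
    """Base face images plus per-item provenance for lazy augmentation.

    Items are rows of ``manifest`` (columns: base_index, expression, identity,
    size, position, flip); images are materialized on demand with
    :meth:`image`, so a 70×-augmented set costs no more memory than its base
    set.
    """

    def __init__(self, base_images: np.ndarray, manifest: pd.DataFrame):
        self.base_images = np.asarray(base_images)
        if self.base_images.ndim != 3 or self.base_images.shape[1:] != (CANVAS, CANVAS):
            raise ValueError(f"base images must be (n, {CANVAS}, {CANVAS})")
        required = {"base_index", "expression", "identity", "size", "position", "flip"}
        if not required <= set(manifest.columns):
            raise ValueError(f"manifest missing columns {required - set(manifest.columns)}")
        self.manifest = manifest.reset_index(drop=True)

    @classmethod
    def from_base(
        cls, base_images: np.ndarray, expression: Sequence, identity: Sequence
    ) -> "LabeledImageSet":
        n = len(base_images)
        manifest = pd.DataFrame(
            {
                "base_index": np.arange(n),
                "expression": list(expression),
                "identity": list(identity),
                "size": CANVAS,
                "position": "center",
                "flip": False,
            }
        )
        return cls(base_images, manifest)

    def __len__(self) -> int:
        return len(self.manifest)

    @property
    def expression(self) -> np.ndarray:
        return self.manifest["expression"].to_numpy()

    @property
    def identity(self) -> np.ndarray:
        return self.manifest["identity"].to_numpy()

    def image(self, i: int) -> np.ndarray:
        """Materialize item i as a float32 198×198 array."""
        row = self.manifest.iloc[i]
        base = np.asarray(self.base_images[int(row["base_index"])], np.float32)
        dx, dy = next((x, y) for name, x, y in AUGMENT_POSITIONS if name == row["position"])
        return _render_variant(base, int(row["size"]), dx, dy, bool(row["flip"]))

    def subset(self, mask: np.ndarray) -> "LabeledImageSet":
        return LabeledImageSet(self.base_images, self.manifest[mask])


def _render_variant(base: np.ndarray, size: int, dx: int, dy: int, flip: bool) -> np.ndarray:
    """Rescale the whole face image, paste on the gray canvas, clip at edges."""
    img = np.fliplr(base) if flip else base
    if size == CANVAS and dx == 0 and dy == 0:
        return np.asarray(img, np.float32).copy()
    patch = _resize(img, size)
    canvas = np.full((CANVAS, CANVAS), GRAY, np.float32)
    top = (CANVAS - size) // 2 + dy
    left = (CANVAS - size) // 2 + dx
    r0, r1 = max(top, 0), min(top + size, CANVAS)
    c0, c1 = max(left, 0), min(left + size, CANVAS)
    canvas[r0:r1, c0:c1] = patch[r0 - top : r1 - top, c0 - left : c1 - left]
    return canvas


def augment_image(base: np.ndarray) -> list[np.ndarray]:
    """The 70 deterministic augmentation variants of one base image."""
    base = np.asarray(base, np.float32)
    if base.shape != (CANVAS, CANVAS):
        raise ValueError(f"base image must be {CANVAS}×{CANVAS}, got {base.shape}")
    return [
        _render_variant(base, s, dx, dy, f)
        for s in AUGMENT_SIZES
        for _, dx, dy in AUGMENT_POSITIONS
        for f in AUGMENT_FLIPS
    ]


def augment_dataset(base_set: LabeledImageSet) -> LabeledImageSet:
    """Expand every item of a base set 70-fold (lazily; images on demand)."""
    rows = []
    for _, row in base_set.manifest.iterrows():
        for s in AUGMENT_SIZES:
            for name, _, _ in AUGMENT_POSITIONS:
                for f in AUGMENT_FLIPS:
                    rows.append(
                        {
                            "base_index": row["base_index"],
                            "expression": row["expression"],
                            "identity": row["identity"],
                            "size": s,
                            "position": name,
                            "flip": f,
                        }
                    )
    return LabeledImageSet(base_set.base_images, pd.DataFrame(rows))


def split_by_individual(
    dataset: LabeledImageSet, fractions: Sequence[float], seed: int
) -> tuple[LabeledImageSet, ...]:
    """Partition a set at identity granularity into train/validation/test.

    ``fractions`` are identity fractions and must resolve to whole identity
    counts.  Because every identity carries the same number of images of each
    expression, identity-level splitting automatically balances expressions
    within each split.
    """
    identities = np.unique(dataset.identity)
    counts = pd.Series(dataset.identity).value_counts()
    if counts.nunique() != 1:
        raise ValueError("every identity must have the same number of images")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_ids = len(identities)
    sizes = [f * n_ids for f in fractions]
    if any(abs(s - round(s)) > 1e-9 for s in sizes):
        raise ValueError(
            f"fractions {fractions} not realizable at identity granularity (n={n_ids})"
        )
    sizes = [int(round(s)) for s in sizes]
    rng = np.random.default_rng(seed)
    order = rng.permutation(identities)
    splits = []
    start = 0
    for s in sizes:
        chosen = set(order[start : start + s])
        mask = np.array([i in chosen for i in dataset.identity])
        splits.append(dataset.subset(mask))
        start += s
    return tuple(splits)


# ---------------------------------------------------------------------------
# Network input formatting
# ---------------------------------------------------------------------------


def prepare_input(image: np.ndarray) -> np.ndarray:
    """Grayscale square image in [0, 255] → 227×227×3 zero-centered input.

    Bilinear resize, replication to 3 channels, scaling by 1/255, and
    subtraction of the background gray level (128/255), so the uniform
    background maps to exactly 0 and pixel values lie in [-0.502, 0.498].
    Centering makes the first-layer filters respond to image contrast rather
    than to absolute luminance — without it the low-pass bank members produce
    a large common-mode response to the background itself, which destabilizes
    SGD at the protocol's fixed learning rate (see the methods note).
    """
    image = np.asarray(image, np.float32)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"expected a square grayscale image, got shape {image.shape}")
    resized = (_resize(image, NETWORK_INPUT) - GRAY) / 255.0
    return np.repeat(resized[:, :, None], 3, axis=2)


def prepare_batch(images: Sequence[np.ndarray]) -> np.ndarray:
    return np.stack([prepare_input(im) for im in images])


# ---------------------------------------------------------------------------
# Bandpass SF probes
# ---------------------------------------------------------------------------


def center_sf_grid() -> np.ndarray:
    """The 61-value center-SF ladder: 2^0 … 2^6 cycles/object in 0.1 log2 steps."""
    return 2.0 ** (0.1 * np.arange(61))


@dataclass(frozen=True)
class BandpassSpec:
    """One bandpass probe: center SF in cycles/object at a given face size."""

    center_sf: float
    size: int = CANVAS
    bandwidth_sd: float = BANDWIDTH_OCTAVES


def bandpass_filter_image(
    image: np.ndarray,
    center_sf: float,
    bandwidth_octaves: float = BANDWIDTH_OCTAVES,
    gain: float = BANDPASS_GAIN,
) -> np.ndarray:
    """Flatten the amplitude spectrum, impose a log-SF Gaussian, invert.

    ``center_sf`` is in cycles per image width of ``image``.  The Gaussian is
    isotropic (radial frequency only); its peak amplitude is ``gain /
    center_sf``.  The DC component is set to the gray-background level so the
    output remains a displayable image around gray 128.
    """
    image = np.asarray(image, np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square")
    if center_sf <= 0:
        raise ValueError("center SF must be positive")
    n = image.shape[0]
    spec = np.fft.fft2(image)
    amp = np.abs(spec)
    if np.all(amp == 0):
        raise ValueError("blank image: amplitude spectrum is all zero")
    # unit-amplitude spectrum, phase preserved (zero-amplitude cells -> 1)
    phase = np.where(amp > 0, spec / np.where(amp > 0, amp, 1.0), 1.0)
    fx = np.fft.fftfreq(n)
    fr = n * np.hypot(*np.meshgrid(fx, fx, indexing="ij"))  # cycles per image width
    with np.errstate(divide="ignore"):
        logf = np.log2(np.where(fr > 0, fr, 1.0))
    gauss = (gain / center_sf) * np.exp(
        -((logf - np.log2(center_sf)) ** 2) / (2.0 * bandwidth_octaves**2)
    )
    gauss[fr == 0] = 0.0
    # n²/CANVAS undoes the ifft 1/n² and makes pixel-domain contrast
    # independent of the image size (the fr grid spacing is 1 cycle/image
    # regardless of n, so the passband holds ~equally many cells at any size)
    filtered = np.real(np.fft.ifft2(phase * gauss * n * n / CANVAS))
    return (filtered + GRAY).astype(np.float32)


def make_bandpass_stimulus(
    face: np.ndarray, center_sf: float, size: int, gain: float = BANDPASS_GAIN
) -> np.ndarray:
    """Bandpass probe on the 198×198 canvas for one face, center SF, and size.

    The face image is rescaled to ``size``×``size`` (the object), filtered at
    ``center_sf`` cycles per object width, then pasted centered on the gray
    canvas.  Feed through :func:`prepare_input` to obtain the network input.
    """
    face = np.asarray(face, np.float32)
    if face.shape != (CANVAS, CANVAS):
        raise ValueError(f"face must be {CANVAS}×{CANVAS}")
    if not 0 < size <= CANVAS:
        raise ValueError(f"size must be in (0, {CANVAS}]")
    patch = bandpass_filter_image(_resize(face, size), center_sf, gain=gain)
    canvas = np.full((CANVAS, CANVAS), GRAY, np.float32)
    off = (CANVAS - size) // 2
    canvas[off : off + size, off : off + size] = patch
    return canvas


def bandpass_stimulus_batch(
    face: np.ndarray,
    center_sfs: Optional[np.ndarray] = None,
    size: int = CANVAS,
    gain: float = BANDPASS_GAIN,
) -> np.ndarray:
    """Network-ready inputs for one face over the center-SF ladder."""
    if center_sfs is None:
        center_sfs = center_sf_grid()
    return np.stack(
        [prepare_input(make_bandpass_stimulus(face, c, size, gain)) for c in center_sfs]
    )
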