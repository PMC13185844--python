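"""Layer-wise reconstruction quantification from light-sheet frames.

During printing, an orthogonal light sheet images each just-projected layer.
To avoid intersecting the meniscus, the sheet sits a fixed distance D_LS
below the projection plane, so recorded frame k shows the layer projected
``lag = D_LS / D_LH`` layers earlier (D_LH is the layer height).  The QC
chain here:

1. synthesize realistic light-sheet frames from a ground-truth slice stack
   (blur for the sheet thickness, depth attenuation, additive + speckle
   noise, a smooth background gradient),
2. segment each frame with a pluggable segmenter (a classical
   background-subtraction/threshold/morphology baseline is provided; a
   learned model can be dropped in behind the same frame->mask interface),
3. register each predicted mask to its lag-aligned ground-truth
   cross-section (translation only, cross-correlation peak), and
4. score each layer with the structural similarity index,
   delta_struct,k = SSIM_k in [0, 1], reporting the mean over scored layers
   and stacking masks back into a voxel volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, metrics, morphology, registration

from .errors import DomainError, NoScorableLayersError

__all__ = [
    "SliceStack",
    "FrameSequence",
    "OpticsModel",
    "ReconstructionReport",
    "slice_lag",
    "synth_frames",
    "baseline_segmenter",
    "segment_frame",
    "register_pair",
    "layer_ssim",
    "reconstruction_report",
    "stack_to_volume",
]

#: replicate count used for summary statistics of repeated reconstructions
DEFAULT_N_REPLICATES = 3


@dataclass(frozen=True)
class SliceStack:
    """Ground-truth binary cross-sections, one per printed layer."""

    masks: np.ndarray  # (K, rows, cols), binary
    layer_height_um: float = 50.0  # D_LH
    build_height_um: float | None = None

    def __post_init__(self):
        m = np.asarray(self.masks)
        if m.ndim != 3:
            raise DomainError("slice stack must be (K, rows, cols)")
        object.__setattr__(self, "masks", (m > 0).astype(np.uint8))
        if self.build_height_um is None:
            object.__setattr__(
                self, "build_height_um", self.layer_height_um * m.shape[0]
            )

    @property
    def n_layers(self) -> int:
        return self.masks.shape[0]


@dataclass(frozen=True)
class OpticsModel:
    """Synthetic light-sheet imaging artefacts.

    ``blur_sigma`` emulates the finite sheet thickness, ``attenuation`` the
    per-layer intensity loss from propagation through already-printed
    material, and the noise terms sensor + speckle statistics.
    """

    blur_sigma: float = 1.0  # px
    attenuation: float = 0.002  # per layer, foreground intensity decay
    noise_sd: float = 0.02  # additive Gaussian, on unit range
    speckle_sd: float = 0.05  # multiplicative, foreground only
    background_level: float = 0.08  # baseline background intensity
    background_slope: float = 0.04  # in-plane gradient amplitude
    foreground_level: float = 0.85  # undimmed foreground intensity


@dataclass(frozen=True)
class FrameSequence:
    """Ordered grayscale light-sheet frames plus acquisition geometry."""

    frames: np.ndarray  # (K, rows, cols), float in [0, 1]
    sheet_offset_um: float  # D_LS
    layer_height_um: float  # D_LH
    optics: OpticsModel = field(default_factory=OpticsModel)
    seed: int | None = None

    def __post_init__(self):
        if self.sheet_offset_um < 0:
            raise DomainError("sheet offset must be non-negative")

    @property
    def lag(self) -> int:
        return slice_lag(self.sheet_offset_um, self.layer_height_um)


@dataclass(frozen=True)
class ReconstructionReport:
    """Per-layer SSIM scores and their mean."""

    per_layer: tuple[float, ...]  # delta_struct,k in [0, 1]
    mean_delta: float
    lag_layers: int
    n_layers_scored: int
    n_layers_excluded: int = 0


def slice_lag(sheet_offset_um: float, layer_height_um: float) -> int:
    """Integer index lag D_LS / D_LH between projected and recorded slices.

    The physical offsets divide exactly in a well-configured system; a
    non-integer ratio is rounded to the nearest layer with a warning, since
    any remainder signals misconfiguration.
    """
    if layer_height_um <= 0:
        raise DomainError("layer height must be positive")
    if sheet_offset_um < 0:
        raise DomainError("sheet offset must be non-negative")
    ratio = sheet_offset_um / layer_height_um
    lag = int(np.floor(ratio + 0.5))
    if abs(ratio - lag) > 1e-9:
        warnings.warn(
            f"sheet offset {sheet_offset_um} um is not a multiple of layer height "
            f"{layer_height_um} um; rounding lag {ratio:.3f} -> {lag}",
            stacklevel=2,
        )
    return lag


def synth_frames(
    truth: SliceStack,
    optics: OpticsModel | None = None,
    sheet_offset_um: float = 500.0,
    rng: np.random.Generator | None = None,
) -> FrameSequence:
    """Render synthetic light-sheet frames from a ground-truth stack.

    Frame k images truth layer k - lag; frames recorded before the sheet
    reaches the first printed layer contain background only.  Foreground
    intensity decays with the *truth* layer depth (light traverses everything
    printed below), then sheet-thickness blur, speckle on the foreground,
    a smooth background gradient and additive sensor noise are applied.
    Bit-reproducible for a fixed generator state.
    """
    optics = OpticsModel() if optics is None else optics
    rng = np.random.default_rng() if rng is None else rng
    lag = slice_lag(sheet_offset_um, truth.layer_height_um)
    k_total, rows, cols = truth.masks.shape

    jj = np.linspace(0.0, 1.0, cols)[None, :]
    background = optics.background_level + optics.background_slope * jj
    background = np.broadcast_to(background, (rows, cols))

    frames = np.empty((k_total, rows, cols), dtype=float)
    for k in range(k_total):
        t_idx = k - lag
        if t_idx < 0:
            fg = np.zeros((rows, cols))
        else:
            level = optics.foreground_level * np.exp(-optics.attenuation * t_idx)
            fg = truth.masks[t_idx].astype(float) * level
        if optics.speckle_sd > 0:
            fg = fg * (1.0 + rng.normal(0.0, optics.speckle_sd, fg.shape))
        if optics.blur_sigma > 0:
            fg = ndimage.gaussian_filter(fg, optics.blur_sigma)
        frame = background * (1.0 - np.clip(fg, 0, 1)) + fg
        if optics.noise_sd > 0:
            frame = frame + rng.normal(0.0, optics.noise_sd, frame.shape)
        frames[k] = np.clip(frame, 0.0, 1.0)
    return FrameSequence(
        frames=frames,
        sheet_offset_um=sheet_offset_um,
        layer_height_um=truth.layer_height_um,
        optics=optics,
    )


def baseline_segmenter(
    frame: np.ndarray,
    background_sigma: float = 25.0,
    min_object_px: int = 16,
    closing_radius: int = 1,
) -> np.ndarray:
    """Classical frame->mask baseline.

    Large-scale background subtraction, Otsu threshold, morphological
    open/close, small-component removal.  Returns a uint8 {0, 1} mask; an
    empty mask is a valid result for background-only frames.
    """
    frame = np.asarray(frame, dtype=float)
    background = ndimage.gaussian_filter(frame, background_sigma)
    detail = frame - background
    spread = float(detail.max() - detail.min())
    if spread < 0.05:  # flat frame: nothing printed in view
        return np.zeros(frame.shape, dtype=np.uint8)
    # Otsu seed refined by isodata iteration: the midpoint between class
    # means lands in the inter-class gap even when the foreground is tiny
    thresh = filters.threshold_otsu(detail)
    for _ in range(50):
        lo, hi = detail[detail <= thresh], detail[detail > thresh]
        if not (lo.size and hi.size):
            break
        new = 0.5 * (lo.mean() + hi.mean())
        if abs(new - thresh) < 1e-9:
            break
        thresh = new
    lo, hi = detail[detail <= thresh], detail[detail > thresh]
    if lo.size and hi.size:
        # foreground must be genuinely separated from background, not just
        # the upper tail of its noise: otherwise the frame holds no structure
        if hi.mean() - lo.mean() < 2.5 * (lo.std() + hi.std()):
            return np.zeros(frame.shape, dtype=np.uint8)
    mask = detail > thresh
    footprint = morphology.disk(closing_radius)
    # opening/closing by reconstruction: kills specks and fills pinholes while
    # leaving every surviving object's boundary exactly intact
    seed = ndimage.binary_erosion(mask, footprint)
    mask = ndimage.binary_propagation(seed, mask=mask)
    inv = ~mask
    seed = ndimage.binary_erosion(inv, footprint, border_value=1)
    mask = ~ndimage.binary_propagation(seed, mask=inv, border_value=1)
    labels, n = ndimage.label(mask)
    if n:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = np.isin(labels, np.flatnonzero(sizes >= min_object_px))
    return mask.astype(np.uint8)


Segmenter = Callable[[np.ndarray], np.ndarray]


def segment_frame(frame: np.ndarray, segmenter: Segmenter | None = None) -> np.ndarray:
    """Binary mask from a grayscale frame via the configured segmenter."""
    segmenter = baseline_segmenter if segmenter is None else segmenter
    return (np.asarray(segmenter(frame)) > 0).astype(np.uint8)


def register_pair(
    pred: np.ndarray, truth: np.ndarray, max_shift: int = 10
) -> np.ndarray:
    """Translate ``pred`` onto ``truth`` by the cross-correlation peak.

    Translation-only (print/camera drift dominates); the recovered shift is
    rounded to integer pixels for mask comparison and clipped to
    ``max_shift`` in each axis.  Identical images give zero shift.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise DomainError("register_pair requires equal shapes")
    if pred.max() == pred.min() or truth.max() == truth.min():
        return pred  # constant image: correlation undefined, leave unshifted
    shift, _, _ = registration.phase_cross_correlation(
        truth, pred, upsample_factor=4, normalization=None
    )
    shift = np.clip(np.round(shift[:2]), -max_shift, max_shift)
    if np.all(shift == 0):
        return pred
    return ndimage.shift(pred, shift, order=0, mode="constant", cval=0.0)


def layer_ssim(
    pred: np.ndarray,
    truth: np.ndarray,
    win_size: int = 11,
    sigma: float = 1.5,
) -> float:
    """Structural similarity delta_struct,k between two masks, in [0, 1].

    Binary inputs are treated as unit-range scalar images; an 11x11 Gaussian
    window (sd 1.5) with the standard stability constants is used, and the
    result is clipped into [0, 1].
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise DomainError("layer_ssim requires equal shapes")
    score = metrics.structural_similarity(
        pred,
        truth,
        win_size=win_size,
        gaussian_weights=True,
        sigma=sigma,
        use_sample_covariance=False,
        data_range=1.0,
    )
    return float(np.clip(score, 0.0, 1.0))


def reconstruction_report(
    frames: FrameSequence,
    truth: SliceStack,
    segmenter: Segmenter | None = None,
    register: bool = True,
    max_shift: int = 10,
) -> ReconstructionReport:
    """Lag-aligned per-layer SSIM scores and their mean.

    Frame k is segmented and compared to truth layer k - lag; frames with no
    lagged counterpart (the first ``lag`` frames, or indices past the truth
    stack) are excluded from the mean and counted.
    """
    lag = frames.lag
    k_total = frames.frames.shape[0]
    scores: list[float] = []
    excluded = 0
    for k in range(k_total):
        t_idx = k - lag
        if t_idx < 0 or t_idx >= truth.n_layers:
            excluded += 1
            continue
        mask = segment_frame(frames.frames[k], segmenter)
        ref = truth.masks[t_idx]
        if register:
            mask = register_pair(mask, ref, max_shift=max_shift)
        scores.append(layer_ssim(mask, ref))
    if not scores:
        raise NoScorableLayersError("no frame has a lag-aligned ground-truth layer")
    return ReconstructionReport(
        per_layer=tuple(scores),
        mean_delta=float(np.mean(scores)),
        lag_layers=lag,
        n_layers_scored=len(scores),
        n_layers_excluded=excluded,
    )


def stack_to_volume(masks: Sequence[np.ndarray] | np.ndarray, layer_height_um: float = 50.0):
    """Stack segmented cross-sections along the print direction.

    Returns a (rows, cols, K) occupancy grid whose z-pitch is the layer
    height.  All masks must share one shape.
    """
    masks = [np.asarray(m) for m in masks]
    if not masks:
        return np.zeros((0, 0, 0), dtype=np.uint8)
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise DomainError("all masks must share the same shape")
    return np.stack([(m > 0).astype(np.uint8) for m in masks], axis=-1)
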