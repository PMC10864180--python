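"""Selective patch-pair extraction with a foreground-coverage stopping rule.

Training pairs are cut from a co-registered degraded/ground-truth volume at
centers drawn from a per-voxel extraction probability.  Voxels are classified
foreground/background by an Otsu intensity threshold, and a tunable weight
``B`` fixes the total probability mass on foreground:

    P(i,j,k) = B / N_f        for foreground voxels,
    P(i,j,k) = (1 - B) / N_b  for background voxels,

where ``N_f`` and ``N_b`` count the two classes.  ``B = N_f / N`` recovers
the homogeneous distribution ``P = 1/N`` exactly; the working default
``B = 0.9`` admits only ~10 % background-centered patches.  Extraction is
iterated in batches and stops once the fraction of foreground voxels covered
by at least one extracted patch reaches the coverage target (default 95 %).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateInputError,
    GeometryError,
    InfeasibleWeightingError,
    InvalidConfigError,
)
from .phantom import PairedVolume

#: centers drawn between two coverage evaluations
COVERAGE_BATCH = 50


@dataclass
class SamplingConfig:
    """Patch-extraction parameters.

    ``patch_shape`` is in voxels, ``(z, y, x)`` order; the working default
    (32, 128, 128) corresponds to the conventional 128×128×32 (rows × cols ×
    planes) citation.  ``B`` is the foreground probability mass, ``coverage_target``
    the foreground-coverage fraction at which extraction stops.
    """

    patch_shape: tuple[int, int, int] = (32, 128, 128)
    B: float = 0.9
    coverage_target: float = 0.95
    max_patches: int = 2000
    otsu_bins: int = 256
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.B <= 1.0):
            raise InvalidConfigError(f"B must lie in [0, 1], got {self.B}")
        if not (0.0 < self.coverage_target <= 1.0):
            raise InvalidConfigError(
                f"coverage_target must lie in (0, 1], got {self.coverage_target}"
            )
        if self.max_patches < 1:
            raise InvalidConfigError("max_patches must be >= 1")
        if self.otsu_bins < 2:
            raise InvalidConfigError("otsu_bins must be >= 2")
        self.patch_shape = tuple(int(p) for p in self.patch_shape)
        if any(p < 1 for p in self.patch_shape):
            raise InvalidConfigError("patch_shape entries must be >= 1")


@dataclass
class ProbabilityField:
    """Per-voxel extraction probability with its Otsu classification."""

    p: np.ndarray  # per-voxel probability, sums to 1
    foreground: np.ndarray  # boolean mask, True where value > threshold
    threshold: float
    n: int
    n_f: int
    n_b: int


@dataclass
class PatchPair:
    """Co-located degraded/ground-truth sub-volumes.

    ``center`` is the voxel the pair was drawn at; the patch occupies
    ``[center - p//2, center - p//2 + p)`` along each axis.
    """

    degraded_patch: np.ndarray
    truth_patch: np.ndarray
    center: tuple[int, int, int]
    is_foreground_center: bool
    registration_offset: tuple[int, int, int] = (0, 0, 0)


@dataclass
class ExtractionResult:
    """Output of :func:`extract_training_set`."""

    pairs: list[PatchPair]
    coverage_trace: list[float]
    threshold: float
    status: str  # "converged" | "max_patches"
    config: SamplingConfig = field(repr=False, default=None)

    @property
    def coverage(self) -> float:
        return self.coverage_trace[-1] if self.coverage_trace else 0.0


def otsu_threshold(volume: np.ndarray, bins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance.

    The volume is binned over its min–max range; the returned threshold is
    the upper edge of the last background bin, with ties broken toward the
    lower threshold.  Foreground is ``value > threshold``.
    """
    v = np.asarray(volume).ravel()
    vmin, vmax = float(v.min()), float(v.max())
    if vmin == vmax:
        raise DegenerateInputError("cannot threshold a constant volume")
    hist, edges = np.histogram(v, bins=bins, range=(vmin, vmax))
    hist = hist.astype(np.float64)
    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    centers = (edges[:-1] + edges[1:]) / 2.0
    cum_mass = np.cumsum(hist * centers)
    total_mass = cum_mass[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = cum_mass / w0
        m1 = (total_mass - cum_mass) / w1
        var_between = w0 * w1 * (m0 - m1) ** 2
    var_between[~np.isfinite(var_between)] = -np.inf
    # cut after bin i -> threshold is the edge between bins i and i+1;
    # argmax returns the first (lowest) maximizer
    i = int(np.argmax(var_between[:-1]))
    return float(edges[i + 1])


def build_probability_field(volume: np.ndarray,
                            config: SamplingConfig) -> ProbabilityField:
    """Selective per-voxel extraction probability from an Otsu split."""
    data = np.asarray(volume, dtype=np.float64)
    threshold = otsu_threshold(data, config.otsu_bins)
    fg = data > threshold
    n = data.size
    n_f = int(fg.sum())
    n_b = n - n_f
    if config.B > 0 and n_f == 0:
        raise InfeasibleWeightingError("B > 0 but the volume has no foreground")
    if config.B < 1 and n_b == 0:
        raise InfeasibleWeightingError("B < 1 but the volume has no background")
    p = np.empty(data.shape, dtype=np.float64)
    if n_f:
        p[fg] = config.B / n_f
    if n_b:
        p[~fg] = (1.0 - config.B) / n_b
    return ProbabilityField(p=p, foreground=fg, threshold=threshold,
                            n=n, n_f=n_f, n_b=n_b)


def admissible_center_bounds(volume_shape, patch_shape):
    """Half-open per-axis center ranges for fully-contained patches.

    A patch centered at ``c`` spans ``[c - p//2, c - p//2 + p)``; admissible
    centers along an axis of size ``S`` are ``[p//2, S - p + p//2)``.
    """
    bounds = []
    for s, p in zip(volume_shape, patch_shape):
        lo, hi = p // 2, s - p + p // 2
        if hi <= lo:
            raise GeometryError(
                f"patch extent {p} does not fit in axis of size {s}"
            )
        bounds.append((lo, hi))
    return bounds


def patch_slices(center, patch_shape):
    """Slices of the block belonging to a patch center."""
    return tuple(
        slice(c - p // 2, c - p // 2 + p) for c, p in zip(center, patch_shape)
    )


def _admissible_mask(shape, patch_shape):
    adm = np.zeros(shape, dtype=bool)
    bounds = admissible_center_bounds(shape, patch_shape)
    adm[tuple(slice(lo, hi) for lo, hi in bounds)] = True
    return adm


def sample_patch_centers(field: ProbabilityField, n: int, patch_shape,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` i.i.d. patch centers from the extraction probability.

    The field is restricted to the admissible region (centers whose patch
    fits entirely inside the volume) and renormalized per class, so the
    foreground mass stays exactly ``B`` wherever both classes survive the
    restriction.  Returns an ``(n, 3)`` integer array in draw order.
    """
    if n < 1:
        raise InvalidConfigError(f"n must be >= 1, got {n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    adm = _admissible_mask(field.p.shape, patch_shape)
    fg_idx = np.flatnonzero((field.foreground & adm).ravel())
    bg_idx = np.flatnonzero((~field.foreground & adm).ravel())
    if fg_idx.size == 0 and bg_idx.size == 0:
        raise GeometryError("no admissible patch centers")
    # class masses: B on foreground, 1-B on background; a class emptied by
    # the border restriction cedes its mass to the other
    b_eff = _effective_foreground_mass(field, fg_idx.size, bg_idx.size)
    k_fg = rng.binomial(n, b_eff)
    picks = np.empty(n, dtype=np.int64)
    fg_draws = fg_idx[rng.integers(0, fg_idx.size, k_fg)] if k_fg else []
    bg_draws = bg_idx[rng.integers(0, bg_idx.size, n - k_fg)] if n - k_fg else []
    picks[:k_fg] = fg_draws
    picks[k_fg:] = bg_draws
    rng.shuffle(picks)
    return np.stack(np.unravel_index(picks, field.p.shape), axis=1)


def _effective_foreground_mass(field: ProbabilityField, n_fg_adm: int,
                               n_bg_adm: int) -> float:
    """Probability of drawing a foreground center after border restriction.

    Foreground keeps its total mass B when both classes survive the border
    restriction; a class with no admissible voxel cedes its mass to the other.
    """
    if n_fg_adm == 0:
        return 0.0
    if n_bg_adm == 0:
        return 1.0
    return float(field.p[field.foreground].sum()) if field.n_f else 0.0


def compute_coverage(centers, patch_shape, foreground_mask: np.ndarray) -> float:
    """Fraction of foreground voxels covered by at least one patch."""
    fg = np.asarray(foreground_mask, dtype=bool)
    n_f = int(fg.sum())
    if n_f == 0:
        raise DegenerateInputError("foreground mask is empty")
    covered = np.zeros(fg.shape, dtype=bool)
    for c in centers:
        covered[patch_slices(tuple(int(x) for x in c), patch_shape)] = True
    return float(np.count_nonzero(covered & fg)) / n_f


def extract_training_set(paired: PairedVolume,
                         config: SamplingConfig) -> ExtractionResult:
    """Iteratively sample patch pairs until foreground coverage is reached.

    Centers are drawn in batches of :data:`COVERAGE_BATCH`; after each batch
    the coverage of the foreground by the union of all extracted patches is
    appended to the trace.  Extraction stops at ``coverage_target`` or at
    ``max_patches`` (the latter flags ``status="max_patches"`` instead of
    raising).  Patches reference the source arrays as views; callers that
    mutate patches should copy first.
    """
    if paired.degraded is None or paired.ground_truth is None:
        raise InvalidConfigError("paired volume must carry both channels")
    deg = paired.degraded.data
    truth = paired.ground_truth.data
    if deg.shape != truth.shape:
        raise InvalidConfigError("channels differ in shape")

    field_ = build_probability_field(deg, config)
    rng = np.random.default_rng(config.seed)
    fg = field_.foreground
    covered = np.zeros(fg.shape, dtype=bool)
    n_f = int(fg.sum())

    pairs: list[PatchPair] = []
    trace: list[float] = []
    status = "max_patches"
    while len(pairs) < config.max_patches:
        batch = min(COVERAGE_BATCH, config.max_patches - len(pairs))
        centers = sample_patch_centers(field_, batch, config.patch_shape, rng=rng)
        for c in centers:
            c = tuple(int(x) for x in c)
            sl = patch_slices(c, config.patch_shape)
            pairs.append(PatchPair(
                degraded_patch=deg[sl],
                truth_patch=truth[sl],
                center=c,
                is_foreground_center=bool(fg[c]),
            ))
            covered[sl] = True
        trace.append(float(np.count_nonzero(covered & fg)) / n_f)
        if trace[-1] >= config.coverage_target:
            status = "converged"
            break
    return ExtractionResult(pairs=pairs, coverage_trace=trace,
                            threshold=field_.threshold, status=status,
                            config=config)
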