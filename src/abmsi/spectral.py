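"""Per-pixel spectral processing and criterion-based peptide annotation.

The processing chain mirrors standard MSI practice for reflector-TOF peptide
imaging: morphological (top-hat) baseline subtraction, weak per-spectrum
denoising without any spatial smoothing, TIC normalisation, SNR-gated peak
detection, and annotation of A-beta variants against a theoretical mass list.
A species counts as *detected* in a pixel only when (i) a peak sits at the
expected [M+H]+ within the m/z tolerance, (ii) that signal clears the SNR
threshold, and (iii) the observed isotope envelope matches the theoretical
one. Variants whose envelopes overlap on the m/z axis are resolved jointly by
non-negative least squares over the local spectrum segment.

All heavy operations are implemented on (n_pixels, n_mz) matrices so whole
datasets can be processed in chunks; the single-``Spectrum`` API wraps the
matrix kernels with one-row inputs, which guarantees that per-pixel and batch
processing agree bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage, optimize, signal

from .masslist import PeptideVariant

__all__ = [
    "Spectrum",
    "Peak",
    "PeakList",
    "ProcessingConfig",
    "AnnotationResult",
    "InvalidConfigError",
    "AmbiguityError",
    "subtract_baseline",
    "weak_denoise",
    "tic_normalize",
    "estimate_noise",
    "detect_peaks",
    "annotate_peptides",
    "deconvolve_envelopes",
    "process_matrix",
    "annotate_matrix",
    "overlap_groups",
]

MAD_TO_SD = 1.4826


class InvalidConfigError(ValueError):
    pass


class AmbiguityError(ValueError):
    """Two variants with numerically indistinguishable envelopes."""


@dataclass
class Spectrum:
    """One profile spectrum: intensities on a strictly increasing m/z axis."""

    mz: np.ndarray
    intensities: np.ndarray
    pixel_id: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.mz.shape != self.intensities.shape:
            raise ValueError("mz and intensity lengths differ")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")


@dataclass(frozen=True)
class Peak:
    mz: float
    height: float
    sigma: float

    @property
    def snr(self) -> float:
        return self.height / self.sigma if self.sigma > 0 else np.inf


PeakList = list[Peak]


@dataclass(frozen=True)
class ProcessingConfig:
    """Thresholds and windows of the processing chain.

    ``baseline_window`` is the structuring-element width of the top-hat filter
    (Da); ``mz_tolerance`` the annotation match window in ppm;
    ``envelope_min_cosine`` the minimum cosine similarity between theoretical
    and observed envelopes (the envelope-presence criterion); ``peak_fwhm`` the assumed
    instrument peak width used when rendering theoretical envelopes for
    deconvolution; ``envelope_sample_min_p`` restricts envelope sampling to
    isotopologues that carry meaningful probability mass.
    """

    baseline_window: float = 15.0
    mz_tolerance: float = 200.0
    snr_threshold: float = 3.0
    envelope_min_cosine: float = 0.8
    denoise: str = "weak"
    tic_target: float = 1.0
    noise_window: float = 50.0
    peak_fwhm: float = 0.625
    envelope_sample_min_p: float = 1e-3
    overlap_window: float = 2.0
    spike_clip_factor: float = 3.0

    def __post_init__(self) -> None:
        if min(self.baseline_window, self.mz_tolerance, self.snr_threshold,
               self.noise_window, self.peak_fwhm, self.tic_target) <= 0:
            raise InvalidConfigError("thresholds and windows must be positive")
        if not 0.0 < self.envelope_min_cosine <= 1.0:
            raise InvalidConfigError("envelope_min_cosine must be in (0, 1]")
        if self.denoise not in ("none", "weak"):
            raise InvalidConfigError("denoise must be 'none' or 'weak'")


@dataclass
class AnnotationResult:
    """Per-pixel, per-variant annotation of one processed dataset chunk.

    ``abundance`` holds normalized-intensity abundances (0 where a variant is
    neither detected nor assigned a positive deconvolution share); the three
    flag matrices record the individual detection criteria.
    """

    variant_names: list[str]
    abundance: np.ndarray          # (n_pixels, n_variants) float
    detected: np.ndarray           # bool
    mz_match: np.ndarray           # bool
    snr_pass: np.ndarray           # bool
    envelope_pass: np.ndarray      # bool
    empty_pixels: np.ndarray       # (n_pixels,) bool: all-zero spectra

    def __post_init__(self) -> None:
        if np.any(self.abundance < 0):
            raise ValueError("abundances must be non-negative")


# ---------------------------------------------------------------------------
# matrix kernels

def _window_samples(mz: np.ndarray, window_da: float) -> int:
    """Odd sample count spanning ``window_da`` on a (near-)uniform axis."""
    step = float(np.median(np.diff(mz)))
    n = max(3, int(round(window_da / step)))
    return n + 1 if n % 2 == 0 else n


def subtract_baseline_matrix(Y: np.ndarray, mz: np.ndarray, baseline_window: float) -> np.ndarray:
    span = float(mz[-1] - mz[0])
    if baseline_window >= span:
        raise InvalidConfigError("baseline window must be smaller than the m/z span")
    size = _window_samples(mz, baseline_window)
    eroded = ndimage.minimum_filter1d(Y, size, axis=-1, mode="nearest")
    opened = ndimage.maximum_filter1d(eroded, size, axis=-1, mode="nearest")
    return Y - opened


def weak_denoise_matrix(Y: np.ndarray, spike_clip_factor: float = 3.0) -> np.ndarray:
    """Light spectral smoothing plus hot-sample clipping; no spatial mixing.

    A short Savitzky-Golay filter (window 5, order 2) suppresses
    single-sample noise; isolated hot samples (detector spikes) are capped at
    ``spike_clip_factor`` times the per-spectrum 99.9th intensity percentile,
    which leaves genuine peak tops (many correlated samples) untouched.
    """
    if Y.shape[-1] >= 5:
        out = signal.savgol_filter(Y, 5, 2, axis=-1)
    else:
        out = Y.copy()
    np.maximum(out, 0.0, out=out)
    cap = spike_clip_factor * np.quantile(out, 0.999, axis=-1, keepdims=True)
    positive = cap[..., 0] > 0
    if np.any(positive):
        np.minimum(out, np.where(cap > 0, cap, np.inf), out=out)
    return out


def tic_normalize_matrix(Y: np.ndarray, tic_target: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Scale each spectrum to total intensity ``tic_target``.

    Returns the scaled matrix and a boolean mask of empty (all-zero) spectra,
    which are flagged for exclusion from downstream statistics.
    """
    sums = Y.sum(axis=-1, keepdims=True)
    empty = sums[..., 0] <= 0
    scale = np.divide(tic_target, sums, out=np.zeros_like(sums), where=sums > 0)
    return Y * scale, empty


def estimate_noise_matrix(Y: np.ndarray, mz: np.ndarray, noise_window: float) -> np.ndarray:
    """Per-sample robust noise level: windowed MAD scaled to Gaussian sd.

    The MAD is evaluated on tiling windows of ``noise_window`` Da and
    broadcast to the samples of each window; this is robust to sparse peaks
    occupying a minority of a window.
    """
    n = Y.shape[-1]
    block = _window_samples(mz, noise_window)
    n_blocks = max(1, n // block)
    trimmed = n_blocks * block
    body = Y[..., :trimmed].reshape(*Y.shape[:-1], n_blocks, block)
    if block >= 100:
        # a systematic subsample per window is ample for a robust scale
        # estimate and several-fold cheaper on large datacubes
        body = body[..., ::4]
    med = np.median(body, axis=-1, keepdims=True)
    mad = np.median(np.abs(body - med), axis=-1)
    sigma_blocks = MAD_TO_SD * mad
    sigma = np.repeat(sigma_blocks, block, axis=-1)
    if trimmed < n:
        tail = Y[..., trimmed:]
        med_t = np.median(tail, axis=-1, keepdims=True)
        mad_t = np.median(np.abs(tail - med_t), axis=-1, keepdims=True)
        sigma = np.concatenate(
            [sigma, np.repeat(MAD_TO_SD * mad_t, n - trimmed, axis=-1)], axis=-1
        )
    return sigma


def process_matrix(
    Y: np.ndarray, mz: np.ndarray, cfg: ProcessingConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-order chain: baseline -> weak denoise -> TIC normalise.

    Returns processed spectra and the empty-pixel mask.
    """
    Y = np.asarray(Y)
    if Y.dtype not in (np.float32, np.float64):
        Y = Y.astype(np.float64)
    out = subtract_baseline_matrix(Y, mz, cfg.baseline_window)
    if cfg.denoise == "weak":
        out = weak_denoise_matrix(out, cfg.spike_clip_factor)
    else:
        np.maximum(out, 0.0, out=out)
    out, empty = tic_normalize_matrix(out, cfg.tic_target)
    return out, empty


def _local_maxima_snr(Y: np.ndarray, sigma: np.ndarray, snr_threshold: float) -> np.ndarray:
    """Boolean mask of local maxima exceeding the SNR threshold."""
    mask = np.zeros(Y.shape, dtype=bool)
    core = (Y[..., 1:-1] > Y[..., :-2]) & (Y[..., 1:-1] >= Y[..., 2:])
    mask[..., 1:-1] = core & (Y[..., 1:-1] > snr_threshold * sigma[..., 1:-1])
    return mask


def _parabolic_apex(Y: np.ndarray, idx: np.ndarray, rows: np.ndarray, mz: np.ndarray):
    """3-point parabolic apex refinement for peaks at (rows, idx)."""
    step = np.diff(mz).mean()
    y0 = Y[rows, idx - 1]
    y1 = Y[rows, idx]
    y2 = Y[rows, idx + 1]
    denom = y0 - 2 * y1 + y2
    delta = np.where(np.abs(denom) > 0, 0.5 * (y0 - y2) / np.where(denom == 0, 1, denom), 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    apex_mz = mz[idx] + delta * step
    apex_h = y1 - 0.25 * (y0 - y2) * delta
    return apex_mz, apex_h


def _sample_at(Y: np.ndarray, mz: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Observed intensity at exact m/z positions via local parabolic fit.

    For each requested position the three samples around the nearest grid
    point are fit with a parabola and evaluated at the position, which
    corrects the sub-sample attenuation a plain nearest-sample lookup would
    incur. Values are clipped at zero.
    """
    step = np.diff(mz).mean()
    j = np.clip(np.round((positions - mz[0]) / step).astype(int), 1, len(mz) - 2)
    x = (positions - mz[j]) / step
    y0, y1, y2 = Y[..., j - 1], Y[..., j], Y[..., j + 1]
    val = y1 + 0.5 * (y2 - y0) * x + 0.5 * (y0 - 2 * y1 + y2) * x * x
    return np.clip(val, 0.0, None)


def _sample_envelope_obs(Y: np.ndarray, mz: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Local-background-corrected observed intensities at envelope positions.

    Any slowly varying pedestal that survives baseline subtraction (e.g.
    rectified noise) would otherwise both inflate abundances and mimic an
    envelope in the cosine test, because an all-positive constant vector has
    high cosine similarity with a smooth envelope. The pedestal is estimated
    per spectrum from the two flank positions one isotopologue spacing
    before and after the envelope — outside the envelope's own peaks, so the
    correction never eats genuine signal — and subtracted before use.
    """
    from .masslist import NEUTRON_SPACING

    obs = _sample_at(Y, mz, pos)
    flanks = np.array([pos[0] - NEUTRON_SPACING, pos[-1] + NEUTRON_SPACING])
    pedestal = _sample_at(Y, mz, flanks).mean(axis=-1, keepdims=True)
    return np.clip(obs - pedestal, 0.0, None)


def overlap_groups(
    variants: Sequence[PeptideVariant], cfg: ProcessingConfig
) -> list[list[int]]:
    """Partition variant indices into groups of mutually overlapping envelopes.

    Two variants overlap when their sampled envelope spans come within
    ``cfg.overlap_window`` Da; the partition is the transitive closure, so a
    chain of pairwise overlaps forms one group.
    """
    spans = []
    for i, v in enumerate(variants):
        pos = _sampled_positions(v, cfg)
        spans.append((pos[0] - cfg.overlap_window / 2, pos[-1] + cfg.overlap_window / 2, i))
    spans.sort()
    groups: list[list[int]] = []
    current: list[int] = []
    current_end = -np.inf
    for lo, hi, i in spans:
        if current and lo > current_end:
            groups.append(current)
            current = []
            current_end = -np.inf
        current.append(i)
        current_end = max(current_end, hi)
    if current:
        groups.append(current)
    return groups


def _sampled_positions(v: PeptideVariant, cfg: ProcessingConfig):
    p = np.asarray(v.envelope.probabilities)
    pos = np.asarray(v.envelope.mz_positions)
    keep = p >= cfg.envelope_sample_min_p
    if not keep.any():
        keep = p == p.max()
    return pos[keep]


def _sampled_envelope(v: PeptideVariant, cfg: ProcessingConfig):
    p = np.asarray(v.envelope.probabilities)
    pos = np.asarray(v.envelope.mz_positions)
    keep = p >= cfg.envelope_sample_min_p
    if not keep.any():
        keep = p == p.max()
    return pos[keep], p[keep]


def _render_envelope(mzseg: np.ndarray, v: PeptideVariant, cfg: ProcessingConfig) -> np.ndarray:
    """Theoretical unit-abundance envelope profile on a grid segment."""
    pos, p = _sampled_envelope(v, cfg)
    sd = cfg.peak_fwhm / 2.354820045
    prof = np.zeros_like(mzseg)
    for mzi, pi in zip(pos, p):
        prof += pi * np.exp(-0.5 * ((mzseg - mzi) / sd) ** 2)
    return prof


def annotate_matrix(
    Y: np.ndarray,
    mz: np.ndarray,
    variants: Sequence[PeptideVariant],
    cfg: ProcessingConfig,
    empty_pixels: np.ndarray | None = None,
) -> AnnotationResult:
    """Criterion-based annotation of processed spectra against a mass list.

    ``Y`` must already be baseline-subtracted and TIC-normalised. Variants
    with isolated envelopes get their abundance from the summed observed
    intensity at the envelope positions; overlapping variants are resolved
    jointly by non-negative least squares on the covering grid segment.
    """
    Y = np.asarray(Y)
    if Y.dtype not in (np.float32, np.float64):
        Y = Y.astype(np.float64)
    if Y.ndim == 1:
        Y = Y[None, :]
    n_px = Y.shape[0]
    n_var = len(variants)
    if n_var == 0:
        raise ValueError("mass list must be non-empty")
    if empty_pixels is None:
        empty_pixels = ~np.any(Y > 0, axis=-1)

    sigma = estimate_noise_matrix(Y, mz, cfg.noise_window)
    peak_mask = _local_maxima_snr(Y, sigma, cfg.snr_threshold)
    step = np.diff(mz).mean()

    mz_match = np.zeros((n_px, n_var), dtype=bool)
    snr_pass = np.zeros((n_px, n_var), dtype=bool)
    env_pass = np.zeros((n_px, n_var), dtype=bool)
    abundance = np.zeros((n_px, n_var), dtype=np.float64)
    env_sum = np.zeros(n_var)
    env_top_pass = np.zeros((n_px, n_var), dtype=bool)

    for k, v in enumerate(variants):
        tol_da = v.mz_mh * cfg.mz_tolerance * 1e-6
        lo = max(0, int(np.floor((v.mz_mh - tol_da - mz[0]) / step)))
        hi = min(len(mz), int(np.ceil((v.mz_mh + tol_da - mz[0]) / step)) + 1)
        if lo >= hi:
            continue
        window_hit = peak_mask[:, lo:hi].any(axis=1)
        # mz_match is the pure positional criterion (any local maximum in the
        # tolerance window); snr_pass additionally applies the SNR gate
        mz_match[:, k] = _window_local_max(Y, lo, hi).any(axis=1)
        snr_pass[:, k] = window_hit
        pos, p = _sampled_envelope(v, cfg)
        env_sum[k] = p.sum()
        obs = _sample_envelope_obs(Y, mz, pos)
        j0 = min(len(mz) - 1, max(0, int(round((v.mz_mh - mz[0]) / step))))
        env_top_pass[:, k] = obs.max(axis=1) > cfg.snr_threshold * sigma[:, j0]
        denom = np.linalg.norm(obs, axis=1) * np.linalg.norm(p)
        cosine = np.divide(
            obs @ p, denom, out=np.zeros(n_px), where=denom > 0
        )
        env_pass[:, k] = cosine >= cfg.envelope_min_cosine
        abundance[:, k] = obs.sum(axis=1)

    detected = mz_match & snr_pass & env_pass & ~empty_pixels[:, None]
    abundance[~detected] = 0.0

    # joint NNLS for overlapping envelopes
    groups = overlap_groups(variants, cfg)
    for group in groups:
        if len(group) < 2:
            continue
        # deconvolution candidacy demands both an SNR-passing peak in the
        # tolerance window and envelope signal clearing the noise floor;
        # otherwise noise fluctuations would trigger NNLS on most pixels
        candidates = (
            (snr_pass[:, group] & env_top_pass[:, group]).any(axis=1) & ~empty_pixels
        )
        rows = np.nonzero(candidates)[0]
        if len(rows) == 0:
            continue
        members, A, seg, n_bg = _group_design(
            mz, variants, group, cfg, with_background=True,
            apply_denoise=cfg.denoise == "weak",
        )
        coeffs = np.zeros((len(rows), len(members)))
        seg_Y = Y[np.ix_(rows, seg)]
        for r in range(len(rows)):
            sol, _ = optimize.nnls(A, seg_Y[r])
            coeffs[r] = sol[: len(members)]
        # the SNR gate applies to deconvolved components too: a fitted
        # component whose apex contribution stays below snr_threshold times
        # the local noise is not a detection, only noise absorbed by NNLS
        sig_seg = np.median(sigma[np.ix_(rows, seg)], axis=1)
        for c_idx, k in enumerate(members):
            apex = coeffs[:, c_idx] * A[:, c_idx].max()
            coeffs[apex <= cfg.snr_threshold * sig_seg, c_idx] = 0.0
        for c_idx, k in enumerate(members):
            share = coeffs[:, c_idx] * env_sum[k]
            abundance[rows, k] = share
        dropped = [k for k in group if k not in members]
        for k in dropped:
            abundance[rows, k] = 0.0

    detected &= abundance > 0
    return AnnotationResult(
        variant_names=[v.name for v in variants],
        abundance=abundance,
        detected=detected,
        mz_match=mz_match,
        snr_pass=snr_pass,
        envelope_pass=env_pass,
        empty_pixels=np.asarray(empty_pixels, dtype=bool),
    )


def _window_local_max(Y: np.ndarray, lo: int, hi: int) -> np.ndarray:
    lo_i = max(1, lo)
    hi_i = min(Y.shape[-1] - 1, hi)
    seg = Y[:, lo_i - 1 : hi_i + 1]
    return (seg[:, 1:-1] > seg[:, :-2]) & (seg[:, 1:-1] >= seg[:, 2:]) & (seg[:, 1:-1] > 0)


def _group_design(
    mz: np.ndarray,
    variants: Sequence[PeptideVariant],
    group: Sequence[int],
    cfg: ProcessingConfig,
    with_background: bool = True,
    apply_denoise: bool = False,
):
    """Design matrix of rendered envelopes over the group's grid segment.

    The segment margin (1 Da) is kept below the grouping window so that
    peaks of species outside the group cannot leak into the fit. A constant
    and a linear background column absorb any residual pedestal; their
    coefficients are discarded by the caller. When the processed spectra
    passed through the weak denoiser, the same filter is applied to the
    theoretical columns so model and data share one lineshape.
    Numerically collinear columns (indistinguishable envelopes, e.g. two
    truncations with identical elemental composition) are reduced to the
    lower-m/z member with a warning.
    """
    step = np.diff(mz).mean()
    margin = min(1.0, cfg.overlap_window / 2)
    all_pos = np.concatenate([_sampled_positions(variants[k], cfg) for k in group])
    lo = max(0, int((all_pos.min() - margin - mz[0]) / step))
    hi = min(len(mz), int((all_pos.max() + margin - mz[0]) / step) + 1)
    seg = np.arange(lo, hi)
    mzseg = mz[seg]
    cols = {k: _render_envelope(mzseg, variants[k], cfg) for k in group}
    if apply_denoise and len(mzseg) >= 5:
        for k in cols:
            cols[k] = np.clip(signal.savgol_filter(cols[k], 5, 2), 0.0, None)
    members: list[int] = []
    for k in sorted(group, key=lambda k: variants[k].mz_mh):
        duplicate = False
        for m in members:
            a, b = cols[k], cols[m]
            denom = np.linalg.norm(a) * np.linalg.norm(b)
            if denom > 0 and float(a @ b) / denom > 1 - 1e-9:
                warnings.warn(
                    f"envelopes of {variants[k].name} and {variants[m].name} are "
                    "indistinguishable; keeping the lower-m/z species",
                    stacklevel=2,
                )
                duplicate = True
                break
        if not duplicate:
            members.append(k)
    design_cols = [cols[k] for k in members]
    n_bg = 0
    if with_background:
        design_cols.append(np.ones(len(mzseg)))
        ramp = np.linspace(0.0, 1.0, len(mzseg))
        design_cols.append(ramp)
        n_bg = 2
    A = np.column_stack(design_cols)
    return members, A, seg, n_bg


# ---------------------------------------------------------------------------
# single-spectrum API (thin wrappers over the matrix kernels)

def subtract_baseline(s: Spectrum, baseline_window: float = 15.0) -> Spectrum:
    """Top-hat baseline removal; output intensities are >= 0."""
    out = subtract_baseline_matrix(s.intensities[None, :], s.mz, baseline_window)[0]
    return Spectrum(s.mz, out, s.pixel_id)


def weak_denoise(s: Spectrum, spike_clip_factor: float = 3.0) -> Spectrum:
    out = weak_denoise_matrix(s.intensities[None, :], spike_clip_factor)[0]
    return Spectrum(s.mz, out, s.pixel_id)


def tic_normalize(s: Spectrum, tic_target: float = 1.0) -> Spectrum:
    """Scale to total intensity ``tic_target``; all-zero spectra are an error
    (they flag empty pixels, excluded upstream)."""
    out, empty = tic_normalize_matrix(s.intensities[None, :], tic_target)
    if empty[0]:
        raise ValueError("all-zero spectrum: empty pixel, excluded from statistics")
    return Spectrum(s.mz, out[0], s.pixel_id)


def estimate_noise(s: Spectrum, window: float = 50.0) -> np.ndarray:
    return estimate_noise_matrix(s.intensities[None, :], s.mz, window)[0]


def detect_peaks(s: Spectrum, cfg: ProcessingConfig | None = None) -> PeakList:
    """SNR-gated local maxima with parabolic apex refinement, sorted by m/z."""
    cfg = cfg or ProcessingConfig()
    Y = s.intensities[None, :]
    sigma = estimate_noise_matrix(Y, s.mz, cfg.noise_window)
    mask = _local_maxima_snr(Y, sigma, cfg.snr_threshold)
    rows, idx = np.nonzero(mask)
    apex_mz, apex_h = _parabolic_apex(Y, idx, rows, s.mz)
    peaks = [
        Peak(float(m), float(h), float(sigma[0, i]))
        for m, h, i in zip(apex_mz, apex_h, idx)
    ]
    peaks.sort(key=lambda p: p.mz)
    return peaks


def annotate_peptides(
    peaks: PeakList,
    s: Spectrum,
    masslist: Sequence[PeptideVariant],
    cfg: ProcessingConfig | None = None,
) -> AnnotationResult:
    """Annotate one spectrum; delegates to the batch kernel so that
    independent per-pixel processing equals batch processing exactly."""
    cfg = cfg or ProcessingConfig()
    return annotate_matrix(s.intensities[None, :], s.mz, masslist, cfg)


def deconvolve_envelopes(
    s: Spectrum,
    variants: Sequence[PeptideVariant],
    window: float = 1.0,
    cfg: ProcessingConfig | None = None,
) -> tuple[dict[str, float], float]:
    """Resolve overlapping isotope envelopes by non-negative least squares.

    The observed segment covering the variants' envelopes is modelled as a
    non-negative combination of theoretical envelope profiles; coefficients
    are returned as abundances (same scale as annotation abundances) together
    with the residual norm. Numerically identical envelopes raise
    :class:`AmbiguityError` naming the colliding species.
    """
    if len(variants) < 1:
        raise ValueError("need at least one variant")
    cfg = replace(cfg or ProcessingConfig(), overlap_window=window)
    group = list(range(len(variants)))
    with warnings.catch_warnings(record=True):
        warnings.simplefilter("always")
        members, A, seg, n_bg = _group_design(
            s.mz, variants, group, cfg, with_background=True, apply_denoise=False
        )
    if len(members) < len(group):
        names = sorted(set(v.name for v in variants) - set(variants[m].name for m in members))
        kept = [variants[m].name for m in members]
        raise AmbiguityError(
            f"indistinguishable envelopes among {names + kept}: cannot deconvolve"
        )
    coef, residual = optimize.nnls(A, s.intensities[seg])
    env_sums = [sum(_sampled_envelope(variants[m], cfg)[1]) for m in members]
    result = {
        variants[m].name: float(c * e) for m, c, e in zip(members, coef, env_sums)
    }
    return result, float(residual)
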