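"""Feature extraction: band power, magnitude-squared coherence, Granger causality.

Three feature families per 30 s observation, each computed over the eight
3 s analysis windows:

* **power** — absolute band power (mean Hann-tapered periodogram power over
  the band's bins, averaged over windows) and relative power (absolute
  divided by the mean 1–45 Hz broadband power): 100 columns.
* **MSC** — magnitude-squared coherence between every ROI pair,
  ``|<Sxy>|^2 / (<Sxx><Syy>)`` with ``< >`` the across-window (Welch
  ensemble) average, then averaged over the band's frequency bins: 45
  columns per band (upper triangle of the symmetric 10 x 10 matrix).
* **GC** — pairwise Granger causality: for every ordered ROI pair the
  restricted autoregression (own lags only) is compared against the full
  one (own plus cross lags); the per-window binary verdict is averaged
  over windows: 100 columns per band (full 10 x 10 matrix, diagonal 0).

The literal "full residual variance smaller than restricted" rule is
degenerate in-sample — adding regressors almost never increases the raw
residual variance — so the default verdict compares degrees-of-freedom
adjusted variances; a nested-model F-test and the literal raw rule are
available as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal.windows import hann

from .preprocess import BandDefinition, DEFAULT_BANDS, ObservationSet

__all__ = [
    "FeatureMatrix",
    "SpectralEstimate",
    "ARModelFit",
    "band_power_features",
    "estimate_spectra",
    "msc",
    "msc_features",
    "fit_ar_pair",
    "granger_binary",
    "gc_features",
    "DEFAULT_AR_ORDER",
    "GC_RULES",
]

DEFAULT_AR_ORDER = 5
GC_RULES = ("dof_adjusted", "ftest", "raw")

#: Frequency range of the relative-power denominator (Hz).
TOTAL_POWER_RANGE = (1.0, 45.0)


@dataclass
class FeatureMatrix:
    """Observations x named features with label and provenance metadata.

    Column names encode provenance: ``pow.delta.r1.abs``,
    ``msc.alpha.r1_r2``, ``gc.beta.r3_to_r4``.
    """

    data: pd.DataFrame
    labels: pd.DataFrame  # condition, participant, session, trial per row
    family: str
    is_baseline: bool = False

    def __post_init__(self) -> None:
        if len(self.data) != len(self.labels):
            raise ValueError("data and labels must have the same number of rows")
        if self.data.columns.duplicated().any():
            raise ValueError("feature column names must be unique")

    @property
    def band_names(self) -> list[str]:
        seen: list[str] = []
        for c in self.data.columns:
            b = c.split(".")[1]
            if b not in seen:
                seen.append(b)
        return seen

    def columns_for_band(self, band: str) -> list[str]:
        return [c for c in self.data.columns if c.split(".")[1] == band]

    def subset(self, columns: list[str]) -> "FeatureMatrix":
        return FeatureMatrix(
            data=self.data[columns].copy(),
            labels=self.labels,
            family=self.family,
            is_baseline=self.is_baseline,
        )


def _labels(obs: ObservationSet) -> pd.DataFrame:
    return obs.metadata[["condition", "participant", "session", "trial"]].reset_index(drop=True)


def _taper(n: int) -> np.ndarray:
    return hann(n, sym=False)


def _periodogram(windows: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hann-tapered periodogram over the last axis.

    Returns ``(freqs, Pxx)`` with ``Pxx`` shaped like ``windows`` but the
    last axis replaced by frequency bins.
    """
    n = windows.shape[-1]
    w = _taper(n)
    z = np.fft.rfft(windows * w, axis=-1)
    scale = 1.0 / (rate * (w * w).sum())
    p = (z.real**2 + z.imag**2) * scale
    p[..., 1:] *= 2.0
    if n % 2 == 0:
        p[..., -1] /= 2.0
    return np.fft.rfftfreq(n, 1.0 / rate), p


def _band_bins(freqs: np.ndarray, low: float, high: float) -> np.ndarray:
    return (freqs >= low) & (freqs < high)


def _chunked_band_mean_power(tensor, rate, low, high, chunk_size=64) -> np.ndarray:
    """Mean per-bin periodogram power in [low, high), averaged over windows."""
    n_obs = tensor.shape[0]
    out = np.empty(tensor.shape[:2])
    mask = None
    for lo in range(0, n_obs, chunk_size):
        x = np.asarray(tensor[lo : lo + chunk_size], dtype=float)
        freqs, p = _periodogram(x, rate)
        if mask is None:
            mask = _band_bins(freqs, low, high)
        out[lo : lo + x.shape[0]] = p[..., mask].mean(axis=(-2, -1))
    return out


def band_power_features(
    obs: ObservationSet,
    side: str = "emotional",
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> FeatureMatrix:
    """Absolute and relative band power per ROI: 100 columns.

    Columns are ordered band-major, then ROI, then ``abs``/``rel``.
    A zero-power observation gets relative power 0 (not NaN).
    """
    tensors = getattr(obs, side)
    for b in bands:
        if b.name not in tensors:
            raise ValueError(f"observation set lacks band {b.name!r}")
    if "broadband" not in tensors:
        raise ValueError("observation set lacks broadband windows (needed for relative power)")

    rate = obs.sampling_rate
    lo, hi = TOTAL_POWER_RANGE
    # mean per-bin broadband power over 1-45 Hz, averaged over windows
    denom = _chunked_band_mean_power(tensors["broadband"], rate, lo, hi)  # (n_obs, n_roi)

    cols: dict[str, np.ndarray] = {}
    for b in bands:
        absolute = _chunked_band_mean_power(tensors[b.name], rate, b.low, b.high)
        with np.errstate(invalid="ignore", divide="ignore"):
            relative = np.where(denom > 0, absolute / np.where(denom > 0, denom, 1.0), 0.0)
        for roi in range(absolute.shape[1]):
            cols[f"pow.{b.name}.r{roi + 1}.abs"] = absolute[:, roi]
            cols[f"pow.{b.name}.r{roi + 1}.rel"] = relative[:, roi]

    return FeatureMatrix(
        data=pd.DataFrame(cols),
        labels=_labels(obs),
        family="pow",
        is_baseline=(side == "baseline"),
    )


@dataclass
class SpectralEstimate:
    """Across-window (Welch ensemble) auto- and cross-spectra.

    ``cross[i, j]`` holds ``<Sxy(f)>`` for ROIs ``i+1`` and ``j+1``;
    the diagonal is real and non-negative.
    """

    freqs: np.ndarray  # (n_freq,)
    cross: np.ndarray  # (n_roi, n_roi, n_freq) complex, Hermitian in (i, j)
    n_windows: int

    @property
    def auto(self) -> np.ndarray:
        return np.real(np.einsum("iif->if", self.cross))


def estimate_spectra(row: np.ndarray, rate: float) -> SpectralEstimate:
    """Ensemble-averaged spectra of one observation (ROIs x windows x samples).

    With a single window the coherence estimator is identically 1, so at
    least two windows are required.
    """
    x = np.asarray(row, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected (n_rois, n_windows, n_samples)")
    n_roi, n_win, n = x.shape
    if n_win < 2:
        raise ValueError(
            "coherence needs >= 2 windows per observation; adjust the windowing "
            "configuration (a single-window ensemble gives MSC == 1 identically)"
        )
    w = _taper(n)
    z = np.fft.rfft(x * w, axis=-1)  # (roi, win, freq)
    cross = np.einsum("iwf,jwf->ijf", z, np.conj(z)) / n_win
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    return SpectralEstimate(freqs=freqs, cross=cross, n_windows=n_win)


def _msc_bins(est: SpectralEstimate) -> np.ndarray:
    """Per-bin MSC matrix (n_roi, n_roi, n_freq); bins with a zero
    auto-spectrum contribute 0."""
    auto = est.auto  # (roi, freq)
    num = np.abs(est.cross) ** 2
    den = auto[:, None, :] * auto[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.clip(g, 0.0, 1.0)


def msc(est: SpectralEstimate, pair: tuple[int, int], band: BandDefinition) -> float:
    """Band-averaged magnitude-squared coherence for one ROI pair (1-based)."""
    mask = _band_bins(est.freqs, band.low, band.high)
    if not mask.any():
        raise ValueError(f"band {band.name!r} outside the analyzed frequency range")
    i, j = pair[0] - 1, pair[1] - 1
    return float(_msc_bins(est)[i, j, mask].mean())


def _pair_columns(n_roi: int, band: str) -> list[str]:
    return [
        f"msc.{band}.r{i + 1}_r{j + 1}"
        for i in range(n_roi)
        for j in range(i + 1, n_roi)
    ]


def msc_features(
    obs: ObservationSet,
    side: str = "emotional",
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    chunk_size: int = 32,
) -> FeatureMatrix:
    """Per-band MSC connectivity vectorized to 45 columns per band.

    The upper triangle of each symmetric 10 x 10 connectivity matrix is
    unrolled row-major: (1,2), (1,3), ..., (1,10), (2,3), ...  Spectra are
    estimated from the broadband windows; averaging over each band's bins
    is equivalent to computing coherence on the band-filtered signals,
    since the filter gain cancels between numerator and denominator.
    """
    tensors = getattr(obs, side)
    broad = tensors["broadband"]
    n_obs, n_roi, n_win, n = broad.shape
    rate = obs.sampling_rate
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    masks = {b.name: _band_bins(freqs, b.low, b.high) for b in bands}
    iu = np.triu_indices(n_roi, k=1)

    w = _taper(n)
    out = {b.name: np.empty((n_obs, len(iu[0]))) for b in bands}
    for lo in range(0, n_obs, chunk_size):
        x = np.asarray(broad[lo : lo + chunk_size], dtype=float)
        z = np.fft.rfft(x * w, axis=-1)  # (B, roi, win, freq)
        cross = np.einsum("biwf,bjwf->bijf", z, np.conj(z)) / n_win
        auto = np.real(np.einsum("biif->bif", cross))
        num = np.abs(cross[:, iu[0], iu[1], :]) ** 2  # (B, pairs, freq)
        den = auto[:, iu[0], :] * auto[:, iu[1], :]
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        g = np.clip(g, 0.0, 1.0)
        for b in bands:
            out[b.name][lo : lo + x.shape[0]] = g[..., masks[b.name]].mean(axis=-1)

    cols = {}
    for b in bands:
        for q, name in enumerate(_pair_columns(n_roi, b.name)):
            cols[name] = out[b.name][:, q]
    return FeatureMatrix(
        data=pd.DataFrame(cols),
        labels=_labels(obs),
        family="msc",
        is_baseline=(side == "baseline"),
    )


@dataclass
class ARModelFit:
    """Nested autoregression fits for one ordered signal pair (x -> y)."""

    order: int
    coeffs_restricted: np.ndarray  # a(i), own lags of y
    coeffs_full: np.ndarray  # a(i) then b(j)
    rss_restricted: float
    rss_full: float
    n_used: int
    rank_deficient: bool = False

    @property
    def var_restricted(self) -> float:
        """DoF-adjusted residual variance of the own-lags model."""
        return self.rss_restricted / (self.n_used - self.order)

    @property
    def var_full(self) -> float:
        """DoF-adjusted residual variance of the own-plus-cross-lags model."""
        return self.rss_full / (self.n_used - 2 * self.order)


def _lag_matrix(x: np.ndarray, p: int) -> np.ndarray:
    """(n - p, p) matrix whose row m holds x[t-1], ..., x[t-p] for t = p + m."""
    sw = np.lib.stride_tricks.sliding_window_view(x, p + 1)
    return sw[:, :p][:, ::-1]


def fit_ar_pair(y: np.ndarray, x: np.ndarray, order: int = DEFAULT_AR_ORDER) -> ARModelFit:
    """Least-squares nested AR fits of y on its own lags vs own + x lags.

    Both models are fit on the same sample range (the first ``order``
    samples are dropped); inputs are demeaned.  A rank-deficient full
    design (e.g., constant x) is flagged and the residual sums are set
    equal, which forces a Granger verdict of 0.
    """
    p = int(order)
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if p < 1:
        raise ValueError("order must be >= 1")
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-D arrays of equal length")
    if len(y) <= 3 * p:
        raise ValueError(f"need more than {3 * p} samples for order {p}")
    y = y - y.mean()
    x = x - x.mean()
    Ly, Lx = _lag_matrix(y, p), _lag_matrix(x, p)
    target = y[p:]
    n_used = len(target)

    br, rss_r, rank_r, _ = np.linalg.lstsq(Ly, target, rcond=None)
    full = np.hstack([Ly, Lx])
    bf, rss_f, rank_f, _ = np.linalg.lstsq(full, target, rcond=None)
    # lstsq returns an empty rss when rank deficient
    rss_r = float(rss_r[0]) if rss_r.size else float(((target - Ly @ br) ** 2).sum())
    rss_f = float(rss_f[0]) if rss_f.size else float(((target - full @ bf) ** 2).sum())
    deficient = rank_f < 2 * p
    if deficient:
        rss_f = rss_r
        bf = np.concatenate([br, np.zeros(p)])
    return ARModelFit(
        order=p,
        coeffs_restricted=br,
        coeffs_full=bf,
        rss_restricted=max(rss_r, 0.0),
        rss_full=max(rss_f, 0.0),
        n_used=n_used,
        rank_deficient=deficient,
    )


def granger_binary(fit: ARModelFit, rule: str = "dof_adjusted", alpha: float = 0.05) -> int:
    """Binary Granger verdict for x -> y from a nested AR fit.

    ``dof_adjusted`` (default): 1 iff the adjusted full-model variance is
    strictly smaller than the adjusted restricted variance (ties -> 0).
    ``ftest``: 1 iff the nested-model F-test rejects at ``alpha``.
    ``raw``: the literal in-sample residual-variance comparison; kept for
    reference, degenerate in practice (fires on nearly every pair).
    """
    if rule not in GC_RULES:
        raise ValueError(f"rule must be one of {GC_RULES}")
    if fit.rank_deficient or fit.rss_restricted == fit.rss_full == 0.0:
        return 0
    if rule == "raw":
        return int(fit.rss_full < fit.rss_restricted)
    if rule == "dof_adjusted":
        return int(fit.var_full < fit.var_restricted)
    p, n = fit.order, fit.n_used
    if fit.rss_full <= 0.0:
        return int(fit.rss_restricted > 0.0)
    f_stat = ((fit.rss_restricted - fit.rss_full) / p) / (fit.rss_full / (n - 2 * p))
    return int(stats.f.sf(max(f_stat, 0.0), p, n - 2 * p) < alpha)


def _gc_matrices_window(
    x: np.ndarray, p: int, rule: str, alpha: float
) -> np.ndarray:
    """Binary GC matrix for one window of a batch: x is (B, n_roi, n).

    Vectorized over the batch and all ordered ROI pairs via precomputed
    lag cross-products; a tiny relative ridge keeps the batched solves
    defined for degenerate (constant) inputs, where both models collapse
    to equality and the verdict is 0.
    """
    B, k, n = x.shape
    x = x - x.mean(axis=-1, keepdims=True)
    sw = np.lib.stride_tricks.sliding_window_view(x, p + 1, axis=-1)
    L = sw[..., :p][..., ::-1]  # (B, k, n_used, p): lags 1..p
    Y = sw[..., p]  # (B, k, n_used)
    n_used = Y.shape[-1]
    Lf = np.ascontiguousarray(np.moveaxis(L, -1, 2)).reshape(B, k * p, n_used)

    C = Lf @ np.swapaxes(Lf, 1, 2)  # (B, kp, kp)
    V = np.einsum("ban,bjn->baj", Lf, Y)  # (B, kp, k)
    Syy = np.einsum("bjn,bjn->bj", Y, Y)  # (B, k)

    blocks = np.arange(k * p).reshape(k, p)
    eps = 1e-9 * np.einsum("bii->b", C) / (k * p) + 1e-300

    # restricted models: one per target ROI
    Ar = C[:, blocks[:, :, None], blocks[:, None, :]]  # (B, k, p, p)
    Ar = Ar + eps[:, None, None, None] * np.eye(p)
    rr = np.take_along_axis(V[:, blocks, :], np.arange(k)[None, :, None, None], axis=-1)[..., 0]
    beta_r = np.linalg.solve(Ar, rr[..., None])[..., 0]
    rss_r = np.maximum(Syy - np.einsum("bkp,bkp->bk", beta_r, rr), 0.0)  # (B, k)

    # full models: one per ordered pair (source i -> target j)
    pairs = [(i, j) for j in range(k) for i in range(k) if i != j]
    src = np.array([i for i, _ in pairs])
    tgt = np.array([j for _, j in pairs])
    idx = np.concatenate([blocks[tgt], blocks[src]], axis=1)  # (npair, 2p)
    Af = C[:, idx[:, :, None], idx[:, None, :]] + eps[:, None, None, None] * np.eye(2 * p)
    rf = V[:, idx, tgt[:, None]]  # (B, npair, 2p)
    beta_f = np.linalg.solve(Af, rf[..., None])[..., 0]
    rss_f = np.maximum(Syy[:, tgt] - np.einsum("bqd,bqd->bq", beta_f, rf), 0.0)

    rss_r_pair = rss_r[:, tgt]
    degenerate = (rss_r_pair <= 0.0) & (rss_f <= 0.0)
    if rule == "raw":
        hit = rss_f < rss_r_pair
    elif rule == "dof_adjusted":
        hit = rss_f / (n_used - 2 * p) < rss_r_pair / (n_used - p)
    else:  # ftest
        with np.errstate(invalid="ignore", divide="ignore"):
            f_stat = ((rss_r_pair - rss_f) / p) / (rss_f / (n_used - 2 * p))
        hit = np.where(
            rss_f <= 0.0,
            rss_r_pair > 0.0,
            stats.f.sf(np.maximum(np.nan_to_num(f_stat), 0.0), p, n_used - 2 * p) < alpha,
        )
    hit = np.where(degenerate, False, hit)

    out = np.zeros((B, k, k))
    out[:, src, tgt] = hit.astype(float)
    return out


def gc_features(
    obs: ObservationSet,
    order: int = DEFAULT_AR_ORDER,
    rule: str = "dof_adjusted",
    side: str = "emotional",
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    alpha: float = 0.05,
    chunk_size: int = 64,
) -> FeatureMatrix:
    """Window-averaged binary Granger causality per band: 100 columns/band.

    For each ordered pair (i -> j) and each of the 8 windows of the
    band-filtered signals a binary verdict is computed; the window mean
    (a value in [0, 1]) fills entry (i, j).  The diagonal is fixed at 0
    and vectorization is row-major over the full 10 x 10 matrix.
    """
    if rule not in GC_RULES:
        raise ValueError(f"rule must be one of {GC_RULES}")
    tensors = getattr(obs, side)
    for b in bands:
        if b.name not in tensors:
            raise ValueError(f"observation set lacks band {b.name!r}")
    n_obs, n_roi, n_win, _ = tensors[bands[0].name].shape

    per_band = {}
    for b in bands:
        acc = np.zeros((n_obs, n_roi, n_roi))
        tensor = tensors[b.name]
        for lo in range(0, n_obs, chunk_size):
            x = np.asarray(tensor[lo : lo + chunk_size], dtype=float)
            for wdx in range(n_win):
                acc[lo : lo + x.shape[0]] += _gc_matrices_window(x[:, :, wdx, :], order, rule, alpha)
        per_band[b.name] = acc / n_win

    cols = {}
    for b in bands:
        m = per_band[b.name]
        for i in range(n_roi):
            for j in range(n_roi):
                cols[f"gc.{b.name}.r{i + 1}_to_r{j + 1}"] = m[:, i, j]
    return FeatureMatrix(
        data=pd.DataFrame(cols),
        labels=_labels(obs),
        family="gc",
        is_baseline=(side == "baseline"),
    )
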