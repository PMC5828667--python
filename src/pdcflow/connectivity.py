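"""Directed functional connectivity: PDC spectra from fitted MVAR models,
spectral-power weighting (wPDC), band reduction, and summed outflow.

Conventions, stated once because the literature varies:

* element (i, j, f) of every connectivity tensor is the influence FROM
  column j TO row i;
* PDC is the column-normalised magnitude of the spectral coefficient
  matrix: with Abar(f) = I - sum_r A_r exp(-i 2 pi f r / fs),

      PDC(i, j, f) = |Abar_ij(f)| / sqrt(sum_k |Abar_kj(f)|^2),

  so each sender column has unit squared sum at every frequency;
* wPDC(i, j, f) = scaledSP(j, f) * scaledPDC(i, j, f): weighting by the
  SENDER's spectral power;
* summed outflow of ROI j in a band is the column sum over receivers
  excluding the diagonal.

The epoch-level pipeline fits one MVAR per 1-s epoch, computes PDC per
epoch, averages PDC within subject, then scales and weights at the
subject level. Min-max scaling pools over regions and the 1-40 Hz grid
and, by default, excludes the PDC diagonal (self-influence) from both the
scaling pool and downstream sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mvar import MVARModel, fit_mvar

DEFAULT_FREQS = np.arange(1.0, 41.0)  # 1-40 Hz, 1 Hz steps

BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
}


@dataclass
class SpectralPower:
    """Per-region source power on the analysis frequency grid."""

    values: np.ndarray  # (n_rois, n_freqs), >= 0
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.values.shape[1] != len(self.freqs):
            raise ValueError("values/freqs length mismatch")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("spectral power must be finite and non-negative")


def pdc_spectrum(
    model: MVARModel,
    freqs: np.ndarray = DEFAULT_FREQS,
    require_stable: bool = True,
) -> np.ndarray:
    """Column-normalised PDC tensor (n, n, n_freqs) of a stable model.

    ``require_stable=False`` skips the stationarity check: PDC is a
    well-defined function of the coefficients either way, and per-epoch
    least-squares fits on short epochs routinely land marginally outside
    the stability region without invalidating the spectral quantity.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    if require_stable and not model.is_stable():
        raise ValueError("PDC requires a stable MVAR model")
    p, n = model.order, model.n_channels
    lags = np.arange(1, p + 1)
    # phase (p, F): exp(-i 2 pi f r dt)
    phase = np.exp(-2j * np.pi * np.outer(lags, freqs) / model.fs)
    Abar = np.eye(n)[:, :, None] - np.einsum("rij,rf->ijf", model.coeffs, phase)
    mag = np.abs(Abar)
    col_norm = np.sqrt((mag**2).sum(axis=0, keepdims=True))
    return mag / col_norm


def average_pdc_over_epochs(pdc_stack: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Elementwise mean of per-epoch PDC tensors (column normalisation is
    not preserved by averaging; downstream scaling handles that)."""
    tensors = [np.asarray(t, dtype=float) for t in pdc_stack]
    if not tensors:
        raise ValueError("need at least one epoch")
    shape = tensors[0].shape
    if any(t.shape != shape for t in tensors):
        raise ValueError("per-epoch PDC tensors have mismatched grids")
    return np.mean(tensors, axis=0)


def subject_pdc(
    roi_epochs: np.ndarray,
    fs: float,
    order: int = 5,
    freqs: np.ndarray = DEFAULT_FREQS,
    per_epoch: bool = False,
) -> np.ndarray:
    """Subject-level PDC from epoched ROI series (n_rois, n_samples,
    n_epochs).

    Default: one multi-trial MVAR pooled over epochs, then its PDC. An
    order-p model over n regions has n*p lag coefficients per channel —
    more than one 1-s epoch can identify once n is large — so pooling
    epochs as independent realisations is the estimator of record here.
    ``per_epoch=True`` instead fits each epoch separately and averages
    the per-epoch PDC tensors elementwise; feasible for small n, with
    far noisier estimates.
    """
    x = np.asarray(roi_epochs, dtype=float)
    n, T, E = x.shape
    if not per_epoch:
        model = fit_mvar(x, order=order, fs=fs)
        return pdc_spectrum(model, freqs, require_stable=False)
    acc = np.zeros((n, n, len(freqs)))
    for e in range(E):
        model = fit_mvar(x[:, :, e], order=order, fs=fs)
        acc += pdc_spectrum(model, freqs, require_stable=False)
    return acc / E


def roi_spectral_power(
    sensor_epochs: np.ndarray,
    fs: float,
    inv,
    point_indices: np.ndarray,
    orientations: np.ndarray,
    freqs: np.ndarray = DEFAULT_FREQS,
) -> SpectralPower:
    """Source spectral power via the FFT-through-the-inverse route.

    Per epoch: FFT each electrode's series, pass the real and imaginary
    coefficient maps separately through the (linear) inverse + centroid
    reduction + fixed orientation projection, then SP(j, f) = re^2 +
    im^2, averaged over epochs. Because every step is linear this equals
    the power spectrum of the projected source series (Parseval), while
    avoiding frequency doubling.
    """
    from .inverse import reduce_to_centroids

    x = np.asarray(sensor_epochs, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
    ne, T, E = x.shape
    if ne != inv.n_electrodes:
        raise ValueError("montage mismatch between data and inverse kernel")
    fftfreqs = np.fft.rfftfreq(T, d=1.0 / fs)
    bins = []
    for f in np.asarray(freqs, dtype=float):
        hit = np.flatnonzero(np.isclose(fftfreqs, f, atol=1e-6))
        if hit.size == 0:
            raise ValueError(
                f"frequency {f} Hz is not on the FFT grid (T={T}, fs={fs})"
            )
        bins.append(int(hit[0]))
    bins = np.asarray(bins)

    # reduced oriented kernel: (n_rois, ne)
    k3 = inv.kernel.reshape(inv.n_points, 3, ne)
    kroi = reduce_to_centroids(k3, point_indices)  # (n_rois, 3, ne)
    kor = np.einsum("rke,rk->re", kroi, np.asarray(orientations, dtype=float))

    n_rois = kor.shape[0]
    sp = np.zeros((n_rois, len(bins)))
    for e in range(E):
        ref = x[:, :, e] - x[:, :, e].mean(axis=0, keepdims=True)
        F = np.fft.rfft(ref, axis=1)[:, bins]  # (ne, nf)
        re = kor @ F.real
        im = kor @ F.imag
        sp += re**2 + im**2
    return SpectralPower(values=sp / E, freqs=np.asarray(freqs, dtype=float))


def minmax_scale(values: np.ndarray, pool_mask: np.ndarray | None = None) -> np.ndarray:
    """Global 0-1 scaling: subtract the pool minimum, divide by the range.

    ``pool_mask`` selects the entries defining min and max (e.g. the
    off-diagonal of a connectivity tensor); the transform is applied to
    every entry. Constant pools (zero range) raise.
    """
    v = np.asarray(values, dtype=float)
    pool = v[pool_mask] if pool_mask is not None else v
    lo, hi = float(np.min(pool)), float(np.max(pool))
    if hi == lo:
        raise ValueError("cannot min-max scale a constant input (zero range)")
    return (v - lo) / (hi - lo)


def offdiagonal_mask(n: int, n_freqs: int) -> np.ndarray:
    mask = ~np.eye(n, dtype=bool)
    return np.repeat(mask[:, :, None], n_freqs, axis=2)


def weight_pdc(scaled_pdc: np.ndarray, scaled_sp: np.ndarray) -> np.ndarray:
    """wPDC(i, j, f) = scaledSP(j, f) * scaledPDC(i, j, f) (sender power)."""
    pdc = np.asarray(scaled_pdc, dtype=float)
    sp = np.asarray(scaled_sp, dtype=float)
    if pdc.shape[1] != sp.shape[0] or pdc.shape[2] != sp.shape[1]:
        raise ValueError("PDC and SP disagree on regions or frequency grid")
    return sp[None, :, :] * pdc


def band_average(
    tensor: np.ndarray,
    freqs: np.ndarray = DEFAULT_FREQS,
    bands: dict[str, tuple[float, float]] = BANDS,
) -> dict[str, np.ndarray]:
    """Mean over in-band frequency bins, per band (inclusive edges)."""
    freqs = np.asarray(freqs, dtype=float)
    out = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs <= hi)
        if not sel.any():
            raise ValueError(f"band {name} ({lo}-{hi} Hz) has no grid bins")
        out[name] = np.asarray(tensor)[:, :, sel].mean(axis=2)
    return out


def summed_outflow(band_matrix: np.ndarray) -> np.ndarray:
    """Per-ROI driving statistic: column sums excluding the diagonal."""
    m = np.asarray(band_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("band connectivity matrix must be square")
    return m.sum(axis=0) - np.diag(m)


def subject_outflow(
    pdc_avg: np.ndarray,
    sp: SpectralPower,
    freqs: np.ndarray = DEFAULT_FREQS,
    bands: dict[str, tuple[float, float]] = BANDS,
    include_diagonal: bool = False,
) -> dict[str, np.ndarray]:
    """Subject-level scale -> weight -> band-average -> summed outflow.

    Returns {band: outflow vector}. With ``include_diagonal=False`` (the
    default) self-influence is excluded from the PDC scaling pool and the
    diagonal contributes nothing to outflow by construction of the sum.
    """
    n = pdc_avg.shape[0]
    mask = None if include_diagonal else offdiagonal_mask(n, pdc_avg.shape[2])
    pdc_scaled = minmax_scale(pdc_avg, pool_mask=mask)
    sp_scaled = minmax_scale(sp.values)
    wpdc = weight_pdc(np.clip(pdc_scaled, 0.0, 1.0), np.clip(sp_scaled, 0.0, 1.0))
    per_band = band_average(wpdc, freqs=freqs, bands=bands)
    return {name: summed_outflow(mat) for name, mat in per_band.items()}
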