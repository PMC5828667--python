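"""Sensor-space cleaning chain.

Order of operations mirrors the intended pipeline narrative: montage
reduction -> band-pass (1-40 Hz) + 50 Hz notch, zero-phase -> downsample
to 125 Hz -> spherical-spline interpolation of bad channels -> average
reference -> 1-s epoching with a 120-epoch minimum. Each step appends to
the container's ``history`` so the applied order is recorded in output
metadata.

Filters are windowed-sinc FIR applied forward-backward (scipy
``filtfilt``), hence exactly zero-phase; the notch is a narrow band-stop
(49-51 Hz). Spherical-spline interpolation uses an order-4 Legendre
expansion truncated at 7 terms with ridge regularisation 1e-5.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.special import eval_legendre

from .containers import SensorEpochs


class InsufficientEpochsError(RuntimeError):
    """Raised when a recording cannot supply the required epoch count."""

    def __init__(self, n_found: int, n_required: int):
        self.n_found = n_found
        self.n_required = n_required
        super().__init__(
            f"insufficient epochs: {n_found} available, {n_required} required"
        )


def reduce_montage(raw: SensorEpochs, keep: list[str]) -> SensorEpochs:
    """Restrict to the given channel labels (order taken from ``keep``)."""
    missing = [c for c in keep if c not in raw.ch_names]
    if missing:
        raise KeyError(f"unknown channel labels: {missing}")
    idx = [raw.ch_names.index(c) for c in keep]
    pos = raw.ch_positions[idx] if raw.ch_positions is not None else None
    return raw.copy_with(
        data=raw.data[idx],
        ch_names=list(keep),
        ch_positions=pos,
        history=raw.history + [f"reduce_montage:{len(keep)}"],
    )


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def _filtfilt(b: np.ndarray, data: np.ndarray) -> np.ndarray:
    padlen = min(3 * len(b), data.shape[1] - 2)
    return signal.filtfilt(b, [1.0], data, axis=1, padlen=padlen)


def filter_band(
    raw: SensorEpochs,
    low: float = 1.0,
    high: float = 40.0,
    notch: float | None = 50.0,
    transition: float | None = None,
) -> SensorEpochs:
    """Zero-phase FIR band-pass plus optional narrow notch.

    Transition width defaults to min(low, 2) Hz; the notch stop band is
    notch +/- 1 Hz. Forward-backward application squares the magnitude
    response, so quoted attenuations double in dB.
    """
    fs = raw.fs
    if not fs > 2 * high:
        raise ValueError("sampling rate must exceed twice the upper band edge")
    if not 0 < low < high < fs / 2:
        raise ValueError("band edges must satisfy 0 < low < high < fs/2")
    width = transition if transition is not None else min(low, 2.0)
    ntaps = _odd(int(np.ceil(3.3 * fs / width)))
    b_bp = signal.firwin(ntaps, [low, high], pass_zero=False, fs=fs)

    out = np.empty_like(raw.data)
    for e in range(raw.n_epochs):
        x = _filtfilt(b_bp, raw.data[:, :, e])
        if notch is not None:
            if not 0 < notch < fs / 2:
                raise ValueError("notch frequency outside (0, fs/2)")
            n_nt = _odd(int(np.ceil(3.3 * fs / 1.0)))
            b_nt = signal.firwin(
                n_nt, [notch - 1.0, notch + 1.0], pass_zero=True, fs=fs
            )
            x = _filtfilt(b_nt, x)
        out[:, :, e] = x
    label = f"filter_band:{low}-{high}" + (f",notch{notch}" if notch else "")
    return raw.copy_with(data=out, history=raw.history + [label])


def downsample(raw: SensorEpochs, target_fs: float = 125.0) -> SensorEpochs:
    """Anti-aliased polyphase resampling to ``target_fs``."""
    if target_fs > raw.fs:
        raise ValueError("target sampling rate must not exceed the current rate")
    if target_fs == raw.fs:
        return raw.copy_with(history=raw.history + ["downsample:identity"])
    frac = Fraction(target_fs / raw.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(raw.data, up, down, axis=1)
    return raw.copy_with(
        data=out,
        fs=target_fs,
        history=raw.history + [f"downsample:{target_fs}"],
    )


def _spline_g(cosang: np.ndarray, order: int = 4, n_terms: int = 7) -> np.ndarray:
    """Perrin-style spherical-spline kernel g(cos theta)."""
    g = np.zeros_like(cosang, dtype=float)
    for n in range(1, n_terms + 1):
        g += (2 * n + 1) / (n**order * (n + 1) ** order) * eval_legendre(n, cosang)
    return g / (4.0 * np.pi)


def interpolation_matrix(
    good_pos: np.ndarray,
    bad_pos: np.ndarray,
    order: int = 4,
    n_terms: int = 7,
    reg: float = 1e-5,
) -> np.ndarray:
    """Matrix mapping good-channel potentials to bad-channel estimates.

    Solves the spline system [[G + reg I, 1], [1^T, 0]] for weights and a
    constant, then evaluates at the bad positions; the constant term makes
    constant fields reproduce exactly.
    """
    ng = len(good_pos)
    Ggg = _spline_g(np.clip(good_pos @ good_pos.T, -1, 1), order, n_terms)
    Gbg = _spline_g(np.clip(bad_pos @ good_pos.T, -1, 1), order, n_terms)
    A = np.zeros((ng + 1, ng + 1))
    A[:ng, :ng] = Ggg + reg * np.eye(ng)
    A[:ng, ng] = 1.0
    A[ng, :ng] = 1.0
    Ainv = np.linalg.pinv(A)
    B = np.concatenate([Gbg, np.ones((len(bad_pos), 1))], axis=1)  # (nb, ng+1)
    return (B @ Ainv)[:, :ng]


def interpolate_bad_channels(raw: SensorEpochs, bad: list[str]) -> SensorEpochs:
    """Replace listed channels by spherical-spline estimates from the rest."""
    if not bad:
        return raw.copy_with(history=raw.history + ["interpolate:none"])
    if raw.ch_positions is None:
        raise ValueError("channel positions are required for interpolation")
    unknown = [c for c in bad if c not in raw.ch_names]
    if unknown:
        raise KeyError(f"unknown channels: {unknown}")
    bad_idx = [raw.ch_names.index(c) for c in bad]
    good_idx = [i for i in range(raw.n_channels) if i not in bad_idx]
    if not good_idx:
        raise ValueError("cannot interpolate: all channels marked bad")
    if len(bad_idx) >= raw.n_channels / 4:
        raise ValueError(
            f"{len(bad_idx)} bad of {raw.n_channels} exceeds the n/4 safety bound"
        )
    pos = raw.ch_positions / np.linalg.norm(raw.ch_positions, axis=1, keepdims=True)
    M = interpolation_matrix(pos[good_idx], pos[bad_idx])
    out = raw.data.copy()
    flat = raw.data[good_idx].reshape(len(good_idx), -1)
    out[bad_idx] = (M @ flat).reshape(len(bad_idx), raw.n_samples, raw.n_epochs)
    return raw.copy_with(
        data=out, history=raw.history + [f"interpolate:{','.join(bad)}"]
    )


def detect_bad_channels(raw: SensorEpochs, factor: float = 5.0) -> list[str]:
    """Optional variance screen: channels whose variance exceeds ``factor``
    times the median absolute deviation of channel variances. Off by
    default in the pipeline; visual inspection is the primary route."""
    var = raw.data.reshape(raw.n_channels, -1).var(axis=1)
    med = np.median(var)
    mad = np.median(np.abs(var - med))
    if mad == 0:
        return []
    return [raw.ch_names[i] for i in np.flatnonzero(var > med + factor * mad)]


def rereference_average(raw: SensorEpochs) -> SensorEpochs:
    """Common average reference; a projection, hence idempotent."""
    out = raw.data - raw.data.mean(axis=0, keepdims=True)
    return raw.copy_with(
        data=out,
        reference="average",
        history=raw.history + ["rereference:average"],
    )


def epoch_continuous(
    raw: SensorEpochs,
    length_s: float = 1.0,
    min_epochs: int = 120,
    mask_spans: list[tuple[float, float]] | None = None,
) -> SensorEpochs:
    """Cut a continuous recording into non-overlapping fixed-length epochs.

    ``mask_spans`` are (start_s, end_s) intervals to exclude (artefact
    annotations); epochs are tiled within each clean span and never
    straddle a mask edge. Raises InsufficientEpochsError when fewer than
    ``min_epochs`` epochs survive, mirroring a subject-exclusion rule.
    """
    if raw.n_epochs != 1:
        raise ValueError("epoch_continuous expects a continuous (1-epoch) record")
    n_len = int(round(length_s * raw.fs))
    total = raw.n_samples

    excluded = sorted(
        (max(0, int(np.floor(s * raw.fs))), min(total, int(np.ceil(e * raw.fs))))
        for s, e in (mask_spans or [])
    )
    spans, cursor = [], 0
    for s, e in excluded:
        if s > cursor:
            spans.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < total:
        spans.append((cursor, total))

    starts = [
        a + k * n_len
        for a, bnd in spans
        for k in range((bnd - a) // n_len)
    ]
    if len(starts) < min_epochs:
        raise InsufficientEpochsError(len(starts), min_epochs)
    cut = np.stack([raw.data[:, s : s + n_len, 0] for s in starts], axis=2)
    return raw.copy_with(
        data=cut,
        history=raw.history + [f"epoch:{length_s}s,n={len(starts)}"],
    )
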