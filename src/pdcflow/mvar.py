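"""Multivariate autoregressive (MVAR) models: container, simulation, fitting.

An order-p MVAR over n channels,

    x_t = sum_{r=1..p} A_r x_{t-r} + e_t,   e_t ~ N(0, Sigma),

is the generative object behind every directed-connectivity quantity in
this package. ``A_r[i, j]`` is the influence of channel j at lag r on
channel i at the current sample, so columns are senders and rows are
receivers throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MVARModel:
    """Order-p coefficient matrices plus innovation covariance.

    coeffs has shape (p, n, n); ``coeffs[r]`` is A_{r+1} (lag r+1 in
    samples). Stability means the companion matrix has spectral
    radius < 1, i.e. the process has a stationary distribution.
    """

    coeffs: np.ndarray
    noise_cov: np.ndarray
    fs: float = 125.0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != self.coeffs.shape[2]:
            raise ValueError("coeffs must be (p, n, n)")
        if self.coeffs.shape[0] < 1:
            raise ValueError("model order must be >= 1")
        n = self.coeffs.shape[1]
        if self.noise_cov.shape != (n, n):
            raise ValueError("noise_cov must be (n, n)")
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-12):
            raise ValueError("noise_cov must be symmetric")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("coefficients must be finite")
        # positive semi-definiteness; allow zero covariance for noiseless use
        eigmin = np.linalg.eigvalsh(self.noise_cov).min()
        if eigmin < -1e-10:
            raise ValueError("noise_cov must be positive semi-definite")

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    @property
    def lag_span_ms(self) -> float:
        """Temporal span of the lags in milliseconds (order / fs)."""
        return 1000.0 * self.order / self.fs

    def companion(self) -> np.ndarray:
        """(n*p, n*p) companion matrix stacking the lag matrices."""
        p, n = self.order, self.n_channels
        top = np.concatenate(list(self.coeffs), axis=1)  # (n, n*p)
        bottom = np.eye(n * (p - 1), n * p)
        return np.vstack([top, bottom]) if p > 1 else top

    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.companion())).max())

    def is_stable(self, tol: float = 1.0) -> bool:
        return self.spectral_radius() < tol


def simulate_mvar_epochs(
    model: MVARModel,
    n_epochs: int,
    n_samples: int,
    seed: int,
    burn_in: int | None = None,
) -> np.ndarray:
    """Simulate independent epochs from a stable MVAR model.

    Each epoch starts from zeros, runs ``burn_in`` extra samples (default
    max(10*order, 100)) that are discarded, and uses Gaussian innovations
    with the model's covariance. Returns (n, n_samples, n_epochs).
    Bit-reproducible for a fixed seed.
    """
    if not model.is_stable():
        raise ValueError(
            f"model is unstable (spectral radius {model.spectral_radius():.3f})"
        )
    p, n = model.order, model.n_channels
    if n_samples <= p:
        raise ValueError("n_samples must exceed the model order")
    if burn_in is None:
        burn_in = max(10 * p, 100)
    total = n_samples + burn_in
    rng = np.random.default_rng(seed)
    # sqrt factor of the covariance (eigh handles PSD incl. zero)
    w, v = np.linalg.eigh(model.noise_cov)
    w = np.clip(w, 0.0, None)
    chol = v * np.sqrt(w)
    innov = rng.standard_normal((total, n_epochs, n)) @ chol.T  # (T, E, n)

    x = np.zeros((total, n_epochs, n))
    A = model.coeffs  # (p, n, n)
    for t in range(total):
        acc = innov[t]
        for r in range(min(p, t)):
            acc = acc + x[t - r - 1] @ A[r].T
        x[t] = acc
    out = x[burn_in:]  # (n_samples, E, n)
    return np.ascontiguousarray(out.transpose(2, 0, 1))


def fit_mvar(data: np.ndarray, order: int = 5, fs: float = 125.0) -> MVARModel:
    """Least-squares MVAR fit of one epoch (n, T) or of multiple epochs
    (n, T, E) pooled as independent realisations.

    Channel means are removed (per epoch), x_t is regressed on its
    ``order`` lags — lagged rows never cross an epoch boundary — and the
    residual covariance becomes the innovation-covariance estimate
    (denominator: pooled rows minus n*order regression degrees of
    freedom). Pooling is the standard multi-trial estimator: a model with
    n*order lag coefficients per channel is identifiable from short
    epochs only jointly. The regressor matrix must have full column rank;
    a rank-deficient design raises instead of silently pseudo-inverting.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise ValueError("data must be (n_channels, n_samples[, n_epochs])")
    n, T, E = data.shape
    p = int(order)
    if p < 1:
        raise ValueError("order must be >= 1")
    if E * (T - p) <= n * p:
        raise ValueError(
            f"{E} epoch(s) of T={T} too short to identify {n * p} lag coefficients"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError("data must be finite")
    x = data - data.mean(axis=1, keepdims=True)

    # design rows t = p..T-1 within each epoch, columns [x_{t-1};...;x_{t-p}]
    Ys, Xs = [], []
    for e in range(E):
        xe = x[:, :, e]
        Ys.append(xe[:, p:].T)
        Xs.append(
            np.concatenate([xe[:, p - r : T - r].T for r in range(1, p + 1)], axis=1)
        )
    Y = np.vstack(Ys)  # (E*(T-p), n)
    X = np.vstack(Xs)
    coefs, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < n * p:
        raise np.linalg.LinAlgError(
            f"rank-deficient lag regressor matrix (rank {rank} < {n * p})"
        )
    resid = Y - X @ coefs
    dof = max(len(Y) - n * p, 1)
    sigma = resid.T @ resid / dof
    A = coefs.T.reshape(n, p, n).transpose(1, 0, 2)  # (p, n, n), A[r][i,j]
    return MVARModel(coeffs=A, noise_cov=0.5 * (sigma + sigma.T), fs=fs)
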