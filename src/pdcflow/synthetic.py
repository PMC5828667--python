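"""Ground-truth generators: MVAR source networks, an analytic spherical
forward model, sensor projection, gaze datasets, and phenotype scores.

Everything here exists so that each downstream stage (inverse, PDC,
Proximity Index, statistics) has a recovery test against known truth.
Defaults mirror the study conditions the pipeline targets: 120 epochs of
1 s at 125 Hz, ~111 electrodes, theta/alpha oscillatory source dynamics.
All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import connected_components

from .containers import GazeDataset, Leadfield, SourcePlacement
from .mvar import MVARModel


# ---------------------------------------------------------------------------
# planted directed networks


@dataclass
class GroundTruthNetwork:
    """Planted directed edges (source -> target, strength, lag in samples)."""

    n_rois: int
    edges: list[tuple[int, int, float, int]] = field(default_factory=list)
    hub_rois: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for src, tgt, strength, lag in self.edges:
            if src == tgt:
                raise ValueError("self-edges are not allowed in the planted list")
            if not (0 <= src < self.n_rois and 0 <= tgt < self.n_rois):
                raise ValueError(f"edge ({src}->{tgt}) outside [0, {self.n_rois})")
            if not np.isfinite(strength):
                raise ValueError("edge strengths must be finite")
            if lag < 1:
                raise ValueError("edge lags are in samples and must be >= 1")
        if any(not 0 <= h < self.n_rois for h in self.hub_rois):
            raise ValueError("hub_rois must lie in [0, n_rois)")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "n_rois": self.n_rois,
            "edges": [list(e) for e in self.edges],
            "hub_rois": list(self.hub_rois),
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthNetwork":
        obj = json.loads(Path(path).read_text())
        return cls(
            n_rois=int(obj["n_rois"]),
            edges=[(int(a), int(b), float(c), int(d)) for a, b, c, d in obj["edges"]],
            hub_rois=[int(h) for h in obj["hub_rois"]],
        )


def hub_network(
    n_rois: int, hub: int, targets: list[int], strength: float, lag: int = 1
) -> GroundTruthNetwork:
    """Star network: one dominant driver feeding the given targets."""
    edges = [(hub, t, strength, lag) for t in targets]
    return GroundTruthNetwork(n_rois=n_rois, edges=edges, hub_rois=[hub])


def make_random_stable_mvar(
    n_rois: int,
    order: int,
    network: GroundTruthNetwork,
    offdiag_strength: float = 0.0,
    seed: int = 0,
    osc_freq_hz: float | np.ndarray = 6.0,
    osc_damping: float | np.ndarray = 0.85,
    fs: float = 125.0,
    noise_cov: np.ndarray | None = None,
) -> MVARModel:
    """Build a stable MVAR model embedding the planted network.

    Diagonal dynamics give each channel a damped oscillation peaking at
    ``osc_freq_hz`` (an AR(2) resonance on lags 1-2: a1 = 2 rho cos(2 pi
    f0/fs), a2 = -rho^2), so planted edges carry band-limited content.
    ``offdiag_strength`` adds dense Gaussian background coupling of that
    scale at random lags. Planted edges overwrite the background at their
    (target, source, lag) slots. If the draft exceeds companion spectral
    radius 0.95, all lag-r matrices are scaled by gamma^r, which scales
    the companion eigenvalues by exactly gamma.
    """
    if n_rois < 2:
        raise ValueError("n_rois must be >= 2")
    if order < 1:
        raise ValueError("order must be >= 1")
    if offdiag_strength < 0:
        raise ValueError("offdiag_strength must be >= 0")
    if network.n_rois != n_rois:
        raise ValueError("network.n_rois disagrees with n_rois")
    for _, _, _, lag in network.edges:
        if lag > order:
            raise ValueError(f"planted lag {lag} exceeds model order {order}")

    rng = np.random.default_rng(seed)
    A = np.zeros((order, n_rois, n_rois))

    f0 = np.broadcast_to(np.asarray(osc_freq_hz, dtype=float), (n_rois,))
    rho = np.broadcast_to(np.asarray(osc_damping, dtype=float), (n_rois,))
    if order >= 2:
        a1 = 2.0 * rho * np.cos(2.0 * np.pi * f0 / fs)
        A[0][np.diag_indices(n_rois)] = a1
        A[1][np.diag_indices(n_rois)] = -rho**2
    else:  # order 1: plain damping, no resonance possible
        A[0][np.diag_indices(n_rois)] = rho

    if offdiag_strength > 0:
        for r in range(order):
            block = offdiag_strength * rng.standard_normal((n_rois, n_rois))
            block[np.diag_indices(n_rois)] = 0.0
            mask = rng.random((n_rois, n_rois)) < 1.0 / order
            A[r] += np.where(mask, block, 0.0)

    for src, tgt, strength, lag in network.edges:
        A[lag - 1][tgt, src] = strength

    cov = np.eye(n_rois) if noise_cov is None else np.asarray(noise_cov, float)
    model = MVARModel(coeffs=A, noise_cov=cov, fs=fs)
    rho = model.spectral_radius()
    if rho > 0.95:
        gamma = 0.95 / rho
        scale = gamma ** np.arange(1, order + 1)
        model = MVARModel(
            coeffs=A * scale[:, None, None], noise_cov=cov, fs=fs
        )
    return model


# ---------------------------------------------------------------------------
# analytic single-shell spherical forward model


def _legendre_pn_dpn(t: np.ndarray, nmax: int):
    """Yield (n, P_n(t), P_n'(t)) for n = 1..nmax via stable recurrences."""
    p_prev = np.ones_like(t)  # P_0
    p_cur = t.copy()  # P_1
    d_prev = np.zeros_like(t)  # P_0'
    d_cur = np.ones_like(t)  # P_1'
    yield 1, p_cur, d_cur
    for n in range(1, nmax):
        p_next = ((2 * n + 1) * t * p_cur - n * p_prev) / (n + 1)
        d_next = d_prev + (2 * n + 1) * p_cur  # P'_{n+1} = P'_{n-1} + (2n+1) P_n
        yield n + 1, p_next, d_next
        p_prev, p_cur = p_cur, p_next
        d_prev, d_cur = d_cur, d_next


def spherical_gain(
    electrodes: np.ndarray,
    points: np.ndarray,
    sigma: float = 1.0,
    tol: float = 1e-13,
    nmax: int = 400,
) -> np.ndarray:
    """Surface potential per unit dipole in a homogeneous unit sphere.

    Harmonic-series solution of the insulated-boundary problem: with the
    dipole p at x (b = |x| < 1) and the electrode at unit vector u,

        V = (1/4 pi sigma) sum_{n>=1} ((2n+1)/n) p . grad_x[b^n P_n(t)],
        t = (x . u)/b,

    where grad_x[r^n P_n] = r^{n-1} (n P_n x_hat + P_n' (u - t x_hat)).
    The n = 1 term reduces to 3 (p . u)/(4 pi sigma) at the centre, the
    textbook central-dipole law. Series truncated once b_max^{n-1} (2n+1)
    drops below ``tol``. Returns (n_electrodes, n_points, 3).
    """
    u = np.asarray(electrodes, dtype=float)
    x = np.asarray(points, dtype=float)
    if not np.allclose(np.linalg.norm(u, axis=1), 1.0, atol=1e-8):
        raise ValueError("electrodes must lie on the unit sphere")
    b = np.linalg.norm(x, axis=1)
    if np.any(b >= 1.0 - 1e-9):
        raise ValueError("solution points must lie strictly inside the sphere")

    ne, npt = len(u), len(x)
    xhat = np.where(b[:, None] > 1e-12, x / np.maximum(b, 1e-300)[:, None],
                    np.array([0.0, 0.0, 1.0]))
    t = u @ xhat.T  # (ne, npt) cos angle
    t = np.clip(t, -1.0, 1.0)

    bmax = float(b.max()) if npt else 0.0
    n_terms = 1
    while n_terms < nmax and (bmax ** max(n_terms - 1, 0)) * (2 * n_terms + 1) > tol:
        n_terms += 1

    gain = np.zeros((ne, npt, 3))
    b_pow = np.ones(npt)  # b^{n-1}
    for n, pn, dpn in _legendre_pn_dpn(t, n_terms):
        cn = (2 * n + 1) / n
        # grad vector per (electrode, point): n Pn xhat + Pn' (u - t xhat)
        radial = (n * pn)[:, :, None] * xhat[None, :, :]
        tangential = dpn[:, :, None] * (u[:, None, :] - t[:, :, None] * xhat[None, :, :])
        gain += cn * b_pow[None, :, None] * (radial + tangential)
        b_pow = b_pow * b
    return gain / (4.0 * np.pi * sigma)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + 5.0**0.5) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_spherical_leadfield(
    n_electrodes: int = 111,
    n_solution_points: int = 300,
    seed: int = 0,
    min_radius: float = 0.45,
    max_radius: float = 0.75,
    k_neighbors: int = 6,
) -> Leadfield:
    """Analytic dipole-in-sphere leadfield on a synthetic sensor/source grid.

    Electrodes are a golden-angle lattice on the unit sphere; solution
    points are drawn uniformly in the shell [min_radius, max_radius],
    emulating a grey-matter compartment (cortical mantle plus deep
    structures; the sphere centre itself holds no sources). The neighbor
    graph is the symmetrised k-nearest-neighbor graph (k=6), patched to
    be connected if sampling leaves isolated components.
    """
    if n_electrodes < 8:
        raise ValueError("need at least 8 electrodes")
    if not 0 <= min_radius < max_radius < 1:
        raise ValueError("need 0 <= min_radius < max_radius < 1")
    rng = np.random.default_rng(seed)
    electrodes = fibonacci_sphere(n_electrodes)
    # concentric Fibonacci shells, counts proportional to shell area,
    # each shell randomly rotated: quasi-uniform and exactly n points
    n_shells = 5
    radii = np.linspace(min_radius, max_radius, n_shells)
    weights = radii**2 / (radii**2).sum()
    counts = np.floor(weights * n_solution_points).astype(int)
    counts[-1] += n_solution_points - counts.sum()
    shells = []
    for r, c in zip(radii, counts):
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        shells.append(fibonacci_sphere(max(int(c), 1)) @ q.T * r)
    points = np.vstack(shells)[:n_solution_points]

    gain = spherical_gain(electrodes, points)

    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    adj = np.zeros((n_solution_points, n_solution_points), dtype=int)
    k = min(k_neighbors, n_solution_points - 1)
    nn = np.argsort(d2, axis=1)[:, :k]
    rows = np.repeat(np.arange(n_solution_points), k)
    adj[rows, nn.ravel()] = 1
    adj = np.maximum(adj, adj.T)
    # stitch disconnected components via their closest cross pair
    n_comp, labels = connected_components(adj, directed=False)
    while n_comp > 1:
        in0 = labels == labels[0]
        cross = d2[np.ix_(in0, ~in0)]
        i0, j0 = np.unravel_index(np.argmin(cross), cross.shape)
        a = np.flatnonzero(in0)[i0]
        c = np.flatnonzero(~in0)[j0]
        adj[a, c] = adj[c, a] = 1
        n_comp, labels = connected_components(adj, directed=False)

    return Leadfield(
        gain=gain,
        electrode_positions=electrodes,
        point_positions=points,
        point_neighbors=adj,
    )


def assign_rois_to_points(
    lf: Leadfield,
    n_rois: int,
    seed: int = 0,
    min_radius: float = 0.6,
    orientation: str = "radial",
) -> SourcePlacement:
    """Well-separated ROI placement with physiological orientations.

    Points are chosen by farthest-point sampling restricted to
    cortical-mantle depth (radius >= ``min_radius``), and orientations
    are radial by default — the surface-normal direction of pyramidal
    generators on a spherical cortex, which also gives the ROIs
    comparable sensor visibility. ``orientation="random"`` draws
    arbitrary unit vectors instead. Deterministic per seed.
    """
    if n_rois > lf.n_points:
        raise ValueError("more ROIs than solution points")
    rng = np.random.default_rng(seed)
    pts = lf.point_positions
    depths = np.linalg.norm(pts, axis=1)
    allowed = np.flatnonzero(depths >= min_radius)
    if len(allowed) < n_rois:
        allowed = np.argsort(depths)[-n_rois:]
    blocked = np.setdiff1d(np.arange(lf.n_points), allowed)
    chosen = [int(rng.choice(allowed))]
    d = np.linalg.norm(pts - pts[chosen[0]], axis=1)
    for _ in range(n_rois - 1):
        dd = d.copy()
        dd[blocked] = -1.0
        dd[chosen] = -1.0
        nxt = int(np.argmax(dd))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    if orientation == "radial":
        orient = pts[chosen] / np.linalg.norm(pts[chosen], axis=1, keepdims=True)
    elif orientation == "random":
        orient = rng.standard_normal((n_rois, 3))
        orient /= np.linalg.norm(orient, axis=1, keepdims=True)
    else:
        raise ValueError("orientation must be 'radial' or 'random'")
    return SourcePlacement(point_indices=np.array(chosen), orientations=orient)


def placement_gain(lf: Leadfield, placement: SourcePlacement) -> np.ndarray:
    """(n_electrodes, n_rois) gain of the oriented ROI dipoles."""
    g = lf.gain[:, placement.point_indices, :]  # (ne, nroi, 3)
    return np.einsum("erk,rk->er", g, placement.orientations)


def project_to_sensors(
    sources: np.ndarray,
    lf: Leadfield,
    placement: SourcePlacement,
    snr: float,
    seed: int = 0,
) -> np.ndarray:
    """Forward-project ROI sources and add white sensor noise at a given SNR.

    SNR is the ratio of mean signal power to mean noise power across all
    channels, samples and epochs; ``snr=inf`` gives the noiseless
    projection. Output is average-referenced. Returns
    (n_electrodes, n_samples, n_epochs).
    """
    sources = np.asarray(sources, dtype=float)
    if sources.ndim == 2:
        sources = sources[:, :, None]
    if sources.shape[0] != placement.n_rois:
        raise ValueError("source count does not match placement size")
    if not snr > 0:
        raise ValueError("snr must be positive")
    G = placement_gain(lf, placement)  # (ne, nroi)
    clean = np.einsum("cr,rte->cte", G, sources)  # (ne, T, E)
    if np.isinf(snr):
        noisy = clean
    else:
        rng = np.random.default_rng(seed)
        sig_power = float(np.mean(clean**2))
        noise_std = np.sqrt(sig_power / snr) if sig_power > 0 else 1.0
        noisy = clean + noise_std * rng.standard_normal(clean.shape)
    return noisy - noisy.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# gaze


def simulate_gaze_dataset(
    n_td: int,
    n_test: int,
    n_frames: int,
    deviation: np.ndarray | list[float],
    seed: int = 0,
    frame_rate: float = 25.0,
    n_films: int = 2,
    mixture_sd: float = 0.05,
    secondary_weight: float = 0.3,
    invalid_frac: float = 0.05,
    jitter_sd: float = 0.01,
) -> GazeDataset:
    """Per-frame reference gaze clouds plus deviating test tracks.

    The attention locus is a smooth random walk inside the screen; each
    frame's reference points are drawn from a two-component Gaussian
    mixture (main locus, weight 0.7; a second smoothly moving locus,
    weight 0.3), SD ``mixture_sd`` in screen units. Test subject i gazes
    at the sampled component centre displaced by ``deviation[i] *
    mixture_sd`` in a random direction plus jitter, so delta=0 subjects
    are exchangeable with reference draws. A fraction of samples is
    flagged invalid at random.
    """
    deviation = np.asarray(deviation, dtype=float)
    if n_td < 5:
        raise ValueError("need at least 5 reference subjects")
    if len(deviation) != n_test:
        raise ValueError("deviation must have one entry per test subject")
    if np.any(deviation < 0):
        raise ValueError("deviation values must be >= 0")
    rng = np.random.default_rng(seed)

    def smooth_track(n: int) -> np.ndarray:
        # heavily smoothed random walk mapped into [0.2, 0.8]^2
        steps = rng.standard_normal((n + 200, 2))
        kern = np.hanning(101)
        kern /= kern.sum()
        sm = np.column_stack(
            [np.convolve(steps[:, k], kern, mode="same") for k in range(2)]
        )[200:]
        sm = np.cumsum(sm, axis=0)
        lo, hi = sm.min(axis=0), sm.max(axis=0)
        span = np.where(hi - lo > 0, hi - lo, 1.0)
        return 0.2 + 0.6 * (sm - lo) / span

    locus_main = smooth_track(n_frames)
    locus_alt = smooth_track(n_frames)

    def draw(n_pts_frames: tuple[int, ...], centers_main, centers_alt):
        comp = rng.random(n_pts_frames) < (1.0 - secondary_weight)
        centers = np.where(comp[..., None], centers_main, centers_alt)
        pts = centers + mixture_sd * rng.standard_normal(centers.shape)
        return np.clip(pts, 0.0, 1.0), centers

    ref_xy, _ = draw(
        (n_frames, n_td),
        np.broadcast_to(locus_main[:, None, :], (n_frames, n_td, 2)),
        np.broadcast_to(locus_alt[:, None, :], (n_frames, n_td, 2)),
    )
    ref_valid = (rng.random((n_frames, n_td)) >= invalid_frac).astype(float)
    reference = np.concatenate([ref_xy, ref_valid[..., None]], axis=2)

    test_xy, test_centers = draw(
        (n_test, n_frames),
        np.broadcast_to(locus_main[None, :, :], (n_test, n_frames, 2)),
        np.broadcast_to(locus_alt[None, :, :], (n_test, n_frames, 2)),
    )
    theta = rng.random((n_test, n_frames)) * 2 * np.pi
    offset = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    displaced = (
        test_centers
        + deviation[:, None, None] * mixture_sd * offset
        + mixture_sd * rng.standard_normal((n_test, n_frames, 2))
        + jitter_sd * rng.standard_normal((n_test, n_frames, 2))
    )
    test_xy = np.clip(displaced, 0.0, 1.0)
    test_valid = (rng.random((n_test, n_frames)) >= invalid_frac).astype(float)
    test_tracks = np.concatenate([test_xy, test_valid[..., None]], axis=2)

    film_ids = np.minimum(
        (np.arange(n_frames) * n_films) // max(n_frames, 1), n_films - 1
    )
    return GazeDataset(
        reference=reference,
        test_tracks=test_tracks,
        frame_rate=frame_rate,
        film_ids=film_ids,
    )


def mode_following_gaze_dataset(
    n_frames: int = 15, n_td: int = 8, seed: int = 0, grid_size: int = 64
) -> GazeDataset:
    """Reference clouds plus one test track glued to each frame's KDE
    mode: the constructive case whose Proximity Index is exactly 1."""
    from .gaze import kde_frame

    rng = np.random.default_rng(seed)
    ref = np.zeros((n_frames, n_td, 3))
    ref[:, :, 2] = 1.0
    track = np.zeros((n_frames, 3))
    track[:, 2] = 1.0
    for f in range(n_frames):
        centre = 0.3 + 0.4 * rng.random(2)
        ref[f, :, :2] = np.clip(
            centre + 0.04 * rng.standard_normal((n_td, 2)), 0, 1
        )
        dens = kde_frame(ref[f], grid_size=grid_size)
        i, j = np.unravel_index(np.argmax(dens.values), dens.values.shape)
        track[f, :2] = ((i + 0.5) / grid_size, (j + 0.5) / grid_size)
    return GazeDataset(
        reference=ref,
        test_tracks=track[None, :, :],
        frame_rate=25.0,
        film_ids=np.array(
            [0] * (n_frames // 2) + [1] * (n_frames - n_frames // 2)
        ),
    )


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    outflow: np.ndarray | list[float],
    rho: float,
    seed: int = 0,
    loc: float = 75.0,
    scale: float = 12.0,
):
    """Scores with a target Spearman correlation to per-subject outflow.

    Gaussian-copula construction: the latent score is rho_p * z(x) +
    sqrt(1-rho_p^2) * eps with rho_p = 2 sin(pi rho / 6), the Pearson
    correlation whose bivariate-normal Spearman equals ``rho``. The
    latent values are affinely mapped to a standard-score-like range
    (monotone, so Spearman is preserved). rho = +/-1 bypasses the noise
    and returns an exact monotone transform.
    """
    import pandas as pd

    x = np.asarray(outflow, dtype=float)
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 subjects")
    rng = np.random.default_rng(seed)
    ranks = np.argsort(np.argsort(x))
    zx = np.array(
        [float(v) for v in _normal_scores(ranks, n)]
    )
    if abs(rho) == 1.0:
        latent = np.sign(rho) * zx
    else:
        rho_p = 2.0 * np.sin(np.pi * rho / 6.0)
        latent = rho_p * zx + np.sqrt(1.0 - rho_p**2) * rng.standard_normal(n)
    scores = loc + scale * latent
    return pd.DataFrame(
        {"subject_id": [f"S{i:03d}" for i in range(n)], "score": scores}
    )


def _normal_scores(ranks: np.ndarray, n: int) -> np.ndarray:
    from scipy.stats import norm

    return norm.ppf((ranks + 1 - 0.375) / (n + 0.25))  # Blom plotting positions
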