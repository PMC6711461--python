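"""Noise singular-value spectra and optimal singular value shrinkage.

Each patch Casorati matrix is modeled as Y = X + W with X low rank and W
zero-mean complex Gaussian noise whose covariance follows from the
reconstruction.  The asymptotic behaviour of the singular values of Y
depends on the noise only through the empirical spectral distribution (ESD)
of noise-only matrices, f(eta_W), with bulk upper edge eta_W+.  From a
discrete ESD one evaluates

    phi(x)  = mean_m [ x / (x^2 - eta_m^2) ],
    D(x)    = phi(x) * (gamma * phi(x) + (1 - gamma) / x),     x > eta_W+,

and the shrinker that asymptotically minimizes the Frobenius loss maps each
observed singular value eta_Y above the edge to -2 D(eta_Y) / D'(eta_Y) and
everything at or below the edge to zero.  The number of surviving values is
the rank estimate; the estimated asymptotic MSE of the recovered matrix is
sum over kept components of 1/D(eta_Y) - eta_hat_X^2.

The ESD is obtained either by Monte-Carlo simulation from an arbitrary
patch noise covariance (including the per-encoding-group heteroscedastic
case) or, for white noise, from the closed-form Marchenko-Pastur law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recon import PatchCovariance

__all__ = [
    "ESDModel",
    "ShrinkageResult",
    "simulate_esd",
    "mp_closed_form_esd",
    "d_transform",
    "d_transform_deriv",
    "shrink",
    "estimate_amse",
    "spiked_limit",
    "mp_singular_quantiles",
]


@dataclass
class ESDModel:
    """Discrete noise singular-value spectrum on the M x N scale.

    ``spectrum`` holds B*M non-negative atoms sorted decreasingly (zero
    padded when M > N); ``edge`` is the detection threshold eta_W+;
    ``gamma`` = M/N is the Casorati aspect ratio.
    """

    spectrum: np.ndarray
    edge: float
    gamma: float
    B: int = 1
    provenance: str = "monte_carlo"
    seed: int | None = None

    def __post_init__(self):
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        if np.any(self.spectrum < 0):
            raise ValueError("noise spectrum must be non-negative")
        if np.any(np.diff(self.spectrum) > 1e-12):
            raise ValueError("noise spectrum must be sorted decreasingly")
        if self.gamma <= 0:
            raise ValueError("aspect ratio must be positive")


@dataclass
class ShrinkageResult:
    """Shrunk singular values, rank estimate and AMSE for one patch."""

    eta_hat: np.ndarray
    rank: int
    amse: float
    kept_indices: np.ndarray


def _draw_noise_matrix(pc: PatchCovariance, M: int, N: int, B: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw a (B*M) x (B*N) matrix following the patch noise law.

    The spatial covariance is block-replicated B times across rows; for the
    heteroscedastic (INTER) case each encoding's column group is replicated
    B times with its own spatial covariance.
    """
    def chol_psd(mat):
        mat = np.asarray(mat, dtype=np.complex128)
        vals, vecs = np.linalg.eigh((mat + mat.conj().T) / 2.0)
        if vals.min() < -1e-8 * max(vals.max(), 1.0):
            raise ValueError("patch covariance is not positive semi-definite")
        vals = np.clip(vals, 0.0, None)
        return vecs * np.sqrt(vals)

    def iid(shape):
        return (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2.0)

    BM, BN = B * M, B * N
    if pc.stationary:
        C = chol_psd(pc.matrix)
        G = iid((BM, BN))
        W = np.empty((BM, BN), dtype=np.complex128)
        for b in range(B):
            W[b * M:(b + 1) * M] = C @ G[b * M:(b + 1) * M]
        return W
    W = np.empty((BM, BN), dtype=np.complex128)
    col = 0
    for enc, cols in sorted(pc.volume_groups.items()):
        C = chol_psd(pc.per_encoding[enc])
        n_a = len(cols) * B
        G = iid((BM, n_a))
        for b in range(B):
            W[b * M:(b + 1) * M, col:col + n_a] = C @ G[b * M:(b + 1) * M]
        col += n_a
    if col != BN:
        raise ValueError("volume groups do not partition the columns")
    return W


def simulate_esd(pc: PatchCovariance, M: int, N: int, B: int = 2,
                 seed: int = 0) -> ESDModel:
    """Monte-Carlo ESD: singular values of one B(M x N) noise draw.

    The (B*M) x (B*N) draw preserves the aspect ratio; dividing its singular
    values by sqrt(B) maps the spectrum onto the M x N singular-value scale.
    The edge estimate is the largest simulated value.
    """
    if B < 1 or int(B) != B:
        raise ValueError("oversampling factor B must be a positive integer")
    rng = np.random.default_rng(seed)
    W = _draw_noise_matrix(pc, M, N, int(B), rng)
    sv = np.linalg.svd(W, compute_uv=False) / np.sqrt(B)
    spectrum = np.zeros(int(B) * M)
    spectrum[: len(sv)] = sv  # zero-padded when M > N
    return ESDModel(spectrum=spectrum, edge=float(spectrum[0]), gamma=M / N,
                    B=int(B), provenance="monte_carlo", seed=seed)


def mp_singular_quantiles(gamma: float, n_points: int) -> np.ndarray:
    """Quantiles of the unit-scale Marchenko-Pastur singular-value law.

    Works on the normalized scale where bulk singular values lie in
    [|1 - sqrt(gamma)|, 1 + sqrt(gamma)]; for gamma > 1 a point mass of
    weight 1 - 1/gamma sits at zero.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    g = gamma
    lo, hi = (1 - np.sqrt(g)) ** 2, (1 + np.sqrt(g)) ** 2
    lam = np.linspace(lo + 1e-12, hi - 1e-12, 20001)
    # standard MP density; its positive-part mass is 1 for gamma <= 1 and
    # 1/gamma for gamma > 1 (the remainder is a point mass at zero)
    dens = np.sqrt(np.maximum((hi - lam) * (lam - lo), 0.0)) / (2 * np.pi * g * lam)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(lam))])
    mass0 = max(1.0 - 1.0 / g, 0.0)
    cdf = mass0 + cdf
    cdf /= cdf[-1]
    probs = (np.arange(n_points) + 0.5) / n_points
    out = np.zeros(n_points)
    positive = probs > mass0
    out[positive] = np.sqrt(np.interp(probs[positive], cdf, lam))
    return np.sort(out)[::-1]


def mp_closed_form_esd(gamma: float, sigma: float = 1.0, n_points: int = 2000) -> ESDModel:
    """Deterministic Marchenko-Pastur ESD for white noise of scale sigma.

    Atoms are quantiles of the MP singular-value law scaled by sigma, with
    the top atom pinned to the exact bulk edge sigma * (1 + sqrt(gamma)).
    """
    q = sigma * mp_singular_quantiles(gamma, n_points)
    edge = sigma * (1 + np.sqrt(gamma))
    q[0] = edge
    return ESDModel(spectrum=q, edge=float(edge), gamma=gamma,
                    B=1, provenance="mp_closed_form")


def _phi(x, spectrum):
    x = np.asarray(x, dtype=float)
    denom = x[..., None] ** 2 - spectrum ** 2
    return (x[..., None] / denom).mean(axis=-1)


def _phi_prime(x, spectrum):
    x = np.asarray(x, dtype=float)
    x2, e2 = x[..., None] ** 2, spectrum ** 2
    return (-(x2 + e2) / (x2 - e2) ** 2).mean(axis=-1)


def _check_domain(x, esd: ESDModel):
    x = np.asarray(x, dtype=float)
    if np.any(x <= esd.edge):
        raise ValueError(
            f"D-transform requires x > edge ({esd.edge:.6g}); values at or "
            "below the edge belong to the zero branch of the shrinker"
        )
    return x


def d_transform(x, esd: ESDModel):
    """D-transform of the discrete ESD, defined for x above the bulk edge."""
    x = _check_domain(x, esd)
    phi = _phi(x, esd.spectrum)
    out = phi * (esd.gamma * phi + (1 - esd.gamma) / x)
    return out if out.ndim else float(out)


def d_transform_deriv(x, esd: ESDModel):
    """Exact derivative of :func:`d_transform` from the discrete atoms."""
    x = _check_domain(x, esd)
    phi = _phi(x, esd.spectrum)
    dphi = _phi_prime(x, esd.spectrum)
    out = dphi * (esd.gamma * phi + (1 - esd.gamma) / x) + phi * (
        esd.gamma * dphi - (1 - esd.gamma) / x ** 2
    )
    return out if out.ndim else float(out)


def shrink(eta_y: np.ndarray, esd: ESDModel) -> ShrinkageResult:
    """Optimal Frobenius shrinkage of observed singular values.

    Values above the bulk edge map to -2 D / D'; values at or below the edge
    are set exactly to zero.  Negative numerical outputs are clamped to 0.
    The rank estimate is the count of surviving components and the AMSE is
    computed over them.
    """
    eta_y = np.asarray(eta_y, dtype=float)
    if np.any(np.diff(eta_y) > 1e-12):
        raise ValueError("observed singular values must be sorted decreasingly")
    kept = np.flatnonzero(eta_y > esd.edge)
    eta_hat = np.zeros_like(eta_y)
    amse = 0.0
    if len(kept):
        x = eta_y[kept]
        D = d_transform(x, esd)
        Dp = d_transform_deriv(x, esd)
        vals = -2.0 * np.atleast_1d(D) / np.atleast_1d(Dp)
        vals = np.maximum(vals, 0.0)
        eta_hat[kept] = vals
        terms = 1.0 / np.atleast_1d(D) - vals ** 2
        amse = float(np.maximum(terms, 0.0).sum())
    return ShrinkageResult(eta_hat=eta_hat, rank=int(len(kept)), amse=amse,
                           kept_indices=kept)


def estimate_amse(eta_y: np.ndarray, result: ShrinkageResult, esd: ESDModel) -> float:
    """Asymptotic MSE estimate: sum over kept r of 1/D(eta_Y_r) - eta_hat_r^2.

    Negative terms (possible numerically just above the edge) are floored
    at zero.  With no kept components the estimate is zero.
    """
    if result.rank == 0:
        return 0.0
    x = np.asarray(eta_y, dtype=float)[result.kept_indices]
    D = np.atleast_1d(d_transform(x, esd))
    terms = 1.0 / D - result.eta_hat[result.kept_indices] ** 2
    return float(np.maximum(terms, 0.0).sum())


def spiked_limit(population_sv_squared: float, gamma: float) -> float:
    """Deterministic large-N limit of a spiked sample eigenvalue.

    For a population spike eta_X^2 > 1 + sqrt(gamma) above the detection
    threshold, the top sample eigenvalue converges to
    eta_X^2 * (1 + gamma / (eta_X^2 - 1)); always >= eta_X^2 (positive bias).
    """
    ex2 = float(population_sv_squared)
    if ex2 <= 1.0:
        raise ValueError("population eigenvalue must exceed 1 (the noise level)")
    return ex2 * (1.0 + gamma / (ex2 - 1.0))
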