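"""Constrained deconvolution of fluorescence decays on a discrete Laguerre basis.

The fluorescence impulse response ``h`` of a pixel is expanded on an
orthonormal discrete-time Laguerre basis, ``h = B c``, and the expansion
coefficients are estimated by least squares against the measured decay
``y ≈ irf ⊛ h`` subject to the physical constraint ``h ≥ 0`` (fluorescence
cannot be negative).  The exponentially decaying basis regularizes the
deconvolution, so only a handful of coefficients are fitted per pixel.

Two summary parameters are derived from the deconvolved response:

* the **average lifetime**, the expected value of the photon-arrival-time
  distribution obtained by normalizing ``h`` by its area, and
* the **integrated intensity** of the refit observation ``irf ⊛ h``, from
  which per-channel intensity ratios are formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import nnls
from scipy.signal import fftconvolve, lfilter

__all__ = [
    "LaguerreBasis",
    "DeconvResult",
    "DeconvolutionEngine",
    "laguerre_basis",
    "deconvolve",
    "average_lifetime",
    "intensity_ratio",
    "calibrate_alpha",
]

DEFAULT_ALPHA = 0.96
DEFAULT_ORDER = 12
#: grid searched when the basis scale is calibrated against data
DEFAULT_ALPHA_GRID = (0.90, 0.92, 0.94, 0.96, 0.98)

_ORTHO_TOL = 1e-8
_TAIL_TOL = 1e-3
_MAX_AUTO_LENGTH = 1 << 15


@dataclass(frozen=True)
class LaguerreBasis:
    """Orthonormal discrete-time Laguerre functions, one per column of ``B``.

    ``alpha`` in (0, 1) sets the exponential time scale of the functions
    (larger alpha = slower decay); ``order`` is the number of functions.
    ``length`` is the number of samples over which the functions are
    constructed; it must be long enough for every function to decay within
    it, which is what makes the columns orthonormal in finite precision.
    The recurrence is causal, so ``B[:n]`` for any ``n <= length`` equals
    the basis one would build directly at length ``n``.
    """

    alpha: float
    order: int
    length: int
    B: np.ndarray = field(repr=False)

    def restricted(self, n: int) -> np.ndarray:
        """First ``n`` rows of the basis (the analysis window)."""
        if n > self.length:
            raise ValueError(
                f"data length {n} exceeds basis length {self.length}"
            )
        return self.B[:n]


def _build_matrix(alpha: float, order: int, length: int) -> np.ndarray:
    a = np.sqrt(alpha)
    B = np.empty((length, order))
    n = np.arange(length)
    B[:, 0] = np.sqrt(1.0 - alpha) * a**n
    # b_j(n) = sqrt(a) b_j(n-1) + sqrt(a) b_{j-1}(n) - b_{j-1}(n-1):
    # an order-1 IIR filter of the previous function.
    for j in range(1, order):
        B[:, j] = lfilter([a, -1.0], [1.0, -a], B[:, j - 1])
    return B


def _invariants_ok(B: np.ndarray) -> tuple[bool, float, float]:
    order = B.shape[1]
    ortho = float(np.max(np.abs(B.T @ B - np.eye(order))))
    ntail = max(1, int(0.05 * B.shape[0]))
    tail = float(
        np.max(np.max(np.abs(B[-ntail:, :]), axis=0) / np.max(np.abs(B), axis=0))
    )
    return ortho < _ORTHO_TOL and tail < _TAIL_TOL, ortho, tail


def laguerre_basis(
    alpha: float, order: int = DEFAULT_ORDER, length: int | None = None
) -> LaguerreBasis:
    """Construct an orthonormal discrete Laguerre basis.

    Parameters
    ----------
    alpha
        Scale parameter in (0, 1).
    order
        Number of basis functions (1..30).
    length
        Number of samples.  If ``None`` the length is grown automatically
        (starting at 1024, doubling) until the columns are orthonormal to
        1e-8 and each function's tail (last 5% of samples) is below 1e-3
        of its peak.

    Raises
    ------
    ValueError
        If the invariants cannot be met at the requested (or maximum
        automatic) length — the remedy is a smaller alpha or a longer
        window.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not 1 <= order <= 30:
        raise ValueError(f"order must be in 1..30, got {order}")
    if length is not None:
        if length < order:
            raise ValueError("length must be at least the basis order")
        B = _build_matrix(alpha, order, length)
        ok, ortho, tail = _invariants_ok(B)
        if not ok:
            raise ValueError(
                f"Laguerre basis (alpha={alpha}, order={order}, length={length}) "
                f"does not decay within its window (orthonormality error "
                f"{ortho:.2e}, tail fraction {tail:.2e}); use a smaller alpha "
                f"or a longer window"
            )
        return LaguerreBasis(alpha, order, length, B)
    n = 1024
    while n <= _MAX_AUTO_LENGTH:
        B = _build_matrix(alpha, order, n)
        ok, _, _ = _invariants_ok(B)
        if ok:
            return LaguerreBasis(alpha, order, n, B)
        n *= 2
    raise ValueError(
        f"Laguerre basis (alpha={alpha}, order={order}) does not decay within "
        f"{_MAX_AUTO_LENGTH} samples; use a smaller alpha"
    )


def average_lifetime(h: np.ndarray, dt: float) -> float:
    """Intensity-weighted mean arrival time of a decay, in the units of ``dt``.

    Defined as ``sum(t_n h_n) / sum(h_n)`` with ``t_n = n dt`` — the
    expected value of the distribution obtained by normalizing the decay
    by its area.
    """
    h = np.asarray(h, dtype=float)
    s = h.sum()
    if not s > 0:
        raise ValueError("average lifetime undefined: decay has non-positive area")
    t = np.arange(h.shape[0]) * dt
    return float((t * h).sum() / s)


def intensity_ratio(intensities) -> np.ndarray:
    """Normalize three channel intensities to the 3-simplex.

    The last component is computed as the complement so the triple sums to
    1 exactly.
    """
    v = np.asarray(intensities, dtype=float)
    if v.shape != (3,):
        raise ValueError("expected exactly 3 channel intensities")
    if np.any(v < 0):
        raise ValueError("intensities must be non-negative")
    s = v.sum()
    if not s > 0:
        raise ValueError("intensity ratio undefined: zero total intensity")
    r = np.empty(3)
    r[0] = v[0] / s
    r[1] = v[1] / s
    r[2] = 1.0 - r[0] - r[1]
    return r


@dataclass
class DeconvResult:
    """Outcome of deconvolving a single channel decay."""

    coeffs: np.ndarray
    h: np.ndarray
    avg_lifetime: float
    intensity: float
    residual_rms: float
    converged: bool


class DeconvolutionEngine:
    """Reusable solver for one (irf, basis) pair.

    Precomputes the convolved design matrix ``A = irf ⊛ B`` and its QR
    factorization; per-pixel solves are a triangular back-substitution.
    For pixels whose unconstrained reconstruction dips negative, the
    inequality-constrained quadratic program is solved exactly via its
    Moreau/polar-cone dual: with ``A = QR`` and ``d = Qᵀy`` the problem is
    the projection of ``d`` onto the cone ``{u : G R⁻¹ u ≥ 0}``, whose
    dual is the non-negative least-squares problem
    ``min_{μ≥0} ‖(G R⁻¹)ᵀ μ + d‖²`` solved by Lawson–Hanson NNLS.
    """

    def __init__(
        self,
        irf: np.ndarray,
        basis: LaguerreBasis,
        dt: float,
        monotone: bool = False,
    ):
        irf = np.asarray(irf, dtype=float)
        self.n = irf.shape[0]
        self.dt = float(dt)
        self.basis = basis
        self.Bw = basis.restricted(self.n)
        cols = [fftconvolve(self.Bw[:, j], irf)[: self.n] for j in range(basis.order)]
        self.A = np.stack(cols, axis=1)
        Q, R = np.linalg.qr(self.A)
        sign = np.sign(np.diag(R))
        sign[sign == 0] = 1.0
        self.Q = Q * sign
        self.R = R * sign[:, None]
        G = self.Bw
        if monotone:
            # optional h_{n+1} <= h_n rows: (B[n] - B[n+1]) c >= 0
            G = np.vstack([G, self.Bw[:-1] - self.Bw[1:]])
        norms = np.linalg.norm(G, axis=1)
        self.G = G / np.maximum(norms, 1e-300)[:, None]
        # dual NNLS matrix (order x n_constraints): (G R^-1)^T = R^-T G^T
        self.Mt = solve_triangular(self.R, self.G.T, trans="T", lower=False)

    # -- solvers ---------------------------------------------------------

    def _constrained(self, d: np.ndarray) -> tuple[np.ndarray, bool]:
        """Project d = Q'y onto {u: G R^-1 u >= 0}; return (c, converged)."""
        scale = float(np.max(np.abs(d))) or 1.0
        try:
            mu, _ = nnls(self.Mt, -d / scale)
            ok = True
        except RuntimeError:  # iteration cap inside Lawson-Hanson
            mu = np.zeros(self.Mt.shape[1])
            ok = False
        u = d + scale * (self.Mt @ mu)
        c = solve_triangular(self.R, u, lower=False)
        return c, ok

    def _finish(self, c: np.ndarray, y: np.ndarray, converged: bool) -> DeconvResult:
        h = self.Bw @ c
        h = np.where(h < 0, 0.0, h)  # project numerical dust onto the cone
        fit = self.A @ c
        resid = y - fit
        y_rms = float(np.sqrt(np.mean(y**2)))
        residual_rms = float(np.sqrt(np.mean(resid**2)) / y_rms) if y_rms > 0 else 0.0
        intensity = float(fit.sum() * self.dt)
        if h.sum() > 0:
            lt = average_lifetime(h, self.dt)
        else:
            lt = float("nan")
            converged = False
        return DeconvResult(c, h, lt, intensity, residual_rms, converged)

    def solve(self, y: np.ndarray) -> DeconvResult:
        y = np.asarray(y, dtype=float)
        d = self.Q.T @ y
        c = solve_triangular(self.R, d, lower=False)
        g = self.G @ c
        scale = float(np.max(np.abs(g))) or 1.0
        if g.min() >= -1e-9 * scale:
            return self._finish(c, y, True)
        c, ok = self._constrained(d)
        return self._finish(c, y, ok)

    def solve_many(self, Y: np.ndarray) -> list[DeconvResult]:
        """Deconvolve many decays (rows of ``Y``) with a shared vectorized
        unconstrained pass; only violating pixels fall back to the QP."""
        Y = np.asarray(Y, dtype=float)
        D = self.Q.T @ Y.T  # order x npix
        Cu = solve_triangular(self.R, D, lower=False)
        Gall = self.G @ Cu
        Hmin = Gall.min(axis=0)
        Hmax = np.abs(Gall).max(axis=0)
        out: list[DeconvResult] = []
        for i in range(Y.shape[0]):
            if Hmin[i] >= -1e-9 * (Hmax[i] or 1.0):
                out.append(self._finish(Cu[:, i], Y[i], True))
            else:
                c, ok = self._constrained(D[:, i])
                out.append(self._finish(c, Y[i], ok))
        return out


def deconvolve(
    y: np.ndarray,
    irf: np.ndarray,
    basis: LaguerreBasis,
    dt: float,
    monotone: bool = False,
) -> DeconvResult:
    """Deconvolve one decay: min ||irf ⊛ (B c) − y||² s.t. (B c) ≥ 0."""
    return DeconvolutionEngine(irf, basis, dt, monotone=monotone).solve(y)


def calibrate_alpha(
    decays: np.ndarray,
    irf: np.ndarray,
    dt: float,
    order: int = DEFAULT_ORDER,
    grid=DEFAULT_ALPHA_GRID,
) -> float:
    """Pick the basis scale by grid search, minimizing the mean relative
    residual of the constrained fit over a calibration set of decays.

    At realistic noise levels the residual is flat across all adequate
    alphas (the noise floor dominates), so ties within 0.5% of the
    minimum are broken toward the largest alpha — the basis with the
    longest time support, whose truncation bias is smallest.  Alphas
    whose basis cannot satisfy its invariants are skipped.
    """
    decays = np.atleast_2d(np.asarray(decays, dtype=float))
    residuals: dict[float, float] = {}
    for alpha in grid:
        try:
            basis = laguerre_basis(alpha, order)
        except ValueError:
            continue
        engine = DeconvolutionEngine(irf, basis, dt)
        residuals[alpha] = float(
            np.mean([r.residual_rms for r in engine.solve_many(decays)])
        )
    if not residuals:
        raise ValueError("no alpha in the grid yields a valid basis")
    rmin = min(residuals.values())
    return max(a for a, r in residuals.items() if r <= rmin * 1.005 + 1e-15)
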