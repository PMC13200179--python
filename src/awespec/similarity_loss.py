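"""One-dimensional multiscale structural similarity (MS-SSIM) and the
composite training objective.

At each scale k, spectra are smoothed with a Gaussian kernel whose standard
deviation is a fixed fraction of the spectral length (defaults 3%, 5% and 7%),
yielding local means mu, variances sigma^2 and the cross-covariance sigma_xy.
The pointwise similarity

    SSIM = (2 mu_x mu_y + C1)(2 sigma_xy + C2)
           / ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2))

is averaged over spectral points to a scalar s_k, and the scales are combined
as a normalized weighted average.  The stabilization constants use the global
data range R = max(yhat, y) - min(yhat, y, 0) with C1 = (0.01 R)^2 and
C2 = (0.03 R)^2.  The loss is 1 - MS-SSIM in [0, 2]; the composite objective
adds a mean-squared error over the spectral-basis coefficients, with no extra
weighting factor between the two terms.

Smoothing is realized as multiplication with a dense convolution operator
(kernel truncated at 3 standard deviations, reflective boundary padding),
which makes the same code path usable both on plain numpy arrays (evaluation
metric) and on autodiff tensors (training objective).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .autodiff import Tensor, concat, maximum_const
from .exceptions import ContractError, ValidationError

__all__ = ["MsSsimConfig", "LossBreakdown", "gaussian_local_stats",
           "ssim_single_scale", "ms_ssim", "ms_ssim_loss", "composite_loss",
           "ms_ssim_loss_tensor", "window_widths", "smoothing_operator"]


@dataclass(frozen=True)
class MsSsimConfig:
    """Scale fractions (of the spectral length), scale weights and prefactors."""

    scale_fractions: tuple[float, ...] = (0.03, 0.05, 0.07)
    scale_weights: tuple[float, ...] = (1.0, 1.0, 1.0)
    c1_prefactor: float = 0.01
    c2_prefactor: float = 0.03

    def __post_init__(self):
        if any(not 0 < f < 1 for f in self.scale_fractions):
            raise ValueError("scale fractions must lie in (0, 1)")
        if len(self.scale_weights) != len(self.scale_fractions):
            raise ValueError("one weight per scale required")
        if any(w <= 0 for w in self.scale_weights):
            raise ValueError("scale weights must be positive")

    @property
    def normalized_weights(self) -> np.ndarray:
        w = np.asarray(self.scale_weights, dtype=float)
        return w / w.sum()


@dataclass(frozen=True)
class LossBreakdown:
    ssim_term: float
    coeff_mse: float

    @property
    def total(self) -> float:
        return self.ssim_term + self.coeff_mse


def window_widths(n_points: int, config: MsSsimConfig) -> list[int]:
    """Window width in grid points per scale: round(fraction * N), minimum 1."""
    return [max(1, round(f * n_points)) for f in config.scale_fractions]


@lru_cache(maxsize=32)
def smoothing_operator(n_points: int, width: int) -> np.ndarray:
    """Dense Gaussian smoothing matrix with reflective padding.

    Kernel std equals ``width`` grid points, truncated at 3 std.  Row i of the
    returned (n, n) matrix holds the effective weights of grid point j after
    folding the out-of-range taps back by reflection (edge not repeated).
    """
    radius = int(np.ceil(3.0 * width))
    taps = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (taps / float(width)) ** 2)
    kernel /= kernel.sum()
    op = np.zeros((n_points, n_points))
    for i in range(n_points):
        for t, kv in zip(taps, kernel):
            j = i + t
            # reflect without repeating the edge sample (like np.pad 'reflect')
            while j < 0 or j >= n_points:
                if j < 0:
                    j = -j
                else:
                    j = 2 * (n_points - 1) - j
            op[i, j] += kv
    return op


def gaussian_local_stats(a: np.ndarray, b: np.ndarray, window_width: int):
    """Local means, variances and cross-covariance at one smoothing scale.

    Variances are computed as E[x^2] - E[x]^2 under the same kernel and
    floored at zero against roundoff.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ContractError("inputs must be equal-length vectors")
    if window_width < 1:
        raise ValueError("window width must be >= 1 point")
    op = smoothing_operator(a.size, int(window_width))
    mu_a, mu_b = op @ a, op @ b
    var_a = np.maximum(op @ (a * a) - mu_a ** 2, 0.0)
    var_b = np.maximum(op @ (b * b) - mu_b ** 2, 0.0)
    cov = op @ (a * b) - mu_a * mu_b
    return mu_a, mu_b, var_a, var_b, cov


def _data_range(yhat: np.ndarray, y: np.ndarray) -> float:
    return float(max(yhat.max(), y.max()) - min(yhat.min(), y.min(), 0.0))


def ssim_single_scale(yhat: np.ndarray, y: np.ndarray, k: int,
                      config: MsSsimConfig = MsSsimConfig()) -> float:
    """Scalar structural-similarity score s_k at scale index k."""
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    if yhat.shape != y.shape:
        raise ContractError("spectra must share a grid")
    if not (np.all(np.isfinite(yhat)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in SSIM input")
    r = _data_range(yhat, y)
    if r == 0.0:
        # both signals are identically zero: define similarity as 1 so the
        # objective stays continuous at the degenerate point
        return 1.0
    width = window_widths(y.size, config)[k]
    mu_a, mu_b, var_a, var_b, cov = gaussian_local_stats(yhat, y, width)
    c1 = (config.c1_prefactor * r) ** 2
    c2 = (config.c2_prefactor * r) ** 2
    ssim_map = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)
                / ((mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)))
    return float(ssim_map.mean())


def ms_ssim(yhat: np.ndarray, y: np.ndarray,
            config: MsSsimConfig = MsSsimConfig()) -> float:
    """Normalized weighted average of the per-scale scores; symmetric, in [-1, 1]."""
    weights = config.normalized_weights
    return float(sum(w * ssim_single_scale(yhat, y, k, config)
                     for k, w in enumerate(weights)))


def ms_ssim_loss(yhat: np.ndarray, y: np.ndarray,
                 config: MsSsimConfig = MsSsimConfig()) -> float:
    """1 - MS-SSIM, in [0, 2]; zero iff the similarity is perfect."""
    return 1.0 - ms_ssim(yhat, y, config)


def composite_loss(yhat: np.ndarray, y: np.ndarray, c_pred, c_ref,
                   config: MsSsimConfig = MsSsimConfig()) -> LossBreakdown:
    """MS-SSIM loss plus mean-squared error over the basis coefficients."""
    basis_pred = getattr(c_pred, "basis", None)
    basis_ref = getattr(c_ref, "basis", None)
    if basis_pred is not None and basis_ref is not None and basis_pred is not basis_ref:
        raise ContractError("coefficient vectors belong to different bases")
    cp = np.asarray(getattr(c_pred, "values", c_pred), dtype=float)
    cr = np.asarray(getattr(c_ref, "values", c_ref), dtype=float)
    if cp.shape != cr.shape:
        raise ContractError("coefficient vectors differ in length")
    return LossBreakdown(ssim_term=ms_ssim_loss(yhat, y, config),
                         coeff_mse=float(np.mean((cp - cr) ** 2)))


# --------------------------------------------------------------- tensor path
def ms_ssim_loss_tensor(yhat: Tensor, y: np.ndarray,
                        config: MsSsimConfig = MsSsimConfig()) -> Tensor:
    """Batched differentiable 1 - MS-SSIM for training.

    ``yhat`` is a (B, N_E) tensor on the tape, ``y`` a constant (B, N_E)
    array.  Identical formula to the numpy path (same smoothing operators,
    same range definition), evaluated per sample and averaged over the batch.
    The degenerate both-signals-zero branch is not taken during training
    (targets always carry an absorption edge) and is therefore only handled
    on the numpy metric path.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if yhat.ndim == 1:
        yhat = yhat.reshape(1, -1)
    _, n_e = y.shape
    both = concat([yhat, Tensor(y)], axis=-1)            # (B, 2 N_E)
    mx = both.max(axis=-1, keepdims=True)
    mn = both.min(axis=-1, keepdims=True)
    r = mx - (-maximum_const(-mn, 0.0))                  # max(yhat,y) - min(yhat,y,0)
    c1 = (config.c1_prefactor ** 2) * r * r
    c2 = (config.c2_prefactor ** 2) * r * r
    weights = config.normalized_weights
    widths = window_widths(n_e, config)
    total = None
    for k, w in enumerate(weights):
        op_t = smoothing_operator(n_e, widths[k]).T      # right-multiplication
        mu_a = yhat @ op_t
        mu_b = y @ op_t
        var_a = maximum_const((yhat * yhat) @ op_t - mu_a * mu_a, 0.0)
        var_b = np.maximum((y * y) @ op_t - mu_b * mu_b, 0.0)
        cov = (yhat * y) @ op_t - mu_a * mu_b
        ssim_map = ((2.0 * mu_a * mu_b + c1) * (2.0 * cov + c2)
                    / ((mu_a * mu_a + mu_b * mu_b + c1) * (var_a + var_b + c2)))
        s_k = ssim_map.mean(axis=-1)                     # (B,)
        total = s_k * float(w) if total is None else total + s_k * float(w)
    return (1.0 - total).mean()
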