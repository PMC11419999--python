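"""Artifact-removal filters: anisotropic diffusion and non-local means.

Both filters operate on normalised [0, 1] reconstructions and are written
directly from their defining update rules rather than wrapping a library
implementation, because their exact discrete behaviour is what the
evaluation stage measures.

**Anisotropic diffusion (Perona-Malik).**  Explicit Euler iteration of
``dI/dt = div(c(|grad I|) grad I)``: each pixel s moves by
``(dt / |eta_s|) * sum_p c(|I_p - I_s|) (I_p - I_s)`` over its 4-neighbour
set eta_s (smaller at borders), with reflective boundaries.  The diffusion
coefficient is either ``exp(-(x/k)^2)`` or the rational ``1/(1+(x/k)^2)``;
gradients far above the edge scale k stop diffusing (edges kept), far
below k the update tends to isotropic smoothing.

**Non-local means.**  Each output pixel is the weighted average of all
pixels in its search window, the weight being
``exp(-||v_p - v_q||^2 / h^2)`` on the squared Euclidean distance between
the two patch vectors (reflective padding at borders), normalised by the
sum of weights.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import uniform_filter

from .fields import FieldMap

__all__ = ["ADFParams", "NLMParams", "adf", "nlm",
           "default_adf_params", "default_nlm_params"]

_COEFFS = ("exponential", "rational", "rational_printed")


@dataclasses.dataclass(frozen=True)
class ADFParams:
    """Anisotropic-diffusion hyperparameters.

    k is the edge-magnitude scale in image-intensity units; dt must lie in
    (0, 0.25] for stability of the 4-neighbour explicit scheme.
    ``rational_printed`` is an audit variant fixing the rational
    coefficient's denominator scale at 2 instead of k.
    """

    k: float = 0.1
    dt: float = 0.2
    n_iter: int = 20
    coefficient: str = "exponential"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if not 0.0 < self.dt <= 0.25:
            raise ValueError("dt must lie in (0, 0.25] for stability")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.coefficient not in _COEFFS:
            raise ValueError(f"coefficient must be one of {_COEFFS}")


@dataclasses.dataclass(frozen=True)
class NLMParams:
    """Non-local-means hyperparameters.

    h is the weight decay scale in image-intensity units; patch_radius
    sets the similarity neighbourhood, search_radius the candidate window.
    """

    h: float = 0.1
    patch_radius: int = 2
    search_radius: int = 7

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("h must be positive (h = 0 degenerates the weights)")
        if self.patch_radius < 0:
            raise ValueError("patch_radius must be >= 0")
        if self.search_radius < self.patch_radius:
            raise ValueError("search_radius must be >= patch_radius")


def default_adf_params(image: np.ndarray, **overrides) -> ADFParams:
    """Defaults scaling k to 10 % of the image dynamic range."""
    rng = float(np.ptp(image))
    return ADFParams(k=0.1 * rng if rng > 0 else 0.1, **overrides)


def default_nlm_params(image: np.ndarray, **overrides) -> NLMParams:
    """Defaults scaling h to 10 % of the image dynamic range."""
    rng = float(np.ptp(image))
    return NLMParams(h=0.1 * rng if rng > 0 else 0.1, **overrides)


def _coefficient(x: np.ndarray, params: ADFParams) -> np.ndarray:
    if params.coefficient == "exponential":
        return np.exp(-((x / params.k) ** 2))
    scale = 2.0 if params.coefficient == "rational_printed" else params.k
    return 1.0 / (1.0 + (x / scale) ** 2)


def _as_array(image):
    if isinstance(image, FieldMap):
        return image.values.astype(np.float64), image
    return np.asarray(image, dtype=np.float64), None


def _wrap(values: np.ndarray, template: FieldMap | None, extra: dict):
    if template is None:
        return values
    return FieldMap(values, template.pitch, template.origin, quantity="image",
                    meta={**template.meta, **extra})


def adf(image, params: ADFParams):
    """Perona-Malik anisotropic diffusion of a 1-D or 2-D image.

    Accepts an ndarray or FieldMap and returns the same type.  A constant
    image is a fixed point; output values stay within the input range
    (the update is a convex combination for dt <= 0.25 and c <= 1).
    """
    values, template = _as_array(image)
    if not np.all(np.isfinite(values)):
        raise ValueError("image must be finite")
    out = values.copy()
    # neighbour count per pixel: 2*ndim interior, fewer at borders
    n_nb = np.zeros_like(out)
    for axis in range(out.ndim):
        n = out.shape[axis]
        count = np.ones(n) * 2
        count[0] = count[-1] = 1
        shape = [1] * out.ndim
        shape[axis] = n
        n_nb = n_nb + count.reshape(shape)
    for _ in range(params.n_iter):
        flux = np.zeros_like(out)
        for axis in range(out.ndim):
            d_fwd = np.diff(out, axis=axis)  # I_{i+1} - I_i
            c_fwd = _coefficient(np.abs(d_fwd), params)
            pad = [(0, 0)] * out.ndim
            lead = list(pad)
            lead[axis] = (0, 1)
            trail = list(pad)
            trail[axis] = (1, 0)
            # neighbour ahead contributes +c*d, neighbour behind -c*d
            flux += np.pad(c_fwd * d_fwd, lead)
            flux -= np.pad(c_fwd * d_fwd, trail)
        out = out + params.dt / n_nb * flux
    return _wrap(out, template, {"filter": "adf", **dataclasses.asdict(params)})


def nlm(image, params: NLMParams):
    """Non-local-means filtering of a 2-D image.

    Candidate pixels q range over the search window clipped to the image;
    patch vectors use reflective padding at the borders.  The output is a
    convex combination of input pixels, hence bounded by the input range.
    """
    values, template = _as_array(image)
    if values.ndim != 2:
        raise ValueError("nlm expects a 2-D image")
    if not np.all(np.isfinite(values)):
        raise ValueError("image must be finite")
    pr, sr = params.patch_radius, params.search_radius
    h2 = params.h**2
    padded = np.pad(values, pr + sr, mode="reflect")
    core = padded[sr:-sr, sr:-sr] if sr else padded  # image + patch margin
    nr, nc = values.shape
    num = np.zeros_like(values)
    den = np.zeros_like(values)
    win = 2 * pr + 1
    rows = np.arange(nr)
    cols = np.arange(nc)
    for dy in range(-sr, sr + 1):
        valid_r = (rows + dy >= 0) & (rows + dy < nr)
        for dx in range(-sr, sr + 1):
            shifted = padded[sr + dy: sr + dy + nr + 2 * pr,
                             sr + dx: sr + dx + nc + 2 * pr]
            sq = (core - shifted) ** 2
            # patch-summed squared distance via a uniform box filter
            dist2 = uniform_filter(sq, size=win)[pr: pr + nr, pr: pr + nc] \
                * win**2
            weight = np.exp(-dist2 / h2)
            valid_c = (cols + dx >= 0) & (cols + dx < nc)
            mask = valid_r[:, None] & valid_c[None, :]
            q_vals = shifted[pr: pr + nr, pr: pr + nc]
            num += np.where(mask, weight * q_vals, 0.0)
            den += np.where(mask, weight, 0.0)
    out = num / den
    return _wrap(out, template, {"filter": "nlm", **dataclasses.asdict(params)})
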