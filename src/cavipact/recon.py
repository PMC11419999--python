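"""Image reconstruction: 750 kHz low-pass filtering + delay-and-sum.

Traces are zero-phase low-pass filtered (4th-order Butterworth applied
forward and backward, preserving the arrival times DAS depends on) and
then beamformed: each image pixel sums every element's trace at the
straight-ray time of flight from pixel to element.

Reconstruction sound speeds follow the imaging-system calibration (water
1429 m/s, air 430 m/s) and are deliberately independent of the forward
simulation speeds.  The default ``uniform`` mode delays with the water
speed only; the optional ``two-speed`` mode integrates the straight ray
piecewise through air pixels at the air speed.  DAS output is signed; the
final normalisation clips negative lobes to zero and scales the maximum to
1 — no envelope detection — matching the normalised dark-background
renderings the pipeline is evaluated on.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import signal

from .acoustics import SensorData
from .fields import FieldMap, centered_origin
from .phantom import LABELS

__all__ = ["ReconSpec", "lowpass", "das_reconstruct", "normalize_das"]


@dataclasses.dataclass
class ReconSpec:
    """Reconstruction grid and delay model.

    The default is the desk-scale grid (300x300 at 0.4 mm);
    ``full_scale()`` gives the full-resolution 1200x1200 grid at 0.1 mm.
    """

    grid_shape: tuple[int, int] = (300, 300)
    pitch: float = 0.4  # mm
    sound_speed_water: float = 1429.0  # m/s
    sound_speed_air: float = 430.0  # m/s
    lowpass_cutoff: float = 750e3  # Hz
    speed_mode: str = "uniform"  # or "two-speed"

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if self.speed_mode not in ("uniform", "two-speed"):
            raise ValueError("speed_mode must be 'uniform' or 'two-speed'")

    @classmethod
    def full_scale(cls, **overrides) -> "ReconSpec":
        return cls(grid_shape=(1200, 1200), pitch=0.1, **overrides)


def lowpass(data: SensorData, cutoff: float | None = None) -> SensorData:
    """Zero-phase Butterworth low-pass (order 4 per pass) on every trace."""
    cutoff = 750e3 if cutoff is None else cutoff
    nyquist = 0.5 / data.dt
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist:.3g}) Hz")
    sos = signal.butter(4, cutoff, btype="low", fs=1.0 / data.dt, output="sos")
    filtered = signal.sosfiltfilt(sos, data.traces, axis=1)
    return SensorData(
        traces=filtered, dt=data.dt, array=data.array,
        meta={**data.meta, "lowpass_hz": cutoff},
    )


def normalize_das(field: FieldMap) -> FieldMap:
    """Clip negative DAS lobes to zero and scale the peak to 1.

    Invariant to positive rescaling of the traces; an all-nonpositive
    image maps to zero.
    """
    v = np.clip(field.values, 0.0, None)
    peak = v.max()
    out = v / peak if peak > 0 else v
    return dataclasses.replace(field, values=out,
                               meta={**field.meta, "normalized": True})


def _air_fraction_along_rays(px, py, ex, ey, labels: FieldMap, n_ray: int = 64):
    """Fraction of each element->pixel straight ray passing through air.

    Sampled at n_ray points per ray on the acoustic label grid; pixels
    outside the label grid count as non-air.
    """
    t = (np.arange(n_ray) + 0.5) / n_ray
    sx = ex + (px[:, None] - ex) * t[None, :]
    sy = ey + (py[:, None] - ey) * t[None, :]
    rows, cols = labels.xy_to_rowcol(sx, sy)
    r = np.round(rows).astype(int)
    c = np.round(cols).astype(int)
    inside = (r >= 0) & (r < labels.shape[0]) & (c >= 0) & (c < labels.shape[1])
    r, c = np.clip(r, 0, labels.shape[0] - 1), np.clip(c, 0, labels.shape[1] - 1)
    is_air = (labels.values[r, c] == LABELS["air"]) & inside
    return is_air.mean(axis=1)


def das_reconstruct(
    data: SensorData,
    spec: ReconSpec | None = None,
    labels: FieldMap | None = None,
    normalize: bool = True,
) -> FieldMap:
    """Delay-and-sum beamforming of (low-passed) sensor traces.

    Delays outside the recorded window contribute zero; if more than 10 %
    of element-pixel pairs fall outside, a warning reports the fraction.
    ``labels`` (acoustic-grid label map) is required for the two-speed
    delay mode.  With ``normalize=False`` the raw signed sum is returned,
    which is linear in the input traces.
    """
    spec = spec or ReconSpec()
    if spec.speed_mode == "two-speed" and labels is None:
        raise ValueError("two-speed delays require the acoustic label map")
    origin = centered_origin(spec.grid_shape, spec.pitch)
    xs = origin[0] + spec.pitch * np.arange(spec.grid_shape[1])
    ys = origin[1] - spec.pitch * np.arange(spec.grid_shape[0])
    X, Y = np.meshgrid(xs, ys)
    px, py = X.ravel(), Y.ravel()

    t_grid = data.times
    image = np.zeros(px.size)
    n_out = 0
    for e, (ex, ey) in enumerate(data.array.element_positions):
        dist = np.hypot(px - ex, py - ey) * 1e-3  # m
        if spec.speed_mode == "two-speed":
            f_air = _air_fraction_along_rays(px, py, ex, ey, labels)
            tof = dist * ((1 - f_air) / spec.sound_speed_water
                          + f_air / spec.sound_speed_air)
        else:
            tof = dist / spec.sound_speed_water
        idx = tof / data.dt
        out = idx > (data.n_samples - 1)
        n_out += int(out.sum())
        image += np.interp(idx, np.arange(data.n_samples), data.traces[e],
                           left=0.0, right=0.0) * ~out
    frac_out = n_out / (px.size * data.array.n_elements)
    if frac_out > 0.10:
        warnings.warn(
            f"{frac_out:.1%} of element-pixel delays fall outside the "
            "recorded window and contribute zero"
        )
    img = image.reshape(spec.grid_shape)
    field = FieldMap(
        img, spec.pitch, origin, quantity="image",
        meta={**data.meta, "recon": dataclasses.asdict(spec),
              "normalized": False, "out_of_window_fraction": frac_out},
    )
    return normalize_das(field) if normalize else field
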