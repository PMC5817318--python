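"""Scatter estimation and subtraction chain.

Per view: smooth the noisy simulated scatter tally with a Gaussian
low-pass (the scatter field is dominated by low spatial frequencies, so
heavy smoothing only removes Monte Carlo noise), rescale it to experiment
level through the blank-scan ratio

    S_exp = S'_sim * I_b,exp / I_b,sim ,

cap the implied scatter fraction at SF_max to prevent overcorrection,
and subtract with a global weighting factor w:

    I_C = I_exp - w * S_exp_capped .

The cap is applied to S_exp before weighting, so the corrected intensity
is bounded below by (1 - w * SF_max) * I_exp before flooring. A
low-resolution scatter estimate can be bicubically upsampled to match
higher-resolution measured data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import transform

from .geometry import ProjectionImage

__all__ = [
    "CorrectionParams",
    "smooth_scatter",
    "scale_to_experiment",
    "cap_scatter_fraction",
    "subtract_scatter",
    "upsample_scatter",
    "correct_projection_set",
]


@dataclass
class CorrectionParams:
    """Tunables of the correction chain.

    w: scatter weighting factor (default 0.8) compensating size/position
       mismatch between the simulated phantom and the scanned head;
    sf_max: maximum allowed scatter fraction S/I (default 0.8);
    smoothing_sigma: Gaussian width in detector pixels (default 8);
    epsilon_floor: minimum corrected intensity before the log transform.
    """

    w: float = 0.8
    sf_max: float = 0.8
    smoothing_sigma: float = 8.0
    epsilon_floor: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            warnings.warn(f"weighting factor w={self.w} outside [0, 1]", stacklevel=2)
        if not 0.0 < self.sf_max < 1.0:
            raise ValueError("sf_max must lie in (0, 1)")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, ProjectionImage) else np.asarray(img, dtype=float)


def smooth_scatter(s_sim, sigma: float) -> np.ndarray:
    """Gaussian low-pass of the simulated scatter image (reflect borders)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    p = _pixels(s_sim)
    if sigma == 0:
        return p.copy()
    return np.clip(ndimage.gaussian_filter(p, sigma=sigma, mode="reflect"), 0.0, None)


def scale_to_experiment(s_sim_smooth, i_b_exp, i_b_sim) -> np.ndarray:
    """Blank-scan ratio scaling: S_exp = S'_sim * I_b,exp / I_b,sim."""
    s = _pixels(s_sim_smooth)
    be = _pixels(i_b_exp)
    bs = _pixels(i_b_sim)
    if not (s.shape == be.shape == bs.shape):
        raise ValueError("shape mismatch between scatter and blank images")
    bad = np.argwhere(bs <= 0)
    if bad.size:
        j, i = bad[0]
        raise ZeroDivisionError(
            f"simulated blank scan non-positive at pixel (i={i}, j={j})"
        )
    return s * be / bs


def cap_scatter_fraction(i_exp, s_exp, sf_max: float) -> np.ndarray:
    """Limit the scatter fraction S/I at sf_max: S -> min(S, sf_max * I)."""
    i = _pixels(i_exp)
    s = _pixels(s_exp)
    if i.shape != s.shape:
        raise ValueError("shape mismatch")
    return np.minimum(s, sf_max * i)


def subtract_scatter(i_exp, s_exp_capped, w: float,
                     epsilon_floor: float = 0.0) -> np.ndarray:
    """Weighted subtraction I_C = I_exp - w * S_exp, floored."""
    i = _pixels(i_exp)
    s = _pixels(s_exp_capped)
    if i.shape != s.shape:
        raise ValueError("shape mismatch")
    return np.maximum(i - w * s, epsilon_floor)


def upsample_scatter(s, target_shape: tuple[int, int]) -> np.ndarray:
    """Bicubic upsampling of a scatter image by an integer factor.

    target_shape is (nv, nu); both axes must be integer multiples of the
    input. The interpolation treats pixel values as samples at pixel
    centers (grid-aligned zoom); negative bicubic overshoot clamps to 0.
    """
    p = _pixels(s)
    fv = target_shape[0] / p.shape[0]
    fu = target_shape[1] / p.shape[1]
    if fv < 1 or fu < 1 or fv != int(fv) or fu != int(fu):
        raise ValueError("upsampling factor must be a positive integer")
    if fv == 1 and fu == 1:
        return p.copy()
    out = transform.resize(p, target_shape, order=3, mode="symmetric",
                           anti_aliasing=False)
    return np.clip(out, 0.0, None)


def correct_projection(i_exp, s_sim, i_b_exp, i_b_sim,
                       params: CorrectionParams) -> np.ndarray:
    """Full chain for one view: smooth -> upsample -> scale -> cap -> subtract."""
    i = _pixels(i_exp)
    s = smooth_scatter(s_sim, params.smoothing_sigma)
    if s.shape != i.shape:
        s = upsample_scatter(s, i.shape)
    s = scale_to_experiment(s, i_b_exp, i_b_sim)
    s = cap_scatter_fraction(i, s, params.sf_max)
    return subtract_scatter(i, s, params.w, params.epsilon_floor)


def correct_projection_set(
    measured: list[ProjectionImage],
    simulated_scatter: list[ProjectionImage],
    i_b_exp,
    i_b_sim,
    params: CorrectionParams | None = None,
    angle_warn_deg: float = 0.5,
):
    """Correct a stack of measured views with a stack of simulated scatter.

    Each measured view is paired with the simulated view of nearest angle
    (warning if more than `angle_warn_deg` apart). Returns
    ``(corrected, log_projections)`` where log_projections are the line
    integrals p = ln(I_b,exp / I_C) fed to reconstruction.

    The blank scans may be full-resolution even when the simulated scatter
    stack is low-resolution; the scatter is upsampled first.
    """
    params = params or CorrectionParams()
    if not measured or not simulated_scatter:
        raise ValueError("empty projection stack")
    sim_angles = np.array([s.view_angle for s in simulated_scatter])
    be = _pixels(i_b_exp)

    corrected = []
    log_proj = []
    for meas in measured:
        if meas.pixels.shape != be.shape:
            raise ValueError("measured stack and experimental blank shape mismatch")
        delta = np.abs((sim_angles - meas.view_angle + 180.0) % 360.0 - 180.0)
        k = int(np.argmin(delta))
        if delta[k] > angle_warn_deg:
            warnings.warn(
                f"nearest simulated view {delta[k]:.2f} deg from measured "
                f"view {meas.view_angle:.2f}",
                stacklevel=2,
            )
        i_c = correct_projection(meas, simulated_scatter[k], i_b_exp, i_b_sim, params)
        corrected.append(ProjectionImage(i_c, meas.view_angle, role="corrected"))
        log_proj.append(ProjectionImage(
            np.log(np.maximum(be, params.epsilon_floor)
                   / np.maximum(i_c, params.epsilon_floor)).clip(0.0, None),
            meas.view_angle, role="measured",
        ))
    return corrected, log_proj


def log_projections(measured: list[ProjectionImage], i_b_exp,
                    epsilon_floor: float = 1.0) -> list[ProjectionImage]:
    """Line integrals p = ln(I_b / I) of an uncorrected stack."""
    be = _pixels(i_b_exp)
    out = []
    for meas in measured:
        p = np.log(np.maximum(be, epsilon_floor)
                   / np.maximum(meas.pixels, epsilon_floor)).clip(0.0, None)
        out.append(ProjectionImage(p, meas.view_angle, role="measured"))
    return out
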