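"""Red-blood-cell velocimetry from linescan space-time images.

Repeated one-dimensional scans along a capillary produce an image whose
rows are successive scan lines (time) and whose columns are position along
the scan.  Moving red blood cells appear as tilted dark streaks; the streak
slope encodes velocity.  The velocity is estimated per time window as the
angle that maximizes the variance of the Radon transform of the
mean-subtracted window — projections along the streak direction are
maximally structured.

Sign convention: positive velocity means cells move toward increasing
column index over time.  The reported ``angle`` is the streak angle from
the time axis, so ``v = pixel_size * line_rate * tan(angle)``; stationary
cells give vertical streaks (angle 0), and streaks approaching +/-90
degrees (cells crossing the whole scan within one line) are unresolvable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import radon

from .errors import InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "LinescanImage",
    "VelocityEstimate",
    "radon_velocity",
    "velocity_quality_filter",
]


@dataclass
class LinescanImage:
    """Space-time image from repeated scans along a capillary.

    ``image[i, j]`` is the intensity of line ``i`` (time) at position ``j``
    along the scan (space); ``pixel_size`` in um/px, ``line_rate`` in
    lines/s.
    """

    image: np.ndarray
    pixel_size: float
    line_rate: float
    ground_truth: dict | None = None
    metadata: dict = field(default_factory=lambda: {
        "axis0": "time (line index)",
        "axis1": "space (position along scan)",
        "positive_velocity": "increasing column index over time",
    })

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise InvalidParameterError("linescan image must be 2-D")
        if self.pixel_size <= 0 or self.line_rate <= 0:
            raise InvalidParameterError("pixel_size and line_rate must be > 0")

    @property
    def n_lines(self) -> int:
        return self.image.shape[0]


@dataclass(frozen=True)
class VelocityEstimate:
    """Velocity for one analysis window.

    ``velocity`` is NaN when the window was unresolvable (streaks within a
    degree of parallel to the space axis, i.e. |v| out of range).
    ``angle`` is the streak angle from the time axis in degrees, in
    (-90, 90).  ``separability`` in [0, 1) measures how strongly the
    projection variance is concentrated at the best angle.
    """

    window_start: float
    velocity: float
    angle: float
    separability: float

    @property
    def resolvable(self) -> bool:
        return bool(np.isfinite(self.velocity))


def _window_angle(window: np.ndarray, thetas: np.ndarray) -> tuple[float, np.ndarray]:
    sino = radon(window, theta=thetas, circle=False)
    var = sino.var(axis=0)
    k = int(np.argmax(var))
    return float(thetas[k]), var


def radon_velocity(
    image: LinescanImage,
    window_lines: int = 128,
    overlap: float = 0.5,
    fine_step: float = 0.1,
) -> list[VelocityEstimate]:
    """Windowed RBC velocity estimates from a linescan image.

    Each window of ``window_lines`` lines (advanced by ``1 - overlap`` of
    its length) is mean-subtracted and Radon-transformed over 1-179
    degrees in 1-degree steps; the angle maximizing the projection
    variance is refined on a ``fine_step`` grid within +/-1.5 degrees.
    With rows as time, a streak advancing ``m`` px/line lies at the Radon
    angle ``theta = atan(m)``, so

        v = pixel_size * line_rate * tan(theta)   [um/s -> mm/s]

    Windows whose best angle is within one degree of +/-90 from the time
    axis are unresolvable (velocity NaN).
    """
    if window_lines < 8:
        raise InvalidParameterError("window_lines must be >= 8")
    if window_lines > image.n_lines:
        raise InvalidParameterError(
            f"window_lines={window_lines} exceeds image lines={image.n_lines}"
        )
    if not 0 <= overlap < 1:
        raise InvalidParameterError("overlap must be in [0, 1)")

    hop = max(1, int(round(window_lines * (1.0 - overlap))))
    coarse = np.arange(1.0, 180.0, 1.0)
    estimates: list[VelocityEstimate] = []

    for start in range(0, image.n_lines - window_lines + 1, hop):
        win = image.image[start : start + window_lines]
        win = win - win.mean()
        theta0, var = _window_angle(win, coarse)
        fine = np.arange(theta0 - 1.5, theta0 + 1.5 + fine_step / 2, fine_step)
        fine = fine[(fine > 0.0) & (fine < 180.0)]
        theta_best, _ = _window_angle(win, fine)

        peak_var = float(var.max())
        mean_var = float(var.mean())
        separability = max(0.0, (peak_var - mean_var) / peak_var) if peak_var > 0 else 0.0

        # streak angle from the time axis: tan is shared between theta and
        # theta-180, so fold into (-90, 90)
        angle = theta_best if theta_best < 90.0 else theta_best - 180.0
        t_start = start / image.line_rate
        if abs(abs(angle) - 90.0) < 1.0:
            logger.debug("window at %.3fs unresolvable (angle %.2f)", t_start, angle)
            estimates.append(VelocityEstimate(t_start, float("nan"), angle, separability))
            continue
        slope = math.tan(math.radians(angle))  # px per line
        velocity = slope * image.pixel_size * image.line_rate / 1000.0  # mm/s
        estimates.append(VelocityEstimate(t_start, velocity, angle, separability))
    return estimates


def velocity_quality_filter(
    estimates: list[VelocityEstimate],
    min_separability: float = 0.5,
) -> list[VelocityEstimate]:
    """Drop unresolvable windows and windows below the separability floor."""
    kept = [
        e for e in estimates
        if e.resolvable and e.separability >= min_separability
    ]
    n_rejected = len(estimates) - len(kept)
    if n_rejected:
        logger.info(
            "velocity quality filter: rejected %d of %d windows",
            n_rejected, len(estimates),
        )
    return kept
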