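"""Acquisition geometry and timing for slow-interval HILO single-molecule tracking.

The default parameters describe a 5 Hz acquisition (200 ms frame interval)
with a short 10 ms exposure, 104 nm pixels and a ~400 nm depth of focus —
the regime in which only chromatin-bound molecules survive frame-to-frame
while freely diffusing molecules defocalize between frames.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera timing and optical geometry of an SMT acquisition.

    Parameters
    ----------
    frame_interval : float
        Time between frame starts, seconds.
    exposure : float
        Camera integration time per frame, seconds. Must not exceed the
        frame interval.
    pixel_size : float
        Lateral pixel size in the sample plane, micrometres.
    depth_of_focus : float
        Axial detection range ``dz``: molecules with ``|z| > dz/2`` are not
        detected, micrometres.
    n_frames : int
        Number of frames in a movie.
    field_size : tuple of int
        Field of view in pixels (ny, nx).
    """

    frame_interval: float = 0.2
    exposure: float = 0.01
    pixel_size: float = 0.104
    depth_of_focus: float = 0.4
    n_frames: int = 600
    field_size: tuple[int, int] = (128, 128)

    def __post_init__(self) -> None:
        if self.frame_interval <= 0 or self.exposure <= 0:
            raise ValueError("frame_interval and exposure must be positive")
        if self.exposure > self.frame_interval:
            raise ValueError(
                f"exposure ({self.exposure}) exceeds frame interval "
                f"({self.frame_interval})"
            )
        if self.pixel_size <= 0 or self.depth_of_focus <= 0:
            raise ValueError("pixel_size and depth_of_focus must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def motion_blur_coefficient(self) -> float:
        """Motion blur coefficient R = (1/6) * exposure / frame_interval.

        R corrects displacement covariances for the averaging of a moving
        molecule's position over the camera exposure; it lies in (0, 1/6].
        """
        return self.exposure / (6.0 * self.frame_interval)
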