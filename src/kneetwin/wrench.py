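"""Force/moment pairs tagged with the frame and origin they are expressed in.

A wrench is the fundamental load carrier of the package: every ligament,
contact and external load is a force 3-vector (N) plus a moment 3-vector
(N·m) taken about a stated origin point (mm) in a stated frame.  Keeping the
frame label and origin on the object lets downstream code refuse to combine
loads that are not expressed about the same point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class FrameMismatchError(ValueError):
    """Raised when wrenches/registrations tagged with different frames meet."""


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    return v


@dataclass(frozen=True)
class Wrench:
    """A force and moment pair.

    Parameters
    ----------
    force_N : (3,) array
        Force components in the coordinate frame ``frame_id``.
    moment_Nm : (3,) array
        Moment about ``origin_mm``, components in ``frame_id``.
    frame_id : str
        Label of the coordinate frame the components are expressed in.
    origin_mm : (3,) array
        Point (in ``frame_id`` coordinates) the moment is taken about.
    """

    force_N: np.ndarray
    moment_Nm: np.ndarray
    frame_id: str = "femoral"
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "force_N", _as_vec3(self.force_N, "force_N"))
        object.__setattr__(self, "moment_Nm", _as_vec3(self.moment_Nm, "moment_Nm"))
        object.__setattr__(self, "origin_mm", _as_vec3(self.origin_mm, "origin_mm"))

    @classmethod
    def zero(cls, frame_id: str = "femoral", origin_mm=None) -> "Wrench":
        return cls(np.zeros(3), np.zeros(3), frame_id,
                   np.zeros(3) if origin_mm is None else origin_mm)

    def __add__(self, other: "Wrench") -> "Wrench":
        if other.frame_id != self.frame_id:
            raise FrameMismatchError(
                f"cannot add wrench in frame {other.frame_id!r} to frame "
                f"{self.frame_id!r}")
        if not np.allclose(other.origin_mm, self.origin_mm, atol=1e-9):
            raise FrameMismatchError(
                "cannot add wrenches taken about different origins "
                f"({self.origin_mm} vs {other.origin_mm}); re-express first")
        return Wrench(self.force_N + other.force_N,
                      self.moment_Nm + other.moment_Nm,
                      self.frame_id, self.origin_mm)

    def resultant_invariant(self) -> float:
        """The frame-independent scalar force·moment (N²·m)."""
        return float(self.force_N @ self.moment_Nm)
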