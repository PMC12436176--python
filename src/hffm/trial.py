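"""Containers for marker trajectories and gait events."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NoCycleError
from .model import MarkerFrame

__all__ = ["MarkerTrajectories", "GaitEvents"]


@dataclass
class MarkerTrajectories:
    """Uniformly sampled marker trajectories for one foot.

    ``data`` maps marker label to an ``(n, 3)`` array in mm (lab frame);
    gaps are NaN rows.  ``rate`` is the sampling rate in Hz.
    """

    data: dict[str, np.ndarray]
    rate: float
    side: str = "R"

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        self.data = {k: np.asarray(v, dtype=float) for k, v in self.data.items()}
        lengths = {v.shape[0] for v in self.data.values()}
        if len(lengths) > 1:
            raise ValueError(f"marker trajectories have mixed lengths: {lengths}")
        for k, v in self.data.items():
            if v.ndim != 2 or v.shape[1] != 3:
                raise ValueError(f"trajectory {k} must be (n, 3), got {v.shape}")

    @property
    def n_samples(self) -> int:
        return next(iter(self.data.values())).shape[0] if self.data else 0

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.data)

    def frame(self, i: int) -> MarkerFrame:
        """Extract one time sample as a :class:`MarkerFrame`."""
        return MarkerFrame(
            {k: v[i] for k, v in self.data.items() if np.all(np.isfinite(v[i]))},
            side=self.side,
            time_index=i,
        )

    def transformed(self, R, t) -> "MarkerTrajectories":
        R = np.asarray(R, float)
        t = np.asarray(t, float)
        return MarkerTrajectories(
            {k: v @ R.T + t for k, v in self.data.items()},
            rate=self.rate,
            side=self.side,
        )

    def copy(self) -> "MarkerTrajectories":
        return MarkerTrajectories(
            {k: v.copy() for k, v in self.data.items()}, rate=self.rate, side=self.side
        )


@dataclass
class GaitEvents:
    """Initial-contact and toe-off sample indices; IC(k) < TO(k) < IC(k+1)."""

    initial_contact: np.ndarray
    toe_off: np.ndarray
    side: str = "R"

    def __post_init__(self):
        self.initial_contact = np.asarray(self.initial_contact, dtype=int)
        self.toe_off = np.asarray(self.toe_off, dtype=int)
        ic, to = self.initial_contact, self.toe_off
        if len(ic) < 2:
            raise NoCycleError("need at least two initial contacts for one cycle")
        if np.any(np.diff(ic) <= 0) or np.any(np.diff(to) <= 0):
            raise NoCycleError("events must be strictly increasing")
        for k in range(min(len(to), len(ic) - 1)):
            if not (ic[k] < to[k] < ic[k + 1]):
                raise NoCycleError(
                    f"event ordering violated at cycle {k}: "
                    f"IC={ic[k]}, TO={to[k]}, next IC={ic[k + 1]}"
                )

    @property
    def n_cycles(self) -> int:
        return len(self.initial_contact) - 1
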