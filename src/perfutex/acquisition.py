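"""Acquisition parameters of the dynamic contrast-enhanced protocol.

The defaults describe a 3 T abdominal DCE protocol: a spoiled gradient echo
read out every 6 s for 40 frames (240 s total), TR/TE = 3.9/1.4 ms at a 12°
flip angle, with two pre-contrast frames acquired before a 0.1 mmol/kg
gadolinium bolus.  The variable-flip-angle baseline T1 acquisition and the
contrast-agent relaxivity are configurable because neither is fixed by the
protocol itself.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError


@dataclass(frozen=True)
class AcquisitionParams:
    """Scanner and injection constants needed by every stage.

    Parameters
    ----------
    repetition_time : float
        TR of the dynamic spoiled-gradient-echo sequence, seconds.
    echo_time : float
        TE, seconds (carried for provenance; no T2* modelling is done).
    flip_angle_dynamic : float
        Flip angle of the dynamic series, degrees.
    flip_angles_t1 : tuple of float
        Flip angles of the baseline variable-flip-angle T1 acquisition,
        degrees.
    n_timepoints, dt : int, float
        Number of dynamic frames and frame spacing in seconds.
    n_baseline : int
        Pre-contrast frames acquired before the bolus.
    relaxivity_r1 : float
        Longitudinal relaxivity of the contrast agent, s^-1 (mmol/L)^-1.
    dose : float
        Injected dose, mmol per kg body weight.
    hematocrit : float
        Large-vessel hematocrit used to convert blood to plasma
        concentration.
    """

    repetition_time: float = 0.0039
    echo_time: float = 0.0014
    flip_angle_dynamic: float = 12.0
    flip_angles_t1: tuple[float, ...] = (3.0, 6.0, 9.0, 12.0, 15.0)
    n_timepoints: int = 40
    dt: float = 6.0
    n_baseline: int = 2
    relaxivity_r1: float = 4.3
    dose: float = 0.1
    hematocrit: float = 0.42

    def __post_init__(self) -> None:
        object.__setattr__(self, "flip_angles_t1", tuple(self.flip_angles_t1))
        positive = {
            "repetition_time": self.repetition_time,
            "echo_time": self.echo_time,
            "flip_angle_dynamic": self.flip_angle_dynamic,
            "n_timepoints": self.n_timepoints,
            "dt": self.dt,
            "relaxivity_r1": self.relaxivity_r1,
            "dose": self.dose,
        }
        for name, value in positive.items():
            if not value > 0:
                raise InvalidInputError(f"{name} must be positive, got {value!r}")
        if not 0 <= self.hematocrit < 1:
            raise InvalidInputError("hematocrit must be in [0, 1)")
        if not 1 <= self.n_baseline < self.n_timepoints:
            raise InvalidInputError(
                "n_baseline must be >= 1 and < n_timepoints "
                f"(got {self.n_baseline} of {self.n_timepoints})"
            )
        angles = (self.flip_angle_dynamic, *self.flip_angles_t1)
        if any(not 0 < a <= 90 for a in angles):
            raise InvalidInputError("flip angles must lie in (0, 90] degrees")
        if len(self.flip_angles_t1) < 2:
            raise InvalidInputError("need at least two baseline flip angles")

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at 0."""
        return np.arange(self.n_timepoints, dtype=float) * self.dt

    @property
    def bolus_onset(self) -> float:
        """Injection time implied by the pre-contrast frame count, seconds."""
        return self.n_baseline * self.dt
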