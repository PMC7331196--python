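"""Subject anthropometry used for feature normalization and simulation.

Positions in the pipeline are anteroposterior (x, forward positive) and
mediolateral (y) coordinates relative to the mean ankle position over the
two seconds preceding the perturbation.  The normalization measures are
body height ``H``, baseline CoM height ``h_com``, heel-to-toe foot length
``l_foot`` and stance width ``w_stance`` (5th metatarsal head to 5th
metatarsal head), together with body mass ``M`` for the angular-momentum
normalization ``1/(M h_com^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["SubjectAnthropometry", "sample_anthropometry", "ANKLE_FRACTION"]

#: Fraction of the foot length between the heel and the ankle joint.  The
#: base of support relative to the ankle origin therefore spans
#: [-ANKLE_FRACTION * l_foot, (1 - ANKLE_FRACTION) * l_foot].
ANKLE_FRACTION = 0.25


@dataclass(frozen=True)
class SubjectAnthropometry:
    """Per-subject scalars for normalization and simulation.

    Parameters
    ----------
    subject_id : str
        Identifier, e.g. ``"S01"``.
    mass : float
        Body mass ``M`` in kg.
    height : float
        Body height ``H`` in m.
    com_height : float
        Height of the whole-body CoM in the baseline pose, ``h_com`` in m.
    foot_length : float
        Heel-to-toe foot length ``l_foot`` in m.
    stance_width : float
        Distance between the heads of the fifth metatarsals, ``w_stance``
        in m.
    """

    subject_id: str
    mass: float
    height: float
    com_height: float
    foot_length: float
    stance_width: float

    def __post_init__(self) -> None:
        for name in ("mass", "height", "com_height", "foot_length", "stance_width"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not 1.4 <= self.height <= 2.1:
            raise ValueError(f"implausible body height {self.height} m")
        if not 20.0 <= self.mass <= 200.0:
            raise ValueError(f"implausible body mass {self.mass} kg")
        if self.com_height >= self.height:
            raise ValueError("CoM height must be below body height")
        if not 0.15 <= self.foot_length <= 0.40:
            raise ValueError(f"implausible foot length {self.foot_length} m")
        if not 0.05 <= self.stance_width <= 0.80:
            raise ValueError(f"implausible stance width {self.stance_width} m")

    # Foot geometry relative to the ankle origin ------------------------
    @property
    def x_heel(self) -> float:
        """Heel position relative to the ankle (m, negative = backward)."""
        return -ANKLE_FRACTION * self.foot_length

    @property
    def x_toe(self) -> float:
        """Toe position relative to the ankle (m, forward positive)."""
        return (1.0 - ANKLE_FRACTION) * self.foot_length

    def to_dict(self) -> dict:
        return asdict(self)


def sample_anthropometry(n_subjects: int, rng: np.random.Generator) -> list[SubjectAnthropometry]:
    """Draw a cohort of plausible young-adult anthropometries.

    Heights and masses follow the cohort statistics of typical young
    healthy adults (height 1.80 +/- 0.09 m, mass 75 +/- 11 kg); CoM height,
    foot length and stance width are derived as fixed fractions of height
    (0.55, 0.15 and 0.14 respectively).
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    subjects = []
    for i in range(n_subjects):
        height = float(np.clip(rng.normal(1.80, 0.09), 1.55, 2.05))
        mass = float(np.clip(rng.normal(75.0, 11.0), 48.0, 110.0))
        subjects.append(
            SubjectAnthropometry(
                subject_id=f"S{i + 1:02d}",
                mass=mass,
                height=height,
                com_height=0.55 * height,
                foot_length=0.15 * height,
                stance_width=0.14 * height,
            )
        )
    return subjects


def subjects_to_frame(subjects: list[SubjectAnthropometry]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in subjects])


def subjects_from_frame(frame: pd.DataFrame) -> list[SubjectAnthropometry]:
    return [SubjectAnthropometry(**row) for row in frame.to_dict("records")]
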