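"""Two-step GDM diagnosis at 24-28 weeks of gestation.

Step 1 is a 50-g glucose load test (GLT) with plasma glucose measured 1 h
after the load; a value of 140 mg/dL or more triggers step 2, a 100-g oral
glucose tolerance test (OGTT).  GDM is diagnosed by the Carpenter & Coustan
criteria: positive when at least two of the four OGTT plasma glucose levels
meet their thresholds (fasting >= 95, 1 h >= 180, 2 h >= 155, 3 h >= 140,
all mg/dL).  All thresholds are inclusive ("at least"); only mg/dL units
are supported.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import GDM, NON_GDM

#: GLT 1-h plasma glucose trigger for the diagnostic OGTT (mg/dL, inclusive)
GLT_THRESHOLD: float = 140.0

#: Carpenter & Coustan thresholds (mg/dL, inclusive): fasting, 1 h, 2 h, 3 h
CC_THRESHOLDS: tuple[float, float, float, float] = (95.0, 180.0, 155.0, 140.0)

#: minimum number of thresholds met for a positive diagnosis
CC_MIN_CRITERIA: int = 2


class MissingPanelError(ValueError):
    """The GLT triggered an OGTT but no panel was supplied."""


@dataclass(frozen=True)
class OgttPanel:
    """100-g OGTT plasma glucose panel, mg/dL."""

    fasting: float
    h1: float
    h2: float
    h3: float

    def __post_init__(self):
        for name in ("fasting", "h1", "h2", "h3"):
            if not getattr(self, name) > 0:
                raise ValueError(f"OGTT value '{name}' must be > 0")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.fasting, self.h1, self.h2, self.h3)


def carpenter_coustan(panel: OgttPanel) -> bool:
    """Carpenter & Coustan call on an OGTT panel.

    True (GDM positive) iff at least two of: fasting >= 95, 1 h >= 180,
    2 h >= 155, 3 h >= 140 mg/dL.  Boundary values count.
    """
    n_met = sum(
        value >= threshold
        for value, threshold in zip(panel.as_tuple(), CC_THRESHOLDS)
    )
    return n_met >= CC_MIN_CRITERIA


def two_step_diagnose(glt_1h: float, panel: OgttPanel | None = None) -> int:
    """Two-step diagnosis; returns the group code (1 non-GDM, 2 GDM).

    Women with a 1-h GLT below 140 mg/dL do not undergo the OGTT and are
    non-GDM; at or above 140 the OGTT panel is required and the Carpenter &
    Coustan call decides.
    """
    if not glt_1h > 0:
        raise ValueError("GLT value must be > 0")
    if glt_1h < GLT_THRESHOLD:
        return NON_GDM
    if panel is None:
        raise MissingPanelError(
            f"GLT 1-h value {glt_1h} mg/dL >= {GLT_THRESHOLD:g} requires an "
            "OGTT panel"
        )
    return GDM if carpenter_coustan(panel) else NON_GDM
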