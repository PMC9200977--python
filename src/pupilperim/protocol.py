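"""Stimulus protocol and visual-field geometry for chromatic pupilloperimetry.

The test presents small (0.43 deg) focal light stimuli at perimetric
locations while the pupil diameter is video-recorded.  Four stimulus
conditions are used:

* ``dim_red`` (624 nm, 1000 cd/m^2) -- primarily cone-mediated transient
  pupil light reflex (PLR); 1 s stimulus, 4 s recording, 54 targets.
* ``dim_blue`` (485 nm, 170 cd/m^2) -- primarily rod-mediated transient
  PLR; 1 s stimulus, 4 s recording, 54 targets.
* ``bright_red`` / ``bright_blue`` (6000 cd/m^2) -- melanopsin-probing
  sustained PLR (red at equal luminance serves as control); 8 s stimulus,
  16 s recording, 4 targets (two central, two peripheral).

Dim-condition targets follow the standard 24-2 perimetry pattern: rows at
y in {+-3, +-9, +-15, +-21} degrees, |x| <= 21 degrees, plus two nasal
extension points at |x| = 27, y = +-3, for a total of 54 locations.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = [
    "Condition",
    "Eye",
    "StimulusSpec",
    "STIMULI",
    "DIM_CONDITIONS",
    "BRIGHT_CONDITIONS",
    "BACKGROUND_LUMINANCE",
    "GridLocation",
    "VisualFieldGrid",
    "make_grid",
    "bright_grid",
]

BACKGROUND_LUMINANCE = 0.04
"""Mesopic background luminance in cd/m^2."""


class Condition(str, Enum):
    """Chromatic stimulus condition."""

    dim_red = "dim_red"
    dim_blue = "dim_blue"
    bright_red = "bright_red"
    bright_blue = "bright_blue"


class Eye(str, Enum):
    right = "right"
    left = "left"


@dataclass(frozen=True)
class StimulusSpec:
    """Physical description of one stimulus condition.

    Attributes
    ----------
    condition:
        Stimulus condition label.
    wavelength_nm:
        Peak LED wavelength (624 nm red, 485 nm blue).
    luminance_cdm2:
        Stimulus luminance in cd/m^2.
    stim_duration_s:
        Light-on duration (1 s dim, 8 s bright).
    record_duration_s:
        Pupil recording duration from stimulus onset (4 s dim, 16 s bright).
    n_targets:
        Number of visual-field targets tested (54 dim, 4 bright).
    """

    condition: Condition
    wavelength_nm: float
    luminance_cdm2: float
    stim_duration_s: float
    record_duration_s: float
    n_targets: int

    def __post_init__(self) -> None:
        if self.condition in DIM_CONDITIONS:
            if (self.stim_duration_s, self.record_duration_s) != (1.0, 4.0):
                raise ValueError("dim conditions use a 1 s stimulus and 4 s recording")
            if self.n_targets != 54:
                raise ValueError("dim conditions use 54 targets")
        else:
            if (self.stim_duration_s, self.record_duration_s) != (8.0, 16.0):
                raise ValueError("bright conditions use an 8 s stimulus and 16 s recording")
            if self.n_targets != 4:
                raise ValueError("bright conditions use 4 targets")
        if self.wavelength_nm not in (624.0, 485.0):
            raise ValueError("wavelength must be 624 nm (red) or 485 nm (blue)")
        if self.luminance_cdm2 not in (1000.0, 170.0, 6000.0):
            raise ValueError("luminance must be one of 1000, 170 or 6000 cd/m^2")


DIM_CONDITIONS = (Condition.dim_red, Condition.dim_blue)
BRIGHT_CONDITIONS = (Condition.bright_red, Condition.bright_blue)

STIMULI: dict[Condition, StimulusSpec] = {
    Condition.dim_red: StimulusSpec(Condition.dim_red, 624.0, 1000.0, 1.0, 4.0, 54),
    Condition.dim_blue: StimulusSpec(Condition.dim_blue, 485.0, 170.0, 1.0, 4.0, 54),
    Condition.bright_red: StimulusSpec(Condition.bright_red, 624.0, 6000.0, 8.0, 16.0, 4),
    Condition.bright_blue: StimulusSpec(Condition.bright_blue, 485.0, 6000.0, 8.0, 16.0, 4),
}
"""Canonical stimulus registry, one spec per condition."""


@dataclass(frozen=True)
class GridLocation:
    """One perimetric target: 1-based index and field coordinates in degrees.

    Positive ``x_deg`` is the temporal visual field for the right eye and the
    nasal field for the left eye; positive ``y_deg`` is the superior field.
    """

    index: int
    x_deg: float
    y_deg: float


@dataclass(frozen=True)
class VisualFieldGrid:
    """Ordered 54-point 24-2 target grid for one eye."""

    eye: Eye
    locations: tuple[GridLocation, ...]

    def __post_init__(self) -> None:
        if len(self.locations) != 54:
            raise ValueError("a 24-2 grid has exactly 54 locations")
        coords = {(loc.x_deg, loc.y_deg) for loc in self.locations}
        if len(coords) != 54:
            raise ValueError("grid locations must be unique")

    def coordinates(self, index: int) -> tuple[float, float]:
        loc = self.locations[index - 1]
        assert loc.index == index
        return (loc.x_deg, loc.y_deg)


# Half-row x offsets of the 24-2 pattern, keyed by |y|.  The nasal extension
# points at |x| = 27 exist only on the y = +-3 rows.
_ROW_HALF_X = {21.0: (3.0, 9.0), 15.0: (3.0, 9.0, 15.0), 9.0: (3.0, 9.0, 15.0, 21.0)}


def _right_eye_coords() -> list[tuple[float, float]]:
    coords: list[tuple[float, float]] = []
    for y in (21.0, 15.0, 9.0, 3.0, -3.0, -9.0, -15.0, -21.0):
        if abs(y) == 3.0:
            # nasal extension point first (nasal field = x < 0 for the right eye)
            xs = [-27.0, -21.0, -15.0, -9.0, -3.0, 3.0, 9.0, 15.0, 21.0]
        else:
            half = _ROW_HALF_X[abs(y)]
            xs = sorted([-x for x in half] + list(half))
        coords.extend((x, y) for x in xs)
    return coords


def make_grid(eye: Eye | str) -> VisualFieldGrid:
    """Build the 54-point 24-2 target grid for one eye.

    Locations are ordered row by row from the superior field downwards
    (y = +21 ... -21) and within each row by ascending x, indexed 1..54.
    The left-eye grid is the horizontal mirror (x -> -x) of the right-eye
    grid with identical indices, so a given index refers to mirror-image
    retinal positions in the two eyes.
    """
    eye = Eye(eye)
    coords = _right_eye_coords()
    sign = 1.0 if eye is Eye.right else -1.0
    locations = tuple(
        GridLocation(index=i + 1, x_deg=sign * x, y_deg=y)
        for i, (x, y) in enumerate(coords)
    )
    return VisualFieldGrid(eye=eye, locations=locations)


def bright_grid(eye: Eye | str) -> tuple[GridLocation, ...]:
    """The four bright-stimulus targets: two central, two peripheral."""
    eye = Eye(eye)
    sign = 1.0 if eye is Eye.right else -1.0
    coords = [(3.0, 3.0), (-3.0, -3.0), (21.0, 3.0), (-21.0, -3.0)]
    return tuple(
        GridLocation(index=i + 1, x_deg=sign * x, y_deg=y)
        for i, (x, y) in enumerate(coords)
    )


#: Right-eye indices of the two peripheral temporal-field targets (x = +21,
#: y = +-3) where group differences in contraction latency concentrate.
TEMPORAL_PERIPHERY_TARGETS = (27, 36)
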