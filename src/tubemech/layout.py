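"""Chip-layout arithmetic for the pollen-tube guidance device.

The Lab-on-a-Chip is a tiling of identical unit cells, each feeding a fan of
guidance microchannels from a grain reservoir.  This module does the
bookkeeping that sizes such a device for a given species: theoretical
guidance capacity, the number of tubes expected to be guided at an observed
per-cell rate, and the geometric compatibility checks between pollen grain,
pollen tube, and channel cross-section.

Units: all lateral dimensions in micrometres, channel lengths in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass


class LayoutError(ValueError):
    """Raised for physically impossible layout queries."""


@dataclass(frozen=True)
class GrainSpec:
    """Pollen grain approximated as a prolate ellipsoid.

    Parameters
    ----------
    major_diameter, minor_diameter : float
        Ellipsoid axes in µm; ``major_diameter >= minor_diameter > 0``.
    """

    major_diameter: float
    minor_diameter: float

    def __post_init__(self) -> None:
        if not self.minor_diameter > 0:
            raise ValueError("grain minor diameter must be positive")
        if self.major_diameter < self.minor_diameter:
            raise ValueError("grain major diameter must be >= minor diameter")


@dataclass(frozen=True)
class ChannelSpec:
    """Guidance microchannel cross-section (µm) and length range (mm)."""

    width: float
    height: float
    length_min: float
    length_max: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("channel width and height must be positive")
        if self.length_min > self.length_max:
            raise ValueError("channel length_min must be <= length_max")

    @property
    def min_cross_dim(self) -> float:
        return min(self.width, self.height)


@dataclass(frozen=True)
class ChipLayout:
    """One chip: ``n_unit_cells`` identical unit cells side by side.

    ``channels_per_cell``, ``chamber_depth`` and ``channel`` may be ``None``
    for designs whose dimensions are not published; queries that need them
    then raise.  ``footprint`` is the chip (length, width) in mm,
    informational.
    """

    n_unit_cells: int
    channels_per_cell: int | None
    chamber_depth: float | None = None
    channel: ChannelSpec | None = None
    footprint: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_unit_cells < 1:
            raise ValueError("n_unit_cells must be >= 1")
        if self.channels_per_cell is not None and self.channels_per_cell < 1:
            raise ValueError("channels_per_cell must be >= 1 when given")
        if self.chamber_depth is not None and self.chamber_depth <= 0:
            raise ValueError("chamber_depth must be positive")


def capacity(layout: ChipLayout) -> int:
    """Theoretical maximum number of simultaneously guided tubes.

    Simply ``n_unit_cells * channels_per_cell`` — every channel of every
    unit cell occupied by one tube.
    """
    if layout.channels_per_cell is None:
        raise LayoutError(
            "capacity undefined: channels_per_cell is not known for this layout"
        )
    return layout.n_unit_cells * layout.channels_per_cell


def expected_guided(layout: ChipLayout, mean_guided_per_cell: int) -> int:
    """Expected number of guided tubes at an observed mean per-cell count.

    ``mean_guided_per_cell`` is the observed integer average of tubes guided
    per unit cell; it cannot exceed the number of channels in a cell.
    """
    if mean_guided_per_cell < 0:
        raise LayoutError("mean_guided_per_cell must be non-negative")
    if (
        layout.channels_per_cell is not None
        and mean_guided_per_cell > layout.channels_per_cell
    ):
        raise LayoutError(
            f"mean_guided_per_cell ({mean_guided_per_cell}) exceeds "
            f"channels_per_cell ({layout.channels_per_cell})"
        )
    return layout.n_unit_cells * mean_guided_per_cell


@dataclass(frozen=True)
class CompatibilityReport:
    """Geometric compatibility flags between grain/tube and channel.

    grain_retained
        The grain cannot enter a channel (its minor axis exceeds the
        smallest channel cross-dimension); grains can rotate, so the minor
        axis is the conservative criterion.
    tube_fits
        The tube grows unconstricted (tube diameter strictly below the
        smallest channel cross-dimension).
    grain_monolayer
        The grain chamber is too shallow for grains to stack in two layers.
    """

    grain_retained: bool
    tube_fits: bool
    grain_monolayer: bool

    @property
    def compatible(self) -> bool:
        return self.grain_retained and self.tube_fits and self.grain_monolayer


def compatibility(
    grain: GrainSpec,
    tube_diameter: float,
    channel: ChannelSpec,
    chamber_depth: float,
) -> CompatibilityReport:
    """Check grain retention, tube clearance and grain monolayering.

    All comparisons use strict inequalities (a tube exactly as wide as the
    channel does not fit).
    """
    if tube_diameter <= 0 or chamber_depth <= 0:
        raise ValueError("tube_diameter and chamber_depth must be positive")
    gate = channel.min_cross_dim
    return CompatibilityReport(
        grain_retained=grain.minor_diameter > gate,
        tube_fits=tube_diameter < gate,
        grain_monolayer=chamber_depth < 2.0 * grain.minor_diameter,
    )
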