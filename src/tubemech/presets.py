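"""Species presets loaded from the packaged YAML configuration."""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

from .layout import ChannelSpec, ChipLayout, GrainSpec
from .synth import SpeciesParams


@dataclass(frozen=True)
class SpeciesPreset:
    """Bundle of species geometry and its chip layout (where published)."""

    species: SpeciesParams
    layout: ChipLayout | None
    mean_guided_per_cell: int | None


@lru_cache(maxsize=1)
def _raw() -> dict:
    text = resources.files("tubemech.data").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def species_names() -> list[str]:
    return sorted(_raw()["species"])


def get_preset(name: str) -> SpeciesPreset:
    try:
        entry = _raw()["species"][name]
    except KeyError:
        raise KeyError(
            f"unknown species {name!r}; available: {species_names()}"
        ) from None
    grain = GrainSpec(entry["grain_major_um"], entry["grain_minor_um"])
    species = SpeciesParams(
        label=name,
        tube_diameter_mean=entry["tube_diameter_mean_um"],
        tube_diameter_sd=entry["tube_diameter_sd_um"],
        grain=grain,
    )
    lay = entry.get("layout")
    layout = None
    if lay is not None:
        ch = lay.get("channel")
        channel = (
            ChannelSpec(
                ch["width_um"], ch["height_um"], ch["length_min_mm"], ch["length_max_mm"]
            )
            if ch
            else None
        )
        fp = lay.get("footprint_mm")
        layout = ChipLayout(
            n_unit_cells=lay["n_unit_cells"],
            channels_per_cell=lay.get("channels_per_cell"),
            chamber_depth=lay.get("chamber_depth_um"),
            channel=channel,
            footprint=tuple(fp) if fp else None,
        )
    return SpeciesPreset(
        species=species,
        layout=layout,
        mean_guided_per_cell=entry.get("mean_guided_per_cell"),
    )
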