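"""Cortical region table used to group electrodes by Brodmann area.

Regions-of-interest follow the standard speech-study parcellation: each named
region maps to the Brodmann areas it covers. Channels whose area is not in
the table fall into ``"other"``.
"""

from __future__ import annotations

# region name -> tuple of Brodmann areas
REGION_TABLE: dict[str, tuple[int, ...]] = {
    "anterior prefrontal cortex": (10,),
    "dlPFC": (46, 9),
    "pars opercularis": (44,),
    "pars triangularis": (45,),
    "pars orbitalis": (47,),
    "premotor/SMA": (6,),
    "primary motor cortex": (4,),
    "primary somatosensory cortex": (1, 2, 3),
    "SMG": (40,),
    "angular gyrus": (39,),
    "STG": (22,),
    "MTG": (21,),
    "FG": (37,),
}

#: Brodmann area -> region name
BA_TO_REGION: dict[int, str] = {
    ba: name for name, bas in REGION_TABLE.items() for ba in bas
}

KNOWN_BAS = frozenset(BA_TO_REGION)


def region_of(brodmann_area) -> str:
    """Region name for a Brodmann area, ``"other"`` when unmapped."""
    try:
        return BA_TO_REGION.get(int(brodmann_area), "other")
    except (TypeError, ValueError):
        return "other"
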