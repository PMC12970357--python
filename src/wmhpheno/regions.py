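"""Bullseye region naming: 9 lobes x 4 depth layers = 36 spatial cells.

Layer 1 is periventricular, layer ``n_layers`` juxtacortical. The composite
``bgit`` lobe covers basal ganglia, thalamus and infratentorial structures.
"""

from __future__ import annotations

LOBES: tuple[str, ...] = (
    "frontal_l",
    "frontal_r",
    "parietal_l",
    "parietal_r",
    "occipital_l",
    "occipital_r",
    "temporal_l",
    "temporal_r",
    "bgit",
)

N_LOBES = len(LOBES)
N_LAYERS = 4
N_REGIONS = N_LOBES * N_LAYERS

#: Integer label assigned to each lobe in label volumes (0 = background).
LOBE_LABELS: dict[str, int] = {name: i + 1 for i, name in enumerate(LOBES)}


def region_name(lobe: str, layer: int) -> str:
    """Column name for one bullseye cell, e.g. ``frontal_l_2``."""
    if lobe not in LOBES:
        raise ValueError(f"unknown lobe {lobe!r}; expected one of {LOBES}")
    if not 1 <= layer <= N_LAYERS:
        raise ValueError(f"layer must be in 1..{N_LAYERS}, got {layer}")
    return f"{lobe}_{layer}"


#: Canonical lobe-major ordering of the 36 region columns.
REGION_COLUMNS: tuple[str, ...] = tuple(
    f"{lobe}_{layer}" for lobe in LOBES for layer in range(1, N_LAYERS + 1)
)


def region_index(lobe: str, layer: int) -> int:
    """Position of a (lobe, layer) cell in :data:`REGION_COLUMNS`."""
    return REGION_COLUMNS.index(region_name(lobe, layer))
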