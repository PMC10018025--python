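"""Cortical parcellation labels.

The pipeline works on region-level cortical thickness tables parcellated into
68 cortical areas, 34 per hemisphere, named with ``L_``/``R_`` hemisphere
prefixes (e.g. ``L_superiorfrontal``).
"""

from __future__ import annotations

# 34 cortical areas per hemisphere.
CORTICAL_AREAS = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)


def region_names(n_regions: int = 68) -> list[str]:
    """Hemisphere-prefixed region names, left hemisphere first.

    For the standard 68-region case the real cortical labels are used;
    for other (even) sizes generic numbered labels are generated.
    """
    if n_regions % 2 != 0:
        raise ValueError("n_regions must be even (equal split across hemispheres)")
    per_hemi = n_regions // 2
    if per_hemi == len(CORTICAL_AREAS):
        base = list(CORTICAL_AREAS)
    else:
        base = [f"region{i + 1:02d}" for i in range(per_hemi)]
    return [f"L_{b}" for b in base] + [f"R_{b}" for b in base]


def left_regions(regions) -> list[str]:
    """Subset of region names in the left hemisphere, order preserved."""
    return [r for r in regions if str(r).startswith("L_")]
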