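"""Desikan-Killiany cortical parcellation labels (34 per hemisphere)."""

from __future__ import annotations

_DK_BASE = (
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

#: The 68 cortical region labels, left hemisphere first.
DK68: tuple[str, ...] = tuple(f"{name}-{hemi}" for hemi in ("lh", "rh") for name in _DK_BASE)

#: Central sensorimotor strip, where the aperiodic exponent shows
#: disease-related steepening over time.
SENSORIMOTOR: tuple[str, ...] = tuple(
    f"{name}-{hemi}" for hemi in ("lh", "rh") for name in ("precentral", "postcentral", "paracentral")
)

#: Parieto-temporo-occipital regions, where oscillatory beta power is
#: elevated in patients relative to controls.
POSTERIOR: tuple[str, ...] = tuple(
    f"{name}-{hemi}"
    for hemi in ("lh", "rh")
    for name in (
        "superiorparietal",
        "inferiorparietal",
        "supramarginal",
        "precuneus",
        "lateraloccipital",
        "cuneus",
        "fusiform",
        "superiortemporal",
        "middletemporal",
        "inferiortemporal",
    )
)


def validate_region(label: str) -> str:
    """Return *label* if it is a known atlas region, else raise ``ValueError``."""
    if label not in DK68:
        raise ValueError(f"unknown region label: {label!r}")
    return label
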