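"""Node vocabulary: the 90 non-cerebellar AAL regions.

The Automated Anatomical Labeling (AAL) atlas defines 45 cortical and
subcortical regions per hemisphere (cerebellum excluded).  The canonical
atlas order interleaves hemispheres: each region appears first as its
left-hemisphere label (``.L``) then as its right (``.R``).
"""

from __future__ import annotations

_BASE = (
    "PreCG", "SFGdor", "ORBsup", "MFG", "ORBmid", "IFGoperc", "IFGtriang",
    "ORBinf", "ROL", "SMA", "OLF", "SFGmed", "ORBsupmed", "REC", "INS",
    "ACG", "DCG", "PCG", "HIP", "PHG", "AMYG", "CAL", "CUN", "LING",
    "SOG", "MOG", "IOG", "FFG", "PoCG", "SPG", "IPL", "SMG", "ANG",
    "PCUN", "PCL", "CAU", "PUT", "PAL", "THA", "HES", "STG", "TPOsup",
    "MTG", "TPOmid", "ITG",
)

#: Abbreviations of the 90 non-cerebellar AAL regions in atlas order.
AAL90_LABELS: tuple[str, ...] = tuple(
    f"{name}.{hemi}" for name in _BASE for hemi in ("L", "R")
)

#: The nine regions with the strongest three-group pattern changes, used as
#: the default planted-effect seeds of the synthetic generator.
DEFAULT_SEED_LABELS: tuple[str, ...] = (
    "ORBsup.L", "ORBmid.L", "SMA.L", "SMA.R", "INS.L", "INS.R",
    "HIP.L", "PUT.L", "THA.L",
)


def label_index(label: str) -> int:
    """Return the atlas position of an AAL abbreviation."""
    try:
        return AAL90_LABELS.index(label)
    except ValueError:
        raise KeyError(f"unknown AAL label: {label!r}") from None


def default_labels(n_nodes: int) -> tuple[str, ...]:
    """AAL labels for 90 nodes, generic ``N001..`` labels otherwise."""
    if n_nodes == len(AAL90_LABELS):
        return AAL90_LABELS
    return tuple(f"N{i + 1:03d}" for i in range(n_nodes))
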