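"""58-channel scalp montage used throughout the package.

The recordings this package targets were made with a 58-channel Quik-Cap
laid out on the international 10/10 system, with the older NeuroScan-style
channel names in which ``CxA``/``CxP`` denote rows anterior/posterior to the
central row and ``TCP1``/``TCP2`` sit over the temporo-centro-parietal
junction.  The montage here fixes a canonical channel order, approximate 2-D
scalp coordinates (used by the volume-conduction mixing model of the
simulator), the left/right hemisphere electrode sets used for the
intradensity biomarkers, and the homologous left-right pairing used to flip
matrices across the midsagittal plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical channel order: midline, then left/right pairs interleaved row
#: by row from frontal pole to occiput.
MIDLINE: tuple[str, ...] = ("FPZ", "FZ", "FCZ", "CZ", "PZ", "OZ")

_LEFT: tuple[str, ...] = (
    "FP1", "F7", "F5", "F3", "F1", "FT7",
    "C5A", "C3A", "C1A", "T3", "C5", "C3", "C1",
    "TP7", "TCP1", "C5P", "C3P", "C1P",
    "T5", "P5", "P3", "P1", "PO7", "PO5", "PO3", "O1",
)
_RIGHT: tuple[str, ...] = (
    "FP2", "F8", "F6", "F4", "F2", "FT8",
    "C6A", "C4A", "C2A", "T4", "C6", "C4", "C2",
    "TP8", "TCP2", "C6P", "C4P", "C2P",
    "T6", "P6", "P4", "P2", "PO8", "PO6", "PO4", "O2",
)

CHANNELS_58: tuple[str, ...] = MIDLINE + _LEFT + _RIGHT
N_CHANNELS = len(CHANNELS_58)

#: Homologous left<->right pairs for the midsagittal flip; midline channels
#: map to themselves.
FLIP_PAIRS: tuple[tuple[str, str], ...] = tuple(zip(_LEFT, _RIGHT))

# Approximate 2-D scalp positions (x: left negative, y: anterior positive),
# on a unit-radius head.  Only relative distances matter (mixing kernel).
_ROW_Y = {
    "FP": 0.90, "F": 0.55, "FT": 0.30, "CA": 0.28, "C": 0.0,
    "TP": -0.30, "CP": -0.28, "TCP": -0.42, "T": 0.0,
    "P": -0.55, "PO": -0.75, "O": -0.90,
}


def _coord(label: str) -> tuple[float, float]:
    if label in ("FPZ", "FZ", "FCZ", "CZ", "PZ", "OZ"):
        return {"FPZ": (0.0, 0.95), "FZ": (0.0, 0.55), "FCZ": (0.0, 0.28),
                "CZ": (0.0, 0.0), "PZ": (0.0, -0.55), "OZ": (0.0, -0.95)}[label]
    num = int("".join(ch for ch in label if ch.isdigit()))
    side = 1.0 if num % 2 == 0 else -1.0  # 10/10 convention: odd left, even right
    if label.startswith("FP"):
        return (side * 0.25, _ROW_Y["FP"])
    if label.startswith("FT"):
        return (side * 0.78, _ROW_Y["FT"])
    if label.startswith("TCP"):
        return (side * 0.68, _ROW_Y["TCP"])
    if label.startswith("TP"):
        return (side * 0.78, _ROW_Y["TP"])
    if label.startswith("PO"):
        return (side * (0.10 + 0.11 * num), _ROW_Y["PO"])
    if label.startswith("O"):
        return (side * 0.25, _ROW_Y["O"])
    if label[0] == "T":  # T3/T4 central temporal, T5/T6 posterior temporal
        return (side * 0.80, 0.0 if num in (3, 4) else -0.55)
    if label[0] == "F":
        return (side * (0.05 + 0.09 * num), _ROW_Y["F"])
    if label[0] == "P":
        return (side * (0.05 + 0.09 * num), _ROW_Y["P"])
    # central rows: C1..C6 with optional A/P suffix
    y = _ROW_Y["CA"] if label.endswith("A") else _ROW_Y["CP"] if label.endswith("P") else 0.0
    return (side * (0.05 + 0.09 * num), y)


def channel_positions(labels: tuple[str, ...] = CHANNELS_58) -> np.ndarray:
    """Return an (n_channels, 2) array of approximate scalp coordinates."""
    return np.asarray([_coord(lab) for lab in labels], dtype=float)


# Hemisphere electrode sets for the intradensity biomarkers, as used in the
# source study.  Note the asymmetry: the right list contains C5P where the
# left list's C3P/C1P would suggest C4P; the published list is kept as the
# default and a symmetric variant is available via ``symmetric=True``.
LEFT_SET_PUBLISHED: tuple[str, ...] = (
    "F1", "F3", "F5", "C1A", "C3A", "C5A", "C1", "C3", "C5",
    "C1P", "C3P", "TCP1", "P1", "P3", "P5",
)
RIGHT_SET_PUBLISHED: tuple[str, ...] = (
    "F2", "F4", "F6", "C2A", "C4A", "C6A", "C2", "C4", "C6",
    "C2P", "C5P", "TCP2", "P2", "P4", "P6",
)
RIGHT_SET_SYMMETRIC: tuple[str, ...] = tuple(
    lab if lab != "C5P" else "C4P" for lab in RIGHT_SET_PUBLISHED
)


@dataclass(frozen=True)
class HemisphereMap:
    """Left/affected and right/unaffected electrode sets plus flip pairing.

    After the midsagittal flip the ipsilesional hemisphere is always on the
    left, so ``affected_set`` is the left list and ``unaffected_set`` the
    right list.
    """

    affected_set: tuple[str, ...] = LEFT_SET_PUBLISHED
    unaffected_set: tuple[str, ...] = RIGHT_SET_PUBLISHED
    flip_pairs: tuple[tuple[str, str], ...] = FLIP_PAIRS

    def __post_init__(self) -> None:
        if set(self.affected_set) & set(self.unaffected_set):
            raise ValueError("hemisphere sets must be disjoint")
        if len(self.affected_set) != len(self.unaffected_set):
            raise ValueError("hemisphere sets must have equal cardinality")

    @property
    def flip_map(self) -> dict[str, str]:
        """Label -> homologous label; midline labels map to themselves."""
        m = {lab: lab for lab in MIDLINE}
        for left, right in self.flip_pairs:
            m[left] = right
            m[right] = left
        return m


def default_hemisphere_map(symmetric: bool = False) -> HemisphereMap:
    """The default hemisphere map (published electrode lists).

    With ``symmetric=True`` the right-hemisphere list uses C4P in place of
    the published C5P, restoring mirror symmetry with the left list.
    """
    right = RIGHT_SET_SYMMETRIC if symmetric else RIGHT_SET_PUBLISHED
    return HemisphereMap(unaffected_set=right)
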