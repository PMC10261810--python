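"""Indicator PCB congeners and the regulatory constants used throughout.

Six non-dioxin-like polychlorinated biphenyls (NDL-PCBs) serve as the
indicator set for residue monitoring in food: PCB 28, 52, 101, 138, 153
and 180, ordered by ascending IUPAC number. Concentrations are expressed
on a milk-fat basis (ng per g fat).
"""

from __future__ import annotations

import enum


class Congener(str, enum.Enum):
    """The six indicator NDL-PCB congeners, in fixed ascending IUPAC order."""

    PCB28 = "PCB28"
    PCB52 = "PCB52"
    PCB101 = "PCB101"
    PCB138 = "PCB138"
    PCB153 = "PCB153"
    PCB180 = "PCB180"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CONGENERS: tuple[Congener, ...] = tuple(Congener)
CONGENER_NAMES: tuple[str, ...] = tuple(c.value for c in Congener)

PRODUCTS: tuple[str, ...] = ("yogurt", "doogh", "kashk")
BRANDS: tuple[str, ...] = ("A", "B", "C", "D", "E")

#: EU maximum level for the sum of the six indicator congeners, ng/g fat.
EU_LIMIT_NG_G_FAT: float = 40.0

#: WHO tolerable daily intake for NDL-PCBs, ng per kg body weight per day.
TDI_NG_KG_DAY: float = 10.0

#: US EPA oral cancer slope factor for PCBs, (mg/(kg*day))^-1.
SLOPE_FACTOR: float = 2.0

#: Conventional acceptability threshold for incremental lifetime cancer risk.
ILCR_THRESHOLD: float = 1e-4
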