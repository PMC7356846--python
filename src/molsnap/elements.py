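"""Packaged per-element depiction tables.

Covalent radii (classic Pauling-style values, Å) drive distance-based bond
perception; van der Waals radii (Bondi-style, Å) set drawn atom sizes; CPK
colors follow the conventional scheme used by common 3D molecular viewers
(carbon grey, oxygen red, nitrogen blue, bromine dark red, ...).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from functools import lru_cache


@dataclass(frozen=True)
class ElementInfo:
    symbol: str
    covalent_radius: float  # Å
    vdw_radius: float  # Å
    cpk_color: tuple[int, int, int]  # 8-bit RGB


class UnknownElementError(KeyError):
    """Raised when an element symbol is absent from the packaged tables."""

    def __init__(self, symbol: str):
        super().__init__(symbol)
        self.symbol = symbol

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"element {self.symbol!r} is not in the packaged radius/color tables"


@lru_cache(maxsize=1)
def element_table() -> dict[str, ElementInfo]:
    path = resources.files("molsnap.data").joinpath("element_tables.csv")
    table: dict[str, ElementInfo] = {}
    with path.open() as fh:
        for row in csv.DictReader(fh):
            table[row["symbol"]] = ElementInfo(
                symbol=row["symbol"],
                covalent_radius=float(row["covalent_radius_A"]),
                vdw_radius=float(row["vdw_radius_A"]),
                cpk_color=(int(row["cpk_r"]), int(row["cpk_g"]), int(row["cpk_b"])),
            )
    return table


def element_info(symbol: str) -> ElementInfo:
    """Look up one element; raises :class:`UnknownElementError` by name."""
    try:
        return element_table()[symbol]
    except KeyError:
        raise UnknownElementError(symbol) from None
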