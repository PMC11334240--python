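"""Chemical-element reference data for tissue dosimetry.

Atomic numbers, standard atomic weights (IUPAC, g/mol) and elemental mean
excitation energies (ICRU-37 style, eV) for the elements that occur in
human-tissue composition tables.  The mean excitation energies feed the
Bragg-additivity estimate of a compound's ionization potential; everything
else (electron densities, effective atomic numbers) needs only Z and A.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ElementRecord:
    """One chemical element: symbol, atomic number, atomic weight, I-value.

    Attributes
    ----------
    symbol : str
        Chemical symbol, e.g. ``"Ca"``.
    Z : int
        Atomic number (>= 1).
    A : float
        Standard atomic weight in g/mol (> 0).
    I_eV : float
        Elemental mean excitation energy in eV, used for Bragg-additivity
        ionization-potential estimates.
    """

    symbol: str
    Z: int
    A: float
    I_eV: float

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"atomic number must be >= 1, got {self.Z}")
        if self.A <= 0:
            raise ValueError(f"atomic weight must be > 0, got {self.A}")
        if self.I_eV <= 0:
            raise ValueError(f"I-value must be > 0, got {self.I_eV}")


_RECORDS = [
    # symbol, Z, A (IUPAC 2021 conventional), I (eV)
    ElementRecord("H", 1, 1.008, 19.2),
    ElementRecord("C", 6, 12.011, 78.0),
    ElementRecord("N", 7, 14.007, 82.0),
    ElementRecord("O", 8, 15.999, 95.0),
    ElementRecord("F", 9, 18.998, 115.0),
    ElementRecord("Na", 11, 22.990, 149.0),
    ElementRecord("Mg", 12, 24.305, 156.0),
    ElementRecord("Al", 13, 26.982, 166.0),
    ElementRecord("Si", 14, 28.085, 173.0),
    ElementRecord("P", 15, 30.974, 173.0),
    ElementRecord("S", 16, 32.06, 180.0),
    ElementRecord("Cl", 17, 35.45, 174.0),
    ElementRecord("Ar", 18, 39.948, 188.0),
    ElementRecord("K", 19, 39.098, 190.0),
    ElementRecord("Ca", 20, 40.078, 191.0),
    ElementRecord("Ti", 22, 47.867, 233.0),
    ElementRecord("Fe", 26, 55.845, 286.0),
    ElementRecord("Zn", 30, 65.38, 330.0),
    ElementRecord("I", 53, 126.904, 491.0),
    ElementRecord("Ba", 56, 137.327, 491.0),
]


class ElementTable:
    """Lookup table of :class:`ElementRecord` keyed by symbol.

    Symbols are unique; lookups of unknown symbols raise ``KeyError`` with
    the offending symbol in the message so composition errors are traceable.
    """

    def __init__(self, records=None):
        records = list(records) if records is not None else list(_RECORDS)
        self._by_symbol: dict[str, ElementRecord] = {}
        for rec in records:
            if rec.symbol in self._by_symbol:
                raise ValueError(f"duplicate element symbol {rec.symbol!r}")
            self._by_symbol[rec.symbol] = rec

    def __getitem__(self, symbol: str) -> ElementRecord:
        try:
            return self._by_symbol[symbol]
        except KeyError:
            raise KeyError(
                f"unknown element symbol {symbol!r}; known: "
                f"{sorted(self._by_symbol)}"
            ) from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def __iter__(self):
        return iter(self._by_symbol.values())

    def symbols(self) -> list[str]:
        return list(self._by_symbol)


#: Default element table used throughout the package.
DEFAULT_ELEMENTS = ElementTable()
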