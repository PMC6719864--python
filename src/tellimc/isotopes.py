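"""Natural isotopic abundances and abundance-ratio arithmetic.

Unit-mass-resolution mass cytometry cannot distinguish isobars — nuclides of
different elements sharing a mass number — so xenon contamination of the argon
carrier gas appears in the tellurium mass channels (124, 126, 128, 130).
Correcting for it, and for per-isotope detection bias, needs the fixed natural
isotopic composition of each element.  The bundled table is sourced from the
NIST/CIAAW standard isotopic-composition compilation (see
``data/isotope_abundances.json`` for source and retrieval date).
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Mapping

__all__ = [
    "IsotopeAbundanceTable",
    "default_table",
    "abundance",
    "theoretical_ratio",
    "TE_STABLE_MASSES",
    "XE_MASSES",
    "XE_ISOBARS_OF_TE",
]

#: Mass numbers of the eight stable tellurium isotopes.
TE_STABLE_MASSES = (120, 122, 123, 124, 125, 126, 128, 130)

#: Mass numbers of the nine naturally occurring xenon isotopes.
XE_MASSES = (124, 126, 128, 129, 130, 131, 132, 134, 136)

#: Tellurium mass channels that have a stable xenon isobar and therefore
#: receive xenon background.  125Te notably has none.
XE_ISOBARS_OF_TE = (124, 126, 128, 130)


class UnknownIsotopeError(KeyError):
    """Lookup of an (element, mass) pair absent from the abundance table."""

    def __init__(self, element: str, mass: int):
        self.element = element
        self.mass = mass
        super().__init__(f"no abundance entry for isotope {mass}{element}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return f"no abundance entry for isotope {self.mass}{self.element}"


class IsotopeAbundanceTable:
    """Read-only mapping (element symbol, mass number) -> fractional abundance.

    Abundances are dimensionless fractions in [0, 1] and sum to 1 per element
    to the precision of the source table (1e-3 tolerance on ingest).  A
    user-supplied JSON file with the same layout as the bundled one may be
    loaded via :meth:`from_json` for sensitivity analysis.
    """

    def __init__(self, entries: Mapping[tuple[str, int], float],
                 source: str = "user-supplied"):
        self._entries: dict[tuple[str, int], float] = {}
        for (element, mass), frac in entries.items():
            frac = float(frac)
            if not 0.0 <= frac <= 1.0:
                raise ValueError(
                    f"abundance of {mass}{element} is {frac}, outside [0, 1]")
            self._entries[(str(element), int(mass))] = frac
        self.source = source
        # Per-element closure check: fractions must account for the whole
        # element (guards against truncated user tables).
        totals: dict[str, float] = {}
        for (element, _), frac in self._entries.items():
            totals[element] = totals.get(element, 0.0) + frac
        for element, total in totals.items():
            if abs(total - 1.0) > 1e-3:
                raise ValueError(
                    f"abundances for {element} sum to {total:.6f}, not 1")

    @classmethod
    def from_json(cls, path_or_file) -> "IsotopeAbundanceTable":
        """Load a table from a JSON file shaped like the bundled data file."""
        if hasattr(path_or_file, "read"):
            payload = json.load(path_or_file)
        else:
            with open(path_or_file) as fh:
                payload = json.load(fh)
        entries = {
            (element, int(mass)): frac
            for element, masses in payload["abundances"].items()
            for mass, frac in masses.items()
        }
        return cls(entries, source=payload.get("source", "user-supplied"))

    def abundance(self, element: str, mass: int) -> float:
        """Fractional natural abundance of one isotope.

        Raises :class:`UnknownIsotopeError` for isotopes absent from the
        table (including unstable ones, which are never listed).
        """
        try:
            return self._entries[(element, int(mass))]
        except KeyError:
            raise UnknownIsotopeError(element, int(mass)) from None

    def theoretical_ratio(self, element: str, mass_a: int, mass_b: int) -> float:
        """Abundance ratio ``abundance(a) / abundance(b)`` of two isotopes.

        This is the "known isotopic ratio" used both to scale the xenon
        reference channel onto a contaminated tellurium channel and as the
        no-bias expectation for a tellurium channel ratio.
        """
        num = self.abundance(element, mass_a)
        den = self.abundance(element, mass_b)
        if den == 0.0:
            raise ZeroDivisionError(
                f"abundance of {mass_b}{element} is zero; ratio undefined")
        return num / den

    def elements(self) -> tuple[str, ...]:
        return tuple(sorted({el for el, _ in self._entries}))

    def masses(self, element: str) -> tuple[int, ...]:
        return tuple(sorted(m for el, m in self._entries if el == element))

    def __contains__(self, key: tuple[str, int]) -> bool:
        return (key[0], int(key[1])) in self._entries

    def items(self):
        return self._entries.items()

    def __repr__(self) -> str:
        return (f"IsotopeAbundanceTable({len(self._entries)} isotopes, "
                f"elements={self.elements()})")


def _load_bundled() -> IsotopeAbundanceTable:
    with resources.files("tellimc.data").joinpath(
            "isotope_abundances.json").open() as fh:
        return IsotopeAbundanceTable.from_json(fh)


_DEFAULT: IsotopeAbundanceTable | None = None


def default_table() -> IsotopeAbundanceTable:
    """The bundled NIST/CIAAW abundance table (loaded once, cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = _load_bundled()
    return _DEFAULT


def abundance(element: str, mass: int,
              table: IsotopeAbundanceTable | None = None) -> float:
    """Module-level convenience for :meth:`IsotopeAbundanceTable.abundance`."""
    return (table or default_table()).abundance(element, mass)


def theoretical_ratio(element: str, mass_a: int, mass_b: int,
                      table: IsotopeAbundanceTable | None = None) -> float:
    """Module-level convenience for the abundance ratio a/b of one element."""
    return (table or default_table()).theoretical_ratio(element, mass_a, mass_b)
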