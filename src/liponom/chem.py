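"""Elemental-composition arithmetic and exact-mass bookkeeping.

Compositions are integer multisets of nuclides.  A nuclide is an element
symbol plus an optional mass number: ``("H", 0)`` is hydrogen at natural
monoisotopic mass, ``("H", 2)`` is deuterium.  Compositions with negative
counts are legal and represent modification deltas (e.g. the ``(-H)`` of a
ketene loss); physical molecules must have all counts >= 0.

Monoisotopic nuclide masses come from the NIST table shipped with
:mod:`pyteomics`; the electron mass is included in every m/z so that e.g. the
phosphocholine cation C5H15NO4P comes out at m/z 184.0733 and not 184.0739.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

from pyteomics import mass as _ptmass

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ChargeState",
    "ElementalComposition",
    "FormulaError",
    "IsotopeLabelSpec",
    "LabelError",
    "apply_label",
    "monoisotopic_mass",
    "mz",
    "nominal_mass",
    "parse_formula",
]

ELECTRON_MASS: float = _ptmass.nist_mass["e*"][0][0]
PROTON_MASS: float = _ptmass.nist_mass["H"][0][0] - ELECTRON_MASS

#: elements that render at the end of a formula regardless of Hill order, so
#: that sodiated fragment deltas print as "(+ONa)" / "(+HONa)".
_METALS_LAST = ("Li", "Na", "K")

_TOKEN = re.compile(r"(?:\[(?P<a>\d+)\])?(?P<sym>[A-Z][a-z]?)(?P<n>\d*)")

Nuclide = tuple[str, int]


class FormulaError(ValueError):
    """Raised for malformed or unknown-element formula strings."""


class LabelError(ValueError):
    """Raised when an isotope label cannot be applied to a composition."""


def _nuclide_mono(sym: str, a: int) -> float:
    try:
        table = _ptmass.nist_mass[sym]
    except KeyError:
        raise FormulaError(f"unknown element symbol: {sym!r}") from None
    if a == 0:
        return table[0][0]
    try:
        return table[a][0]
    except KeyError:
        raise FormulaError(f"no nuclide [{a}]{sym} in the mass table") from None


def _nuclide_nominal(sym: str, a: int) -> int:
    if a:
        return a
    return round(_nuclide_mono(sym, 0))


class ElementalComposition:
    """Signed multiset of nuclides with exact-mass accessors.

    Supports ``+``, ``-``, unary ``-`` and integer ``*``; equality and hashing
    compare the reduced multiset (zero counts dropped).
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[Nuclide, int] | None = None) -> None:
        self._counts: dict[Nuclide, int] = {}
        if counts:
            for key, n in counts.items():
                if n:
                    self._counts[key] = self._counts.get(key, 0) + int(n)
            self._counts = {k: v for k, v in self._counts.items() if v}

    # -- basic container protocol -------------------------------------------
    def __getitem__(self, key: Nuclide | str) -> int:
        if isinstance(key, str):
            key = (key, 0)
        return self._counts.get(key, 0)

    def items(self) -> Iterator[tuple[Nuclide, int]]:
        return iter(self._counts.items())

    def __iter__(self) -> Iterator[Nuclide]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __bool__(self) -> bool:
        return bool(self._counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalComposition):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def key(self) -> tuple[tuple[Nuclide, int], ...]:
        """Canonical hashable form (sorted nuclide/count pairs)."""
        return tuple(sorted(self._counts.items()))

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = dict(self._counts)
        for k, v in other._counts.items():
            out[k] = out.get(k, 0) + v
        return ElementalComposition(out)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        return self + (-other)

    def __neg__(self) -> "ElementalComposition":
        return ElementalComposition({k: -v for k, v in self._counts.items()})

    def __mul__(self, n: int) -> "ElementalComposition":
        return ElementalComposition({k: v * n for k, v in self._counts.items()})

    __rmul__ = __mul__

    # -- chemistry ----------------------------------------------------------
    def is_physical(self) -> bool:
        return all(v >= 0 for v in self._counts.values())

    def monoisotopic_mass(self) -> float:
        return sum(n * _nuclide_mono(sym, a) for (sym, a), n in self._counts.items())

    def nominal_mass(self) -> int:
        return sum(n * _nuclide_nominal(sym, a) for (sym, a), n in self._counts.items())

    def element_total(self, sym: str) -> int:
        """Total count of an element over all its nuclides."""
        return sum(n for (s, _a), n in self._counts.items() if s == sym)

    def heavy_count(self) -> int:
        """Total number of explicitly heavy nuclides (mass number given)."""
        return sum(n for (_s, a), n in self._counts.items() if a)

    # -- formatting ---------------------------------------------------------
    def hill_formula(self, metals_last: bool = True) -> str:
        """Hill-convention formula; heavy nuclides render inline as ``[a]X``.

        ``metals_last`` moves Li/Na/K to the end so adduct deltas match the
        printed convention (``+ONa`` rather than strict-Hill ``+NaO``).
        """
        if any(v < 0 for v in self._counts.values()):
            raise FormulaError("cannot Hill-format a composition with negative counts; "
                              "use signed_formula()")
        has_c = self.element_total("C") > 0

        def order(key: Nuclide) -> tuple:
            sym, a = key
            if metals_last and sym in _METALS_LAST:
                return (3, _METALS_LAST.index(sym), a)
            if has_c and sym == "C":
                return (0, "", a)
            if has_c and sym == "H":
                return (1, "", a)
            return (2, sym, a)

        parts = []
        for sym, a in sorted(self._counts, key=order):
            n = self._counts[(sym, a)]
            prefix = f"[{a}]" if a else ""
            parts.append(f"{prefix}{sym}{n if n != 1 else ''}")
        return "".join(parts)

    def signed_formula(self) -> str:
        """Render a (possibly mixed-sign) delta as e.g. ``+O -C7H15``."""
        pos = ElementalComposition({k: v for k, v in self._counts.items() if v > 0})
        neg = ElementalComposition({k: -v for k, v in self._counts.items() if v < 0})
        bits = []
        if pos:
            bits.append("+" + pos.hill_formula())
        if neg:
            bits.append("-" + neg.hill_formula())
        return " ".join(bits)

    def __repr__(self) -> str:
        return f"ElementalComposition({self.signed_formula() or '0'!r})"

    def copy(self) -> "ElementalComposition":
        return ElementalComposition(self._counts)


def parse_formula(text: str) -> ElementalComposition:
    """Parse a Hill-style formula, optionally prefixed ``+`` or ``-``.

    Bracketed nuclides are allowed (``[2]H3``); a leading ``-`` negates all
    counts; the empty string is the empty composition.  Mixed-sign deltas in
    the ``signed_formula`` style (``+O -C7H15``) also parse.
    """
    text = text.strip()
    if not text:
        return ElementalComposition()
    # mixed-sign delta: whitespace-separated signed groups
    if " " in text:
        out = ElementalComposition()
        for group in text.split():
            out = out + parse_formula(group)
        return out
    sign = 1
    if text[0] in "+-":
        sign = -1 if text[0] == "-" else 1
        text = text[1:]
    counts: dict[Nuclide, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.start() != pos or m.end() == pos:
            raise FormulaError(f"malformed formula at {text[pos:]!r}")
        sym = m.group("sym")
        if sym not in _ptmass.nist_mass:
            raise FormulaError(f"unknown element symbol: {sym!r}")
        a = int(m.group("a")) if m.group("a") else 0
        if a:
            _nuclide_mono(sym, a)  # validates the nuclide exists
        n = int(m.group("n")) if m.group("n") else 1
        key = (sym, a)
        counts[key] = counts.get(key, 0) + sign * n
        pos = m.end()
    return ElementalComposition(counts)


def monoisotopic_mass(c: ElementalComposition) -> float:
    return c.monoisotopic_mass()


def nominal_mass(c: ElementalComposition) -> int:
    return c.nominal_mass()


@dataclass(frozen=True)
class ChargeState:
    """Nonzero charge with an optional adduct carrier symbol."""

    z: int
    carrier: str | None = None

    def __post_init__(self) -> None:
        if self.z == 0:
            raise ValueError("charge must be nonzero")

    @property
    def polarity(self) -> str:
        return "+" if self.z > 0 else "-"

    def suffix(self) -> str:
        """Charge suffix for bracketed ion names: ``+``, ``-``, ``2-`` ..."""
        mag = abs(self.z)
        return f"{mag if mag > 1 else ''}{self.polarity}"


def mz(ion: ElementalComposition, charge: ChargeState | int) -> float:
    """m/z of an ion whose adduct atoms are already merged into ``ion``.

    m/z = (monoisotopic mass - z * electron mass) / |z|: a cation is missing
    z electrons, an anion carries |z| extra ones.
    """
    z = charge.z if isinstance(charge, ChargeState) else int(charge)
    if z == 0:
        raise ValueError("charge must be nonzero")
    return (ion.monoisotopic_mass() - z * ELECTRON_MASS) / abs(z)


_LABEL_TOKEN = re.compile(r"\[(\d+)\]([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class IsotopeLabelSpec:
    """Stable-isotope label: heavy-nuclide substitutions ``[a]X n``.

    Rendering order is Hill-like: carbon nuclides first, then the remaining
    elements alphabetically, ties broken by increasing mass number, matching
    printed labels such as ``+[13]C2[15]N``.
    """

    substitutions: tuple[tuple[int, str, int], ...]  # (mass number, symbol, count)

    def __post_init__(self) -> None:
        for a, sym, n in self.substitutions:
            if n <= 0:
                raise LabelError(f"label count must be positive: [{a}]{sym}{n}")
            _nuclide_mono(sym, a)

    def __bool__(self) -> bool:
        return bool(self.substitutions)

    @classmethod
    def parse(cls, text: str) -> "IsotopeLabelSpec":
        text = text.strip()
        if text.startswith("+"):
            text = text[1:]
        subs = []
        pos = 0
        while pos < len(text):
            m = _LABEL_TOKEN.match(text, pos)
            if not m:
                raise LabelError(f"malformed isotope label at {text[pos:]!r}")
            subs.append((int(m.group(1)), m.group(2), int(m.group(3) or 1)))
            pos = m.end()
        return cls(tuple(subs))

    def _sorted(self) -> list[tuple[int, str, int]]:
        return sorted(self.substitutions, key=lambda s: (s[1] != "C", s[1], s[0]))

    def render(self, sign: str = "+") -> str:
        body = "".join(
            f"[{a}]{sym}{n if n != 1 else ''}" for a, sym, n in self._sorted()
        )
        return f"{sign}{body}"

    def composition_delta(self) -> ElementalComposition:
        """Delta swapping light atoms for heavy nuclides."""
        counts: dict[Nuclide, int] = {}
        for a, sym, n in self.substitutions:
            counts[(sym, a)] = counts.get((sym, a), 0) + n
            counts[(sym, 0)] = counts.get((sym, 0), 0) - n
        return ElementalComposition(counts)

    def mass_shift(self) -> float:
        return self.composition_delta().monoisotopic_mass()

    def merge(self, other: "IsotopeLabelSpec | None") -> "IsotopeLabelSpec":
        if not other:
            return self
        counts: dict[tuple[int, str], int] = {}
        for a, sym, n in self.substitutions + other.substitutions:
            counts[(a, sym)] = counts.get((a, sym), 0) + n
        return IsotopeLabelSpec(tuple((a, sym, n) for (a, sym), n in counts.items()))


def apply_label(
    c: ElementalComposition, label: IsotopeLabelSpec | None
) -> ElementalComposition:
    """Replace light atoms with heavy nuclides per ``label``.

    Raises :class:`LabelError` on over-substitution (more heavy atoms
    requested than light atoms available).
    """
    if not label:
        return c.copy()
    for a, sym, n in label.substitutions:
        if c[(sym, 0)] < n:
            raise LabelError(
                f"cannot place {n} x [{a}]{sym}: only {c[(sym, 0)]} light {sym} available"
            )
    return c + label.composition_delta()
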