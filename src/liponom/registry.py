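"""Data-driven lipid class registry.

Class templates (backbone composition, chain slots with linkage chemistry,
supported adducts) live in ``data/classes.json`` so that new lipid classes can
be added without code changes.  Adduct definitions are small and fixed, so
they live here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .chem import ChargeState, ElementalComposition, parse_formula

__all__ = ["AdductSpec", "ADDUCTS", "LipidClassTemplate", "SlotDef", "Registry",
           "default_registry"]


@dataclass(frozen=True)
class AdductSpec:
    """Charge-carrying addition/removal defining an ionized precursor."""

    symbol: str               # e.g. "+NH4", "-H"
    delta: ElementalComposition
    z: int

    @property
    def polarity(self) -> str:
        return "+" if self.z > 0 else "-"

    def charge(self) -> ChargeState:
        return ChargeState(self.z, carrier=self.symbol)


def _adduct(symbol: str, delta: str, z: int) -> AdductSpec:
    return AdductSpec(symbol, parse_formula(delta), z)


ADDUCTS: dict[str, AdductSpec] = {
    a.symbol: a
    for a in (
        _adduct("+H", "H", +1),
        _adduct("+NH4", "NH4", +1),
        _adduct("+Na", "Na", +1),
        _adduct("+Li", "Li", +1),
        _adduct("-H", "-H", -1),
        _adduct("-2H", "-H2", -2),
        _adduct("+HCOO", "CHO2", -1),
        _adduct("+CH3COO", "C2H3O2", -1),
    )
}


@dataclass(frozen=True)
class SlotDef:
    """One hydrocarbon-chain slot of a class template."""

    linkage: str  # ester | amide | thioester | ether | none
    hca: str      # FA | ether | LCB | ST

    @property
    def consumes_h(self) -> bool:
        return self.linkage != "none"


@dataclass(frozen=True)
class LipidClassTemplate:
    symbol: str
    category: str
    backbone: ElementalComposition
    slots: tuple[SlotDef, ...]
    adducts: dict[str, tuple[str, ...]]  # polarity -> adduct symbols
    imlf_alias: str                      # "glycerol" or "Cer"
    sn_only: bool = False

    @property
    def n_slots(self) -> int:
        return len(self.slots)

    def supports(self, adduct: AdductSpec) -> bool:
        return adduct.symbol in self.adducts.get(adduct.polarity, ())


class Registry:
    """Lookup of lipid class templates by symbol, longest-prefix matching."""

    def __init__(self, templates: list[LipidClassTemplate]) -> None:
        self._by_symbol = {t.symbol: t for t in templates}
        self._ordered = sorted(self._by_symbol, key=len, reverse=True)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def __iter__(self):
        return iter(self._by_symbol.values())

    def get(self, symbol: str) -> LipidClassTemplate:
        try:
            return self._by_symbol[symbol]
        except KeyError:
            raise KeyError(f"unregistered lipid class: {symbol!r}") from None

    def symbols(self) -> list[str]:
        return sorted(self._by_symbol)

    def match_prefix(self, text: str) -> tuple[LipidClassTemplate, str] | None:
        """Longest class symbol that prefixes ``text``; returns (template, rest)."""
        for symbol in self._ordered:
            if text.startswith(symbol):
                return self._by_symbol[symbol], text[len(symbol):]
        return None


def _load_default() -> Registry:
    raw = json.loads(
        resources.files("liponom.data").joinpath("classes.json").read_text()
    )
    templates = []
    for c in raw["classes"]:
        templates.append(
            LipidClassTemplate(
                symbol=c["symbol"],
                category=c["category"],
                backbone=parse_formula(c["backbone"]),
                slots=tuple(SlotDef(s["linkage"], s["hca"]) for s in c["slots"]),
                adducts={p: tuple(v) for p, v in c["adducts"].items()},
                imlf_alias=c.get("imlf_alias", "glycerol"),
                sn_only=bool(c.get("sn_only", False)),
            )
        )
    return Registry(templates)


_default: Registry | None = None


def default_registry() -> Registry:
    global _default
    if _default is None:
        _default = _load_default()
    return _default
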