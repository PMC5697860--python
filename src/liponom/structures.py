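"""Lipid-class structural templates: intact compositions, HCA bases, adducts.

The elemental composition of an intact lipid is assembled as::

    backbone  +  sum over chain slots ( HCA base  -  H if the linkage binds )

where the backbone carries free hydroxyl/amine groups at every slot and each
ester/amide/thioester/ether linkage consumes one backbone hydrogen.  The HCA
(minimal hydrocarbon chain-based attribute) bases are:

======== =========================== ==============================
HCA       base formula                reference structure
======== =========================== ==============================
FA        C_c H_{2c-1-2d} O_{1+h}     acyl: +O -> carboxylate,
                                      +HO -> fatty acid, -H -> ketene
O-alkyl   C_c H_{2c+1-2d}             plasmanyl ether chain
O-alkenyl C_c H_{2c+1-2d}             plasmenyl; d includes the vinyl bond
LCB       C_c H_{2c+3-2d} N O_h       free long-chain base
ST        C_c H_{2c-6-2d} O           free sterol (27:1 = cholesterol)
======== =========================== ==============================

Species-level names have well-defined intact compositions, because the total
formula depends only on the chain totals, not on how they split across slots.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem import (
    ChargeState,
    ElementalComposition,
    IsotopeLabelSpec,
    apply_label,
    mz,
    parse_formula,
)
from .grammar import ChainSpec, LipidName, parse_name, serialize_name
from .registry import ADDUCTS, AdductSpec, LipidClassTemplate, Registry, default_registry

__all__ = [
    "AdductError",
    "Precursor",
    "StructureError",
    "hca_base",
    "hca_composition",
    "intact_composition",
    "moiety_info",
    "precursor_ion",
]

_H = parse_formula("H")


class StructureError(ValueError):
    """Raised for chain/template combinations with no physical composition."""


class AdductError(ValueError):
    """Raised when an adduct is not supported for a lipid class/polarity."""


def hca_base(ch: ChainSpec) -> ElementalComposition:
    """Base composition of one HCA, chain label applied.

    Not validated for physicality: species-level pseudo-chains legitimately
    produce negative intermediate counts that cancel in the total.
    """
    c, d, h = ch.c, ch.d, ch.h
    if ch.hca == "FA":
        counts = {("C", 0): c, ("H", 0): 2 * c - 1 - 2 * d, ("O", 0): 1 + h}
    elif ch.hca in ("O-alkyl", "O-alkenyl"):
        counts = {("C", 0): c, ("H", 0): 2 * c + 1 - 2 * d, ("O", 0): h}
    elif ch.hca == "LCB":
        counts = {("C", 0): c, ("H", 0): 2 * c + 3 - 2 * d, ("N", 0): 1, ("O", 0): h}
    elif ch.hca == "ST":
        counts = {("C", 0): c, ("H", 0): 2 * c - 6 - 2 * d, ("O", 0): 1}
    else:
        raise StructureError(f"unknown HCA class: {ch.hca!r}")
    base = ElementalComposition(counts)
    if ch.label:
        base = apply_label(base, ch.label)
    return base


def hca_composition(
    ch: ChainSpec, modification: ElementalComposition | str | None = None
) -> ElementalComposition:
    """HCA base plus a modification delta; errors on negative counts."""
    if isinstance(modification, str):
        modification = parse_formula(modification)
    comp = hca_base(ch)
    if modification:
        comp = comp + modification
    if not comp.is_physical():
        raise StructureError(
            f"negative composition for {ch.hca} {ch.c}:{ch.d} with modification "
            f"{modification.signed_formula() if modification else ''!r}"
        )
    return comp


def _species_pseudo_chains(
    n: LipidName, template: LipidClassTemplate
) -> tuple[ChainSpec, ...]:
    """Pseudo-chains that place all totals on the first slot.

    The resulting intact composition is exact because the class total formula
    is linear in (C, DB, OH) regardless of the split.
    """
    c, d, h = n.totals
    chains = []
    for i, slot in enumerate(template.slots):
        hca = {"ether": "O-alkyl"}.get(slot.hca, slot.hca)
        if i == 0:
            chains.append(ChainSpec(hca=hca, c=c, d=d, h=h))
        else:
            chains.append(ChainSpec(hca=hca, c=0, d=0, h=0))
    return tuple(chains)


def intact_composition(
    n: LipidName | str, registry: Registry | None = None
) -> ElementalComposition:
    """Elemental composition of the intact (neutral) lipid molecule."""
    registry = registry or default_registry()
    if isinstance(n, str):
        n = parse_name(n, registry)
    template = registry.get(n.cls)
    if n.level == "species":
        chains = _species_pseudo_chains(n, template)
    else:
        if len(n.chains) != template.n_slots:
            raise StructureError(
                f"{n.cls} takes {template.n_slots} chains, name has {len(n.chains)}"
            )
        chains = n.chains
    comp = template.backbone
    if n.class_label:
        comp = apply_label(comp, n.class_label)
    for chain, slot in zip(chains, template.slots):
        comp = comp + hca_base(chain)
        if slot.consumes_h:
            comp = comp - _H
    if n.molecule_label:
        comp = apply_label(comp, n.molecule_label)
    if not comp.is_physical():
        raise StructureError(f"non-physical composition for {serialize_name(n)}")
    return comp


@dataclass(frozen=True)
class Precursor:
    """Ionized intact lipid: composition includes the adduct atoms."""

    name: LipidName
    template: LipidClassTemplate
    adduct: AdductSpec
    composition: ElementalComposition
    charge: ChargeState

    @property
    def mz(self) -> float:
        return mz(self.composition, self.charge)

    @property
    def class_symbol(self) -> str:
        return self.template.symbol

    @property
    def polarity(self) -> str:
        return self.charge.polarity

    @property
    def chains(self) -> tuple[ChainSpec, ...]:
        return self.name.chains

    @property
    def class_label(self) -> IsotopeLabelSpec | None:
        return self.name.class_label

    @property
    def display(self) -> str:
        return f"[{serialize_name(self.name)}{self.adduct.symbol}]{self.charge.suffix()}"


def precursor_ion(
    n: LipidName | str,
    adduct: AdductSpec | str,
    registry: Registry | None = None,
) -> Precursor:
    """Build the adducted precursor ion for a lipid name.

    Raises :class:`AdductError` if the adduct is not registered for the class.
    """
    registry = registry or default_registry()
    if isinstance(n, str):
        n = parse_name(n, registry)
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise AdductError(f"unknown adduct symbol: {adduct!r}") from None
    template = registry.get(n.cls)
    if not template.supports(adduct):
        raise AdductError(
            f"adduct {adduct.symbol} not supported for {n.cls} "
            f"(registered: {template.adducts})"
        )
    comp = intact_composition(n, registry) + adduct.delta
    return Precursor(
        name=n,
        template=template,
        adduct=adduct,
        composition=comp,
        charge=adduct.charge(),
    )


# ---------------------------------------------------------------------------
# multi-chain (iMLF) moiety naming support

_GLYCEROL = parse_formula("C3H8O3")
_ALIAS_BY_COUNT = {1: "MAG", 2: "DAG", 3: "TAG"}


def moiety_info(
    chains: tuple[ChainSpec, ...], template: LipidClassTemplate
) -> tuple[str, ElementalComposition]:
    """(shorthand, base composition) of the moiety formed by ``chains``.

    Used to name iMLFs: a two-chain remainder of a glycerophospholipid is
    referenced to a DAG moiety, a LCB+FA remainder of a sphingolipid to a Cer
    moiety.  The returned base is the intact reference molecule; fragment
    deltas are expressed against it.
    """
    c = sum(ch.c for ch in chains)
    d = sum(ch.d for ch in chains)
    h = sum(ch.h for ch in chains)
    label: IsotopeLabelSpec | None = None
    for ch in chains:
        if ch.label:
            label = ch.label.merge(label) if label else ch.label
    if template.imlf_alias == "Cer" and any(ch.hca == "LCB" for ch in chains):
        base = ElementalComposition()
        for ch in chains:
            base = base + hca_base(ch)
        base = base - _H * (len(chains) - 1)  # amide bonds
        name = f"Cer {c}:{d}" + (f";{h}" if h else "")
    else:
        base = _GLYCEROL
        ether = False
        for ch in chains:
            base = base + hca_base(ch) - _H
            ether = ether or ch.hca in ("O-alkyl", "O-alkenyl")
        alias = _ALIAS_BY_COUNT.get(len(chains), f"{len(chains)}AG")
        name = f"{alias} {'O-' if ether else ''}{c}:{d}" + (f";{h}" if h else "")
    if label:
        name += f"({label.render()})"
    return name, base
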