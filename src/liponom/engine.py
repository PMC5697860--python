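"""Rule-driven enumeration of CID fragments as mass-balanced reactions.

Every enumerated :class:`FragmentationReaction` satisfies the central
invariant of the framework: the nuclide multiset of the charged fragment plus
all neutral fragments equals the precursor ion exactly (hence mass balance to
numerical precision), and charges sum to the precursor charge.  Rules are
data (``data/rules.json``), not code; the vocabulary is limited to
fixed-composition parts, HCA-slot parts with a modification delta,
double-bond-cleavage parts, chain-pair parts and a precursor-minus-parts
remainder.

Duplicate reactions arising from identical chains (e.g. the two 18:1 moieties
of TAG 16:0-18:1-18:1) collapse to one, keeping the union of the chain slots
they evidence.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

from .chem import (
    ElementalComposition,
    IsotopeLabelSpec,
    LabelError,
    apply_label,
    mz as _mz,
    parse_formula,
)
from .grammar import ChainSpec
from .registry import LipidClassTemplate
from .structures import Precursor, hca_base

__all__ = [
    "EngineError",
    "FragmentationReaction",
    "FragmentPart",
    "FragmentationRule",
    "RuleApplicationError",
    "RuleValidationReport",
    "default_rules",
    "enumerate_fragments",
    "enumerate_ms3",
    "load_rules",
    "validate_rules",
]

MASS_BALANCE_TOL = 1e-9  # Da; atom balance is exact, this guards float sums


class EngineError(RuntimeError):
    """Internal inconsistency (balance violation) — indicates a bug."""


class RuleApplicationError(ValueError):
    """A rule cannot be applied to a precursor (negative composition, bad label)."""


# ---------------------------------------------------------------------------
# rule model


@dataclass(frozen=True)
class PartSpec:
    kind: str                       # fixed | chain | dbf | pair | remainder
    formula: str = ""               # fixed only
    delta: str = ""                 # chain / pair
    hca: tuple[str, ...] = ("FA",)  # chain filter
    head_label: bool = False        # fixed only
    label_to_loss: str = ""         # chain only
    charge: int | None = None       # explicit product charge (charge separation)


@dataclass(frozen=True)
class FragmentationRule:
    id: str
    classes: tuple[str, ...]
    adducts: tuple[str, ...]
    ms_level: int
    charged: PartSpec
    neutrals: tuple[PartSpec, ...]
    polarity: str | None = None

    def applies_to_class(self, symbol: str) -> bool:
        return "*" in self.classes or symbol in self.classes

    def matches(self, ctx: "IonContext", ms_level: int) -> bool:
        if self.ms_level != ms_level or not self.applies_to_class(ctx.class_symbol):
            return False
        if self.polarity and self.polarity != ctx.polarity:
            return False
        if "*" in self.adducts:
            return True
        return ctx.adduct_symbol in self.adducts

    @property
    def parts(self) -> tuple[PartSpec, ...]:
        return (self.charged, *self.neutrals)


def _parse_part(raw: dict) -> PartSpec:
    return PartSpec(
        kind=raw["kind"],
        formula=raw.get("formula", ""),
        delta=raw.get("delta", ""),
        hca=tuple(raw.get("hca", ["FA"])),
        head_label=bool(raw.get("head_label", False)),
        label_to_loss=raw.get("label_to_loss", ""),
        charge=raw.get("charge"),
    )


def load_rules(source) -> list[FragmentationRule]:
    """Load rules from a JSON file path / file object / parsed dict."""
    if isinstance(source, dict):
        raw = source
    elif hasattr(source, "read"):
        raw = json.load(source)
    else:
        with open(source) as fh:
            raw = json.load(fh)
    rules = []
    for r in raw["rules"]:
        rule = FragmentationRule(
            id=r["id"],
            classes=tuple(r["classes"]),
            adducts=tuple(r["adducts"]),
            ms_level=int(r["ms_level"]),
            charged=_parse_part(r["charged"]),
            neutrals=tuple(_parse_part(n) for n in r["neutrals"]),
            polarity=r.get("polarity"),
        )
        iterating = [p for p in rule.parts if p.kind in ("chain", "dbf", "pair")]
        if len(iterating) > 1:
            raise ValueError(f"rule {rule.id}: at most one chain-iterating part")
        if sum(p.kind == "remainder" for p in rule.parts) > 1:
            raise ValueError(f"rule {rule.id}: at most one remainder part")
        rules.append(rule)
    return rules


_default_rules: list[FragmentationRule] | None = None


def default_rules() -> list[FragmentationRule]:
    global _default_rules
    if _default_rules is None:
        with resources.files("liponom.data").joinpath("rules.json").open() as fh:
            _default_rules = load_rules(fh)
    return _default_rules


# ---------------------------------------------------------------------------
# reaction model


@dataclass(frozen=True)
class IonContext:
    """What the engine needs to know about the ion being fragmented.

    Built from a :class:`~liponom.structures.Precursor` for MS2 and from a
    parent reaction's charged fragment for MS3.  ``chains`` holds
    (slot index, chain) pairs; ``chains_known`` is False for species-level
    precursors whose chain split is undetermined (only chain-free rules
    apply, and the remainder is named from the chain totals).
    """

    template: LipidClassTemplate
    composition: ElementalComposition
    z: int
    chains: tuple[tuple[int, ChainSpec], ...]
    chains_known: bool
    class_label: IsotopeLabelSpec | None
    display: str
    adduct_symbol: str | None

    @property
    def class_symbol(self) -> str:
        return self.template.symbol

    @property
    def polarity(self) -> str:
        return "+" if self.z > 0 else "-"


@dataclass(frozen=True)
class FragmentPart:
    """One fragment of a mass-balanced reaction."""

    kind: str                 # fixed | chain | dbf | pair | remainder
    ftype: str                # LCF | MLF | iMLF | DBF
    composition: ElementalComposition
    z: int = 0
    chains: tuple[tuple[int, ChainSpec], ...] = ()
    delta: ElementalComposition | None = None
    fixed_label: IsotopeLabelSpec | None = None
    dbf_position: int | None = None

    @property
    def mass(self) -> float:
        return self.composition.monoisotopic_mass()

    @property
    def charged(self) -> bool:
        return self.z != 0


@dataclass(frozen=True)
class FragmentationReaction:
    context: IonContext
    rule_id: str
    ms_level: int
    charged: FragmentPart
    neutrals: tuple[FragmentPart, ...]
    chain_indices: frozenset[int]
    parent: "FragmentationReaction | None" = None

    def __post_init__(self) -> None:
        total = self.charged.composition
        z = self.charged.z
        for part in self.neutrals:
            total = total + part.composition
            z += part.z
        if total != self.context.composition or z != self.context.z:
            raise EngineError(
                f"rule {self.rule_id}: reaction not balanced against "
                f"{self.context.display}"
            )

    @property
    def mz(self) -> float:
        return _mz(self.charged.composition, self.charged.z)

    @property
    def mass_balance_error(self) -> float:
        total = self.charged.mass + sum(p.mass for p in self.neutrals)
        return abs(total - self.context.composition.monoisotopic_mass())

    def dedup_key(self) -> tuple:
        return (
            self.charged.composition.key(),
            self.charged.z,
            tuple(sorted((p.composition.key(), p.z) for p in self.neutrals)),
            self.ms_level,
        )


# ---------------------------------------------------------------------------
# instantiation

_H = parse_formula("H")


def _context_for(precursor: Precursor) -> IonContext:
    chains_known = precursor.name.level != "species"
    if chains_known:
        chains = tuple(enumerate(precursor.chains))
    else:
        from .structures import _species_pseudo_chains

        chains = tuple(
            enumerate(_species_pseudo_chains(precursor.name, precursor.template))
        )
    return IonContext(
        template=precursor.template,
        composition=precursor.composition,
        z=precursor.charge.z,
        chains=chains,
        chains_known=chains_known,
        class_label=precursor.class_label,
        display=precursor.display,
        adduct_symbol=precursor.adduct.symbol,
    )


def _chain_delta(spec: PartSpec, chain: ChainSpec) -> ElementalComposition:
    """Modification delta with heavy-nuclide transfer into the lost atoms."""
    delta = parse_formula(spec.delta) if spec.delta else ElementalComposition()
    if spec.label_to_loss and chain.label:
        transfer = IsotopeLabelSpec.parse(spec.label_to_loss)
        available = {(a, s): n for a, s, n in chain.label.substitutions}
        for a, sym, n in transfer.substitutions:
            n_move = min(n, available.get((a, sym), 0), -delta[(sym, 0)])
            if n_move > 0:
                delta = delta + ElementalComposition(
                    {(sym, 0): n_move, (sym, a): -n_move}
                )
    return delta


def _make_chain_part(
    spec: PartSpec, idx: int, chain: ChainSpec, z: int
) -> FragmentPart:
    delta = _chain_delta(spec, chain)
    comp = hca_base(chain) + delta
    if not comp.is_physical():
        raise RuleApplicationError(
            f"negative composition for {chain.hca} {chain.c}:{chain.d} "
            f"with delta {spec.delta!r}"
        )
    return FragmentPart(
        kind="chain", ftype="MLF", composition=comp, z=z,
        chains=((idx, chain),), delta=delta,
    )


def _make_dbf_part(
    spec: PartSpec, idx: int, chain: ChainSpec, position: int, z: int
) -> FragmentPart | None:
    k = chain.c - position - 2
    if k <= 0:
        return None  # double bond too close to the methyl end
    delta = parse_formula("O") + parse_formula(f"-C{k}H{2 * k + 1}")
    comp = hca_base(chain) + delta
    if not comp.is_physical():
        return None
    return FragmentPart(
        kind="dbf", ftype="DBF", composition=comp, z=z,
        chains=((idx, chain),), delta=delta, dbf_position=position,
    )


def _make_fixed_part(spec: PartSpec, ctx: IonContext, z: int) -> FragmentPart:
    comp = parse_formula(spec.formula)
    label = None
    if spec.head_label and ctx.class_label:
        try:
            comp = apply_label(comp, ctx.class_label)
        except LabelError as exc:
            raise RuleApplicationError(str(exc)) from exc
        label = ctx.class_label
    return FragmentPart(
        kind="fixed", ftype="LCF", composition=comp, z=z, fixed_label=label
    )


def _make_pair_part(
    spec: PartSpec, picks: tuple[tuple[int, ChainSpec], ...], ctx: IonContext, z: int
) -> FragmentPart:
    from .structures import moiety_info

    _, base = moiety_info(tuple(ch for _i, ch in picks), ctx.template)
    delta = parse_formula(spec.delta) if spec.delta else ElementalComposition()
    comp = base + delta
    if not comp.is_physical():
        raise RuleApplicationError(f"negative pair composition for {spec.delta!r}")
    return FragmentPart(
        kind="pair", ftype="iMLF", composition=comp, z=z, chains=picks, delta=delta
    )


def _remainder_ftype(n_chains: int) -> str:
    if n_chains == 0:
        return "LCF"
    if n_chains == 1:
        return "MLF"
    return "iMLF"


def _instantiate(ctx: IonContext, rule: FragmentationRule) -> list[FragmentationReaction]:
    charged_z = rule.charged.charge if rule.charged.charge is not None else ctx.z

    # expand the (single) iterating part into concrete picks
    iter_spec = next((p for p in rule.parts if p.kind in ("chain", "dbf", "pair")), None)
    picks: list = [None]
    if iter_spec is not None:
        if not ctx.chains_known:
            return []
        if iter_spec.kind == "chain":
            picks = [
                (i, ch) for i, ch in ctx.chains if ch.hca in iter_spec.hca and ch.c > 0
            ]
        elif iter_spec.kind == "dbf":
            picks = [
                (i, ch, pos)
                for i, ch in ctx.chains
                if ch.positions
                for pos in ch.positions
            ]
        else:  # pair
            picks = list(itertools.combinations(
                [(i, ch) for i, ch in ctx.chains if ch.c > 0], 2
            ))
        if not picks:
            return []

    reactions = []
    for pick in picks:
        used: list[tuple[int, ChainSpec]] = []

        def build(spec: PartSpec, z: int) -> FragmentPart | None:
            if spec.kind == "fixed":
                return _make_fixed_part(spec, ctx, z)
            if spec.kind == "chain":
                i, ch = pick
                used.append((i, ch))
                return _make_chain_part(spec, i, ch, z)
            if spec.kind == "dbf":
                i, ch, pos = pick
                used.append((i, ch))
                return _make_dbf_part(spec, i, ch, pos, z)
            if spec.kind == "pair":
                used.extend(pick)
                return _make_pair_part(spec, tuple(pick), ctx, z)
            return None  # remainder: built last

        try:
            charged = build(rule.charged, charged_z)
            neutrals = []
            remainder_slot = None
            for n_idx, spec in enumerate(rule.neutrals):
                if spec.kind == "remainder":
                    remainder_slot = (n_idx, spec)
                    neutrals.append(None)
                else:
                    part = build(spec, spec.charge or 0)
                    if part is None:
                        raise RuleApplicationError("unbuildable part")
                    neutrals.append(part)
            if charged is None and rule.charged.kind != "remainder":
                continue  # dbf pick skipped (chain too short)

            explicit = [p for p in [charged, *neutrals] if p is not None]
            rem_comp = ctx.composition
            for p in explicit:
                rem_comp = rem_comp - p.composition
            used_idx = {ui for ui, _c in used}
            rem_chains = tuple(
                (i, ch) for i, ch in ctx.chains if i not in used_idx
            )
            if rule.charged.kind == "remainder" or remainder_slot is not None:
                if not rem_comp.is_physical():
                    raise RuleApplicationError(
                        f"rule {rule.id}: remainder has negative counts on "
                        f"{ctx.display}"
                    )
                if rule.charged.kind == "remainder":
                    rem_part = FragmentPart(
                        kind="remainder",
                        ftype=_remainder_ftype(len(rem_chains)),
                        composition=rem_comp, z=charged_z, chains=rem_chains,
                    )
                    charged = rem_part
                else:
                    n_idx, spec = remainder_slot
                    rem_z = spec.charge or 0
                    neutrals[n_idx] = FragmentPart(
                        kind="remainder",
                        ftype=_remainder_ftype(len(rem_chains)),
                        composition=rem_comp, z=rem_z, chains=rem_chains,
                    )
            # drop empty neutral parts (e.g. the FA carboxylate remainder)
            neutrals = tuple(p for p in neutrals if p is not None and p.composition)

            # evidence for the molecular-level call comes only from parts that
            # explicitly carry one chain; a single-chain remainder is named as
            # an MLF but its chain content is implied by the candidate, not
            # observed
            evidence = set()
            for part in (charged, *neutrals):
                if part.kind in ("chain", "dbf"):
                    evidence.add(part.chains[0][0])
            reactions.append(
                FragmentationReaction(
                    context=ctx,
                    rule_id=rule.id,
                    ms_level=rule.ms_level,
                    charged=charged,
                    neutrals=neutrals,
                    chain_indices=frozenset(evidence if ctx.chains_known else ()),
                )
            )
        except RuleApplicationError:
            raise
    return reactions


def _dedup(reactions: list[FragmentationReaction]) -> list[FragmentationReaction]:
    seen: dict[tuple, int] = {}
    out: list[FragmentationReaction] = []
    for rxn in reactions:
        key = rxn.dedup_key()
        if key in seen:
            i = seen[key]
            merged = out[i].chain_indices | rxn.chain_indices
            if merged != out[i].chain_indices:
                out[i] = FragmentationReaction(
                    context=out[i].context,
                    rule_id=out[i].rule_id,
                    ms_level=out[i].ms_level,
                    charged=out[i].charged,
                    neutrals=out[i].neutrals,
                    chain_indices=frozenset(merged),
                    parent=out[i].parent,
                )
        else:
            seen[key] = len(out)
            out.append(rxn)
    return out


def enumerate_fragments(
    precursor: Precursor,
    rules: list[FragmentationRule] | None = None,
    ms_level: int = 2,
) -> list[FragmentationReaction]:
    """All mass-balanced fragment reactions of a precursor ion.

    ``ms_level=3`` chains through every MS2 reaction and returns the flattened
    MS3 reactions.  Output order is deterministic (rule order, then slot
    order); duplicate reactions from identical chains are collapsed.
    """
    rules = rules if rules is not None else default_rules()
    if ms_level == 3:
        out = []
        for parent in enumerate_fragments(precursor, rules, ms_level=2):
            out.extend(enumerate_ms3(parent, rules))
        return _dedup(out)
    ctx = _context_for(precursor)
    applicable = [r for r in rules if r.matches(ctx, ms_level)]
    if not applicable:
        warnings.warn(
            f"no fragmentation rules for {ctx.class_symbol} {ctx.adduct_symbol} "
            f"({ctx.polarity})",
            stacklevel=2,
        )
        return []
    reactions = []
    for rule in applicable:
        reactions.extend(_instantiate(ctx, rule))
    return _dedup(reactions)


def enumerate_ms3(
    parent: FragmentationReaction,
    rules: list[FragmentationRule] | None = None,
) -> list[FragmentationReaction]:
    """MS3 reactions: the parent's charged fragment becomes the precursor.

    Empty if the charged fragment carries no hydrocarbon chains or no MS3
    rule applies.
    """
    rules = rules if rules is not None else default_rules()
    charged = parent.charged
    if not charged.chains:
        return []
    ctx = IonContext(
        template=parent.context.template,
        composition=charged.composition,
        z=charged.z,
        chains=charged.chains,
        chains_known=parent.context.chains_known,
        class_label=None,
        display=f"{parent.context.display} -> m/z {parent.mz:.4f}",
        adduct_symbol=parent.context.adduct_symbol,
    )
    reactions = []
    for rule in rules:
        if rule.matches(ctx, ms_level=3):
            for rxn in _instantiate(ctx, rule):
                reactions.append(
                    FragmentationReaction(
                        context=rxn.context,
                        rule_id=rxn.rule_id,
                        ms_level=3,
                        charged=rxn.charged,
                        neutrals=rxn.neutrals,
                        chain_indices=rxn.chain_indices,
                        parent=parent,
                    )
                )
    return _dedup(reactions)


# ---------------------------------------------------------------------------
# rule validation


@dataclass
class RuleValidationReport:
    checked: int = 0
    violations: list[tuple[str, str, str]] = field(default_factory=list)
    # (rule id, probe description, error message)

    @property
    def ok(self) -> bool:
        return not self.violations


_PROBE_FA = [(17, 0), (18, 1), (18, 2), (16, 0)]


def _probe_chain(slot_hca: str, i: int) -> ChainSpec:
    if slot_hca == "LCB":
        return ChainSpec(hca="LCB", c=18, d=1, h=2)
    if slot_hca == "ST":
        return ChainSpec(hca="ST", c=27, d=1)
    if slot_hca == "ether":
        return ChainSpec(hca="O-alkyl", c=16, d=0)
    c, d = _PROBE_FA[i % len(_PROBE_FA)]
    positions = (9,) if d == 1 else None
    return ChainSpec(hca="FA", c=c, d=d, positions=positions)


def validate_rules(
    rules: list[FragmentationRule] | None = None, registry=None
) -> RuleValidationReport:
    """Instantiate every rule on a probe lipid per class; report violations.

    Atom balance is checked structurally on construction; this additionally
    surfaces negative compositions, label failures and vocabulary errors,
    with the offending rule id.
    """
    from .grammar import LipidName
    from .registry import ADDUCTS, default_registry
    from .structures import Precursor

    rules = rules if rules is not None else default_rules()
    registry = registry or default_registry()
    report = RuleValidationReport()
    from .structures import intact_composition

    for template in registry:
        chains = tuple(
            _probe_chain(slot.hca, i) for i, slot in enumerate(template.slots)
        )
        level = "db_defined" if any(ch.positions for ch in chains) else "molecular"
        name = LipidName(cls=template.symbol, level=level, chains=chains)
        for polarity, symbols in template.adducts.items():
            for symbol in symbols:
                adduct = ADDUCTS[symbol]
                precursor = Precursor(
                    name=name,
                    template=template,
                    adduct=adduct,
                    composition=intact_composition(name, registry) + adduct.delta,
                    charge=adduct.charge(),
                )
                ctx = _context_for(precursor)
                for rule in rules:
                    if not rule.matches(ctx, rule.ms_level) or rule.ms_level != 2:
                        continue
                    probe = f"{template.symbol} {symbol}"
                    try:
                        rxns = _instantiate(ctx, rule)
                        report.checked += len(rxns)
                        for rxn in rxns:
                            if rxn.mass_balance_error > MASS_BALANCE_TOL:
                                report.violations.append(
                                    (rule.id, probe, "mass balance violated")
                                )
                            for part in (rxn.charged, *rxn.neutrals):
                                if not part.composition.is_physical():
                                    report.violations.append(
                                        (rule.id, probe, "negative fragment composition")
                                    )
                    except (RuleApplicationError, EngineError) as exc:
                        report.violations.append((rule.id, probe, str(exc)))
    return report
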