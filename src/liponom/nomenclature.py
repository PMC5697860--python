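"""Shorthand notation for fragment parts, dual annotation and prioritization.

Naming rules:

* neutral fragments are prefixed ``-``; charged fragments are not;
* LCFs (class-selective, chain-free) are named by the lipid class symbol and
  the nominal mass in parentheses, e.g. ``SM(184)``, ``-PE O-(141)``, with any
  head-group isotope label inline: ``PC(+[2]H13)(197)``;
* MLFs/DBFs carry the HCA, its C:DB(;OH) token, double-bond positions, chain
  labels and the signed Hill modification delta: ``FA 19:0(+C11H20N2O9P2S)``,
  ``FA 18:1(9)(+O -C7H15)``, ``-FA 16:0(+[2]H3)(-H)``;
* iMLFs are referenced to a multi-chain moiety: ``DAG 28:2(+C6H11O9P2)``,
  ``-Cer 35:1;2(-H2O)``.

Each fragment ion m/z has a dual annotation — the charged fragment and the
composite of neutral losses — and one side is prioritized by fragment type
(DBF > MLF > LCF > iMLF), then by lower total fragment mass (not m/z), ties
going to the charged side.  ``render_dual`` prints ``PRIORITIZED | other``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .chem import ElementalComposition, IsotopeLabelSpec, apply_label, parse_formula
from .engine import FragmentPart, FragmentationReaction
from .grammar import ChainSpec
from .registry import LipidClassTemplate
from .structures import hca_base, moiety_info

__all__ = [
    "FragmentAnnotation",
    "TYPE_PRIORITY",
    "annotate_reaction",
    "name_part",
    "parse_fragment_name",
    "prioritize",
    "render_dual",
]

#: decision-tree priority: lower is better
TYPE_PRIORITY = {"DBF": 0, "MLF": 1, "LCF": 2, "iMLF": 3}

_HCA_DISPLAY = {"FA": "FA ", "O-alkyl": "FA O-", "O-alkenyl": "FA O-",
                "LCB": "LCB ", "ST": "ST "}


def _chain_body(ch: ChainSpec) -> str:
    return _HCA_DISPLAY[ch.hca] + ch.token()


def _delta_suffix(delta: ElementalComposition | None) -> str:
    if not delta:
        return ""
    return f"({delta.signed_formula()})"


def name_part(
    part: FragmentPart, template: LipidClassTemplate
) -> str:
    """Shorthand for one fragment part (without the neutral ``-`` prefix)."""
    if part.kind == "fixed":
        label = f"({part.fixed_label.render()})" if part.fixed_label else ""
        return f"{template.symbol}{label}({part.composition.nominal_mass()})"
    if part.kind in ("chain", "dbf"):
        _idx, ch = part.chains[0]
        return _chain_body(ch) + _delta_suffix(part.delta)
    if part.kind == "pair":
        mname, base = moiety_info(tuple(ch for _i, ch in part.chains), template)
        return mname + _delta_suffix(part.composition - base)
    if part.kind == "remainder":
        chains = tuple(ch for _i, ch in part.chains)
        if not chains:
            return f"{template.symbol}({part.composition.nominal_mass()})"
        if len(chains) == 1:
            delta = part.composition - hca_base(chains[0])
            return _chain_body(chains[0]) + _delta_suffix(delta)
        mname, base = moiety_info(chains, template)
        return mname + _delta_suffix(part.composition - base)
    raise ValueError(f"unknown part kind: {part.kind!r}")


@dataclass(frozen=True)
class FragmentAnnotation:
    """Dual (charged | neutral-composite) annotation of one fragment m/z."""

    mz: float
    charged_name: str
    neutral_names: tuple[str, ...]   # "-"-prefixed when neutral
    charged_mass: float
    neutral_mass: float
    charged_types: tuple[str, ...]
    neutral_types: tuple[str, ...]
    prioritized: str = ""            # "charged" | "neutral"
    reaction: FragmentationReaction | None = None

    @property
    def neutral_composite_name(self) -> str:
        return " ".join(self.neutral_names)

    @property
    def fragment_types(self) -> frozenset[str]:
        return frozenset(self.charged_types) | frozenset(self.neutral_types)

    @property
    def prioritized_name(self) -> str:
        if self.prioritized == "neutral":
            return self.neutral_composite_name
        return self.charged_name

    @property
    def prioritized_types(self) -> tuple[str, ...]:
        return self.neutral_types if self.prioritized == "neutral" else self.charged_types


def _display_order(parts: tuple[FragmentPart, ...]) -> list[FragmentPart]:
    """Chain-derived parts first, then head-group (fixed), then remainder."""
    rank = {"chain": 0, "dbf": 0, "pair": 1, "fixed": 2, "remainder": 3}
    return sorted(parts, key=lambda p: rank[p.kind])


def annotate_reaction(reaction: FragmentationReaction) -> FragmentAnnotation:
    """Build and prioritize the dual annotation of a reaction."""
    template = reaction.context.template
    charged_name = name_part(reaction.charged, template)
    neutral_parts = _display_order(reaction.neutrals)
    neutral_names = tuple(
        name_part(p, template) if p.charged else "-" + name_part(p, template)
        for p in neutral_parts
    )
    ann = FragmentAnnotation(
        mz=reaction.mz,
        charged_name=charged_name,
        neutral_names=neutral_names,
        charged_mass=reaction.charged.mass,
        neutral_mass=sum(p.mass for p in neutral_parts),
        charged_types=(reaction.charged.ftype,),
        neutral_types=tuple(p.ftype for p in neutral_parts),
        reaction=reaction,
    )
    return prioritize(ann)


def prioritize(a: FragmentAnnotation) -> FragmentAnnotation:
    """Apply the decision tree; permutation of neutral parts never matters.

    Type order DBF > MLF > LCF > iMLF; on a type tie the side with the lower
    total fragment mass (not m/z) wins; an exact mass tie goes to the charged
    side.  Single-sided annotations are their own priority.
    """
    if not a.neutral_names:
        return replace(a, prioritized="charged")
    if a.reaction is not None and any(p.charged for p in a.reaction.neutrals):
        # charge separation (e.g. doubly charged CL): the observed m/z IS the
        # charged fragment; the counter-ion is not a neutral-loss composite
        return replace(a, prioritized="charged")
    charged_rank = min(TYPE_PRIORITY[t] for t in a.charged_types)
    neutral_rank = min(TYPE_PRIORITY[t] for t in a.neutral_types)
    if charged_rank != neutral_rank:
        side = "charged" if charged_rank < neutral_rank else "neutral"
    elif a.neutral_mass < a.charged_mass:
        side = "neutral"
    else:
        side = "charged"
    return replace(a, prioritized=side)


def render_dual(a: FragmentAnnotation) -> str:
    """``PRIORITIZED | other``; no separator for single-sided annotations."""
    if not a.neutral_names:
        return a.charged_name
    neutral = a.neutral_composite_name
    if a.prioritized == "neutral":
        return f"{neutral} | {a.charged_name}"
    return f"{a.charged_name} | {neutral}"


# ---------------------------------------------------------------------------
# fragment-name parsing (round-trip support)

_MOIETY_RE = re.compile(
    r"^(?P<alias>MAG|DAG|TAG|Cer)\s(?P<ether>O-)?(?P<c>\d+):(?P<d>\d+)(?:;(?P<h>\d+))?"
)
_CHAIN_NAME_RE = re.compile(
    r"^(?P<hca>FA O-|FA|LCB|ST)\s?(?P<c>\d+):(?P<d>\d+)(?P<p>p?)(?:;(?P<h>\d+))?"
)
_LCF_RE = re.compile(r"^(?P<cls>.+?)(?:\((?P<label>\+\[.+?)\))?\((?P<nominal>\d+)\)$")


def _paren_groups(text: str) -> list[str]:
    groups, depth, start = [], 0, 0
    for i, chr_ in enumerate(text):
        if chr_ == "(":
            if depth == 0:
                start = i + 1
            depth += 1
        elif chr_ == ")":
            depth -= 1
            if depth == 0:
                groups.append(text[start:i])
    return groups


def _moiety_base(alias: str, ether: bool, c: int, d: int, h: int) -> ElementalComposition:
    if alias == "Cer":
        return ElementalComposition(
            {("C", 0): c, ("H", 0): 2 * c + 1 - 2 * d, ("N", 0): 1, ("O", 0): 1 + h}
        )
    k = {"MAG": 1, "DAG": 2, "TAG": 3}[alias]
    if ether:  # one ether chain, k-1 ester chains
        oxy = 3 + (k - 1) + h
        hyd = 8 + 2 * c - 2 * d - 2 * k + (k - 1) - 1 + k - 1
        # ether chain: +2c1+1-2d1 then -H; esters: +2ci-1-2di then -H each
        hyd = 8 + (2 * c + 1 - 2 * d - (k - 1)) - k
    else:
        oxy = 3 + k + h
        hyd = 8 + (2 * c - k - 2 * d) - k
    return ElementalComposition({("C", 0): 3 + c, ("H", 0): hyd, ("O", 0): oxy})


def parse_fragment_name(
    text: str,
    template: LipidClassTemplate,
    lcf_formulas: dict[int, str] | None = None,
) -> ElementalComposition:
    """Recover the elemental composition encoded by a fragment name.

    MLF/iMLF/DBF names are self-contained (HCA base plus signed delta).  LCF
    names carry only the class symbol and nominal mass, so a lookup of the
    class's curated LCF formulas (``nominal -> formula``, unlabeled) must be
    supplied for them.
    """
    text = text.strip()
    if text.startswith("-"):
        text = text[1:].strip()

    m = _CHAIN_NAME_RE.match(text)
    if m and not text.startswith(template.symbol + "("):
        hca = {"FA O-": "O-alkenyl" if m.group("p") else "O-alkyl",
               "FA": "FA", "LCB": "LCB", "ST": "ST"}[m.group("hca")]
        comp = None
        groups = _paren_groups(text[m.end():])
        label = None
        delta = ElementalComposition()
        positions = None
        for g in groups:
            if g.startswith("+["):
                label = IsotopeLabelSpec.parse(g)
            elif re.fullmatch(r"\d+(,\d+)*", g):
                positions = tuple(int(x) for x in g.split(","))
            else:
                delta = delta + parse_formula(g)
        ch = ChainSpec(
            hca=hca, c=int(m.group("c")), d=int(m.group("d")),
            h=int(m.group("h") or 0), positions=positions, label=label,
        )
        return hca_base(ch) + delta

    mm = _MOIETY_RE.match(text)
    if mm:
        base = _moiety_base(
            mm.group("alias"), bool(mm.group("ether")),
            int(mm.group("c")), int(mm.group("d")), int(mm.group("h") or 0),
        )
        comp = base
        for g in _paren_groups(text[mm.end():]):
            if g.startswith("+["):
                comp = apply_label(comp, IsotopeLabelSpec.parse(g))
            else:
                comp = comp + parse_formula(g)
        return comp

    ml = _LCF_RE.match(text)
    if ml:
        nominal = int(ml.group("nominal"))
        label = IsotopeLabelSpec.parse(ml.group("label")) if ml.group("label") else None
        if lcf_formulas is None:
            raise ValueError(f"LCF name {text!r} needs a class LCF formula lookup")
        light_nominal = nominal
        if label:
            light_nominal -= IsotopeLabelSpec.parse(ml.group("label")).composition_delta().nominal_mass()
        comp = parse_formula(lcf_formulas[light_nominal])
        if label:
            comp = apply_label(comp, label)
        return comp
    raise ValueError(f"unparseable fragment name: {text!r}")
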