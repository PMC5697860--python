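"""Parsing and serialization of intact-lipid shorthand names.

Shorthand names carry a lipid class symbol and either per-chain information
(molecular / sn-defined / double-bond-defined levels) or chain totals (species
level)::

    PS 16:0-22:6          molecular level (unordered chains, dash separator)
    SE 27:1/18:2          sn-defined level (slash separator)
    PC 16:0-18:1(9)       double-bond positions known
    SM 35:1;2             species level (totals C:DB;OH)
    PC(+[2]H13) 16:1-18:1 head-group stable-isotope label
    PC 16:0(+[2]H3)-16:0(+[2]H3)   chain-localized labels

Both the ASCII hyphen-minus and the typographic en-dash are accepted as chain
separators on input; the hyphen-minus is emitted on output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .chem import IsotopeLabelSpec
from .registry import LipidClassTemplate, Registry, default_registry

__all__ = [
    "ChainSpec",
    "LipidName",
    "NameParseError",
    "parse_name",
    "serialize_name",
    "species_of",
]

#: chain separators accepted on input (unordered); slash marks sn-assignment
_DASHES = ("-", "–")

LEVELS = ("species", "molecular", "sn_defined", "db_defined")


class NameParseError(ValueError):
    """Raised for names that do not follow the shorthand grammar."""


@dataclass(frozen=True)
class ChainSpec:
    """One hydrocarbon-chain attribute (HCA): class, C, DB, OH, labels.

    ``hca`` is one of ``FA`` (fatty acyl), ``O-alkyl``, ``O-alkenyl``
    (plasmanyl / plasmenyl ether chains), ``LCB`` (long-chain base) or ``ST``
    (sterol).  For alkenyl chains the double-bond count includes the vinyl
    ether double bond (``18:1p`` has the vinyl bond as its single DB).
    """

    hca: str
    c: int
    d: int
    h: int = 0
    positions: tuple[int, ...] | None = None
    label: IsotopeLabelSpec | None = None

    def __post_init__(self) -> None:
        if self.c < 0 or self.d < 0 or self.h < 0:
            raise NameParseError("chain C/DB/OH counts must be non-negative")
        if self.c and self.d > self.c // 2 + 1:
            raise NameParseError(
                f"implausible chain {self.c}:{self.d} (too many double bonds)"
            )
        if self.positions is not None and len(self.positions) != self.d:
            raise NameParseError(
                "number of double-bond positions must equal the double-bond count"
            )

    def token(self) -> str:
        s = f"{self.c}:{self.d}"
        if self.hca == "O-alkenyl":
            s += "p"
        if self.h:
            s += f";{self.h}"
        if self.positions:
            s += "(" + ",".join(str(p) for p in self.positions) + ")"
        if self.label:
            s += f"({self.label.render()})"
        return s


@dataclass(frozen=True)
class LipidName:
    """Parsed shorthand name at any annotation level."""

    cls: str
    level: str
    chains: tuple[ChainSpec, ...] = ()
    totals: tuple[int, int, int] | None = None  # (C, DB, OH) at species level
    class_label: IsotopeLabelSpec | None = None
    molecule_label: IsotopeLabelSpec | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise NameParseError(f"unknown annotation level: {self.level!r}")
        if self.level == "species":
            if self.chains or self.totals is None:
                raise NameParseError("species-level names carry totals, not chains")
        elif not self.chains:
            raise NameParseError(f"{self.level}-level names require chains")

    @property
    def total_c(self) -> int:
        return self.totals[0] if self.totals else sum(ch.c for ch in self.chains)

    @property
    def total_d(self) -> int:
        return self.totals[1] if self.totals else sum(ch.d for ch in self.chains)

    @property
    def total_h(self) -> int:
        return self.totals[2] if self.totals else sum(ch.h for ch in self.chains)

    def __str__(self) -> str:
        return serialize_name(self)


_CHAIN_RE = re.compile(r"^(?P<c>\d+):(?P<d>\d+)(?P<p1>p?)(?:;(?P<h>\d+))?(?P<p2>p?)")


def _split_paren_groups(text: str) -> tuple[list[str], str]:
    """Leading ``(...)`` groups of ``text`` -> (group contents, rest)."""
    groups = []
    while text.startswith("("):
        depth = 0
        for i, ch in enumerate(text):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth == 0:
                    groups.append(text[1:i])
                    text = text[i + 1:]
                    break
        else:
            raise NameParseError(f"unbalanced parentheses in {text!r}")
    return groups, text


def _parse_chain_token(tok: str, slot_hca: str) -> ChainSpec:
    tok = tok.strip()
    m = _CHAIN_RE.match(tok)
    if not m:
        raise NameParseError(f"malformed C:DB token: {tok!r}")
    c, d = int(m.group("c")), int(m.group("d"))
    h = int(m.group("h") or 0)
    alkenyl = bool(m.group("p1") or m.group("p2"))
    groups, rest = _split_paren_groups(tok[m.end():])
    if rest:
        raise NameParseError(f"trailing characters in chain token: {rest!r}")
    positions: tuple[int, ...] | None = None
    label: IsotopeLabelSpec | None = None
    for g in groups:
        if g.startswith("+"):
            label = IsotopeLabelSpec.parse(g)
        else:
            try:
                positions = tuple(int(p) for p in g.split(","))
            except ValueError:
                raise NameParseError(f"malformed chain annotation: ({g})") from None
    if slot_hca == "ether":
        hca = "O-alkenyl" if alkenyl else "O-alkyl"
    else:
        hca = slot_hca
        if alkenyl:
            raise NameParseError("'p' (plasmenyl) marker is only valid on ether chains")
    return ChainSpec(hca=hca, c=c, d=d, h=h, positions=positions, label=label)


def parse_name(text: str, registry: Registry | None = None) -> LipidName:
    """Parse an intact-lipid shorthand name; infers the annotation level."""
    registry = registry or default_registry()
    text = text.strip()
    if not text:
        raise NameParseError("empty lipid name")
    for dash in _DASHES[1:]:
        text = text.replace(dash, "-")
    matched = registry.match_prefix(text)
    if matched is None:
        raise NameParseError(f"unknown lipid class in {text!r}")
    template, rest = matched
    class_label = None
    if rest.startswith("("):
        # a label group directly after the class symbol marks the head group
        groups, rest = _split_paren_groups(rest)
        if len(groups) != 1 or not groups[0].startswith("+"):
            raise NameParseError(f"malformed class label in {text!r}")
        class_label = IsotopeLabelSpec.parse(groups[0])
    rest = rest.strip()
    if not rest:
        raise NameParseError(f"missing chain information in {text!r}")

    sn = "/" in rest
    tokens = _tokenize_chains(rest)
    if sn and any("-" in t for t in tokens):
        raise NameParseError("cannot mix '/' and '-' separators")

    if len(tokens) == 1 and template.n_slots > 1:
        # species level: totals only
        ch = _parse_chain_token(tokens[0], "FA")
        return LipidName(
            cls=template.symbol,
            level="species",
            totals=(ch.c, ch.d, ch.h),
            class_label=class_label,
            molecule_label=ch.label,
        )
    if len(tokens) != template.n_slots:
        raise NameParseError(
            f"{template.symbol} takes {template.n_slots} chain(s), got {len(tokens)}"
        )
    chains = tuple(
        _parse_chain_token(tok, slot.hca)
        for tok, slot in zip(tokens, template.slots)
    )
    if template.sn_only and len(tokens) > 1:
        sn = True
    level = "sn_defined" if sn else "molecular"
    if any(ch.positions for ch in chains):
        level = "db_defined"
    return LipidName(
        cls=template.symbol, level=level, chains=chains, class_label=class_label
    )


def _tokenize_chains(text: str) -> list[str]:
    """Split on top-level '-' and '/' (never inside parentheses)."""
    tokens, depth, start = [], 0, 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch in ("-", "/") and depth == 0:
            tokens.append(text[start:i])
            start = i + 1
    tokens.append(text[start:])
    if any(not t for t in tokens):
        raise NameParseError(f"empty chain token in {text!r}")
    return tokens


def _chains_canonical(n: LipidName, template: LipidClassTemplate) -> tuple[ChainSpec, ...]:
    """Chains in canonical order: sorted by (C, DB, OH) when slots are
    interchangeable and the order is not sn-assigned."""
    if n.level in ("sn_defined",):
        return n.chains
    hcas = {s.hca for s in template.slots}
    if len(hcas) > 1:
        return n.chains  # heterogeneous slots: order fixed by slot
    return tuple(sorted(n.chains, key=lambda ch: (ch.c, ch.d, ch.h)))


def serialize_name(n: LipidName, registry: Registry | None = None) -> str:
    """Canonical shorthand string for a parsed name."""
    registry = registry or default_registry()
    template = registry.get(n.cls)
    head = n.cls
    if n.class_label:
        head += f"({n.class_label.render()})"
    if n.level == "species":
        c, d, h = n.totals
        tok = f"{c}:{d}" + (f";{h}" if h else "")
        if n.molecule_label:
            tok += f"({n.molecule_label.render()})"
        sep = "" if head.endswith("-") else " "
        return f"{head}{sep}{tok}"
    sep_chain = "/" if (n.level == "sn_defined" or template.sn_only and template.n_slots > 1) else "-"
    chains = _chains_canonical(n, template)
    body = sep_chain.join(ch.token() for ch in chains)
    sep = "" if head.endswith("-") else " "
    return f"{head}{sep}{body}"


def species_of(n: LipidName, registry: Registry | None = None) -> LipidName:
    """Collapse a molecular/sn-level name to the species level.

    Totals are element-wise sums over chains; chain labels and the head-group
    label merge into the species-level molecule label (heavy-nuclide counts
    are conserved).  Idempotent on species-level input.
    """
    if n.level == "species":
        return n
    label: IsotopeLabelSpec | None = None
    for part in (n.class_label, *(ch.label for ch in n.chains)):
        if part:
            label = part.merge(label) if label else part
    return LipidName(
        cls=n.cls,
        level="species",
        totals=(n.total_c, n.total_d, n.total_h),
        molecule_label=label,
    )
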