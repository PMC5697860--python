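"""Matching theoretical fragment reactions against observed peak lists.

Peak lists come in as two-column TSV or MGF (``TITLE``/``PEPMASS``/``CHARGE``
honored); each peak is matched to the nearest theoretical fragment within a
ppm or Da tolerance, one annotation per peak per candidate.  The matched
evidence then determines the identification level of the precursor:

* ``db_defined`` — at least one DBF matched;
* ``molecular`` — every chain slot is evidenced by at least one matched MLF;
* ``species`` — at least one LCF or iMLF matched;
* ``none`` — otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .engine import FragmentationReaction, enumerate_fragments
from .grammar import LipidName, parse_name, serialize_name, species_of
from .nomenclature import FragmentAnnotation, annotate_reaction, render_dual
from .registry import Registry, default_registry
from .structures import Precursor, precursor_ion

__all__ = [
    "AnnotationResult",
    "MatchedPeak",
    "Peak",
    "Tolerance",
    "annotate_spectrum",
    "identification_level",
    "read_mgf",
    "read_peaks_tsv",
    "write_peaks_tsv",
]


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass(frozen=True)
class Tolerance:
    """Match tolerance: ``Tolerance(5, "ppm")`` or ``Tolerance(0.3, "da")``."""

    value: float
    unit: str = "ppm"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("tolerance must be positive")
        if self.unit not in ("ppm", "da"):
            raise ValueError("tolerance unit must be 'ppm' or 'da'")

    def matches(self, observed: float, theoretical: float) -> bool:
        if self.unit == "ppm":
            return abs(observed - theoretical) / theoretical * 1e6 <= self.value
        return abs(observed - theoretical) <= self.value


@dataclass(frozen=True)
class MatchedPeak:
    observed_mz: float
    theoretical_mz: float
    ppm: float
    intensity: float
    name: str          # prioritized shorthand
    dual_name: str     # "PRIORITIZED | other"
    fragment_type: str
    ms_level: int
    annotation: FragmentAnnotation


@dataclass
class AnnotationResult:
    """Annotated spectrum for one candidate precursor."""

    precursor: Precursor
    matches: list[MatchedPeak]
    unmatched: list[Peak]
    tolerance: Tolerance
    identification_level: str = "none"
    identified_name: str = ""
    chain_evidence: dict[int, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cols = ["observed_mz", "theoretical_mz", "ppm", "name", "dual_name",
                "fragment_type", "ms_level"]
        rows = [
            (m.observed_mz, m.theoretical_mz, m.ppm, m.name, m.dual_name,
             m.fragment_type, m.ms_level)
            for m in self.matches
        ]
        return pd.DataFrame(rows, columns=cols)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")

    def report(self) -> str:
        lines = [
            f"precursor: {self.precursor.display}  m/z {self.precursor.mz:.4f}",
            f"tolerance: {self.tolerance.value} {self.tolerance.unit}",
            f"matched {len(self.matches)} peak(s), {len(self.unmatched)} unmatched",
        ]
        for m in sorted(self.matches, key=lambda m: m.observed_mz):
            lines.append(
                f"  m/z {m.observed_mz:>10.4f} -> {m.dual_name}   "
                f"({m.ppm:+.1f} ppm, {m.fragment_type})"
            )
        lines.append(
            f"identification level: {self.identification_level}"
            + (f"  ({self.identified_name})" if self.identified_name else "")
        )
        return "\n".join(lines)


def _theoretical(
    precursor: Precursor, rules, ms_level: int
) -> list[tuple[float, FragmentationReaction, FragmentAnnotation]]:
    out = []
    for rxn in enumerate_fragments(precursor, rules, ms_level=ms_level):
        ann = annotate_reaction(rxn)
        out.append((rxn.mz, rxn, ann))
    out.sort(key=lambda t: t[0])
    return out


def annotate_spectrum(
    peaks: list[Peak],
    candidates,
    tolerance: Tolerance | float = Tolerance(5.0, "ppm"),
    ms_level: int = 2,
    rules=None,
    registry: Registry | None = None,
    reactions: list[FragmentationReaction] | None = None,
) -> list[AnnotationResult]:
    """Annotate a peak list against one or more candidate precursors.

    ``candidates``: iterable of ``(lipid name, adduct symbol)`` pairs or
    :class:`Precursor` objects.  One result per candidate; peaks may annotate
    several isomeric candidates (no arbitration between candidates).  Pass
    pre-computed ``reactions`` (e.g. from :func:`~liponom.engine.enumerate_ms3`)
    to annotate MS3 spectra; they must all share one precursor.
    """
    if isinstance(tolerance, (int, float)):
        tolerance = Tolerance(float(tolerance), "ppm")
    registry = registry or default_registry()
    precursors: list[Precursor] = []
    theo_sets = []
    if reactions is not None:
        if not candidates:
            raise ValueError("empty candidate set")
        precursors = list(candidates)
        theo = [(r.mz, r, annotate_reaction(r)) for r in reactions]
        theo.sort(key=lambda t: t[0])
        theo_sets = [theo] * len(precursors)
    else:
        candidates = list(candidates)
        if not candidates:
            raise ValueError("empty candidate set")
        for cand in candidates:
            if isinstance(cand, Precursor):
                prec = cand
            else:
                name, adduct = cand
                prec = precursor_ion(name, adduct, registry)
            precursors.append(prec)
            theo_sets.append(_theoretical(prec, rules, ms_level))

    results = []
    for prec, theo in zip(precursors, theo_sets):
        matches: list[MatchedPeak] = []
        unmatched: list[Peak] = []
        for peak in peaks:
            best = None
            for theo_mz, rxn, ann in theo:
                if tolerance.matches(peak.mz, theo_mz):
                    ppm = (peak.mz - theo_mz) / theo_mz * 1e6
                    if best is None or abs(ppm) < abs(best[0]):
                        best = (ppm, theo_mz, rxn, ann)
            if best is None:
                unmatched.append(peak)
            else:
                ppm, theo_mz, rxn, ann = best
                matches.append(
                    MatchedPeak(
                        observed_mz=peak.mz,
                        theoretical_mz=theo_mz,
                        ppm=ppm,
                        intensity=peak.intensity,
                        name=ann.prioritized_name,
                        dual_name=render_dual(ann),
                        fragment_type=_best_type(ann),
                        ms_level=rxn.ms_level,
                        annotation=ann,
                    )
                )
        result = AnnotationResult(
            precursor=prec, matches=matches, unmatched=unmatched,
            tolerance=tolerance,
        )
        _assign_level(result, registry)
        results.append(result)
    return results


def _best_type(ann: FragmentAnnotation) -> str:
    from .nomenclature import TYPE_PRIORITY

    return min(ann.fragment_types, key=lambda t: TYPE_PRIORITY[t])


def _assign_level(result: AnnotationResult, registry: Registry) -> None:
    name = result.precursor.name
    evidence: dict[int, list[str]] = {}
    any_lcf_imlf = False
    any_dbf = False
    for m in result.matches:
        rxn = m.annotation.reaction
        types = m.annotation.fragment_types
        if "DBF" in types:
            any_dbf = True
        if "LCF" in types or "iMLF" in types:
            any_lcf_imlf = True
        if "MLF" in types or "DBF" in types:
            for idx in rxn.chain_indices:
                evidence.setdefault(idx, []).append(m.name)
    result.chain_evidence = evidence
    n_slots = result.precursor.template.n_slots
    chains_known = name.level != "species"
    if any_dbf and chains_known:
        result.identification_level = "db_defined"
        result.identified_name = serialize_name(name)
    elif chains_known and evidence and all(i in evidence for i in range(n_slots)):
        result.identification_level = "molecular"
        result.identified_name = serialize_name(name)
    elif any_lcf_imlf or evidence:
        result.identification_level = "species"
        result.identified_name = serialize_name(species_of(name))
    else:
        result.identification_level = "none"
        result.identified_name = ""


def identification_level(result: AnnotationResult) -> str:
    """Identification level implied by the matched fragment evidence."""
    return result.identification_level


# ---------------------------------------------------------------------------
# peak-list IO


def read_peaks_tsv(path) -> list[Peak]:
    """Two-column (m/z, intensity) TSV; a non-numeric first row is a header."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    try:
        float(df.iloc[0, 0])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    mzs = df.iloc[:, 0].astype(float)
    intens = (
        df.iloc[:, 1].astype(float) if df.shape[1] > 1 else pd.Series(0.0, index=df.index)
    )
    return [Peak(m, i) for m, i in zip(mzs, intens)]


def write_peaks_tsv(peaks: list[Peak], path) -> None:
    pd.DataFrame(
        {"mz": [p.mz for p in peaks], "intensity": [p.intensity for p in peaks]}
    ).to_csv(path, sep="\t", index=False)


def read_mgf(path) -> list[dict]:
    """MGF spectra as dicts: title, pepmass, charge, peaks (list of Peak)."""
    from pyteomics import mgf

    spectra = []
    with mgf.MGF(str(path)) as reader:
        for spec in reader:
            params = spec.get("params", {})
            pepmass = params.get("pepmass", (None,))
            charge = params.get("charge", None)
            peaks = [
                Peak(float(m), float(i))
                for m, i in zip(spec["m/z array"], spec["intensity array"])
            ]
            spectra.append(
                {
                    "title": params.get("title", ""),
                    "pepmass": pepmass[0] if pepmass else None,
                    "charge": charge[0] if charge else None,
                    "peaks": peaks,
                }
            )
    return spectra
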