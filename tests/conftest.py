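"""Shared fixtures for the liponom test suite."""

import pytest

from liponom.engine import default_rules, enumerate_fragments
from liponom.nomenclature import annotate_reaction, render_dual
from liponom.registry import default_registry
from liponom.structures import precursor_ion


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def rules():
    return default_rules()


def ppm(observed: float, expected: float) -> float:
    return abs(observed - expected) / expected * 1e6


@pytest.fixture(scope="session")
def fragment_duals():
    """lipid, adduct -> list of (m/z, 'PRIORITIZED | other') strings, cached."""
    cache: dict[tuple[str, str, int], list[tuple[float, str]]] = {}

    def run(lipid: str, adduct: str, ms_level: int = 2):
        key = (lipid, adduct, ms_level)
        if key not in cache:
            prec = precursor_ion(lipid, adduct)
            cache[key] = [
                (rxn.mz, render_dual(annotate_reaction(rxn)))
                for rxn in enumerate_fragments(prec, ms_level=ms_level)
            ]
        return cache[key]

    return run
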