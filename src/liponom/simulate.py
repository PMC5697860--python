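"""Synthetic MS2/MS3 peak lists generated from the rule engine.

Emulates FT-type instrument behavior: each theoretical fragment m/z receives
multiplicative ppm jitter (Normal(0, sigma ppm)), optionally diluted with
uniform decoy peaks that avoid windows of ±max(3*sigma, 0.5) ppm around the
theoretical positions — so at matching tolerances up to 3*sigma decoys can
never produce forced false annotations.  A fixed seed fixes the entire
output.  Not emulated: isotope envelopes, chimeric precursors, detector
noise/intensity physics, chromatography.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import Peak
from .engine import enumerate_fragments
from .nomenclature import annotate_reaction, render_dual
from .registry import Registry, default_registry
from .structures import precursor_ion

__all__ = ["SimulationConfig", "simulate_spectrum", "write_mgf"]


@dataclass(frozen=True)
class SimulationConfig:
    lipid: str
    adduct: str
    ms_level: int = 2
    jitter_ppm: float = 0.0
    n_decoys: int = 0
    decoy_range: tuple[float, float] = (100.0, 1000.0)
    intensity_model: str = "rank"  # "rank" (1/rank decay) or "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_ppm < 0:
            raise ValueError("jitter sigma must be >= 0")
        if self.n_decoys < 0:
            raise ValueError("decoy count must be >= 0")
        if self.intensity_model not in ("rank", "uniform"):
            raise ValueError("intensity model must be 'rank' or 'uniform'")


def simulate_spectrum(
    cfg: SimulationConfig,
    rules=None,
    registry: Registry | None = None,
) -> tuple[list[Peak], pd.DataFrame]:
    """(peak list, ground-truth table) for one simulated fragment spectrum.

    The ground truth has one row per theoretical fragment: ``mz_true``,
    ``mz_observed``, ``name``, ``dual_name``, ``fragment_type``; decoy peaks
    appear only in the peak list.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(cfg.seed)
    precursor = precursor_ion(cfg.lipid, cfg.adduct, registry)
    reactions = enumerate_fragments(precursor, rules, ms_level=cfg.ms_level)
    if not reactions:
        raise ValueError(f"no fragments for {precursor.display}")

    rows = []
    seen_mz: dict[float, int] = {}
    for rxn in reactions:
        ann = annotate_reaction(rxn)
        key = round(rxn.mz, 9)
        if key in seen_mz:
            continue  # one peak per distinct theoretical m/z
        seen_mz[key] = len(rows)
        rows.append(
            {
                "mz_true": rxn.mz,
                "name": ann.prioritized_name,
                "dual_name": render_dual(ann),
                "fragment_type": ann.prioritized_types[0],
            }
        )
    truth = pd.DataFrame(rows).sort_values("mz_true").reset_index(drop=True)

    eps = rng.normal(0.0, cfg.jitter_ppm * 1e-6, size=len(truth))
    truth["mz_observed"] = truth["mz_true"] * (1.0 + eps)

    n = len(truth)
    if cfg.intensity_model == "rank":
        order = rng.permutation(n)
        intensities = 1.0 / (1.0 + order)
    else:
        intensities = rng.uniform(0.5, 1.0, size=n)
    truth["intensity"] = intensities

    peaks = [
        Peak(m, i) for m, i in zip(truth["mz_observed"], truth["intensity"])
    ]

    window_ppm = max(3.0 * cfg.jitter_ppm, 0.5)
    lo, hi = cfg.decoy_range
    true_mzs = truth["mz_true"].to_numpy()
    n_placed = 0
    guard = 0
    while n_placed < cfg.n_decoys and guard < 10000 * (cfg.n_decoys + 1):
        guard += 1
        m = rng.uniform(lo, hi)
        if np.all(np.abs(m - true_mzs) / true_mzs * 1e6 > window_ppm):
            peaks.append(Peak(m, float(rng.uniform(0.01, 0.2))))
            n_placed += 1
    if n_placed < cfg.n_decoys:
        raise ValueError("decoy range too crowded for the requested decoy count")

    peaks.sort(key=lambda p: p.mz)
    cols = ["mz_true", "mz_observed", "intensity", "name", "dual_name", "fragment_type"]
    return peaks, truth[cols]


def write_mgf(peaks: list[Peak], path, title: str, pepmass: float, charge: int) -> None:
    """Write one spectrum as MGF via pyteomics."""
    from pyteomics import mgf

    spectra = [
        {
            "m/z array": np.array([p.mz for p in peaks]),
            "intensity array": np.array([p.intensity for p in peaks]),
            "params": {
                "title": title,
                "pepmass": pepmass,
                "charge": f"{abs(charge)}{'+' if charge > 0 else '-'}",
            },
        }
    ]
    mgf.write(spectra, output=str(path), file_mode="w")
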