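"""Queryable precursor/fragment tables over configurable chain enumerations.

``build_db`` enumerates molecular lipid species over chain ranges, runs the
fragmentation engine for every supported (or selected) adduct and stores one
record per precursor ion (MS1) plus one per fragment reaction (MS2), in a
single-file sqlite store with fixed-order TSV export.  Default ranges are
deliberately small; the full catalogue scope of the original online resource
depends on unpublished enumeration ranges and is not a target.
"""

from __future__ import annotations

import itertools
import sqlite3
import warnings

import pandas as pd

from .engine import enumerate_fragments
from .grammar import ChainSpec, LipidName, serialize_name, species_of
from .nomenclature import annotate_reaction, render_dual
from .registry import ADDUCTS, Registry, default_registry
from .structures import intact_composition, precursor_ion

__all__ = ["COLUMNS", "FragmentDatabase", "build_db", "enumerate_molecular_species"]

#: export column order — fixed and versioned (v1)
COLUMNS = [
    "category",
    "lipid_class",
    "species",
    "molecular_species",
    "adduct",
    "charge",
    "polarity",
    "ms_level",
    "formula",
    "fragment_name",
    "fragment_type",
    "mz",
]

_SCHEMA = f"""
CREATE TABLE records (
    {", ".join(f"{c} TEXT" if c not in ("charge", "ms_level", "mz") else f"{c} REAL" for c in COLUMNS)}
);
CREATE INDEX idx_mz ON records (mz);
"""


class FragmentDatabase:
    """Thin wrapper around a sqlite connection holding fragment records."""

    def __init__(self, path: str = ":memory:") -> None:
        self.conn = sqlite3.connect(path)
        cur = self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' AND name='records'"
        )
        if cur.fetchone() is None:
            self.conn.executescript(_SCHEMA)

    def insert(self, rows: list[tuple]) -> None:
        placeholders = ",".join("?" * len(COLUMNS))
        self.conn.executemany(
            f"INSERT INTO records ({','.join(COLUMNS)}) VALUES ({placeholders})", rows
        )
        self.conn.commit()

    def __len__(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM records").fetchone()[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.read_sql_query(
            f"SELECT {','.join(COLUMNS)} FROM records ORDER BY lipid_class, "
            "molecular_species, adduct, ms_level, mz, fragment_name",
            self.conn,
        )

    def export_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, db_path: str = ":memory:") -> "FragmentDatabase":
        db = cls(db_path)
        df = pd.read_csv(path, sep="\t")
        db.insert([tuple(row[c] for c in COLUMNS) for _, row in df.iterrows()])
        return db

    def search_mz(
        self,
        mz: float,
        tolerance: float,
        unit: str = "ppm",
        polarity: str | None = None,
        ms_level: int | None = None,
    ) -> pd.DataFrame:
        """All records within the tolerance window, optionally filtered."""
        if tolerance <= 0:
            raise ValueError("tolerance must be positive")
        delta = mz * tolerance * 1e-6 if unit == "ppm" else tolerance
        query = f"SELECT {','.join(COLUMNS)} FROM records WHERE mz BETWEEN ? AND ?"
        args: list = [mz - delta, mz + delta]
        if polarity is not None:
            query += " AND polarity = ?"
            args.append(polarity)
        if ms_level is not None:
            query += " AND ms_level = ?"
            args.append(ms_level)
        query += " ORDER BY mz, fragment_name"
        return pd.read_sql_query(query, self.conn, params=args)

    def search_name(self, pattern: str) -> pd.DataFrame:
        """Substring search over fragment and molecular-species names."""
        query = (
            f"SELECT {','.join(COLUMNS)} FROM records WHERE fragment_name LIKE ? "
            "OR molecular_species LIKE ? ORDER BY mz"
        )
        like = f"%{pattern}%"
        return pd.read_sql_query(query, self.conn, params=[like, like])


def _chain_options(slot_hca: str, carbons, double_bonds, hydroxyls) -> list[ChainSpec]:
    hca = {"ether": "O-alkyl"}.get(slot_hca, slot_hca)
    opts = []
    for c in carbons:
        for d in double_bonds:
            if d > c // 2:
                continue
            hs = hydroxyls if slot_hca == "LCB" else ((0,) if slot_hca != "FA" else hydroxyls)
            for h in hs:
                opts.append(ChainSpec(hca=hca, c=c, d=d, h=h))
    return opts


def enumerate_molecular_species(
    template,
    carbons,
    double_bonds,
    hydroxyls=(0,),
) -> list[LipidName]:
    """All distinct molecular species of a class over the chain ranges.

    Chains on interchangeable slots are combined without regard to order
    (combinations with replacement), matching shorthand-name identity.
    """
    slot_opts = [
        _chain_options(slot.hca, carbons, double_bonds, hydroxyls)
        for slot in template.slots
    ]
    homogeneous = len({slot.hca for slot in template.slots}) == 1
    names = []
    if homogeneous:
        combos = itertools.combinations_with_replacement(slot_opts[0], template.n_slots)
    else:
        combos = itertools.product(*slot_opts)
    for chains in combos:
        names.append(
            LipidName(cls=template.symbol, level="molecular", chains=tuple(chains))
        )
    return names


def build_db(
    classes: list[str],
    carbons=range(16, 23, 2),
    double_bonds=range(0, 7),
    hydroxyls=(0,),
    adducts: list[str] | None = None,
    rules=None,
    registry: Registry | None = None,
    path: str = ":memory:",
) -> FragmentDatabase:
    """Materialize precursor (MS1) and fragment (MS2) records.

    ``adducts=None`` uses every adduct registered for each class.  Record
    order is deterministic.  Raises on an empty class list.
    """
    if not classes:
        raise ValueError("empty class list")
    registry = registry or default_registry()
    db = FragmentDatabase(path)
    rows: list[tuple] = []
    for symbol in classes:
        template = registry.get(symbol)
        class_adducts = [
            a for pol in sorted(template.adducts) for a in template.adducts[pol]
        ]
        if adducts is not None:
            class_adducts = [a for a in class_adducts if a in adducts]
        for name in enumerate_molecular_species(
            template, carbons, double_bonds, hydroxyls
        ):
            sp = serialize_name(species_of(name))
            mol = serialize_name(name)
            for adduct_symbol in class_adducts:
                prec = precursor_ion(name, ADDUCTS[adduct_symbol], registry)
                formula = prec.composition.hill_formula()
                rows.append(
                    (
                        template.category, symbol, sp, mol, adduct_symbol,
                        prec.charge.z, prec.charge.polarity, 1, formula,
                        prec.display, "precursor", round(prec.mz, 6),
                    )
                )
                with warnings.catch_warnings():
                    # a class/adduct pair without MS2 rules still contributes
                    # its MS1 record; no need to warn per species here
                    warnings.simplefilter("ignore", UserWarning)
                    reactions = enumerate_fragments(prec, rules, ms_level=2)
                for rxn in reactions:
                    ann = annotate_reaction(rxn)
                    rows.append(
                        (
                            template.category, symbol, sp, mol, adduct_symbol,
                            rxn.charged.z, prec.charge.polarity, 2,
                            rxn.charged.composition.hill_formula(),
                            ann.prioritized_name, _record_type(ann),
                            round(rxn.mz, 6),
                        )
                    )
    db.insert(rows)
    return db


def _record_type(ann) -> str:
    from .nomenclature import TYPE_PRIORITY

    return min(ann.fragment_types, key=lambda t: TYPE_PRIORITY[t])
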