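"""Per-formula substructure likelihood vectors from isomer metadata.

A molecular formula rarely identifies a structure: most formulas have
many known isomers. Each isomer carries a "data sources" count — how
many curated databases report it — which serves as a popularity weight.
Normalizing those counts within a formula and summing the
weighted substructure counts yields, per formula, a likelihood-style
vector saying how many benzene rings, amines, ether groups etc. a
molecule with that formula plausibly contains. The vector is fed to the
prediction model to focus its outputs on chemically known territory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class IsomerRecord:
    """One known structure for a formula, with its popularity metadata."""

    formula: str
    structure: str  # SMILES
    data_sources: int
    fragments: dict[str, int]

    def __post_init__(self) -> None:
        if self.data_sources < 0:
            raise ValueError("data_sources must be non-negative")
        if any(v < 0 or int(v) != v for v in self.fragments.values()):
            raise ValueError("fragment counts must be non-negative integers")


@dataclass(frozen=True)
class FragmentPrior:
    """Weighted-sum substructure likelihoods for one formula."""

    formula: str
    prior: dict[str, float]

    def vector(self, catalog: Sequence[str]) -> np.ndarray:
        return np.array([self.prior.get(f, 0.0) for f in catalog], dtype=float)


def normalize_sources(
    isomers: Sequence[IsomerRecord], minmax: bool = False
) -> dict[str, float]:
    """Popularity weight in [0, 1] per structure, for one formula's isomers.

    Default scaling divides by the maximum data-sources count, so every
    reported isomer keeps a positive weight. ``minmax=True`` switches to
    min-max scaling, which zeroes out the least-referenced isomer — kept
    for exploration only. If no isomer has any data source, all weights
    fall back to 1 (uniform).
    """
    if not isomers:
        raise ValueError("need at least one isomer")
    counts = np.array([iso.data_sources for iso in isomers], dtype=float)
    hi = counts.max()
    if hi == 0:
        weights = np.ones_like(counts)
    elif minmax:
        lo = counts.min()
        weights = np.ones_like(counts) if hi == lo else (counts - lo) / (hi - lo)
    else:
        weights = counts / hi
    return {iso.structure: float(w) for iso, w in zip(isomers, weights)}


def fragment_prior(
    isomers: Sequence[IsomerRecord], minmax: bool = False
) -> FragmentPrior:
    """Sum of popularity-weighted substructure counts for one formula."""
    if not isomers:
        raise ValueError("need at least one isomer")
    formulas = {iso.formula for iso in isomers}
    if len(formulas) > 1:
        raise ValueError(f"isomers span multiple formulas: {sorted(formulas)}")
    weights = normalize_sources(isomers, minmax=minmax)
    prior: dict[str, float] = {}
    for iso in isomers:
        w = weights[iso.structure]
        for frag, count in iso.fragments.items():
            prior[frag] = prior.get(frag, 0.0) + w * count
    return FragmentPrior(formula=isomers[0].formula, prior=prior)


def priors_from_isomer_table(
    df: pd.DataFrame, minmax: bool = False
) -> dict[str, FragmentPrior]:
    """Compute a prior for every formula in an isomer table.

    Expects columns {formula, smiles, data_sources} plus ``frag_``-prefixed
    count columns — the on-disk dialect of :func:`read_isomer_table`.
    """
    frag_cols = [c for c in df.columns if c.startswith("frag_")]
    out: dict[str, FragmentPrior] = {}
    for formula, grp in df.groupby("formula", sort=True):
        isomers = [
            IsomerRecord(
                formula=formula,
                structure=row["smiles"],
                data_sources=int(row["data_sources"]),
                fragments={c[len("frag_"):]: int(row[c]) for c in frag_cols},
            )
            for _, row in grp.iterrows()
        ]
        out[formula] = fragment_prior(isomers, minmax=minmax)
    return out


def read_isomer_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"formula", "smiles", "data_sources"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"isomer table missing columns: {sorted(missing)}")
    return df


def write_priors(
    priors: Mapping[str, FragmentPrior], catalog: Sequence[str], path: str | Path
) -> None:
    rows = [
        {"formula": formula, **{f"frag_{f}": p.prior.get(f, 0.0) for f in catalog}}
        for formula, p in sorted(priors.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def count_fragments_rdkit(smiles: str, catalog: Sequence[str]) -> dict[str, int]:
    """Substructure counts for a real structure via the RDKit fragment
    descriptors (catalog names must be ``rdkit.Chem.Fragments`` function
    names, e.g. ``fr_benzene``). Optional backend: requires rdkit."""
    from rdkit import Chem
    from rdkit.Chem import Fragments

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    out = {}
    for name in catalog:
        fn = getattr(Fragments, name, None)
        if fn is None:
            raise ValueError(f"unknown RDKit fragment descriptor: {name}")
        out[name] = int(fn(mol))
    return out
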