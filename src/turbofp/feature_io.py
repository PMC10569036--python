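"""Reading aligned LC-MS feature tables and reference databases.

A feature table is an MS-DIAL-style alignment export: one row per aligned
feature (id, m/z, retention time) and one column of peak areas per sample.
A companion manifest assigns every sample column a role — ``partition``
(aqueous phase after equilibration), ``water_control`` (spiked water, the
total-analyte reference) or ``blank`` — plus the solvent, replicate and
injection indices.

The reference database holds candidate compounds: identifier, molecular
formula, monoisotopic mass, SMILES, theoretical log K_SW per solvent
(columns prefixed ``logK_``) and substructure counts (columns prefixed
``frag_``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ADDUCT_OFFSET, ELEMENT_ALPHABET, log

ROLES = ("partition", "water_control", "blank")

MANIFEST_COLUMNS = ("sample_id", "role", "solvent", "replicate", "injection")
FEATURE_META_COLUMNS = ("feature_id", "mz", "rt")


class FormatError(ValueError):
    """A required column or field is missing or unparseable."""


@dataclass
class FeatureTable:
    """Aligned features with per-sample peak areas and a sample manifest.

    ``features`` is indexed by feature_id with columns mz, rt plus one
    area column per sample_id; ``manifest`` is indexed by sample_id.
    """

    features: pd.DataFrame
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [s for s in self.sample_ids if s not in self.manifest.index]
        if missing:
            raise FormatError(f"samples missing from manifest: {missing}")
        bad_roles = set(self.manifest["role"]) - set(ROLES)
        if bad_roles:
            raise FormatError(f"unknown sample roles: {sorted(bad_roles)}")
        areas = self.features[self.sample_ids]
        if (areas.to_numpy() < 0).any():
            raise ValueError("negative peak areas in feature table")
        # at most one partition and one water_control per (solvent, replicate)
        nonblank = self.manifest[self.manifest["role"] != "blank"]
        dup = nonblank.groupby(["solvent", "replicate", "injection", "role"]).size()
        if (dup > 1).any():
            raise FormatError(
                "duplicate (solvent, replicate, injection, role) assignments: "
                f"{dup[dup > 1].index.tolist()}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [c for c in self.features.columns if c not in ("mz", "rt")]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.features.index)

    def samples(
        self,
        role: str,
        solvent: Optional[str] = None,
        replicate: Optional[int] = None,
    ) -> list[str]:
        """Sample ids with the given role, optionally filtered."""
        m = self.manifest
        mask = m["role"] == role
        if solvent is not None:
            mask &= m["solvent"] == solvent
        if replicate is not None:
            mask &= m["replicate"] == replicate
        return list(m.index[mask])

    def area(self, feature_id: str, sample_id: str) -> float:
        return float(self.features.at[feature_id, sample_id])


@dataclass
class ReferenceDB:
    """Compound database with formulas, masses, theoretical fingerprints
    and substructure-count vectors."""

    records: pd.DataFrame  # indexed by compound_id
    solvents: tuple[str, ...]
    fragments: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.records["monoisotopic_mass"] <= 0).any():
            raise ValueError("monoisotopic_mass must be positive")
        frag_cols = [f"frag_{f}" for f in self.fragments]
        frag = self.records[frag_cols].to_numpy()
        if (frag < 0).any() or not np.allclose(frag, np.round(frag)):
            raise ValueError("fragment counts must be non-negative integers")

    @property
    def compound_ids(self) -> list[str]:
        return list(self.records.index)

    def logk_matrix(self) -> pd.DataFrame:
        """Theoretical log K_SW, compounds x solvents (NaN = missing)."""
        cols = [f"logK_{s}" for s in self.solvents]
        m = self.records[cols].copy()
        m.columns = list(self.solvents)
        return m

    def fragment_matrix(self) -> pd.DataFrame:
        cols = [f"frag_{f}" for f in self.fragments]
        m = self.records[cols].copy()
        m.columns = list(self.fragments)
        return m


@dataclass(frozen=True)
class MatchResult:
    """A feature-to-compound candidate match within the ppm window."""

    feature_id: str
    compound_id: str
    ppm_error: float


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path, manifest_path: str | Path) -> FeatureTable:
    """Read a feature-table CSV and its sample manifest.

    Unknown feature-table columns not present in the manifest raise a
    format error; unknown *manifest* columns are ignored with a warning.
    """
    path, manifest_path = Path(path), Path(manifest_path)
    if not path.exists():
        raise FormatError(f"feature table not found: {path}")
    if not manifest_path.exists():
        raise FormatError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing_cols:
        raise FormatError(f"manifest missing required columns: {missing_cols}")
    extra = [c for c in manifest.columns if c not in MANIFEST_COLUMNS]
    if extra:
        log.warning("ignoring unknown manifest columns: %s", extra)
    manifest = manifest[list(MANIFEST_COLUMNS)].set_index("sample_id")
    manifest["replicate"] = manifest["replicate"].astype(int)
    manifest["injection"] = manifest["injection"].astype(int)
    manifest["solvent"] = manifest["solvent"].fillna("")

    table = pd.read_csv(path, float_precision="round_trip")
    missing_meta = [c for c in FEATURE_META_COLUMNS if c not in table.columns]
    if missing_meta:
        raise FormatError(f"feature table missing required columns: {missing_meta}")
    candidate_cols = [c for c in table.columns if c not in FEATURE_META_COLUMNS]
    # non-numeric extras (MS-DIAL annotation columns etc.) are ignored;
    # numeric columns are samples and must be covered by the manifest
    sample_cols, ignored = [], []
    for c in candidate_cols:
        if pd.to_numeric(table[c], errors="coerce").notna().all():
            sample_cols.append(c)
        else:
            ignored.append(c)
    if ignored:
        log.warning("ignoring non-sample columns: %s", ignored)
        table = table.drop(columns=ignored)
    unknown = [c for c in sample_cols if c not in manifest.index]
    if unknown:
        raise FormatError(f"manifest does not cover sample columns: {unknown}")
    table = table.set_index("feature_id")
    table[sample_cols] = table[sample_cols].astype(float)
    return FeatureTable(features=table, manifest=manifest)


def write_feature_table(
    table: FeatureTable, path: str | Path, manifest_path: str | Path
) -> None:
    """Write a feature table and manifest in the dialect read back by
    :func:`read_feature_table`."""
    out = table.features.reset_index()
    out = out[["feature_id", "mz", "rt"] + table.sample_ids]
    out.to_csv(path, index=False)
    table.manifest.reset_index()[list(MANIFEST_COLUMNS)].to_csv(
        manifest_path, index=False
    )


def read_reference_db(path: str | Path) -> ReferenceDB:
    """Read a reference-database CSV (``logK_`` / ``frag_`` column prefixes)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"reference database not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["compound_id", "formula", "monoisotopic_mass", "smiles"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"reference database missing columns: {missing}")
    solvents = tuple(c[len("logK_"):] for c in df.columns if c.startswith("logK_"))
    fragments = tuple(c[len("frag_"):] for c in df.columns if c.startswith("frag_"))
    df = df.set_index("compound_id")
    return ReferenceDB(records=df, solvents=solvents, fragments=fragments)


def write_reference_db(db: ReferenceDB, path: str | Path) -> None:
    db.records.reset_index().to_csv(path, index=False)


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula string ('C6H4Cl2') to element counts."""
    import re

    counts: dict[str, int] = {}
    pos = 0
    for m in re.finditer(r"([A-Z][a-z]?)(\d*)", formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise FormatError(f"cannot parse formula {formula!r}")
        pos = m.end()
        el, n = m.group(1), int(m.group(2) or 1)
        if el not in ELEMENT_ALPHABET:
            raise FormatError(f"element {el!r} outside the supported alphabet")
        counts[el] = counts.get(el, 0) + n
    if pos != len(formula):
        raise FormatError(f"cannot parse formula {formula!r}")
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    return "".join(
        f"{el}{counts[el]}" for el in ELEMENT_ALPHABET if counts.get(el, 0) > 0
    )


# ---------------------------------------------------------------------------
# matching and blank filtering
# ---------------------------------------------------------------------------

def match_features(
    table: FeatureTable,
    db: ReferenceDB,
    ppm_tol: float,
    ionization: str = "positive",
) -> list[MatchResult]:
    """Match features to candidate compounds by neutral monoisotopic mass.

    Observed m/z is first corrected for the configured adduct (a proton
    for [M+H]+ / [M-H]-), then compared with each candidate's theoretical
    monoisotopic mass; the ppm denominator is the theoretical mass. All
    candidates within ``ppm_tol`` are returned — ambiguity is resolved
    downstream, not here.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    if ionization not in ADDUCT_OFFSET:
        raise ValueError(f"unknown ionization mode {ionization!r}")
    if len(db.records) == 0:
        log.warning("empty reference database; no matches possible")
        return []
    offset = ADDUCT_OFFSET[ionization]
    neutral = table.features["mz"].to_numpy(dtype=float) + offset
    theo = db.records["monoisotopic_mass"].to_numpy(dtype=float)
    ppm = 1e6 * (neutral[:, None] - theo[None, :]) / theo[None, :]
    fid = np.asarray(table.feature_ids)
    cid = np.asarray(db.compound_ids)
    # inclusive boundary, guarded against float rounding at exactly tol
    hits = np.argwhere(np.abs(ppm) <= ppm_tol + 1e-9)
    return [
        MatchResult(feature_id=fid[i], compound_id=cid[j], ppm_error=float(ppm[i, j]))
        for i, j in hits
    ]


def blank_filter(table: FeatureTable, ratio: float = 1.3) -> set[str]:
    """Feature ids whose signal clears the blank by the given ratio.

    The reference signal is each replicate's water-control area; a feature
    is retained if, in any replicate, that area is at least ``ratio`` times
    the mean blank area (inclusive). Features with zero mean blank area are
    always retained — the rule is division-free.
    """
    if ratio < 1:
        raise ValueError("blank ratio must be >= 1")
    blanks = table.samples("blank")
    if not blanks:
        raise ValueError("no blank samples in manifest; cannot blank-filter")
    controls = table.samples("water_control")
    mean_blank = table.features[blanks].mean(axis=1)
    ref = table.features[controls].max(axis=1) if controls else 0.0
    keep = ref >= ratio * mean_blank
    return set(table.features.index[keep])
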