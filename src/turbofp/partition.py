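"""Computing log K_SW (operationally log D_SW) from peak areas.

The shake-flask design measures only the aqueous phase: the partition
sample gives the analyte's post-equilibration water area A_W, and the
spiked water control gives the total-analyte area A_T. The solvent-phase
area is the difference A_S = A_T - A_W, and the partition ratio follows
as

    K_SW = (A_S / A_W) * (V_W / V_S)

where V_W/V_S corrects for the phase-volume ratio of the replicate
(1:1, 2:1 and 0.5:1 solvent:water across the three replicates). The
relative response factor cancels because both areas are measured for the
same analyte in the same aqueous matrix. For ionizable compounds the
quantity actually measured is the distribution ratio D_SW; the
standardization step downstream makes the two interchangeable.

Missingness is a value, not an error: A_S <= 0 (analyte fully in water,
or noise exceeding the true difference) marks the solvent missing and
routes the compound to read-across imputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_SOLVENTS, DEFAULT_VOLUMES, log
from .feature_io import FeatureTable, MatchResult

#: Sentinel for a missing (non-computable) partition value.
MISSING = float("nan")


def is_missing(x: float) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class PartitionMeasurement:
    """One replicate's raw observables for one compound and solvent."""

    compound_id: str
    solvent: str
    replicate: int
    a_w: float  # water area after equilibration
    a_t: float  # total area (water control)
    v_w: float = 1.0  # mL
    v_s: float = 1.0  # mL

    def __post_init__(self) -> None:
        if self.a_w < 0 or self.a_t < 0:
            raise ValueError("peak areas must be non-negative")
        if self.v_w <= 0 or self.v_s <= 0:
            raise ValueError("phase volumes must be positive")


@dataclass
class Fingerprint:
    """Per-compound vector of log10 partition ratios over the solvent panel.

    ``values`` holds the observed (or imputed) solvents; ``missing`` the
    rest; together they cover the declared panel exactly.
    """

    compound_id: str
    values: dict[str, float]
    missing: set[str] = field(default_factory=set)
    standardized: bool = False
    imputed: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = set(self.values) & self.missing
        if overlap:
            raise ValueError(f"solvents both observed and missing: {sorted(overlap)}")

    @property
    def panel(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.values) | self.missing))

    def observed_solvents(self) -> list[str]:
        return sorted(self.values)

    def vector(self, panel: Sequence[str]) -> np.ndarray:
        """Panel-ordered value vector with NaN at missing entries."""
        return np.array([self.values.get(s, MISSING) for s in panel], dtype=float)


def solvent_area(a_t: float, a_w: float) -> float:
    """Solvent-phase area A_S = A_T - A_W; missing when the difference
    is not positive."""
    if a_t < 0 or a_w < 0:
        raise ValueError("peak areas must be non-negative")
    a_s = a_t - a_w
    return a_s if a_s > 0 else MISSING


def log_ksw(m: PartitionMeasurement, volume_correction: bool = True) -> float:
    """log10 K_SW for one replicate measurement, or missing.

    ``volume_correction=False`` reproduces the uncorrected area-ratio
    form (volumes assumed equal), for strict comparison with workflows
    that skip the phase-ratio term.
    """
    a_s = solvent_area(m.a_t, m.a_w)
    if is_missing(a_s) or m.a_w <= 0:
        return MISSING
    ratio = a_s / m.a_w
    if volume_correction:
        ratio *= m.v_w / m.v_s
    return math.log10(ratio)


def aggregate(log_values: Iterable[float]) -> tuple[float, int, float]:
    """Mean of non-missing per-replicate log values.

    Returns (mean, n_used, sd); mean is missing iff every replicate is.
    Averaging happens in log space so that replicates with different
    phase-volume ratios contribute comparably.
    """
    vals = [v for v in log_values if not is_missing(v)]
    if not vals:
        return MISSING, 0, MISSING
    arr = np.asarray(vals, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), len(arr), sd


def _injection_mean(table: FeatureTable, feature_id: str, sample_ids: Sequence[str]) -> float:
    """Mean area over injection duplicates (area space)."""
    if not sample_ids:
        return MISSING
    return float(np.mean([table.area(feature_id, s) for s in sample_ids]))


def build_fingerprints(
    table: FeatureTable,
    matches: Sequence[MatchResult],
    solvents: Sequence[str] = DEFAULT_SOLVENTS,
    volumes: Mapping[int, tuple[float, float]] = DEFAULT_VOLUMES,
    volume_correction: bool = True,
    blank_ratio: Optional[float] = None,
) -> tuple[list[Fingerprint], pd.DataFrame]:
    """Assemble panel-complete fingerprints for every matched compound.

    Injection duplicates are averaged in area space before the log;
    replicates are averaged in log space. A water area below the blank
    threshold (``blank_ratio`` x mean blank area, when a ratio is given)
    counts as undetected and the solvent is marked missing rather than
    treated as a tiny denominator.

    Returns the fingerprints plus a long-format summary table
    {compound_id, solvent, log_ksw, n_replicates, sd, imputed_flag}.
    """
    # compound -> feature, resolving ambiguity by the largest total area
    by_compound: dict[str, list[str]] = {}
    for m in matches:
        by_compound.setdefault(m.compound_id, []).append(m.feature_id)

    blank_samples = table.samples("blank") if blank_ratio is not None else []

    replicates = sorted(set(table.manifest["replicate"]))
    fingerprints: list[Fingerprint] = []
    rows: list[dict] = []
    for compound_id, feature_ids in sorted(by_compound.items()):
        if len(set(feature_ids)) > 1:
            totals = {
                f: float(table.features.loc[f, table.sample_ids].sum())
                for f in set(feature_ids)
            }
            feature_id = max(totals, key=totals.get)
            log.warning(
                "compound %s matched %d features; using highest-area %s",
                compound_id, len(totals), feature_id,
            )
        else:
            feature_id = feature_ids[0]

        blank_threshold = 0.0
        if blank_samples and blank_ratio is not None:
            blank_mean = float(
                np.mean([table.area(feature_id, b) for b in blank_samples])
            )
            blank_threshold = blank_ratio * blank_mean

        values: dict[str, float] = {}
        missing: set[str] = set()
        for solvent in solvents:
            rep_logs = []
            for rep in replicates:
                part = table.samples("partition", solvent=solvent, replicate=rep)
                ctrl = table.samples("water_control", solvent=solvent, replicate=rep)
                a_w = _injection_mean(table, feature_id, part)
                a_t = _injection_mean(table, feature_id, ctrl)
                if is_missing(a_w) or is_missing(a_t):
                    continue
                if a_w < blank_threshold or a_t < blank_threshold:
                    rep_logs.append(MISSING)  # undetected, not zero
                    continue
                v_w, v_s = volumes.get(rep, (1.0, 1.0))
                rep_logs.append(
                    log_ksw(
                        PartitionMeasurement(
                            compound_id, solvent, rep, a_w=a_w, a_t=a_t,
                            v_w=v_w, v_s=v_s,
                        ),
                        volume_correction=volume_correction,
                    )
                )
            mean, n_used, sd = aggregate(rep_logs)
            if is_missing(mean):
                missing.add(solvent)
            else:
                values[solvent] = mean
            rows.append(
                {
                    "compound_id": compound_id,
                    "solvent": solvent,
                    "log_ksw": mean,
                    "n_replicates": n_used,
                    "sd": sd,
                    "imputed_flag": False,
                }
            )
        fingerprints.append(
            Fingerprint(compound_id=compound_id, values=values, missing=missing)
        )
    summary = pd.DataFrame(
        rows,
        columns=[
            "compound_id", "solvent", "log_ksw", "n_replicates", "sd", "imputed_flag",
        ],
    )
    return fingerprints, summary


# ---------------------------------------------------------------------------
# fingerprint CSV round-trip (long format)
# ---------------------------------------------------------------------------

def write_fingerprints(
    fps: Sequence[Fingerprint], path: str | Path, solvents: Sequence[str] = DEFAULT_SOLVENTS
) -> None:
    rows = []
    for fp in fps:
        for s in solvents:
            rows.append(
                {
                    "compound_id": fp.compound_id,
                    "solvent": s,
                    "log_ksw": fp.values.get(s, MISSING),
                    "imputed_flag": s in fp.imputed,
                    "standardized": fp.standardized,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fingerprints(path: str | Path) -> list[Fingerprint]:
    df = pd.read_csv(path, float_precision="round_trip")
    fps = []
    for cid, grp in df.groupby("compound_id", sort=True):
        values, missing, imputed = {}, set(), set()
        for _, r in grp.iterrows():
            if math.isnan(r["log_ksw"]):
                missing.add(r["solvent"])
            else:
                values[r["solvent"]] = float(r["log_ksw"])
                if bool(r.get("imputed_flag", False)):
                    imputed.add(r["solvent"])
        fps.append(
            Fingerprint(
                compound_id=cid,
                values=values,
                missing=missing,
                standardized=bool(grp["standardized"].iloc[0]),
                imputed=imputed,
            )
        )
    return fps
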