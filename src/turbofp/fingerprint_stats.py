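"""Standardization and comparison of physicochemical fingerprints.

For an ionizable compound the measured quantity is the distribution
ratio D_SW = K_SW * f_u, where f_u is the un-ionized aqueous fraction at
the working pH. Since f_u is a property of the aqueous phase only, the
offset log10(f_u) is the same for every solvent: the *differences*
between solvents are pH-invariant even though the absolute values are
not. Z-scoring each compound's fingerprint across the solvent axis
(remove the mean, scale to unit variance) therefore maps log D and log K
onto the same vector, which is what lets a model trained on theoretical
K_SW values consume experimental D_SW measurements.

The same algebra fixes the comparison statistics: an additive ionization
offset inflates the raw MAE and shifts the OLS intercept, while on
standardized vectors the intercept is exactly 0 and the slope equals the
Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .partition import Fingerprint


@dataclass(frozen=True)
class FingerprintComparison:
    """OLS comparison of an observed vs a theoretical fingerprint."""

    compound_id: str
    r2: float
    mae: float
    slope: float
    intercept: float
    n: int
    standardized: bool = False


def standardize(fp: Fingerprint) -> Fingerprint:
    """Z-score a fingerprint across its solvent axis (population variance).

    Missing entries are preserved in the mask and excluded from the
    moments. The operation is idempotent: a zero-mean unit-variance
    vector z-scores to itself.
    """
    solvents = list(fp.values)
    vals = np.array([fp.values[s] for s in solvents], dtype=float)
    if len(vals) < 2:
        raise ValueError(
            f"compound {fp.compound_id}: need >= 2 observed solvents to standardize"
        )
    sd = vals.std()  # population (n) variance
    if sd == 0:
        raise ValueError(f"compound {fp.compound_id}: zero variance across solvents")
    z = (vals - vals.mean()) / sd
    return replace(fp, values=dict(zip(solvents, z.tolist())), standardized=True)


def compare(obs: Fingerprint, theo: Fingerprint) -> FingerprintComparison:
    """Pearson-regression comparison over the common observed solvents.

    Fits OLS of the theoretical values on the observed ones and reports
    R^2 (squared Pearson r), the mean absolute difference, slope and
    intercept. Solvents missing in either fingerprint are excluded
    pairwise; fewer than 3 common solvents leaves the comparison
    undefined.
    """
    common = sorted(set(obs.values) & set(theo.values))
    if len(common) < 3:
        raise ValueError(
            f"compound {obs.compound_id}: only {len(common)} common solvents; "
            "comparison undefined"
        )
    x = np.array([obs.values[s] for s in common])
    y = np.array([theo.values[s] for s in common])
    fit = stats.linregress(x, y)
    return FingerprintComparison(
        compound_id=obs.compound_id,
        r2=float(fit.rvalue**2),
        mae=float(np.mean(np.abs(x - y))),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(common),
        standardized=obs.standardized and theo.standardized,
    )


def cross_platform_select(
    comparisons: Sequence[FingerprintComparison], threshold: float = 0.8
) -> set[str]:
    """Compounds whose two-platform fingerprints agree at R^2 >= threshold
    (inclusive)."""
    return {c.compound_id for c in comparisons if c.r2 >= threshold}


def infer_distribution_ratio(
    logk_target: float, logk_anchor: float, logd_anchor: float
) -> float:
    """Distribution ratio of a target system from an anchor system.

    The ionization offset log D - log K is solvent-independent, so
    log D_target = log K_target + (log D_anchor - log K_anchor) at the
    anchor's pH. E.g. knowing K_OW, K_OC and D_OW at pH 5 yields D_OC at
    pH 5 without a new measurement.
    """
    for v in (logk_target, logk_anchor, logd_anchor):
        if not math.isfinite(v):
            raise ValueError("all inputs must be finite")
    return logk_target + (logd_anchor - logk_anchor)
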