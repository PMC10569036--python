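"""Read-across imputation of missing fingerprint entries.

A missing log K_SW for one solvent is inferred from the compound's values
in three other solvents via a multilinear regression

    K_target = a*K_1 + b*K_2 + d*K_3 + c

fitted by ordinary least squares on the complete-case rows of a large
reference database. The predictor triplet is drawn at random from the
compound's observed solvents; the fit-and-predict step is repeated
(100 iterations by default) with fresh triplets, and the imputed value is
the mean of the predictions. Because solvent-water partitioning is
governed by a small number of solute descriptors, essentially any three
solvents carry enough information to pin down a fourth — which is what
makes the randomized-triplet average stable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import log
from .feature_io import ReferenceDB
from .partition import Fingerprint


class RankDeficientFit(ValueError):
    """The triplet design matrix does not have full column rank."""


@dataclass(frozen=True)
class ReadAcrossModel:
    """One fitted target-from-three-solvents regression."""

    target_solvent: str
    predictor_solvents: tuple[str, str, str]
    coefficients: tuple[float, float, float]  # a, b, d
    constant: float  # c, log10 units
    n_train: int

    def predict(self, values: dict[str, float]) -> float:
        x = np.array([values[s] for s in self.predictor_solvents])
        return float(np.dot(self.coefficients, x) + self.constant)


def fit_readacross(
    db: ReferenceDB | pd.DataFrame,
    target: str,
    predictors: Sequence[str],
) -> ReadAcrossModel:
    """OLS fit of the target solvent's log K on three predictor solvents.

    ``db`` may be a ReferenceDB or its compounds-by-solvents log-K matrix.
    Only complete-case rows (all four solvents present) are used; at
    least four are required for the 4-parameter fit.
    """
    predictors = tuple(predictors)
    if len(predictors) != 3 or len(set(predictors)) != 3 or target in predictors:
        raise ValueError("predictors must be 3 distinct solvents != target")
    matrix = db.logk_matrix() if isinstance(db, ReferenceDB) else db
    cols = [target, *predictors]
    complete = matrix[cols].dropna()
    n = len(complete)
    if n < 4:
        raise ValueError(
            f"need >= 4 complete-case compounds for {target} ~ {predictors}, got {n}"
        )
    x = np.column_stack([complete[list(predictors)].to_numpy(), np.ones(n)])
    y = complete[target].to_numpy()
    if np.linalg.matrix_rank(x) < 4:
        raise RankDeficientFit(f"collinear predictors {predictors} for {target}")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return ReadAcrossModel(
        target_solvent=target,
        predictor_solvents=predictors,
        coefficients=(float(beta[0]), float(beta[1]), float(beta[2])),
        constant=float(beta[3]),
        n_train=n,
    )


def impute(
    fp: Fingerprint,
    db: ReferenceDB | pd.DataFrame,
    n_iter: int = 100,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Fingerprint:
    """Fill every missing solvent of a fingerprint by randomized read-across.

    For each missing solvent, ``n_iter`` predictor triplets are sampled
    uniformly without replacement (within an iteration) from the
    compound's observed solvents; each triplet is fitted on the database
    and used to predict from the compound's own values, and the imputed
    value is the mean prediction. Rank-deficient triplet fits are
    discarded and resampled, up to 10x ``n_iter`` attempts. The
    per-solvent prediction SD is logged informationally.

    Fingerprints with no missing entries are returned unchanged.
    Compounds with fewer than 3 observed solvents cannot be imputed: the
    downstream model requires the full panel, so they are rejected with
    a logged reason.
    """
    if not fp.missing:
        return fp
    observed = fp.observed_solvents()
    if len(observed) < 3:
        raise ValueError(
            f"compound {fp.compound_id}: only {len(observed)} observed solvents; "
            "read-across needs >= 3, compound excluded from model input"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    matrix = db.logk_matrix() if isinstance(db, ReferenceDB) else db

    cache: dict[tuple[str, tuple[str, ...]], ReadAcrossModel] = {}
    new_values = dict(fp.values)
    imputed = set(fp.imputed)
    for target in sorted(fp.missing):
        preds = []
        attempts = 0
        while len(preds) < n_iter:
            if attempts >= 10 * n_iter:
                raise RankDeficientFit(
                    f"could not find {n_iter} full-rank triplet fits for "
                    f"{fp.compound_id}/{target} in {attempts} attempts"
                )
            attempts += 1
            triplet = tuple(rng.choice(observed, size=3, replace=False))
            key = (target, triplet)
            try:
                model = cache.get(key)
                if model is None:
                    model = fit_readacross(matrix, target, triplet)
                    cache[key] = model
            except RankDeficientFit:
                continue
            preds.append(model.predict(fp.values))
        arr = np.asarray(preds)
        new_values[target] = float(arr.mean())
        imputed.add(target)
        log.debug(
            "imputed %s/%s = %.4f (sd %.4f over %d iterations)",
            fp.compound_id, target, arr.mean(), arr.std(), n_iter,
        )
    return replace(fp, values=new_values, missing=set(), imputed=imputed)


def impute_all(
    fps: Sequence[Fingerprint],
    db: ReferenceDB | pd.DataFrame,
    n_iter: int = 100,
    seed: Optional[int] = None,
) -> list[Fingerprint]:
    """Impute a collection of fingerprints with one seeded stream;
    compounds with too few observed solvents are dropped with a warning."""
    rng = np.random.default_rng(seed)
    out = []
    for fp in fps:
        try:
            out.append(impute(fp, db, n_iter=n_iter, rng=rng))
        except ValueError as e:
            log.warning("%s", e)
    return out
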