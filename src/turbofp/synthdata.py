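"""Synthetic partition panels with known ground truth.

The generator emulates the full measurement chain so every pipeline
stage can be tested offline against exact truth:

* compounds with small-integer substructure counts, valid formulas over
  the element alphabet and deterministic monoisotopic masses;
* true log K_SW built LSER-style — three latent solute descriptors per
  compound (a linear function of its substructure counts plus noise),
  mapped to each solvent by solvent-specific loadings and an intercept.
  The rank-3 structure means any three generic solvents determine a
  fourth exactly, which is precisely the assumption behind read-across
  imputation;
* ionizable compounds with an un-ionized fraction f_u, so the measured
  distribution ratio is log D = log K + log10(f_u), an additive
  per-compound offset identical across solvents;
* a rendered feature table: water-control and partition areas from the
  two-phase mass balance at the replicate's volume ratio, a per-compound
  relative response factor (which must cancel in the area ratio),
  lognormal area noise, an optional sigmoid saturation response
  emulating a narrow intrascan dynamic range, a blank-signal floor,
  detection dropout, replicates and injection duplicates.

What it does not emulate: chromatography (retention times are
decorative), isotope patterns, co-eluting interferences, and real
LSER chemistry — the latent maps are random, not fitted descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .config import (
    DEFAULT_SOLVENTS,
    DEFAULT_VOLUMES,
    ELEMENT_ALPHABET,
    PROTON_MASS,
    formula_mass,
)
from .feature_io import FeatureTable, ReferenceDB, format_formula

#: Default substructure catalog for simulated compounds.
DEFAULT_FRAGMENTS: tuple[str, ...] = (
    "benzene", "halogen", "amine", "amide", "ether", "ester",
    "alcohol", "ketone", "carboxyl", "nitro", "aromatic_n", "bicyclic",
)


class SimConfig(BaseModel):
    """Study-design knobs for one simulated panel.

    Defaults mirror the wet-lab design the package targets: a
    10-solvent panel measured in triplicate at solvent:water volume
    ratios 1:1, 2:1 and 0.5:1, duplicate injections, ~5% relative area
    noise, and roughly a third of compounds ionizable at the working pH.
    """

    n_compounds: int = Field(default=200, ge=1)
    n_solvents: int = Field(default=10, ge=4)
    n_fragments: int = Field(default=12, ge=1)
    latent_dim: int = Field(default=3, ge=3)
    max_fragment_count: int = Field(default=4, ge=1)
    latent_noise_sd: float = Field(default=0.3, ge=0)
    noise_sd_area: float = Field(default=0.05, ge=0)  # lognormal sigma (relative)
    ionized_fraction: float = Field(default=0.3, ge=0, le=1)
    f_u_range: tuple[float, float] = (0.05, 1.0)
    response: Literal["linear", "sigmoid"] = "linear"
    saturation_quantile: float = Field(default=0.6, gt=0, lt=1)
    saturation_steepness: float = Field(default=1.0, gt=0)
    dropout_prob: float = Field(default=0.0, ge=0, le=1)
    blank_level: float = Field(default=1e-3, ge=0)  # relative to nominal area
    max_isomers_per_formula: int = Field(default=4, ge=1)
    n_replicates: int = Field(default=3, ge=1)
    n_injections: int = Field(default=2, ge=1)
    nominal_area: float = 1e6
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        lo, hi = self.f_u_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("f_u_range must satisfy 0 < lo <= hi <= 1")
        return self

    @property
    def solvents(self) -> tuple[str, ...]:
        if self.n_solvents <= len(DEFAULT_SOLVENTS):
            return DEFAULT_SOLVENTS[: self.n_solvents]
        extra = tuple(
            f"solvent_{i}" for i in range(len(DEFAULT_SOLVENTS), self.n_solvents)
        )
        return DEFAULT_SOLVENTS + extra

    @property
    def fragment_catalog(self) -> tuple[str, ...]:
        if self.n_fragments <= len(DEFAULT_FRAGMENTS):
            return DEFAULT_FRAGMENTS[: self.n_fragments]
        extra = tuple(
            f"frag{i}" for i in range(len(DEFAULT_FRAGMENTS), self.n_fragments)
        )
        return DEFAULT_FRAGMENTS + extra

    def volumes(self) -> dict[int, tuple[float, float]]:
        out = {}
        for rep in range(1, self.n_replicates + 1):
            out[rep] = DEFAULT_VOLUMES.get(rep, (1.0, 1.0))
        return out


@dataclass
class SimPanel:
    """Ground truth plus the rendered observables for one simulation."""

    config: SimConfig
    compounds: pd.DataFrame  # compound_id, formula, mass, f_u, rrf, frag_*
    logk: pd.DataFrame  # compound_id x solvent, true log K_SW
    logd: pd.DataFrame  # compound_id x solvent, true log D_SW (= K for neutral)
    table: FeatureTable
    isomers: pd.DataFrame  # formula, smiles, data_sources, frag_*

    def reference_db(self) -> ReferenceDB:
        """Database view: theoretical log K plus fragment counts."""
        rec = self.compounds.copy()
        for s in self.config.solvents:
            rec[f"logK_{s}"] = self.logk[s]
        rec = rec.rename(columns={"mass": "monoisotopic_mass"})
        return ReferenceDB(
            records=rec,
            solvents=self.config.solvents,
            fragments=self.config.fragment_catalog,
        )

    def true_standardized(self) -> pd.DataFrame:
        """Per-compound z-scored true log K across the solvent panel."""
        m = self.logk.to_numpy(dtype=float)
        z = (m - m.mean(axis=1, keepdims=True)) / m.std(axis=1, keepdims=True)
        return pd.DataFrame(z, index=self.logk.index, columns=self.logk.columns)


# element composition per substructure unit; the baseline CH2 skeleton
# keeps every formula valid and the mass positive
_FRAGMENT_ELEMENTS: dict[str, dict[str, int]] = {
    "benzene": {"C": 6, "H": 4},
    "halogen": {"Cl": 1},
    "amine": {"N": 1, "H": 2},
    "amide": {"C": 1, "N": 1, "O": 1, "H": 1},
    "ether": {"O": 1},
    "ester": {"C": 1, "O": 2},
    "alcohol": {"O": 1, "H": 1},
    "ketone": {"C": 1, "O": 1},
    "carboxyl": {"C": 1, "O": 2, "H": 1},
    "nitro": {"N": 1, "O": 2},
    "aromatic_n": {"N": 1},
    "bicyclic": {"C": 8, "H": 8},
}


def simulate_compounds(cfg: SimConfig) -> pd.DataFrame:
    """Compounds with integer substructure counts, formulas and masses.

    Fragment counts are small non-negative integers (binomial); the
    formula is the sum of per-fragment element contributions on top of a
    random alkyl skeleton, and the mass follows deterministically from
    the formula.
    """
    rng = np.random.default_rng(cfg.seed)
    catalog = cfg.fragment_catalog
    counts = rng.binomial(cfg.max_fragment_count, 0.25, size=(cfg.n_compounds, len(catalog)))
    skeleton_c = rng.integers(2, 12, size=cfg.n_compounds)
    element_maps = []
    for i in range(cfg.n_compounds):
        elements = {el: 0 for el in ELEMENT_ALPHABET}
        elements["C"] += int(skeleton_c[i])
        elements["H"] += int(2 * skeleton_c[i] + 2)
        for frag, k in zip(catalog, counts[i]):
            contrib = _FRAGMENT_ELEMENTS.get(frag, {"C": 2, "H": 2})
            for el, n in contrib.items():
                elements[el] += n * int(k)
        element_maps.append(elements)

    # a curated mixture is chosen mass-resolvable: spread compounds whose
    # masses would collide within the matching window by extending their
    # alkyl skeleton (+CH2) until all pairwise gaps exceed 25 ppm
    def _mass(e: dict) -> float:
        return formula_mass({el: n for el, n in e.items() if n})

    masses = np.array([_mass(e) for e in element_maps])
    for _ in range(max(200, 10 * cfg.n_compounds)):
        order = np.argsort(masses)
        clash = None
        for a, b in zip(order[:-1], order[1:]):
            if 1e6 * (masses[b] - masses[a]) / masses[a] <= 25.0:
                clash = b
                break
        if clash is None:
            break
        element_maps[clash]["C"] += 1
        element_maps[clash]["H"] += 2
        masses[clash] = _mass(element_maps[clash])
    else:
        raise RuntimeError("could not mass-separate the simulated compounds")

    rows = []
    for i in range(cfg.n_compounds):
        rows.append(
            {
                "compound_id": f"C{i:04d}",
                "formula": format_formula(element_maps[i]),
                "smiles": "",  # simulated compounds carry no real structure
                "mass": float(masses[i]),
                **{f"frag_{f}": int(k) for f, k in zip(catalog, counts[i])},
            }
        )
    return pd.DataFrame(rows).set_index("compound_id")


def simulate_fingerprints(
    compounds: pd.DataFrame, cfg: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """True log K and log D matrices plus f_u and RRF per compound.

    Latent solute descriptors are a linear function of the fragment
    counts plus Gaussian noise; each solvent's log K is an exact linear
    map of the latents plus an intercept, so the panel matrix has rank
    ``latent_dim`` about its column intercepts regardless of the latent
    noise — read-across from any 3 generic solvents is exact by
    construction.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    catalog = cfg.fragment_catalog
    frag = compounds[[f"frag_{f}" for f in catalog]].to_numpy(dtype=float)
    w_lat = rng.normal(0, 0.4, size=(len(catalog), cfg.latent_dim))
    raw = frag @ w_lat + rng.normal(
        0, cfg.latent_noise_sd, size=(len(frag), cfg.latent_dim)
    )
    # unit-scale descriptors: the latent columns are solute descriptors on
    # a common scale, like the normalized descriptor sets LSER models use
    latents = (raw - raw.mean(axis=0)) / raw.std(axis=0)
    # solvent loadings are mostly contrasts (what differs between solvents)
    # plus a small shared hydrophobicity component; intercepts sit in the
    # shake-flask design's measurable window so that most analytes keep
    # detectable signal in both phases
    loadings = rng.normal(0, 0.45, size=(cfg.latent_dim, cfg.n_solvents))
    loadings -= loadings.mean(axis=1, keepdims=True)
    loadings += rng.normal(0, 0.15, size=(cfg.latent_dim, 1))
    intercepts = rng.normal(0.8, 0.3, size=cfg.n_solvents)
    logk = latents @ loadings + intercepts
    logk_df = pd.DataFrame(logk, index=compounds.index, columns=list(cfg.solvents))

    n = len(compounds)
    ionized = rng.random(n) < cfg.ionized_fraction
    f_u = np.ones(n)
    lo, hi = cfg.f_u_range
    f_u[ionized] = rng.uniform(lo, hi, size=int(ionized.sum()))
    logd_df = logk_df.add(np.log10(f_u), axis=0)

    rrf = 10 ** rng.uniform(0, 1, size=n)  # log-uniform over one decade
    return (
        logk_df,
        logd_df,
        pd.Series(f_u, index=compounds.index, name="f_u"),
        pd.Series(rrf, index=compounds.index, name="rrf"),
    )


def simulate_isomers(compounds: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Isomer metadata emulating a structure-database query per formula.

    Each simulated compound is one isomer of its formula; 0 to
    ``max_isomers_per_formula - 1`` decoy isomers are added with fragment
    counts perturbed by +-1 on a few catalog entries. Every isomer gets a
    data-sources popularity count (the true structure tends to be the
    best-known one, as curated mixtures are made of well-studied
    chemicals). The table feeds the per-formula fragment priors, which
    are therefore informative but not a copy of the truth.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    catalog = cfg.fragment_catalog
    frag_cols = [f"frag_{f}" for f in catalog]
    rows = []
    for cid, row in compounds.iterrows():
        true_counts = row[frag_cols].to_numpy(dtype=int)
        n_decoys = int(rng.integers(0, cfg.max_isomers_per_formula))
        sources = rng.geometric(0.2, size=n_decoys + 1)
        sources[0] += sources.max()  # the real structure is the best-known
        rows.append(
            {
                "formula": row["formula"],
                "smiles": f"true_{cid}",
                "data_sources": int(sources[0]),
                **dict(zip(frag_cols, true_counts.tolist())),
            }
        )
        for k in range(n_decoys):
            perturbed = true_counts.copy()
            flips = rng.integers(0, len(catalog), size=int(rng.integers(1, 4)))
            for j in flips:
                perturbed[j] = max(0, perturbed[j] + int(rng.choice([-1, 1])))
            rows.append(
                {
                    "formula": row["formula"],
                    "smiles": f"decoy_{cid}_{k}",
                    "data_sources": int(sources[k + 1]),
                    **dict(zip(frag_cols, perturbed.tolist())),
                }
            )
    return pd.DataFrame(rows)


def _sigmoid_response(area: np.ndarray, level: float, steepness: float) -> np.ndarray:
    """Monotone saturating response: linear-like well below ``level``,
    flattening into the sigmoid's upper edge near and above it."""
    a = np.asarray(area, dtype=float)
    out = np.zeros_like(a)
    pos = a > 0
    out[pos] = level / (1.0 + (level / a[pos]) ** steepness)
    return out


def render_feature_table(
    compounds: pd.DataFrame,
    logd: pd.DataFrame,
    rrf: pd.Series,
    cfg: SimConfig,
) -> FeatureTable:
    """Render observables from the truth: the full sample layout with
    areas from the two-phase mass balance plus instrument effects.

    For a compound with distribution ratio D at volume ratio V_S:V_W,
    the water-phase concentration after equilibration is
    C_W = N0 / (V_W + D * V_S) and the water control sees C0 = N0 / V_W;
    areas are RRF * concentration. The area ratio then returns D exactly
    under a linear response, independent of RRF.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    solvents = cfg.solvents
    volumes = cfg.volumes()
    n = len(compounds)
    d_lin = 10 ** logd[list(solvents)].to_numpy(dtype=float)
    rrf_v = rrf.to_numpy(dtype=float)

    manifest_rows = []
    areas: dict[str, np.ndarray] = {}

    def noise(shape) -> np.ndarray:
        if cfg.noise_sd_area == 0:
            return np.ones(shape)
        return np.exp(rng.normal(0, cfg.noise_sd_area, size=shape))

    n0 = cfg.nominal_area  # spike amount in arbitrary units, same for all samples
    for rep in range(1, cfg.n_replicates + 1):
        v_w, v_s = volumes[rep]
        c0 = n0 / v_w
        for j, solvent in enumerate(solvents):
            c_w = n0 / (v_w + d_lin[:, j] * v_s)
            for inj in range(1, cfg.n_injections + 1):
                sid_p = f"P_{solvent}_r{rep}_i{inj}"
                sid_w = f"W_{solvent}_r{rep}_i{inj}"
                manifest_rows.append((sid_p, "partition", solvent, rep, inj))
                manifest_rows.append((sid_w, "water_control", solvent, rep, inj))
                areas[sid_p] = rrf_v * c_w * noise(n)
                areas[sid_w] = rrf_v * c0 * noise(n)
        for inj in range(1, cfg.n_injections + 1):
            sid_b = f"B_r{rep}_i{inj}"
            manifest_rows.append((sid_b, "blank", "", rep, inj))
            areas[sid_b] = cfg.blank_level * n0 * noise(n)

    sample_ids = [r[0] for r in manifest_rows]
    area_mat = np.column_stack([areas[s] for s in sample_ids])

    if cfg.response == "sigmoid":
        nonblank = [
            i for i, r in enumerate(manifest_rows) if r[1] != "blank"
        ]
        level = float(np.quantile(area_mat[:, nonblank], cfg.saturation_quantile))
        area_mat = _sigmoid_response(area_mat, level, cfg.saturation_steepness)

    if cfg.blank_level > 0:
        floor = cfg.blank_level * n0 * noise(area_mat.shape)
        area_mat = np.maximum(area_mat, floor)

    if cfg.dropout_prob > 0:
        drop = rng.random(area_mat.shape) < cfg.dropout_prob
        area_mat = np.where(drop, 0.0, area_mat)

    index = pd.Index([f"F{i:04d}" for i in range(n)], name="feature_id")
    meta = pd.DataFrame(
        {
            "mz": compounds["mass"].to_numpy() + PROTON_MASS,  # [M+H]+
            "rt": np.round(rng.uniform(0.5, 15.0, size=n), 3),
        },
        index=index,
    )
    features = pd.concat(
        [meta, pd.DataFrame(area_mat, index=index, columns=sample_ids)], axis=1
    )
    manifest = pd.DataFrame(
        manifest_rows, columns=["sample_id", "role", "solvent", "replicate", "injection"]
    ).set_index("sample_id")
    return FeatureTable(features=features, manifest=manifest)


def simulate_panel(cfg: SimConfig) -> SimPanel:
    """Run the whole generator: compounds, truth, rendered feature table."""
    compounds = simulate_compounds(cfg)
    logk, logd, f_u, rrf = simulate_fingerprints(compounds, cfg)
    compounds = compounds.assign(f_u=f_u, rrf=rrf)
    table = render_feature_table(compounds, logd, rrf, cfg)
    isomers = simulate_isomers(compounds, cfg)
    return SimPanel(
        config=cfg, compounds=compounds, logk=logk, logd=logd,
        table=table, isomers=isomers,
    )


def write_panel(panel: SimPanel, outdir: str | Path) -> None:
    """Emit the panel in the pipeline's on-disk dialects: feature table +
    manifest + reference DB + truth CSVs."""
    from .feature_io import write_feature_table, write_reference_db

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_feature_table(
        panel.table, outdir / "features.csv", outdir / "manifest.csv"
    )
    write_reference_db(panel.reference_db(), outdir / "reference_db.csv")
    panel.isomers.to_csv(outdir / "isomers.csv", index=False)
    panel.logk.rename_axis("compound_id").to_csv(outdir / "true_logk.csv")
    panel.logd.rename_axis("compound_id").to_csv(outdir / "true_logd.csv")
    panel.compounds.rename_axis("compound_id").to_csv(outdir / "compounds.csv")
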