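"""Synthetic mother-offspring dyad cohorts with planted metabolite classes.

The generator emulates the structure of a three-group (SGA/AGA/LGA) birthweight
cohort with paired maternal and umbilical-cord plasma metabolomes:

* log-normal metabolite abundances — log-intensity of metabolite ``j`` in dyad
  ``i`` and compartment ``c`` is

  ``baseline_j + effect_j(group_i) + lambda * u_ij + eps_ijc``

  with a per-(dyad, metabolite) latent ``u`` shared between compartments
  ("placental transfer") and independent Gaussian residuals per compartment;
* group effects on the log scale chosen so that the ratio-of-means fold change
  of a planted metabolite converges to ``exp(effect)``;
* five planted classes — ``U_up``/``U_down`` (deviating in the same direction
  in both SGA and LGA relative to AGA), ``line_up``/``line_down`` (monotone
  across SGA -> AGA -> LGA), and ``null``;
* a clinical phenotype table whose per-group means, SDs and category
  proportions default to the source cohort's demographics (16/28/23 dyads).

The latent loading is ``lambda = sigma * sqrt(rho / (1 - rho))`` so that the
maternal-cord Pearson correlation of log intensities equals ``transfer_rho``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .prep import IntensityMatrix

GROUPS = ("SGA", "AGA", "LGA")
GROUP_ORDINAL = {"SGA": 0, "AGA": 1, "LGA": 2}
CLASSES = ("U_up", "U_down", "line_up", "line_down", "null")

# ---------------------------------------------------------------------------
# Default clinical phenotype parameters (per-group mean, SD) and category
# proportions for the 16/28/23 cohort.  Supplemental-only panels (HbA1c,
# HDL-C, LDL-C, FFA, HCY) use typical third-trimester values.
# ---------------------------------------------------------------------------
CONTINUOUS_DEFAULTS: dict[str, tuple[tuple[float, float], ...]] = {
    "maternal_age": ((31.4, 4.6), (33.7, 6.7), (30.9, 5.3)),
    "gestational_age": ((38.7, 1.1), (38.4, 0.9), (39.0, 1.1)),
    "prepreg_bmi": ((22.4, 3.4), (23.4, 3.5), (25.1, 2.6)),
    "weight_gain": ((14.8, 5.2), (14.2, 6.0), (15.5, 5.8)),
    "hba1c": ((5.3, 0.4), (5.3, 0.4), (5.4, 0.4)),
    "fbg": ((4.6, 0.7), (4.7, 0.6), (4.6, 0.5)),
    "hdl_c": ((2.0, 0.4), (2.0, 0.4), (1.7, 0.4)),
    "ldl_c": ((3.0, 0.8), (3.0, 0.8), (3.1, 0.8)),
    "ffa": ((0.5, 0.2), (0.5, 0.2), (0.5, 0.2)),
    "leptin": ((644.9, 494.1), (413.5, 311.1), (518.5, 391.8)),
    "adiponectin": ((6135.8, 3230.1), (6908.0, 5258.9), (6641.8, 393.2)),
    "hcy": ((6.0, 1.5), (6.0, 1.5), (6.2, 1.5)),
    "birthweight": ((2739.4, 250.7), (3300.4, 133.2), (4097.0, 238.2)),
    "cord_glucose": ((4.4, 1.3), (4.5, 1.6), (4.4, 2.1)),
    "cord_insulin": ((4.2, 2.2), (6.9, 3.9), (14.9, 21.1)),
    "cord_leptin": ((43.7, 42.8), (118.7, 203.5), (355.6, 531.5)),
    "cord_adiponectin": ((26221.2, 8062.6), (27014.2, 10613.8), (28995.6, 9760.0)),
}

#: P(first level) per group for each two-level categorical variable
CATEGORICAL_DEFAULTS: dict[str, tuple[tuple[str, str], tuple[float, float, float]]] = {
    "parity": (("first", "subsequent"), (11 / 16, 8 / 28, 14 / 23)),
    "newborn_sex": (("male", "female"), (12 / 16, 15 / 28, 14 / 23)),
    "gdm": (("yes", "no"), (8 / 16, 18 / 28, 13 / 23)),
}


@dataclass(frozen=True)
class CohortConfig:
    """Simulation parameters for one synthetic dyad cohort.

    ``delta_u`` and ``delta_line`` are natural-log effect magnitudes (a value
    of ``ln 2`` plants two-fold abundance shifts); ``noise_sigma`` is the
    log-scale residual SD per compartment; ``transfer_rho`` the target
    maternal-cord Pearson correlation of log intensities.
    """

    group_sizes: tuple[int, int, int] = (16, 28, 23)
    n_metabolites_per_class: dict[str, int] = field(
        default_factory=lambda: {
            "U_up": 30, "U_down": 30, "line_up": 30, "line_down": 30, "null": 200,
        }
    )
    delta_u: float = float(np.log(2.0))
    delta_line: float = float(np.log(2.0))
    transfer_rho: float = 0.5
    noise_sigma: float = 0.4
    modes: tuple[str, ...] = ("pos", "neg")
    missing_rate: float = 0.0
    seed: int = 0
    #: log-intensity baseline mean / SD across metabolites
    baseline_mean: float = 9.0
    baseline_sd: float = 1.0
    #: fraction of planted metabolites whose cord-compartment effect is flipped
    discordant_fraction: float = 0.0
    #: global multiplier on phenotype SDs (0 -> every value equals its group mean)
    pheno_sd_scale: float = 1.0
    #: optional linear links (metabolite_id, phenotype variable, slope):
    #: slope * z(variable) is added to the metabolite's log intensity
    pheno_links: tuple[tuple[str, str, float], ...] = ()
    #: index line-class effects by the dyad's standardized birthweight instead
    #: of the group ordinal
    line_by_birthweight: bool = False

    def validate(self) -> None:
        if len(self.group_sizes) != 3 or any(n < 2 for n in self.group_sizes):
            raise ValueError("need three groups with >= 2 dyads each")
        if sum(self.group_sizes) < 6:
            raise ValueError("cohort too small: total dyads must be >= 6")
        if any(c not in CLASSES for c in self.n_metabolites_per_class):
            raise ValueError(f"class labels must be among {CLASSES}")
        if any(n < 0 for n in self.n_metabolites_per_class.values()):
            raise ValueError("metabolite counts must be nonnegative")
        if sum(self.n_metabolites_per_class.values()) == 0:
            raise ValueError("cohort must contain at least one metabolite")
        if not self.noise_sigma > 0:
            raise ValueError("noise_sigma must be positive")
        if not 0 <= self.transfer_rho < 1:
            raise ValueError("transfer_rho must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not set(self.modes) <= {"pos", "neg"} or not self.modes:
            raise ValueError("modes must be a nonempty subset of {'pos', 'neg'}")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortConfig":
        raw = json.loads(Path(path).read_text())
        if "group_sizes" in raw:
            raw["group_sizes"] = tuple(raw["group_sizes"])
        if "modes" in raw:
            raw["modes"] = tuple(raw["modes"])
        if "pheno_links" in raw:
            raw["pheno_links"] = tuple(tuple(link) for link in raw["pheno_links"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per stage, all derived from one seed
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


def generate_phenotypes(config: CohortConfig) -> pd.DataFrame:
    """Draw the per-dyad clinical phenotype table.

    Continuous variables are Gaussian with the per-group defaults above;
    categorical variables are Bernoulli with the default proportions.  Scaling
    every SD by ``pheno_sd_scale = 0`` returns exact group means.
    """
    config.validate()
    rng = _rng(config, 0)
    n_total = sum(config.group_sizes)
    groups = np.repeat(list(GROUPS), config.group_sizes)
    table: dict[str, object] = {
        "dyad_id": [f"D{i + 1:03d}" for i in range(n_total)],
        "group": groups,
    }
    for var, (levels, props) in CATEGORICAL_DEFAULTS.items():
        p = np.array([props[GROUP_ORDINAL[g]] for g in groups])
        draws = rng.random(n_total) < p
        table[var] = np.where(draws, levels[0], levels[1])
    for var, params in CONTINUOUS_DEFAULTS.items():
        mean = np.array([params[GROUP_ORDINAL[g]][0] for g in groups])
        sd = np.array([params[GROUP_ORDINAL[g]][1] for g in groups]) * config.pheno_sd_scale
        table[var] = mean + sd * rng.standard_normal(n_total)
    return pd.DataFrame(table).set_index("dyad_id")


def _metabolite_ids(config: CohortConfig) -> tuple[list[str], list[str]]:
    ids, labels = [], []
    for cls in CLASSES:
        for i in range(config.n_metabolites_per_class.get(cls, 0)):
            ids.append(f"{cls}_{i + 1:03d}")
            labels.append(cls)
    return ids, labels


def _effect_matrix(
    config: CohortConfig, labels: list[str], groups: np.ndarray, phenotypes: pd.DataFrame
) -> np.ndarray:
    """Planted log-scale effect per (dyad, metabolite)."""
    n, p = len(groups), len(labels)
    ordinal = np.array([GROUP_ORDINAL[g] for g in groups], dtype=float)
    if config.line_by_birthweight:
        bw = phenotypes["birthweight"].to_numpy(dtype=float)
        line_index = (bw - bw.mean()) / bw.std(ddof=1)
    else:
        line_index = ordinal - 1.0
    in_tail = (ordinal != 1).astype(float)  # SGA or LGA
    eff = np.zeros((n, p))
    for j, cls in enumerate(labels):
        if cls == "U_up":
            eff[:, j] = config.delta_u * in_tail
        elif cls == "U_down":
            eff[:, j] = -config.delta_u * in_tail
        elif cls == "line_up":
            eff[:, j] = config.delta_line * line_index
        elif cls == "line_down":
            eff[:, j] = -config.delta_line * line_index
    return eff


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, dict[tuple[str, str], IntensityMatrix], pd.DataFrame]:
    """Generate phenotypes, paired intensity matrices, and the ground truth.

    Returns
    -------
    phenotypes : DataFrame indexed by dyad id.
    matrices : dict keyed by (compartment, mode) -> raw :class:`IntensityMatrix`.
    truth : DataFrame (metabolite_id, class, effect) — the signed log-scale
        effect magnitude planted for each metabolite (0 for nulls).
    """
    config.validate()
    phenotypes = generate_phenotypes(config)
    groups = phenotypes["group"].to_numpy()
    n = len(phenotypes)
    ids, labels = _metabolite_ids(config)
    p = len(ids)

    rng = _rng(config, 1)
    baseline = config.baseline_mean + config.baseline_sd * rng.standard_normal(p)
    sigma = config.noise_sigma
    rho = config.transfer_rho
    lam = sigma * np.sqrt(rho / (1.0 - rho)) if rho > 0 else 0.0
    latent = rng.standard_normal((n, p))

    eff = _effect_matrix(config, labels, groups, phenotypes)
    eff_by_comp = {"maternal": eff, "cord": eff}
    if config.discordant_fraction > 0:
        planted = np.array([lab != "null" for lab in labels])
        flip = rng.random(p) < config.discordant_fraction
        sign = np.where(planted & flip, -1.0, 1.0)
        eff_by_comp = {"maternal": eff, "cord": eff * sign}

    link_shift = np.zeros((n, p))
    for met_id, var, slope in config.pheno_links:
        if met_id not in ids:
            raise ValueError(f"pheno_links references unknown metabolite {met_id!r}")
        if var not in phenotypes.columns:
            raise ValueError(f"pheno_links references unknown variable {var!r}")
        v = phenotypes[var].to_numpy(dtype=float)
        z = (v - v.mean()) / v.std(ddof=1)
        link_shift[:, ids.index(met_id)] += slope * z

    # deterministic round-robin assignment of metabolites to ionization modes
    modes = list(config.modes)
    mode_of = {mid: modes[j % len(modes)] for j, mid in enumerate(ids)}

    miss_rng = _rng(config, 2)
    matrices: dict[tuple[str, str], IntensityMatrix] = {}
    for comp in ("maternal", "cord"):
        eps = rng.standard_normal((n, p)) * sigma
        log_x = baseline + eff_by_comp[comp] + lam * latent + eps + link_shift
        values = np.exp(log_x)
        if config.missing_rate > 0:
            mask = miss_rng.random((n, p)) < config.missing_rate
            values = np.where(mask, np.nan, values)
        full = pd.DataFrame(values, index=phenotypes.index, columns=ids)
        for mode in modes:
            cols = [mid for mid in ids if mode_of[mid] == mode]
            matrices[(comp, mode)] = IntensityMatrix(full[cols].copy(), comp, mode)

    deltas = {
        "U_up": config.delta_u, "U_down": -config.delta_u,
        "line_up": config.delta_line, "line_down": -config.delta_line, "null": 0.0,
    }
    truth = pd.DataFrame(
        {
            "metabolite_id": ids,
            "class": labels,
            "effect": [deltas[lab] for lab in labels],
            "mode": [mode_of[mid] for mid in ids],
        }
    ).set_index("metabolite_id")
    return phenotypes, matrices, truth


# ---------------------------------------------------------------------------
# CSV dialect: phenotypes.csv / intensity_<compartment>_<mode>.csv / truth.csv
# ---------------------------------------------------------------------------

def write_cohort(
    outdir: str | Path,
    phenotypes: pd.DataFrame,
    matrices: dict[tuple[str, str], IntensityMatrix],
    truth: pd.DataFrame | None = None,
) -> list[Path]:
    """Write a cohort in the package's CSV dialect (empty cell = missing)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    path = outdir / "phenotypes.csv"
    phenotypes.to_csv(path, float_format="%.12g")
    written.append(path)
    for (comp, mode), mat in matrices.items():
        path = outdir / f"intensity_{comp}_{mode}.csv"
        mat.data.to_csv(path, index_label="sample", float_format="%.12g")
        written.append(path)
    if truth is not None:
        path = outdir / "truth.csv"
        truth.to_csv(path, float_format="%.12g")
        written.append(path)
    return written


def read_intensity_csv(
    path: str | Path, compartment: str, mode: str, normalized: bool = False
) -> IntensityMatrix:
    import csv
    from collections import Counter

    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    dupes = sorted(c for c, k in Counter(header[1:]).items() if k > 1)
    if dupes:
        raise ValueError(f"duplicate metabolite column(s) in {path}: {dupes}")
    df = pd.read_csv(path, index_col=0)
    bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        raise ValueError(f"non-numeric intensity column(s) in {path}: {bad}")
    return IntensityMatrix(df, compartment, mode, normalized=normalized)


def read_phenotypes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if "group" not in df.columns:
        raise ValueError(f"{path} lacks the required 'group' column")
    unknown = set(df["group"]) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group labels in {path}: {sorted(unknown)}")
    return df
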