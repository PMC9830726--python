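"""End-to-end orchestration: simulate/load -> prep -> OPLS-DA -> shapes -> assoc.

One root seed drives every stochastic stage (fold assignment seeds are derived
deterministically from it), so a finished run is fully reproducible from its
config + seed; the run manifest records both along with per-stage counts, and
re-running over an up-to-date manifest skips the work.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .prep import IntensityMatrix, impute_missing, merge_modes, znormalize
from .synthio import (
    CohortConfig, generate_cohort, read_intensity_csv, read_phenotypes_csv,
    write_cohort,
)
from .mva import cross_validate, fit_oplsda, vip
from .shapes import COMPARISONS, discover_shapes, ordered_zscore_matrix
from .assoc import correlate_panel, maternal_cord_correlation
from .cohorts import summarize_cohort

logger = logging.getLogger("metabshape")

DEFAULT_CLINICAL_VARIABLES = (
    "prepreg_bmi", "weight_gain", "hba1c", "fbg", "hdl_c", "ldl_c",
    "ffa", "leptin", "adiponectin", "hcy",
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, message: str, code: int = 3):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Everything a full discovery run needs.

    Provide either ``simulate`` (a :class:`~metabshape.synthio.CohortConfig`)
    or ``input_dir`` pointing at the CSV dialect written by
    :func:`~metabshape.synthio.write_cohort`.
    """

    outdir: str = "results"
    simulate: CohortConfig | None = None
    input_dir: str | None = None
    modes: tuple[str, ...] = ("pos", "neg")
    impute: str = "half-min"
    #: model intensities on the log scale (abundances are log-normal); fold
    #: changes and Z-score exports always use the raw scale
    log_transform: bool = True
    scale: str = "uv"
    vip_threshold: float = 1.0
    vip_variant: str = "pred"
    n_orth: int = 1
    k_folds: int = 7
    fc_method: str = "mean"
    concordance: str = "both"
    covariate_preset: str = "table"
    clinical_variables: tuple[str, ...] = DEFAULT_CLINICAL_VARIABLES
    seed: int = 0

    def validate(self) -> None:
        if (self.simulate is None) == (self.input_dir is None):
            raise PipelineError(
                "config", "provide exactly one of simulate-block or input_dir", code=2
            )
        if self.simulate is not None:
            self.simulate.validate()
        elif not Path(self.input_dir).is_dir():
            raise PipelineError("config", f"input_dir {self.input_dir!r} not found", code=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            for key in ("group_sizes", "modes"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "pheno_links" in sim:
                sim["pheno_links"] = tuple(tuple(x) for x in sim["pheno_links"])
            raw["simulate"] = CohortConfig(**sim)
        for key in ("modes", "clinical_variables"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        phenotypes, matrices, truth = generate_cohort(config.simulate)
        return phenotypes, matrices, truth
    d = Path(config.input_dir)
    phenotypes = read_phenotypes_csv(d / "phenotypes.csv")
    matrices = {}
    for comp in ("maternal", "cord"):
        for mode in config.modes:
            path = d / f"intensity_{comp}_{mode}.csv"
            if not path.exists():
                raise PipelineError("load", f"missing input {path}", code=2)
            matrices[(comp, mode)] = read_intensity_csv(path, comp, mode)
    return phenotypes, matrices, None


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute the full discovery chain and write the result bundle.

    Returns a dict with the in-memory stage products; writes CSV/JSON outputs
    plus ``run_manifest.json`` under ``config.outdir``.  If a manifest from an
    identical config + seed is already present the run is skipped.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "run_manifest.json"
    digest = config.digest()
    if manifest_path.exists() and not force:
        try:
            old = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            old = {}
        if old.get("config_digest") == digest and old.get("seed") == config.seed:
            logger.info("run up-to-date (config digest %s); skipping", digest[:12])
            return {"skipped": True, "manifest": old}

    counts: dict[str, int] = {}
    try:
        phenotypes, matrices, truth = _load_inputs(config)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError("load", str(exc)) from exc
    counts["dyads"] = len(phenotypes)
    if config.simulate is not None:
        write_cohort(outdir / "inputs", phenotypes, matrices, truth)

    # ---- prep: impute, merge modes, Z-normalize per compartment -----------
    try:
        merged_raw, merged_imputed, merged_z = {}, {}, {}
        for comp in ("maternal", "cord"):
            per_mode_raw = [matrices[(comp, m)] for m in config.modes]
            per_mode_imp = [impute_missing(m, config.impute) for m in per_mode_raw]
            if len(per_mode_raw) == 2:
                raw = merge_modes(per_mode_raw[0], per_mode_raw[1])
                imp = merge_modes(per_mode_imp[0], per_mode_imp[1])
            else:
                raw = IntensityMatrix(
                    per_mode_raw[0].data.add_prefix(f"{config.modes[0]}:"),
                    comp, "merged",
                )
                imp = IntensityMatrix(
                    per_mode_imp[0].data.add_prefix(f"{config.modes[0]}:"),
                    comp, "merged",
                )
            merged_raw[comp] = raw
            merged_imputed[comp] = imp
            merged_z[comp] = znormalize(imp)
        counts["metabolites"] = merged_raw["maternal"].shape[1]
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("prep", str(exc)) from exc

    # ---- mva: four two-class OPLS-DA models -------------------------------
    groups = phenotypes["group"]
    seed_root = np.random.SeedSequence(entropy=config.seed, spawn_key=(99,))
    cv_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seed_root.spawn(4)]
    vip_tables: dict[str, pd.Series] = {}
    model_summaries: dict[str, dict] = {}
    try:
        model_input = {
            comp: (np.log(merged_imputed[comp].data.where(merged_imputed[comp].data > 0))
                   if config.log_transform else merged_imputed[comp].data)
            for comp in ("maternal", "cord")
        }
        for i, name in enumerate(COMPARISONS):
            contrast, comp = name.split("_")
            tail = {"SGAvAGA": "SGA", "LGAvAGA": "LGA"}[contrast]
            keep = groups.isin([tail, "AGA"])
            X = model_input[comp].loc[keep.index[keep]]
            y = groups[keep].to_numpy()
            model = fit_oplsda(X, y, n_orth=config.n_orth, scale=config.scale)
            r2y, q2 = cross_validate(
                X, y, {"kind": "oplsda", "n_orth": config.n_orth, "scale": config.scale},
                k_folds=config.k_folds, seed=cv_seeds[i],
            )
            model.q2 = q2
            vt = vip(model, variant=config.vip_variant)
            vip_tables[name] = vt
            n_sel = int((vt > config.vip_threshold).sum())
            model_summaries[name] = {
                "R2X": model.r2x, "R2Y": model.r2y, "Q2": q2, "n_selected": n_sel,
            }
            logger.info(
                "OPLS-DA %s: R2X=%.3f R2Y=%.3f Q2=%.3f selected=%d",
                name, model.r2x, model.r2y, q2, n_sel,
            )
            counts[f"dms_{name}"] = n_sel
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("mva", str(exc)) from exc

    # ---- shapes: intersection, fold changes, U/line calls -----------------
    try:
        disc = discover_shapes(
            vip_tables, merged_raw["maternal"], merged_raw["cord"], groups,
            threshold=config.vip_threshold, fc_method=config.fc_method,
            concordance=config.concordance,
        )
        calls = disc["shape_calls"]
        labelled = calls.index[calls["label"] != "none"].tolist()
        counts["shared_dms"] = len(disc["venn"]["intersection"])
        counts["u_shaped"] = int(calls["label"].isin(["U_up", "U_down"]).sum())
        counts["line_shaped"] = int(calls["label"].isin(["line_up", "line_down"]).sum())
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("shapes", str(exc)) from exc

    # ---- assoc: maternal-cord + clinical correlations ---------------------
    try:
        ids = labelled if labelled else sorted(disc["venn"]["intersection"])
        mc = maternal_cord_correlation(
            merged_imputed["maternal"], merged_imputed["cord"], ids
        )
        assoc_tables = {}
        present = [v for v in config.clinical_variables if v in phenotypes.columns]
        for model_no in (1, 2):
            frames = [
                correlate_panel(
                    merged_imputed[comp], phenotypes, ids, present,
                    model=model_no, covariate_preset=config.covariate_preset,
                )
                for comp in ("maternal", "cord")
            ]
            assoc_tables[model_no] = pd.concat(frames, ignore_index=True)
        counts["assoc_records"] = sum(len(t) for t in assoc_tables.values())
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("assoc", str(exc)) from exc

    # ---- cohorts: demographics table --------------------------------------
    try:
        table1 = summarize_cohort(phenotypes)
        counts["table1_rows"] = len(table1)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("cohorts", str(exc)) from exc

    # ---- write bundle ------------------------------------------------------
    try:
        (outdir / "dm_sets.json").write_text(json.dumps(
            {
                "threshold": config.vip_threshold,
                **{k: sorted(v) for k, v in disc["dm_sets"].items()},
            }, indent=1,
        ))
        pd.Series(disc["venn"]["regions"], name="count").rename_axis("region") \
            .to_csv(outdir / "venn_counts.csv")
        disc["fold_changes"].rename_axis("metabolite_id") \
            .to_csv(outdir / "fold_changes.csv", float_format="%.12g")
        calls.rename_axis("metabolite_id") \
            .to_csv(outdir / "shape_calls.csv", float_format="%.12g")
        mc.to_csv(outdir / "maternal_cord_corr.csv", index=False, float_format="%.12g")
        for model_no, tab in assoc_tables.items():
            tab.to_csv(outdir / f"assoc_model{model_no}.csv", index=False,
                       float_format="%.12g")
        table1.to_csv(outdir / "table1.csv", index=False, float_format="%.12g")
        (outdir / "opls_models.json").write_text(json.dumps(model_summaries, indent=1))
        for comp in ("maternal", "cord"):
            ordered_zscore_matrix(merged_z[comp], groups, sorted(
                disc["venn"]["intersection"])) \
                .to_csv(outdir / f"ordered_zscores_{comp}.csv", float_format="%.12g")
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config_digest": digest,
            "config": config.to_dict(),
            "counts": counts,
            "models": model_summaries,
        }
        manifest_path.write_text(json.dumps(manifest, indent=1))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("write", str(exc)) from exc

    return {
        "skipped": False,
        "phenotypes": phenotypes,
        "truth": truth,
        "matrices": matrices,
        "merged_raw": merged_raw,
        "merged_z": merged_z,
        "vip_tables": vip_tables,
        "discovery": disc,
        "maternal_cord": mc,
        "assoc": assoc_tables,
        "table1": table1,
        "manifest": manifest,
    }
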