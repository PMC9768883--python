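"""End-to-end pipeline: load or simulate, fit, FDR maps, model grid, classify.

The pipeline is a thin orchestration layer over the library.  A run is
described by a nested config (YAML file or dict); one global seed expands
into independent per-stage seeds through ``numpy.random.SeedSequence``, so
stages can be rerun independently, and identical (config, seed) pairs
produce byte-identical output tables.  The run manifest records the config
snapshot, the per-stage seeds and timings, and a SHA-256 inventory of every
output file.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import MlpSpec, mlp_loocv_scores, regionwise_glm, roc_auc
from .cohort import (
    ThicknessDataset,
    default_truth,
    make_atlas,
    simulate_thickness,
    table1_fixture,
)
from .demographics import age_summaries, anova_report, chisq_report, sex_contingency
from .fdr import bayesian_fdr_threshold, null_probabilities
from .harmonics import SphericalPoint, build_basis
from .model import (
    ModelConfig,
    fit_thickness_model,
    posterior_zscores,
    spatial_coefficient_draws,
)
from .selection import config_grid, evaluate_grid

__all__ = ["PRESETS", "load_inputs", "save_dataset", "run_pipeline"]

logger = logging.getLogger(__name__)

#: stage order; "grid" is opt-in because it refits the model once per
#: subject and configuration.
ALL_STAGES = ("simulate", "fit", "fdr", "grid", "classify")

PRESETS: dict[str, dict] = {
    # the published analysis settings
    "paper": {
        "stages": ["simulate", "fit", "fdr", "classify"],
        "model": {
            "residual": "matern",
            "fe_prior": "gaussian",
            "nonstationary": True,
            "J": 9,
            "L": 7,
            "iterations": 100_000,
            "burn_in": 10_000,
            "thinning": 10,
        },
        "fdr": {"q": 0.01},
        "classify": {"contrasts": [["HC", "LTLE"], ["HC", "RTLE"]], "hidden_units": 3},
    },
    # desk-scale defaults for interactive work
    "demo": {
        "stages": ["simulate", "fit", "fdr", "classify"],
        "model": {
            "residual": "matern",
            "fe_prior": "gaussian",
            "nonstationary": True,
            "J": 9,
            "L": 7,
            "iterations": 5_000,
            "burn_in": 1_000,
            "thinning": 4,
        },
        "fdr": {"q": 0.01},
        "classify": {"contrasts": [["HC", "LTLE"], ["HC", "RTLE"]], "hidden_units": 3},
    },
}

_TSV = dict(sep="\t", float_format="%.10g")


def save_dataset(ds: ThicknessDataset, outdir: str | Path) -> dict[str, Path]:
    """Write thickness.tsv, cohort.tsv and atlas.tsv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "thickness": outdir / "thickness.tsv",
        "cohort": outdir / "cohort.tsv",
        "atlas": outdir / "atlas.tsv",
    }
    ds.thickness.rename_axis("subject_id").to_csv(paths["thickness"], **_TSV)
    ds.cohort.to_csv(paths["cohort"], index=False, **_TSV)
    ds.atlas.to_csv(paths["atlas"], index=False, **_TSV)
    return paths


def load_inputs(
    thickness_path: str | Path,
    atlas_path: str | Path,
    cohort_path: str | Path,
) -> ThicknessDataset:
    """Load and validate the three delimited input files.

    Raises distinct errors for a missing file, a missing (NA) thickness cell
    (named by subject and region), a non-positive thickness, and
    subject/region label mismatches between the tables.
    """
    for p in (thickness_path, atlas_path, cohort_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    thickness = pd.read_csv(thickness_path, sep="\t", index_col="subject_id")
    cohort = pd.read_csv(cohort_path, sep="\t")
    atlas = pd.read_csv(atlas_path, sep="\t")

    na = thickness.isna()
    if na.to_numpy().any():
        i, j = np.argwhere(na.to_numpy())[0]
        raise ValueError(
            f"missing thickness value at subject '{thickness.index[i]}', "
            f"region '{thickness.columns[j]}'"
        )
    required = {"subject_id", "group", "age", "sex"}
    if not required.issubset(cohort.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    if set(thickness.index) != set(cohort["subject_id"]):
        raise ValueError("subject ids in thickness and cohort tables do not align")
    if set(thickness.columns) != set(atlas["region_name"]):
        raise ValueError("region names in thickness and atlas tables do not align")
    thickness = thickness.loc[list(cohort["subject_id"]), list(atlas["region_name"])]
    return ThicknessDataset(thickness=thickness, cohort=cohort, atlas=atlas)


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(ALL_STAGES))
    return {
        stage: int(child.generate_state(1)[0] % 2**31)
        for stage, child in zip(ALL_STAGES, children)
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def run_pipeline(
    config: dict | str | Path,
    outdir: str | Path,
    seed: int | None = None,
    stages: list[str] | None = None,
) -> dict:
    """Execute the requested stages and return the run manifest.

    ``config`` is a dict or a YAML file path; a ``preset`` key ("paper" or
    "demo") supplies defaults that the rest of the config overrides.  The
    manifest (also written to ``manifest.yaml``) lists the config snapshot,
    per-stage seeds and timings, and the SHA-256 of every output file.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    preset = config.get("preset", "demo")
    if preset not in PRESETS:
        raise ValueError(f"unknown preset '{preset}'")
    cfg = _merge(PRESETS[preset], {k: v for k, v in config.items() if k != "preset"})
    if seed is None:
        seed = int(cfg.get("seed", 0))
    stages = list(stages if stages is not None else cfg.get("stages", []))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    # validate the model config before any compute
    model_cfg = ModelConfig(seed=0, **cfg.get("model", {}))
    seeds = _stage_seeds(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    outputs: dict[str, Path] = {}
    timings: dict[str, float] = {}
    ds: ThicknessDataset | None = None
    samples = None

    def _stage(name: str) -> bool:
        return name in stages

    if _stage("simulate"):
        t0 = time.perf_counter()
        sim = cfg.get("simulate", {})
        atlas = make_atlas(seed=seeds["simulate"])
        cohort = table1_fixture()
        truth = default_truth(
            atlas,
            J=model_cfg.J,
            L=model_cfg.L,
            seed=seeds["simulate"],
            group_effect=float(sim.get("group_effect", -0.15)),
        )
        basis = build_basis(
            [SphericalPoint(r.colatitude_rad, r.longitude_rad) for r in atlas.itertuples()],
            model_cfg.L,
        )
        ds = simulate_thickness(atlas, cohort, truth, basis)
        outputs.update(save_dataset(ds, outdir))
        timings["simulate"] = time.perf_counter() - t0
        logger.info("simulate: %d subjects x %d regions", ds.n_subjects, ds.n_regions)
    elif "data" in cfg:
        data = cfg["data"]
        ds = load_inputs(data["thickness"], data["atlas"], data["cohort"])

    if ds is not None:
        report = outdir / "demographics.txt"
        report.write_text(
            chisq_report(sex_contingency(ds.cohort))
            + "\n"
            + anova_report(age_summaries(ds.cohort))
            + "\n"
        )
        outputs["demographics"] = report

    summary = None
    if _stage("fit"):
        if ds is None:
            raise RuntimeError("stage 'fit' failed: no dataset (simulate or data required)")
        t0 = time.perf_counter()
        fit_cfg = dataclasses.replace(model_cfg, seed=seeds["fit"])
        try:
            samples = fit_thickness_model(ds, fit_cfg)
            summary = posterior_zscores(samples)
        except Exception as exc:
            raise RuntimeError(f"stage 'fit' failed: {exc}") from exc
        zpath = outdir / "posterior_zscores.tsv"
        summary.zscore.rename_axis("covariate").to_csv(zpath, **_TSV)
        outputs["posterior_zscores"] = zpath
        timings["fit"] = time.perf_counter() - t0
        logger.info("fit: %d retained draws, acceptance %s", samples.n_retained,
                    samples.acceptance)

    if _stage("fdr"):
        if samples is None or summary is None:
            raise RuntimeError("stage 'fdr' failed: run 'fit' first")
        t0 = time.perf_counter()
        q = float(cfg.get("fdr", {}).get("q", 0.01))
        spatial = spatial_coefficient_draws(samples)
        for k, name in enumerate(samples.covariate_names):
            if name == "intercept":
                continue
            probs = null_probabilities(spatial[:, k, :])
            res = bayesian_fdr_threshold(
                probs, q, zscores=summary.zscore.loc[name].to_numpy()
            )
            table = pd.DataFrame(
                {
                    "region": samples.region_names,
                    "hemisphere": ds.atlas["hemisphere"].to_numpy(),
                    "zscore": summary.zscore.loc[name].to_numpy(),
                    "null_prob": res.null_prob,
                    "rejected": res.rejected.astype(int),
                }
            )
            path = outdir / f"fdr_{name}.tsv"
            table.to_csv(path, index=False, **_TSV)
            outputs[f"fdr_{name}"] = path
        timings["fdr"] = time.perf_counter() - t0

    if _stage("grid"):
        if ds is None:
            raise RuntimeError("stage 'grid' failed: no dataset")
        t0 = time.perf_counter()
        grid_cfg = dataclasses.replace(model_cfg, seed=seeds["grid"])
        try:
            results = evaluate_grid(ds, config_grid(grid_cfg))
        except Exception as exc:
            raise RuntimeError(f"stage 'grid' failed: {exc}") from exc
        path = outdir / "loocv_grid.tsv"
        results.to_csv(path, index=False, **_TSV)
        outputs["loocv_grid"] = path
        timings["grid"] = time.perf_counter() - t0

    if _stage("classify"):
        if ds is None:
            raise RuntimeError("stage 'classify' failed: no dataset")
        t0 = time.perf_counter()
        ccfg = cfg.get("classify", {})
        spec = MlpSpec(
            hidden_units=int(ccfg.get("hidden_units", 3)), seed=seeds["classify"]
        )
        rows = []
        for contrast in ccfg.get("contrasts", [["HC", "LTLE"]]):
            base, target = contrast
            glm = regionwise_glm(ds, (base, target))
            selected = list(glm.loc[glm["selected"], "region"])
            if not selected:  # fall back to the most negative region
                selected = [glm.sort_values("coef").iloc[0]["region"]]
            mask = ds.cohort["group"].isin(contrast).to_numpy()
            feats = ds.thickness.loc[mask, selected].to_numpy(dtype=float)
            labels = (ds.cohort.loc[mask, "group"] == target).to_numpy(dtype=int)
            scores = mlp_loocv_scores(feats, labels, spec)
            roc = roc_auc(scores, labels)
            rows.append(
                {
                    "contrast": f"{base}_vs_{target}",
                    "n_regions": len(selected),
                    "regions": ";".join(selected),
                    "auc": roc.auc,
                }
            )
        path = outdir / "classification.tsv"
        pd.DataFrame(rows).to_csv(path, index=False, **_TSV)
        outputs["classification"] = path
        timings["classify"] = time.perf_counter() - t0

    manifest = {
        "version": __version__,
        "seed": seed,
        "stage_seeds": {k: v for k, v in seeds.items() if k in stages},
        "stages": stages,
        "config": cfg,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "outputs": {
            name: {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
            for name, p in outputs.items()
        },
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    for name, p in outputs.items():
        if not p.exists():
            raise RuntimeError(f"declared output '{name}' missing at run end")
    return manifest
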