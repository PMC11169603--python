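"""End-to-end pipeline orchestration with reproducibility metadata.

A single YAML config declares the stages to run (simulate -> build-pers ->
outcomes -> select -> fit -> interact -> sensitivity -> report) and their
parameters.  Each run writes its outputs plus a ``manifest.json`` recording
the config hash, seed, package version and SHA-256 digests of every stage
output, so that a rerun with the same config and seed can be verified
bit-for-bit for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from . import association_models as am
from . import exposome_scores as es
from . import outcomes as oc
from . import synthetic_cohort as sc

log = logging.getLogger("exposcore")

STAGE_ORDER = ["simulate", "build-pers", "outcomes", "select", "fit",
               "interact", "sensitivity", "report"]

_CALIBRATIONS = {
    "default": sc.default_calibration,
    "exposome_total": sc.exposome_total_calibration,
    "genome": sc.genome_calibration,
    "interaction_driver": sc.interaction_driver_calibration,
}

DEFAULTS = {
    "redundancy_threshold": 0.8,
    "cluster_k": 3,
    "selection": {"B": 1000, "threshold": 0.6},
    "fdr_alpha": 0.05,
}


def analysis_table(gen: sc.GeneratorConfig, seed: int) -> pd.DataFrame:
    """Generate a cohort and derive everything the models consume: binary
    risk indicators (prefixed ``bin_``), PERS columns and outcome columns."""
    cohort = sc.generate_cohort(gen, seed=seed)
    catalogue = sc.cohort_catalogue(gen)
    names = [s.name for s in catalogue]
    binmat = es.binarize_matrix(cohort[names], catalogue)
    pers = es.compute_pers(binmat, es.assign_domains_from_catalogue(catalogue))
    merged = pd.concat([cohort, binmat.add_prefix("bin_"), pers], axis=1)
    return oc.derive_outcomes(merged)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def model_spec_from_config(cfg: dict) -> am.ModelSpec:
    return am.ModelSpec(
        outcome=cfg["outcome"],
        predictors=tuple(cfg["predictors"]),
        covariates=tuple(cfg.get("covariates",
                                 ("age", "sex", "education")
                                 + tuple(f"pc{i + 1}" for i in range(10)))),
        interactions=tuple(tuple(i) for i in cfg.get("interactions", ())),
        forced_in=tuple(cfg["forced_in"]) if "forced_in" in cfg else None,
    )


def validate_config(cfg: dict) -> dict:
    """Schema validation; raises before any stage runs."""
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    stages = cfg.get("stages")
    if not stages:
        raise ValueError("config must declare a non-empty 'stages' list")
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}; valid: {STAGE_ORDER}")
    if [s for s in STAGE_ORDER if s in stages] != list(stages):
        raise ValueError(f"stages must follow the order {STAGE_ORDER}")
    if "simulate" in stages:
        calib = cfg.get("calibration", "default")
        if calib not in _CALIBRATIONS and not Path(str(calib)).exists():
            raise ValueError(f"unknown calibration {calib!r}")
    needs = {"build-pers": ["simulate"], "outcomes": ["simulate"],
             "select": ["build-pers", "outcomes"], "fit": ["build-pers", "outcomes"],
             "interact": ["fit"], "sensitivity": ["build-pers", "outcomes"],
             "report": ["fit"]}
    inputs = cfg.get("inputs", {})
    for stage in stages:
        for dep in needs.get(stage, []):
            if dep not in stages and dep not in inputs:
                raise ValueError(
                    f"stage {stage!r} requires stage {dep!r} or an 'inputs.{dep}' file"
                )
    if any(s in stages for s in ("select", "fit", "interact")) and "model" not in cfg:
        raise ValueError("stages select/fit/interact need a 'model' block")
    return cfg


def run_pipeline(config, out_dir, seed: int | None = None) -> dict:
    """Execute the declared stages; returns the manifest (also written to
    ``out_dir/manifest.json``).  A stage failure leaves completed outputs and
    a failure record in the manifest, then re-raises."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0)) if seed is None else int(seed)

    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest: dict = {"package_version": _pkg_version, "config_hash": cfg_hash,
                      "seed": seed, "stages": []}

    state: dict = {}
    try:
        for stage in cfg["stages"]:
            started = time.time()
            log.info("stage %s", stage)
            outputs = _run_stage(stage, cfg, state, out, seed)
            manifest["stages"].append({
                "name": stage,
                "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
                "started": started, "finished": time.time(),
            })
    except Exception as exc:
        manifest["failure"] = {"stage": stage, "error": f"{type(exc).__name__}: {exc}"}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _load_calibration(cfg: dict) -> sc.GeneratorConfig:
    calib = cfg.get("calibration", "default")
    n = int(cfg.get("n_participants", 2442))
    if calib in _CALIBRATIONS:
        return _CALIBRATIONS[calib](n)
    return sc.GeneratorConfig.from_yaml(calib)


def _run_stage(stage: str, cfg: dict, state: dict, out: Path, seed: int) -> list[Path]:
    inputs = cfg.get("inputs", {})

    if stage == "simulate":
        gen = _load_calibration(cfg)
        cohort = sc.generate_cohort(gen, seed=seed)
        state["cohort"] = cohort
        state["generator"] = gen
        p = out / "cohort.tsv"
        cohort.to_csv(p, sep="\t", index=False)
        dd = out / "data_dictionary.json"
        dd.write_text(json.dumps({
            "exposures": {k: vars(v) for k, v in gen.exposure_specs.items()},
            "prs": list(gen.prs_names),
            "covariates": ["age", "sex", "education"]
                          + [f"pc{i+1}" for i in range(gen.covariates.n_pcs)],
            "outcome": "hads_d",
        }, indent=2, default=str))
        return [p, dd]

    cohort = state.get("cohort")
    if cohort is None and "simulate" in inputs:
        cohort = pd.read_csv(inputs["simulate"], sep="\t")
        state["cohort"] = cohort

    if stage == "build-pers":
        gen = state.get("generator")
        catalogue = (sc.cohort_catalogue(gen) if gen is not None
                     else es.default_catalogue())
        names = [s.name for s in catalogue]
        binmat = es.binarize_matrix(cohort[names], catalogue)
        retained, groups, max_r = es.redundancy_filter(
            binmat, cfg.get("redundancy_threshold", DEFAULTS["redundancy_threshold"]),
            catalogue)
        corr = es.tetrachoric_matrix(binmat[retained])
        linkage, labels = es.cluster_exposures(corr, k=cfg.get("cluster_k",
                                                               DEFAULTS["cluster_k"]))
        domains = es.assign_domains(labels, catalogue)
        pers = es.compute_pers(binmat[retained], domains)
        state["binary"] = binmat
        state["pers"] = pers
        paths = []
        for name, df in [("binary_matrix.tsv", binmat), ("tetrachoric.tsv", corr),
                         ("pers.tsv", pers)]:
            p = out / name
            df.to_csv(p, sep="\t")
            paths.append(p)
        p = out / "linkage.tsv"
        pd.DataFrame(linkage, columns=["node_a", "node_b", "distance", "size"]).to_csv(
            p, sep="\t", index=False)
        paths.append(p)
        p = out / "redundancy.json"
        p.write_text(json.dumps({"retained": retained, "groups": groups,
                                 "max_residual_r": max_r,
                                 "domains": domains.domain}, indent=2))
        paths.append(p)
        return paths

    if stage == "outcomes":
        derived = oc.derive_outcomes(cohort)
        state["outcomes"] = derived
        p = out / "outcomes.tsv"
        derived.to_csv(p, sep="\t", index=False)
        return [p]

    # analysis stages operate on the merged table
    data = state.get("analysis")
    if data is None:
        base = state.get("outcomes", cohort)
        pers = state.get("pers")
        data = pd.concat([base, pers], axis=1) if pers is not None else base
        state["analysis"] = data
    spec = model_spec_from_config(cfg["model"]) if "model" in cfg else None

    if stage == "select":
        sel_cfg = {**DEFAULTS["selection"], **cfg.get("selection", {})}
        res = am.bootstrap_backward_select(data, spec, B=int(sel_cfg["B"]),
                                           retain_threshold=float(sel_cfg["threshold"]),
                                           seed=seed)
        state["selection"] = res
        p = out / "selection.tsv"
        tbl = res.frequency.rename_axis("term").reset_index()
        tbl["retained"] = tbl["retention_frequency"] >= res.threshold
        tbl.to_csv(p, sep="\t", index=False)
        return [p]

    if stage == "fit":
        fit = (am.fit_multinomial(data, spec) if spec.outcome == "severity4"
               else am.fit_binary(data, spec))
        fit = fit.with_fdr(am.fdr_adjust(fit.table["p"].to_numpy()))
        state["fit"] = fit
        p = out / "estimates.tsv"
        fit.table.to_csv(p, sep="\t", index=False)
        summary = out / "model_summary.json"
        summary.write_text(json.dumps({
            "n": fit.n, "loglik": fit.llf, "loglik_null": fit.llnull,
            "aic": fit.aic, "nagelkerke_r2": fit.nagelkerke,
            "warnings": fit.warnings_,
        }, indent=2))
        return [p, summary]

    if stage == "interact":
        gxe = am.fit_gxe(data, spec)
        gxe = gxe.with_fdr(am.fdr_adjust(gxe.table["p"].to_numpy()))
        state["gxe"] = gxe
        p = out / "gxe.tsv"
        gxe.table.to_csv(p, sep="\t", index=False)
        return [p]

    if stage == "sensitivity":
        sens_cfg = cfg["sensitivity"]
        comp_cols = sens_cfg["components"]
        d = data.copy()
        binmat = state.get("binary")
        for c in comp_cols:
            if c not in d.columns and binmat is not None:
                d[c] = binmat[c].to_numpy()
        table = am.sensitivity_leave_one_out(
            d, comp_cols, spec,
            env_term=sens_cfg.get("env_term", "pers_env"),
            level=sens_cfg.get("level", "moderate"))
        p = out / "sensitivity.tsv"
        table.to_csv(p, sep="\t", index=False)
        return [p]

    if stage == "report":
        fit = state["fit"]
        forest = fit.table[["term", "level", "or", "ci_low", "ci_high"]].copy()
        forest["q"] = fit.table.get("q", am.fdr_adjust(fit.table["p"].to_numpy()))
        p = out / "forest.tsv"
        forest.to_csv(p, sep="\t", index=False)
        return [p]

    raise AssertionError(f"unhandled stage {stage}")  # pragma: no cover
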