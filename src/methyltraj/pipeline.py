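"""End-to-end orchestration: simulate/load -> normalize -> select sites ->
embed -> cluster -> trajectory -> pseudotime -> pacemaker states -> trend
comparison -> report.

Every stage serializes its outputs as text with a header carrying the config
hash and seed; re-running with the same config is bit-identical, and a stage
whose outputs already exist is loaded instead of refitted (stage isolation).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np

from . import preprocess, serialize, trajectory as traj, trends
from .datasets import (InputError, MethylationDataset, read_dataset,
                       read_series_tsv, write_betas_tsv, write_metadata_tsv,
                       write_probes_tsv, write_series_tsv)
from .pacemaker import epm_cross_validate, epm_fit, epm_predict
from .reduce_cluster import COVARIANCE_FAMILIES, embed, fit_embedding, select_gmm
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

SPLITS = ("train", "validation", "test")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of one full run; see the CLI docs for the TOML layout."""

    simulation: Optional[SimulationConfig] = None
    betas_path: Optional[str] = None
    metadata_path: Optional[str] = None
    probes_path: Optional[str] = None
    split_fractions: Tuple[float, float, float] = (0.3, 0.1, 0.6)
    pcc_threshold: float = 0.4
    n_components: int = 2
    k_range: Tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    families: Tuple[str, ...] = COVARIANCE_FAMILIES
    curve_max_iter: int = 50
    curve_tol: float = 1e-6
    curve_span: float = 0.3
    curve_n_control: int = 100
    epm_tol: float = 1e-6
    epm_max_iter: int = 100
    epm_n_folds: int = 5
    trend_forms: Tuple[str, ...] = trends.FIVE_FORMS
    seed: int = 0
    outdir: str = "pipeline_out"

    def __post_init__(self) -> None:
        for name in ("pcc_threshold", "curve_tol", "epm_tol", "curve_span"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")

    def config_hash(self) -> str:
        """Hash over the analysis-relevant parameters (output paths excluded)."""
        fields = dataclasses.asdict(self)
        fields.pop("outdir", None)
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        if sim is not None:
            cfg.simulation = SimulationConfig(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in sim.items()})
        return cfg


def _header(config: PipelineConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed}


def _header_lines(config: PipelineConfig):
    return [f"{k}\t{v}" for k, v in _header(config).items()]


def _r2_rmse(predicted: np.ndarray, reference: np.ndarray):
    resid = predicted - reference
    rss = float(resid @ resid)
    tss = float(((reference - reference.mean()) ** 2).sum())
    r2 = 1.0 if tss == 0.0 and rss == 0.0 else 1.0 - rss / tss
    return r2, math.sqrt(rss / len(reference))


def validate_trajectory(model: traj.TrajectoryModel,
                        train: MethylationDataset,
                        validation: MethylationDataset,
                        assigned_train: np.ndarray,
                        assigned_validation: np.ndarray) -> dict:
    """R^2 / RMSE of predicted pseudotime against the assigned values."""
    out = {}
    for name, ds, assigned in (("train", train, assigned_train),
                               ("validation", validation, assigned_validation)):
        predicted = traj.predict_pseudotime(model, ds)
        r2, rmse = _r2_rmse(predicted, assigned)
        out[name] = {"r_squared": r2, "rmse": rmse}
    return out


def run_pipeline(config: PipelineConfig, write_intermediates: bool = True,
                 resume: bool = True) -> dict:
    """Execute every stage and return the run report (also saved as JSON).

    With ``resume=True`` (and intermediates enabled) a stage whose output
    files already exist under ``config.outdir`` is loaded, not recomputed.
    """
    outdir = Path(config.outdir)
    if write_intermediates:
        outdir.mkdir(parents=True, exist_ok=True)
    hdr, lines = _header(config), _header_lines(config)
    report = {"config_hash": hdr["config_hash"], "seed": config.seed,
              "stages": {}, "parameters": {
                  "pcc_threshold": config.pcc_threshold,
                  "n_components": config.n_components,
                  "k_range": list(config.k_range),
                  "families": list(config.families)}}

    def timed(stage):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:
                raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
            report["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
            return out
        return wrap

    # -- stage: cohort -------------------------------------------------------
    def cohort_stage():
        paths = {s: outdir / f"betas_{s}.tsv" for s in SPLITS}
        if (resume and write_intermediates
                and all(p.exists() for p in paths.values())
                and (outdir / "metadata.tsv").exists()):
            logger.info("cohort: reusing existing files")
            loaded_truth = None
            if (outdir / "truth_states.tsv").exists():
                from .simulate import SyntheticTruth
                ids, states = read_series_tsv(outdir / "truth_states.tsv", "state")
                loaded_truth = SyntheticTruth(
                    latent_states=states, site_intercepts=np.array([]),
                    site_rates=np.array([]), seed_used=config.seed,
                    sample_ids=ids)
            return {s: read_dataset(paths[s], outdir / "metadata.tsv",
                                    outdir / "probes.tsv") for s in SPLITS}, loaded_truth
        if config.simulation is not None:
            train, validation, test, truth = simulate_cohort(
                config.simulation, config.split_fractions)
            splits = dict(zip(SPLITS, (train, validation, test)))
        else:
            if not config.betas_path or not Path(config.betas_path).exists():
                raise InputError(f"betas file not found: {config.betas_path}")
            full = read_dataset(config.betas_path, config.metadata_path,
                                config.probes_path)
            import pandas as pd
            meta = pd.read_csv(config.metadata_path, sep="\t", comment="#")
            label = dict(zip(meta["sample_id"].astype(str), meta["split"]))
            splits = {s: full.select_samples(
                [i for i, sid in enumerate(full.sample_ids) if label[sid] == s])
                for s in SPLITS}
            truth = None
        if write_intermediates:
            sample_split = []
            ids, ages = [], []
            for s in SPLITS:
                ds = splits[s]
                write_betas_tsv(ds, outdir / f"betas_{s}.tsv", lines)
                ids += ds.sample_ids
                ages += list(ds.ages)
                sample_split += [s] * ds.n_samples
            merged = MethylationDataset(
                betas=np.zeros((1, len(ids))), sample_ids=ids, ages=ages,
                probe_ids=["x"], probe_types=np.array(["I"], dtype=object))
            write_metadata_tsv(merged, outdir / "metadata.tsv", sample_split, lines)
            write_probes_tsv(splits["train"], outdir / "probes.tsv", lines)
            if truth is not None:
                write_series_tsv(truth.sample_ids, truth.latent_states,
                                 outdir / "truth_states.tsv", "state", lines)
                import pandas as pd
                from .datasets import _write_table
                _write_table(pd.DataFrame({
                    "probe_id": truth.probe_ids,
                    "intercept": truth.site_intercepts,
                    "rate": truth.site_rates}), outdir / "truth_sites.tsv", lines)
        return splits, truth

    splits, truth = timed("cohort")(cohort_stage)

    # -- stage: normalize ----------------------------------------------------
    def normalize_stage():
        ref_path = outdir / "reference.tsv"
        norm_paths = {s: outdir / f"normalized_{s}.tsv" for s in SPLITS}
        if (resume and write_intermediates and ref_path.exists()
                and all(p.exists() for p in norm_paths.values())):
            logger.info("normalize: reusing existing files")
            return {s: read_dataset(norm_paths[s], outdir / "metadata.tsv",
                                    outdir / "probes.tsv") for s in SPLITS}
        reference = preprocess.build_reference(splits["train"])
        normalized = {s: preprocess.quantile_normalize(splits[s], reference)
                      for s in SPLITS}
        if write_intermediates:
            serialize.save_reference(reference, ref_path, lines)
            for s in SPLITS:
                write_betas_tsv(normalized[s], norm_paths[s], lines)
        return normalized

    normalized = timed("normalize")(normalize_stage)

    # -- stage: select sites -------------------------------------------------
    def select_stage():
        sel_path = outdir / "selection.tsv"
        if resume and write_intermediates and sel_path.exists():
            logger.info("select: reusing existing file")
            return serialize.load_selection(sel_path)
        pcc = preprocess.site_age_correlation(normalized["train"])
        selection = preprocess.select_sites(normalized["train"].probe_ids, pcc,
                                            config.pcc_threshold)
        if not selection.probe_ids:
            raise InputError(
                f"no sites pass |PCC| > {config.pcc_threshold}")
        if write_intermediates:
            serialize.save_selection(selection, sel_path, lines)
        return selection

    selection = timed("select")(select_stage)
    selected = {s: normalized[s].select_probes(selection.probe_ids) for s in SPLITS}
    report["n_selected_sites"] = len(selection.probe_ids)

    # -- stage: trajectory ---------------------------------------------------
    def trajectory_stage():
        model_dir = outdir / "trajectory_model"
        if resume and write_intermediates and (model_dir / "curve.tsv").exists():
            logger.info("trajectory: reusing existing model")
            return serialize.load_trajectory(model_dir)
        train = selected["train"]
        embedding = fit_embedding(train.betas, config.n_components, train.ages)
        coords = embed(embedding, train.betas)
        gmm = select_gmm(coords, config.k_range, config.families, config.seed)
        model = traj.fit_trajectory(coords, gmm, train.ages, embedding,
                                    train.probe_ids,
                                    max_iter=config.curve_max_iter,
                                    tol=config.curve_tol,
                                    span=config.curve_span,
                                    n_control=config.curve_n_control)
        if write_intermediates:
            serialize.save_trajectory(model, model_dir, hdr)
        return model

    model = timed("trajectory")(trajectory_stage)
    report["gmm"] = {"k": model.gmm.k, "family": model.gmm.family}

    # -- stage: pseudotime ---------------------------------------------------
    def pseudotime_stage():
        out = {}
        for s in SPLITS:
            path = outdir / f"pseudotime_{s}.tsv"
            if resume and write_intermediates and path.exists():
                _, values = read_series_tsv(path, "pseudotime")
                out[s] = values
                continue
            out[s] = traj.predict_pseudotime(model, selected[s])
            if write_intermediates:
                write_series_tsv(selected[s].sample_ids, out[s], path,
                                 "pseudotime", lines)
        return out

    pseudotime = timed("pseudotime")(pseudotime_stage)
    report["trajectory_fit"] = validate_trajectory(
        model, selected["train"], selected["validation"],
        pseudotime["train"], pseudotime["validation"])

    # -- stage: pacemaker ----------------------------------------------------
    def pacemaker_stage():
        epm_path = outdir / "epm_model.tsv"
        states_paths = {s: outdir / f"epm_states_{s}.tsv" for s in SPLITS}
        if (resume and write_intermediates and epm_path.exists()
                and all(p.exists() for p in states_paths.values())):
            logger.info("pacemaker: reusing existing files")
            return {s: read_series_tsv(states_paths[s], "state")[1] for s in SPLITS}
        epm = epm_fit(selected["train"], tol=config.epm_tol,
                      max_iter=config.epm_max_iter)
        states = {"train": epm.states}
        for s in ("validation", "test"):
            states[s] = epm_predict(epm, selected[s])
        cv_states = epm_cross_validate(selected["train"],
                                       n_folds=config.epm_n_folds,
                                       seed=config.seed, tol=config.epm_tol,
                                       max_iter=config.epm_max_iter)
        if write_intermediates:
            serialize.save_epm(epm, epm_path, lines)
            for s in SPLITS:
                write_series_tsv(selected[s].sample_ids, states[s],
                                 states_paths[s], "state", lines)
            write_series_tsv(selected["train"].sample_ids, cv_states,
                             outdir / "epm_states_cv.tsv", "state", lines)
        return states

    epm_states = timed("pacemaker")(pacemaker_stage)

    # -- stage: correlation & trends ----------------------------------------
    def trends_stage():
        r, p = trends.pearson_with_p(pseudotime["test"], epm_states["test"])
        result = {"pseudotime_state_pcc": {"r": r, "p": p,
                                           "p_text": trends.format_p(p)}}
        if truth is not None:
            true_states = truth.states_for(selected["test"])
            rt, pt = trends.pearson_with_p(pseudotime["test"], true_states)
            result["pseudotime_truth_pcc"] = {"r": rt, "p": pt}
        table = trends.compare_forms(selected["test"].ages, pseudotime["test"],
                                     config.trend_forms)
        result["trend_table"] = table.to_dict(orient="records")
        best = table.iloc[0]
        result["best_form"] = best["form"]
        dts = {}
        if best["form"] in ("exponential", "double_exponential") and best["coefficients"]:
            coeffs = [float(v) for v in best["coefficients"].split(",")]
            rates = [coeffs[1]] if best["form"] == "exponential" else [coeffs[1], coeffs[3]]
            for name, rate in zip(("slow", "fast"), sorted(r_ for r_ in rates if r_ > 0)):
                dts[name] = {"rate": rate,
                             "doubling_time_years": trends.doubling_time(rate)}
        result["doubling_times"] = dts
        if write_intermediates:
            from .datasets import _write_table
            _write_table(table, outdir / "trend_table.tsv", lines)
        return result

    report.update(timed("trends")(trends_stage))

    for row in report.get("trend_table", []):
        if not np.isfinite(row["aic"]):
            row["aic"] = str(row["aic"])
    if write_intermediates:
        # timings go to a sidecar so report.json is byte-identical across reruns
        with open(outdir / "timings.json", "w") as fh:
            json.dump(report["stages"], fh, indent=1, sort_keys=True)
        stable = {k: v for k, v in report.items() if k != "stages"}
        with open(outdir / "report.json", "w") as fh:
            json.dump(stable, fh, indent=1, sort_keys=True)
    return report
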