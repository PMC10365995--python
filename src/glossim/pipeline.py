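"""End-to-end orchestration: design → scenes → features → observers → stats.

A :class:`RunConfig` fixes the design, image size, observer ground truth and
seed; :func:`run_pipeline` executes the stages in order, writes all tabular
outputs as CSV/JSON under the output directory and records a manifest with
per-stage inputs, outputs, SHA-256 checksums and durations.  All randomness
is funnelled through one seeded generator per stage, so re-running the same
config reproduces every non-image statistic bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as dz
from . import features as fz
from . import stats as st
from .io import write_components
from .synthetic import ObserverModel, simulate_categorical_responses, \
    simulate_gloss_ratings, synth_scene

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("glossim.pipeline")

STAGES = ("design", "synth", "features", "observers", "stats")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    design: str = "exp2"              # built-in name or path to a spec file
    n_stimuli: int | None = None      # deterministic subsample; None = all
    image_size: int = 128
    seed: int = 0
    n_categories: int = 18
    n_factors: int = 8
    n_participants: int = 20
    n_raters: int = 12
    fa_factors: int | None = None     # None → max supported by the data
    lda_shrinkage: float = 0.1
    write_images: bool = False
    out_dir: str = "glossim_run"
    feature_config: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(manifest, name, t0, inputs, outputs, **extra):
    entry = {
        "stage": name,
        "inputs": inputs,
        "outputs": [str(p) for p in outputs],
        "checksums": {Path(p).name: _sha256(Path(p)) for p in outputs
                      if Path(p).is_file()},
        "duration_s": round(time.monotonic() - t0, 3),
    }
    entry.update(extra)
    manifest["stages"].append(entry)
    log.info("[%s] done in %.2fs", name, entry["duration_s"])


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": []}
    rng = np.random.default_rng(config.seed)
    stage_seeds = {name: int(s) for name, s in
                   zip(STAGES, rng.integers(0, 2**31 - 1, size=len(STAGES)))}

    try:
        # ---- design ------------------------------------------------------
        t0 = time.monotonic()
        if config.design in dz.BUILTIN_DESIGNS:
            spec = dz.builtin_design(config.design)
        else:
            from .io import load_design
            spec = load_design(config.design)
        cells = dz.enumerate_design(spec)
        if config.n_stimuli is not None and config.n_stimuli < len(cells):
            idx = np.sort(np.random.default_rng(stage_seeds["design"]).choice(
                len(cells), size=config.n_stimuli, replace=False))
            cells = [cells[i] for i in idx]
        design_csv = out / "design.csv"
        pd.DataFrame([c.to_dict() for c in cells]).to_csv(design_csv, index=False)
        _stage(manifest, "design", t0, {"design": config.design},
               [design_csv], n_stimuli=len(cells))

        # ---- synth -------------------------------------------------------
        t0 = time.monotonic()
        size = (config.image_size, config.image_size)
        scenes = [synth_scene(c, size=size, seed=stage_seeds["synth"] + i)
                  for i, c in enumerate(cells)]
        outputs = []
        if config.write_images:
            for i, sc in enumerate(scenes):
                write_components(sc, out / "scenes" / f"stim{i:04d}")
            outputs = sorted((out / "scenes").glob("*/meta.json"))
        _stage(manifest, "synth", t0, {"n": len(scenes), "size": list(size)},
               outputs)

        # ---- features ----------------------------------------------------
        t0 = time.monotonic()
        fcfg = fz.FeatureConfig(**config.feature_config)
        rows = [fz.feature_vector(sc, fcfg).to_dict() for sc in scenes]
        feats = pd.DataFrame(rows)
        feats.insert(0, "stimulus", np.arange(len(feats)))
        features_csv = out / "features.csv"
        feats.to_csv(features_csv, index=False)
        _stage(manifest, "features", t0, {"n": len(feats)}, [features_csv])

        # ---- observers ---------------------------------------------------
        t0 = time.monotonic()
        obs_rng = np.random.default_rng(stage_seeds["observers"])
        Fz = feats[fz.FEATURE_COLUMNS].to_numpy(dtype=float)
        sd = Fz.std(axis=0)
        Fz = (Fz - Fz.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        # Latent stimulus scores: a random linear readout of the measured
        # features plus independent factor noise, so the simulated observers
        # carry genuine feature-driven structure.
        W = obs_rng.normal(size=(Fz.shape[1], config.n_factors))
        scores = Fz @ W / np.sqrt(Fz.shape[1])
        scores += 0.3 * obs_rng.normal(size=scores.shape)
        from .synthetic import make_observer_loadings
        loadings = make_observer_loadings(config.n_categories, config.n_factors,
                                          seed=stage_seeds["observers"])
        model = ObserverModel(loadings=loadings, temperature=0.5,
                              seed=stage_seeds["observers"])
        responses = simulate_categorical_responses(
            scores, model, config.n_participants)
        ratings, mean_ratings = simulate_gloss_ratings(
            feats.set_index("stimulus"), model, config.n_raters)
        responses_csv = out / "responses.csv"
        ratings_csv = out / "ratings.csv"
        responses.to_csv(responses_csv, index=False)
        ratings.to_csv(ratings_csv, index=False)
        _stage(manifest, "observers", t0,
               {"n_participants": config.n_participants,
                "n_raters": config.n_raters},
               [responses_csv, ratings_csv])

        # ---- stats -------------------------------------------------------
        t0 = time.monotonic()
        outputs, computed = _stats_stage(config, out, feats, responses,
                                         ratings, mean_ratings, cells)
        _stage(manifest, "stats", t0, {}, outputs, computed=computed)
    except Exception as exc:
        failed = STAGES[len(manifest["stages"])]
        manifest["failed_stage"] = failed
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _stats_stage(config, out, feats, responses, ratings, mean_ratings, cells):
    outputs, computed = [], []
    feature_cols = fz.FEATURE_COLUMNS

    profiles = st.build_profiles(responses)
    profiles_csv = out / "profiles.csv"
    profiles.to_csv(profiles_csv)
    outputs.append(profiles_csv)
    computed.append("profiles")

    # FA needs non-degenerate category columns; drop never-chosen ones.
    live = profiles.loc[:, profiles.std(axis=0) > 0]
    m_cap = min(st.max_factors(live.shape[1]) if live.shape[1] >= 2 else 0,
                live.shape[0] - 2, config.n_factors)
    m = m_cap if config.fa_factors is None else min(config.fa_factors, m_cap)
    solution = None
    if m >= 1:
        solution = st.fit_factor_model(live, m)
        fa_json = out / "factor_solution.json"
        fa_json.write_text(json.dumps({
            "loadings": solution.loadings.round(6).to_dict(),
            "shared_variance": solution.shared_variance.round(6).to_dict(),
            "cumulative_shared_variance":
                solution.cumulative_shared_variance.round(6).to_dict(),
            "negative_factor": solution.negative_factor,
            "n_dimensions": solution.n_dimensions,
            "flags": solution.flags,
        }, indent=2))
        scores_csv = out / "factor_scores.csv"
        scores = solution.scores.copy()
        scores["dimension"] = solution.assignments
        scores.to_csv(scores_csv)
        outputs += [fa_json, scores_csv]
        computed.append("factor_analysis")

    summary = {}
    reg = st.fit_gloss_regression(feats[feature_cols],
                                  mean_ratings.reindex(feats["stimulus"]))
    summary["gloss_regression"] = {
        "r_squared": reg.r_squared, "f_value": reg.f_value,
        "df_model": reg.df_model, "df_resid": reg.df_resid,
        "coef": reg.params.round(6).to_dict(),
    }
    computed.append("gloss_regression")

    wide = ratings.pivot(index="participant", columns="stimulus", values="rating")
    median_r, loo_r2, agr_flags = st.intersubject_agreement(wide)
    summary["agreement"] = {"median_r": median_r, "loo_r2": loo_r2,
                            "flags": agr_flags}
    computed.append("agreement")

    if len(profiles) >= 3:
        summary["rsa"] = {"spearman": st.rsa(
            profiles, feats.set_index("stimulus")[feature_cols])}
        computed.append("rsa")

    if solution is not None:
        cond = [f"{c.shape}|{c.light_field}" for c in cells]
        dims = solution.assignments.to_numpy()
        ok = dims != st.UNASSIGNED
        feasible = len(np.unique(dims[ok])) >= 2 and len(np.unique(cond)) >= 2
        if feasible:
            try:
                lda = st.lda_loco(
                    feats.loc[ok, feature_cols], dims[ok],
                    np.asarray(cond)[ok], shrinkage=config.lda_shrinkage)
                summary["lda_loco"] = {
                    "overall_accuracy": lda.overall_accuracy,
                    "fold_accuracy": lda.fold_accuracy.round(4).to_dict(),
                    "flags": lda.flags,
                }
                computed.append("lda_loco")
            except ValueError as exc:
                summary["lda_loco"] = {"skipped": str(exc)}
        gloss_vec = mean_ratings.reindex(feats["stimulus"]).to_numpy()
        try:
            med = st.compare_mediation_models(
                feats[feature_cols], gloss_vec, solution.scores)
            med_csv = out / "mediation.csv"
            med.to_csv(med_csv)
            outputs.append(med_csv)
            computed.append("mediation")
        except ValueError as exc:
            summary["mediation"] = {"skipped": str(exc)}

    summary_json = out / "stats_summary.json"
    summary_json.write_text(json.dumps(summary, indent=2))
    outputs.append(summary_json)
    return outputs, computed
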