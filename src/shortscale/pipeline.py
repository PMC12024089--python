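"""End-to-end orchestration: simulate/load -> split -> abbreviate -> validate -> screen.

All randomness is funneled through named seeds in :class:`RunConfig`; a run
writes a manifest recording the config, package version, input digests and
every output path, so identical configs reproduce identical artifacts
(timestamps aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .abbreviate import predict_subscales, sweep_and_select
from .core import (
    ResponseMatrix,
    ValidationError,
    gsi_scores,
    label_high_risk,
    read_responses,
    split_train_test,
    write_responses,
)
from .fixtures import scl90_bank
from .psychometrics import cfa_one_factor, cronbach_alpha, efa, mcdonald_omega, split_half
from .screening import default_classifier_specs, nested_cv_evaluate, train_final
from .simulate import generate_responses, scl90_like_spec


@dataclass
class RunConfig:
    """Named seeds, stage parameters and paths for a full pipeline run."""

    n: int = 4808
    responses_path: str = None  # when given, skip simulation
    simulation_seed: int = 7
    split_seed: int = 11
    cv_seed: int = 13
    validation_seed: int = 17
    test_fraction: float = 0.2
    stop_r: float = 0.96
    k_max: int = 30
    method: str = "ols"
    models: tuple = ("logistic", "gbdt", "adaboost")
    n_outer: int = 10
    n_inner: int = 5
    screening_sample: int = None  # cap rows entering the CV bench

    def __post_init__(self):
        if not 0 < self.stop_r <= 1:
            raise ValidationError(f"stop_r must be in (0, 1], got {self.stop_r}")
        if not 0 < self.test_fraction < 1:
            raise ValidationError("test_fraction must be in (0, 1)")
        if self.k_max < 1:
            raise ValidationError("k_max must be >= 1")
        self.models = tuple(self.models)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full pipeline and return the manifest dict.

    Artifacts: ``responses.csv`` (if simulated), ``scale.json``,
    ``trace.csv``, ``report.json``, ``cv.json``, ``model.joblib`` (+ JSON
    sidecar) and ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": config.to_dict(),
                "stages": {}, "outputs": {}}
    bank = scl90_bank()

    stage = "data"
    try:
        if config.responses_path:
            responses = read_responses(config.responses_path)
            manifest["stages"][stage] = {"source": str(config.responses_path),
                                         "sha256": _digest(config.responses_path)}
        else:
            spec = scl90_like_spec(bank=bank)
            responses = generate_responses(spec, config.n, config.simulation_seed)
            path = out / "responses.csv"
            write_responses(responses, path)
            manifest["outputs"]["responses"] = str(path)
            manifest["stages"][stage] = {"simulated_n": responses.n,
                                         "seed": config.simulation_seed}

        stage = "split"
        train, test = split_train_test(responses, config.test_fraction,
                                       config.split_seed)
        manifest["stages"][stage] = {"n_train": train.n, "n_test": test.n,
                                     "seed": config.split_seed}

        stage = "abbreviate"
        scale, trace = sweep_and_select(train, test, bank,
                                        stop_r=config.stop_r,
                                        k_max=config.k_max,
                                        method=config.method)
        scale_path = out / "scale.json"
        scale_path.write_text(json.dumps({
            "item_ids": [str(i) for i in scale.item_ids],
            "k": scale.k, "stop_r": scale.stop_threshold,
            "met_threshold": scale.met_threshold,
            "rmse": scale.achieved_metrics.rmse,
            "r2": scale.achieved_metrics.r2,
            "pearson_r": scale.achieved_metrics.pearson_r,
        }, indent=2))
        trace_path = out / "trace.csv"
        trace.to_csv(trace_path)
        manifest["outputs"]["scale"] = str(scale_path)
        manifest["outputs"]["trace"] = str(trace_path)
        manifest["stages"][stage] = {"k": scale.k,
                                     "met_threshold": scale.met_threshold}

        stage = "validate"
        items = list(scale.item_ids)
        subset = responses.subset(items)
        alpha = cronbach_alpha(subset) if len(items) >= 2 else None
        half_a, half_b = split_half(subset, seed=config.validation_seed)
        efa_solution = efa(half_a)
        report = {
            "alpha": alpha,
            "efa_eigenvalues": efa_solution.eigenvalues.tolist(),
            "n_factors_kaiser": efa_solution.n_factors_kaiser,
            "efa_loadings": efa_solution.loadings[:, 0].tolist(),
        }
        if len(items) >= 3:
            cfa = cfa_one_factor(half_b)
            report.update({
                "omega": None if cfa.heywood else mcdonald_omega(cfa),
                "cfa_loadings": cfa.loadings.tolist(),
                "chi_square": cfa.chi_square, "df": cfa.df,
                "srmr": cfa.srmr, "rmsea": cfa.rmsea,
                "cfi": cfa.cfi, "tli": cfa.tli, "heywood": cfa.heywood,
            })
        subscale_metrics = predict_subscales(train, test, items, bank,
                                             method=config.method)
        report["subscale_prediction"] = subscale_metrics.to_dict(orient="records")
        report_path = out / "report.json"
        report_path.write_text(json.dumps(report, indent=2))
        manifest["outputs"]["report"] = str(report_path)
        manifest["stages"][stage] = {"alpha": alpha}

        stage = "screen"
        y_train_gsi = gsi_scores(train)
        norms = (float(np.mean(y_train_gsi)), float(np.std(y_train_gsi, ddof=1)))
        labeling = label_high_risk(gsi_scores(train), *norms)
        features = train.subset(items)
        if config.screening_sample and config.screening_sample < features.n:
            rng = np.random.default_rng(config.cv_seed)
            idx = np.sort(rng.choice(features.n, config.screening_sample,
                                     replace=False))
            features = ResponseMatrix(features.values[idx], features.item_ids,
                                      [features.respondent_ids[i] for i in idx])
            labels = labeling.labels[idx]
        else:
            labels = labeling.labels
        specs = [s for s in default_classifier_specs()
                 if s.family in config.models]
        cv_results = nested_cv_evaluate(features, labels, specs,
                                        seed=config.cv_seed,
                                        n_outer=config.n_outer,
                                        n_inner=config.n_inner)
        cv_payload = {}
        for family, res in cv_results.items():
            cv_payload[family] = {
                "summary": res.summary.to_dict(orient="index"),
                "auroc": res.auroc, "auprc": res.auprc, "brier": res.brier,
                "fold_assignments_digest": hashlib.sha256(
                    np.ascontiguousarray(res.oof_probs).tobytes()).hexdigest(),
            }
        cv_path = out / "cv.json"
        cv_path.write_text(json.dumps(cv_payload, indent=2))
        manifest["outputs"]["cv"] = str(cv_path)

        best_family = max(cv_payload,
                          key=lambda f: cv_payload[f]["summary"]["f1"]["mean"])
        best_spec = next(s for s in specs if s.family == best_family)
        final = train_final(features, labels, best_spec, seed=config.cv_seed,
                            item_ids=items, norm_mean=norms[0], norm_sd=norms[1])
        model_path = out / "model.joblib"
        final.save(model_path)
        manifest["outputs"]["model"] = str(model_path)
        manifest["stages"][stage] = {"best_family": best_family}
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    manifest["completed"] = True
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
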