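"""End-to-end pipeline: one configuration in, a reproducible artifact
directory out.

Stage order mirrors the study workflow: cohort (generate or load) ->
subject selection -> eTIV normalization -> stratified split -> training-set
standardization -> RF-importance feature selection -> data valuation ->
exclusion-curve experiments with cutoff rules -> Kernel SHAP
interpretation.  No stage reads data from a later stage; validation and
test rows never influence feature selection, and valuation sees validation
labels only through the validation-accuracy payoff.

A single root seed expands deterministically into per-stage seeds, so a
rerun with the same configuration reproduces every artifact exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, schema
from .cohort import (
    apply_selection_criteria,
    etiv_normalize,
    fit_standardizer,
    stratified_split,
)
from .exclusion import (
    exclusion_curve,
    rank_and_exclude,
    select_cutoff,
    train_and_eval,
    zero_cutoff,
)
from .features import (
    assemble_model_matrix,
    mean_threshold_filter,
    rf_importance_rank,
)
from .interpret import KernelConfig, explain_valuations, force_data, kernel_shap, summarize
from .synthetic import (
    GeneratorConfig,
    generate_feature_table,
    generate_visit_table,
    plant_label_noise,
)
from .valuation import (
    ModelSpec,
    PerformanceFunction,
    ValuationConfig,
    loo_valuation,
    tmc_shapley_averaged,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("mcishapley")

_STAGES = (
    "cohort",
    "selection",
    "split",
    "feature_selection",
    "valuation",
    "classifiers",
    "interpretation",
)


@dataclass
class RunConfig:
    """Full workflow configuration (YAML/JSON-serialisable).

    Either ``generator`` (synthetic cohort) or ``visits_csv``/
    ``features_csv`` paths must be given — not both.
    """

    generator: GeneratorConfig | None = None
    visits_csv: str | None = None
    features_csv: str | None = None

    split_fractions: tuple[float, float, float] = (0.65, 0.15, 0.20)
    valuation_method: str = "tmc"  # "tmc" or "loo"
    valuation_model: str = "logistic"  # base classifier for the payoff
    n_iterations: int = 4
    tolerance: float = 0.01
    err: float = 0.1
    save_every: int = 100
    max_permutations: int = 1000

    classifier: str = "random-forest"  # final classifier family
    grid_step: int = 10
    grid: list[int] | None = None
    n_repetitions: int = 10

    explain: bool = True
    n_explain: int = 20
    n_coalition_samples: int = 3000
    max_background: int = 100

    seed: int = 0

    def validate(self) -> None:
        using_files = self.visits_csv is not None or self.features_csv is not None
        if self.generator is not None and using_files:
            raise ValueError("specify either a generator or input CSV paths, not both")
        if self.generator is None and not (self.visits_csv and self.features_csv):
            raise ValueError("need a generator config or both input CSV paths")
        if self.valuation_method not in ("tmc", "loo"):
            raise ValueError("valuation_method must be 'tmc' or 'loo'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("generator") is not None:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        if "split_fractions" in d:
            d["split_fractions"] = tuple(d["split_fractions"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)

    def stage_seeds(self) -> dict[str, int]:
        """Expand the root seed into one deterministic seed per stage."""
        ss = np.random.SeedSequence(self.seed)
        states = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(len(_STAGES))]
        return dict(zip(_STAGES, states))


def _model_columns() -> list[str]:
    return schema.volumetric_columns() + list(schema.CLINICAL_FEATURES)


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run every stage and persist all artifacts under ``outdir``.

    Writes the selection report, split assignment, importance table,
    valuation result, exclusion curves, cutoff table, explanation
    summaries, and a manifest (config hash, per-stage seeds, version).
    Idempotent for a fixed configuration.  On a stage failure the partial
    manifest records the failed stage before the error propagates.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    manifest: dict = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "version": __version__,
        "stage_seeds": seeds,
        "artifacts": [],
        "completed_stages": [],
    }

    def checkpoint(stage: str) -> None:
        manifest["completed_stages"].append(stage)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    def artifact(name: str) -> Path:
        manifest["artifacts"].append(name)
        return outdir / name

    current = "cohort"
    try:
        # -- cohort -------------------------------------------------------
        logger.info("stage cohort")
        if config.generator is not None:
            visits = generate_visit_table(config.generator)
        else:
            visits = pd.read_csv(config.visits_csv)
        checkpoint("cohort")

        # -- selection ----------------------------------------------------
        current = "selection"
        logger.info("stage selection")
        labels, report = apply_selection_criteria(visits)
        report.to_json(artifact("selection_report.json"))
        artifact("selection_report.txt").write_text(str(report) + "\n")

        flipped: list = []
        if config.generator is not None:
            features = generate_feature_table(config.generator, labels)
            if config.generator.label_noise_fraction > 0:
                noisy, flipped = plant_label_noise(
                    labels, config.generator.label_noise_fraction, seeds["selection"]
                )
                labels = noisy
                features[schema.LABEL_COLUMN] = labels.loc[
                    features[schema.SUBJECT_ID]
                ].to_numpy()
        else:
            features = pd.read_csv(config.features_csv)
            features = features[features[schema.SUBJECT_ID].isin(labels.index)]
            labels = labels.loc[features[schema.SUBJECT_ID]]
        features = etiv_normalize(features)
        checkpoint("selection")

        # -- split + standardization ---------------------------------------
        current = "split"
        logger.info("stage split")
        split = stratified_split(labels, config.split_fractions, seeds["split"])
        split.to_frame().to_csv(artifact("split.csv"), index=False)

        matrix = features.set_index(schema.SUBJECT_ID)
        from .features import encode_clinical

        matrix = encode_clinical(matrix)[_model_columns()]
        standardizer = fit_standardizer(matrix.loc[split.ids("train")])
        matrix = standardizer.transform(matrix)
        parts = {p: matrix.loc[split.ids(p)] for p in ("train", "valid", "test")}
        ylab = {p: labels.loc[split.ids(p)] for p in ("train", "valid", "test")}
        checkpoint("split")

        # -- feature selection ---------------------------------------------
        current = "feature_selection"
        logger.info("stage feature_selection")
        mri_cols = schema.volumetric_columns()
        importances = rf_importance_rank(
            parts["train"][mri_cols], ylab["train"], seeds["feature_selection"]
        )
        importances.to_csv(artifact("importances.csv"), index=False)
        selected = mean_threshold_filter(importances)
        X = {
            p: assemble_model_matrix(parts[p].reset_index(), selected)
            for p in parts
        }
        checkpoint("feature_selection")

        # -- valuation -------------------------------------------------------
        current = "valuation"
        logger.info("stage valuation (%s)", config.valuation_method)
        perf = PerformanceFunction(
            X["train"], ylab["train"], X["valid"], ylab["valid"],
            ModelSpec(config.valuation_model, seeds["valuation"]),
        )
        if config.valuation_method == "loo":
            result = loo_valuation(list(X["train"].index), perf)
        else:
            vconf = ValuationConfig(
                n_iterations=config.n_iterations,
                tolerance=config.tolerance,
                err=config.err,
                save_every=config.save_every,
                max_permutations=config.max_permutations,
                seed=seeds["valuation"],
            )
            result = tmc_shapley_averaged(list(X["train"].index), perf, vconf)
        result.to_csv(artifact(f"valuation_{config.valuation_method}.csv"))
        result.to_json(artifact(f"valuation_{config.valuation_method}.json"))
        values = pd.Series(result.values, index=result.subjects)
        checkpoint("valuation")

        # -- classifiers / exclusion experiments ----------------------------
        current = "classifiers"
        logger.info("stage classifiers (%s)", config.classifier)
        spec = ModelSpec(config.classifier, seeds["classifiers"])
        rep_seeds = [seeds["classifiers"] + r for r in range(config.n_repetitions)]
        eval_sets = {
            "valid": (X["valid"], ylab["valid"]),
            "test": (X["test"], ylab["test"]),
        }
        grid = config.grid
        if grid is None:
            grid = list(range(0, int(0.9 * len(X["train"])) + 1, config.grid_step))
        curves = []
        for strategy, vals in (
            ("random", None),
            (config.valuation_method, values),
        ):
            curves.append(
                exclusion_curve(
                    strategy, X["train"], ylab["train"], eval_sets, spec,
                    grid=grid, values=vals, repetition_seeds=rep_seeds,
                    random_seed=seeds["classifiers"],
                )
            )
        curve = pd.concat(curves, ignore_index=True)
        curve.to_csv(artifact("exclusion_curves.csv"), index=False)

        ranked = curve[curve["strategy"] == config.valuation_method]
        cutoffs = []
        for rule, eval_set in (("max-valid", "valid"), ("max-test", "test")):
            res = select_cutoff(ranked[ranked["eval_set"] == eval_set], rule)
            cutoffs.append(dataclasses.asdict(res))
        n_zero = zero_cutoff(values)
        if 0 <= n_zero < len(values):
            retained = rank_and_exclude(values, n_zero)
            zc = train_and_eval(
                X["train"].loc[retained], ylab["train"].loc[retained],
                X["test"], ylab["test"], spec, rep_seeds,
            )
            cutoffs.append(
                {
                    "rule": "zero-cutoff",
                    "n_excluded": n_zero,
                    "mean_acc": zc["acc_mean"],
                    "mean_f1": zc["f1_mean"],
                    "optimistic": False,
                }
            )
        pd.DataFrame(cutoffs).to_csv(artifact("cutoffs.csv"), index=False)
        checkpoint("classifiers")

        # -- interpretation ---------------------------------------------------
        current = "interpretation"
        if config.explain:
            logger.info("stage interpretation")
            kconf = KernelConfig(
                n_coalition_samples=config.n_coalition_samples,
                max_background=config.max_background,
                seed=seeds["interpretation"],
            )
            base = spec.build(seeds["interpretation"])
            classes = sorted(ylab["train"].unique())
            y_int = ylab["train"].map({c: k for k, c in enumerate(classes)})
            base.fit(X["train"].to_numpy(dtype=float), y_int.to_numpy())
            pos = classes.index(schema.POSITIVE_CLASS)

            def predict_prob(rows):
                return base.predict_proba(np.asarray(rows, dtype=float))[:, pos]

            pooled = pd.concat([X["train"], X["test"]])
            rng = np.random.default_rng(seeds["interpretation"])
            explain_ids = list(
                rng.choice(pooled.index.to_numpy(),
                           size=min(config.n_explain, len(pooled)), replace=False)
            )
            bg = X["train"].to_numpy(dtype=float)
            if len(bg) > kconf.max_background:
                bg = bg[rng.choice(len(bg), size=kconf.max_background, replace=False)]
            explanations = [
                kernel_shap(predict_prob, bg,
                            pooled.loc[i].to_numpy(dtype=float), kconf,
                            feature_names=list(pooled.columns))
                for i in explain_ids
            ]
            norm_cols = selected + list(schema.COGNITIVE_FEATURES)
            summary = summarize(explanations, normalize_columns=norm_cols)
            summary.importance.to_csv(artifact("shap_importance.csv"), index=False)
            summary.points.to_csv(artifact("shap_points.csv"), index=False)
            force_data(explanations[0]).to_csv(
                artifact("force_first_subject.csv"), index=False
            )

            per_group = explain_valuations(
                X["train"], values, ylab["train"], kconf,
                model_seed=seeds["interpretation"],
                normalize_columns=norm_cols,
            )
            for group, summ in per_group.items():
                summ.importance.to_csv(
                    artifact(f"valuation_explanation_{group}.csv"), index=False
                )
        checkpoint("interpretation")
    except Exception:
        manifest["failed_stage"] = current
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        logger.exception("pipeline aborted in stage %s", current)
        raise

    manifest["flipped_subjects"] = list(flipped)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
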