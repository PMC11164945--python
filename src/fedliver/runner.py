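"""Config-driven orchestration of the full simulation study.

Pipeline: generate cohort -> patient-level test split -> partition the
training pool into simulated sites -> federated training across a grid of
(partition strategy x algorithm x epoch schedule x trial) -> evaluation on
the shared test set -> tabular reports:

* ``results.csv`` — one row per grid cell with final AUC (+ jackknife CI)
  and the five confusion metrics, the strategy-by-algorithm grid;
* ``rounds.csv`` — per-round accuracy/AUC curves;
* ``imbalance.csv`` — the global-imbalance x local-heterogeneity grid
  (s0_fraction, alpha, weighted cosine similarity, accuracy, AUC).

Two profiles share the code path and differ only in configuration: ``paper``
(128x128 inputs, VGG16-style net, 100/20 rounds) and ``tiny`` (32x32 inputs,
three-conv-block net, reduced rounds) for desk-scale runs.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import evalstats, fedsim, partition as part
from .model import PreprocessSpec, TrainConfig, preprocess
from .synthdata import (
    CohortConfig,
    Demographics,
    PatientRecord,
    SplitResult,
    generate_cohort,
    make_test_split,
    render_patient_images,
)

STRATEGIES = (
    "dirichlet_class",
    "quantity_class",
    "dirichlet_quantity",
    "source_based",
    "imbalance_scenario",
)


@dataclass(frozen=True)
class PartitionSpec:
    """Declarative description of one partitioning scenario."""

    strategy: str
    n_sites: int = 2
    beta: float = 2.0
    classes_per_site: int = 1
    alpha: float = 1.0
    s0_fraction: float = 0.5
    total_patients: int = 84

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if not 0 < self.s0_fraction < 1:
            raise ValueError("s0_fraction must be in (0, 1)")


def build_partition(
    pool: list[PatientRecord], spec: PartitionSpec, seed: int = 0
) -> list[part.SitePartition]:
    """Dispatch a PartitionSpec to the corresponding strategy."""
    if spec.strategy == "dirichlet_class":
        return part.dirichlet_class_partition(pool, spec.n_sites, spec.beta, seed)
    if spec.strategy == "quantity_class":
        return part.quantity_class_partition(pool, spec.n_sites, spec.classes_per_site)
    if spec.strategy == "dirichlet_quantity":
        return part.dirichlet_quantity_partition(pool, spec.n_sites, spec.beta, seed)
    if spec.strategy == "source_based":
        return part.source_partition(pool)
    return part.imbalance_scenario(
        pool, spec.total_patients, spec.s0_fraction, spec.alpha, spec.n_sites, seed
    )


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one full study run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_test_per_site: int = 10
    scenarios: list[PartitionSpec] = field(
        default_factory=lambda: [
            PartitionSpec("dirichlet_class", beta=2.0),
            PartitionSpec("quantity_class", classes_per_site=1),
            PartitionSpec("dirichlet_quantity", beta=2.0),
            PartitionSpec("source_based"),
        ]
    )
    algorithms: list[str] = field(default_factory=lambda: list(fedsim.ALGORITHMS))
    epoch_schedules: list[tuple[int, int]] = field(
        default_factory=lambda: [(1, 100), (5, 20)]
    )
    imbalance_s0_fractions: list[float] = field(
        default_factory=lambda: [0.1, 0.2, 0.3, 0.4, 0.5]
    )
    imbalance_alphas: list[float] = field(
        default_factory=lambda: [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
    )
    imbalance_rounds: int = 50
    imbalance_local_epochs: int = 1
    imbalance_total_patients: int = 84
    trials: int = 3
    trial_seeds: list[int] | None = None
    train: TrainConfig = field(default_factory=TrainConfig)
    preprocess_size: tuple[int, int] = (128, 128)
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if self.trial_seeds is None:
            self.trial_seeds = [self.seed + 1000 * (t + 1) for t in range(self.trials)]

    # -- profiles -----------------------------------------------------------
    @classmethod
    def paper_profile(cls, seed: int = 0, output_dir: str = "results") -> "ExperimentConfig":
        return cls(
            cohort=CohortConfig.default(seed=seed),
            train=TrainConfig(arch="vgg16_like", input_size=(128, 128), learning_rate=1e-4),
            preprocess_size=(128, 128),
            seed=seed,
            output_dir=output_dir,
        )

    @classmethod
    def tiny_profile(cls, seed: int = 0, output_dir: str = "results") -> "ExperimentConfig":
        """Desk-scale study conditions: same cohort structure, 64x64 rendered
        images downsized to 32x32, the three-conv-block net, reduced rounds."""
        return cls(
            cohort=CohortConfig.tiny(seed=seed, size=64, images_per_patient=5),
            train=TrainConfig(arch="tiny", input_size=(32, 32), learning_rate=1e-3),
            preprocess_size=(32, 32),
            epoch_schedules=[(1, 20), (5, 5)],
            imbalance_rounds=10,
            seed=seed,
            output_dir=output_dir,
        )

    # -- (de)serialization --------------------------------------------------
    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_config_to_dict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return _config_from_dict(raw, path)


def _config_to_dict(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["cohort"]["demographics"] = {
        k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
        for k, v in cfg.cohort.demographics.items()
    }
    d["epoch_schedules"] = [list(s) for s in cfg.epoch_schedules]
    return d


def _config_from_dict(raw: dict, path: str = "<config>") -> ExperimentConfig:
    try:
        cohort_raw = dict(raw.get("cohort", {}))
        if "demographics" in cohort_raw:
            cohort_raw["demographics"] = {
                k: Demographics(**v) for k, v in cohort_raw["demographics"].items()
            }
        if "per_site_grade_counts" in cohort_raw:
            cohort_raw["per_site_grade_counts"] = {
                k: tuple(v) for k, v in cohort_raw["per_site_grade_counts"].items()
            }
        if "image_sizes" in cohort_raw:
            cohort_raw["image_sizes"] = {
                k: tuple(v) for k, v in cohort_raw["image_sizes"].items()
            }
        train_raw = dict(raw.get("train", {}))
        for key in ("adam_betas", "input_size"):
            if key in train_raw:
                train_raw[key] = tuple(train_raw[key])
        return ExperimentConfig(
            cohort=CohortConfig(**cohort_raw),
            n_test_per_site=raw.get("n_test_per_site", 10),
            scenarios=[PartitionSpec(**s) for s in raw.get("scenarios", [])]
            or ExperimentConfig().scenarios,
            algorithms=list(raw.get("algorithms", fedsim.ALGORITHMS)),
            epoch_schedules=[tuple(s) for s in raw.get("epoch_schedules", [(1, 100), (5, 20)])],
            imbalance_s0_fractions=list(raw.get("imbalance_s0_fractions", [0.1, 0.2, 0.3, 0.4, 0.5])),
            imbalance_alphas=list(raw.get("imbalance_alphas", [0.0, 0.2, 0.4, 0.6, 0.8, 1.0])),
            imbalance_rounds=raw.get("imbalance_rounds", 50),
            imbalance_local_epochs=raw.get("imbalance_local_epochs", 1),
            imbalance_total_patients=raw.get("imbalance_total_patients", 84),
            trials=raw.get("trials", 3),
            trial_seeds=raw.get("trial_seeds"),
            train=TrainConfig(**train_raw),
            preprocess_size=tuple(raw.get("preprocess_size", (128, 128))),
            seed=raw.get("seed", 0),
            output_dir=raw.get("output_dir", "results"),
        )
    except (TypeError, ValueError, KeyError) as exc:
        raise ValueError(f"malformed experiment config {path}: {exc}") from exc


class Dataset:
    """Renders, preprocesses and caches per-patient image tensors."""

    def __init__(self, cohort_config: CohortConfig, preprocess_size: tuple[int, int]):
        self.cohort_config = cohort_config
        self.spec = PreprocessSpec(target_size=tuple(preprocess_size))
        self._cache: dict[str, list[np.ndarray]] = {}

    def patient_tensors(self, patient: PatientRecord) -> list[np.ndarray]:
        if patient.patient_id not in self._cache:
            self._cache[patient.patient_id] = [
                preprocess(im, self.spec)
                for im in render_patient_images(patient, self.cohort_config)
            ]
        return self._cache[patient.patient_id]

    def materialize(
        self, patients: list[PatientRecord]
    ) -> tuple[np.ndarray, np.ndarray]:
        X, y = [], []
        for p in patients:
            t = self.patient_tensors(p)
            X.extend(t)
            y.extend([p.label] * len(t))
        if not X:
            return np.empty((0, *self.spec.target_size, 3), dtype=np.float32), np.empty(0, int)
        return np.stack(X), np.asarray(y, dtype=int)

    def scoreset(
        self, patients: list[PatientRecord], probs: np.ndarray
    ) -> evalstats.ScoreSet:
        groups = [
            p.patient_id for p in patients for _ in self.patient_tensors(p)
        ]
        labels = [p.label for p in patients for _ in self.patient_tensors(p)]
        return evalstats.ScoreSet(probs, np.asarray(labels), np.asarray(groups))


@dataclass
class ScenarioResult:
    scenario: str
    algorithm: str
    local_epochs: int
    rounds: int
    weighted_cs: float
    trial_aucs: list[float]
    trial_reports: list[evalstats.MetricReport]
    mean_auc: float
    auc_ci: tuple[float, float, float]  # jackknife estimate, lo, hi (trial 1)
    round_logs: list[list[fedsim.RoundLog]]
    test_scores: list[np.ndarray]


def _evaluate_final(
    dataset: Dataset,
    test_patients: list[PatientRecord],
    network,
    weights,
) -> tuple[np.ndarray, evalstats.MetricReport]:
    X, _ = dataset.materialize(test_patients)
    network.set_weights(weights)
    probs = network.predict_proba(X)
    ss = dataset.scoreset(test_patients, probs)
    return probs, evalstats.confusion_metrics(ss)


def run_scenario(
    config: ExperimentConfig,
    dataset: Dataset,
    split: SplitResult,
    spec: PartitionSpec,
    algorithm: str,
    local_epochs: int,
    rounds: int,
    scenario_name: str | None = None,
) -> ScenarioResult:
    """One grid cell: partition, train ``config.trials`` times, evaluate."""
    from .model import build_model

    tc = config.train.with_(local_epochs=local_epochs)
    eval_X, eval_y = dataset.materialize(split.test_patients)
    network = build_model(tc.arch, tc.init_seed, tc.input_size)
    trial_aucs, reports, all_logs, all_scores = [], [], [], []
    weighted_cs = float("nan")
    for t, trial_seed in enumerate(config.trial_seeds[: config.trials]):
        sites = build_partition(split.train_patients, spec, seed=trial_seed)
        weighted_cs = part.weighted_avg_cosine(sites).weighted_cs
        site_data = [dataset.materialize(s.patients) for s in sites]
        site_data = [d for d in site_data if len(d[0]) > 0]
        weights, logs = fedsim.run_federated(
            site_data,
            algorithm,
            rounds,
            tc,
            eval_data=(eval_X, eval_y),
            trial_seed=trial_seed,
        )
        probs, report = _evaluate_final(dataset, split.test_patients, network, weights)
        trial_aucs.append(report.auc)
        reports.append(report)
        all_logs.append(logs)
        all_scores.append(probs)
    ss = dataset.scoreset(split.test_patients, all_scores[0])
    ci = evalstats.jackknife_ci(ss, evalstats.roc_auc)
    return ScenarioResult(
        scenario=scenario_name or spec.strategy,
        algorithm=algorithm,
        local_epochs=local_epochs,
        rounds=rounds,
        weighted_cs=weighted_cs,
        trial_aucs=trial_aucs,
        trial_reports=reports,
        mean_auc=float(np.mean(trial_aucs)),
        auc_ci=ci,
        round_logs=all_logs,
        test_scores=all_scores,
    )


def run_grid(config: ExperimentConfig) -> dict:
    """Run the full study grid and write the report files.

    Returns a dict with the scenario results, baselines, the imbalance-grid
    dataframe and the DeLong comparison of the best federated scenario
    against the single-site baseline.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    cohort = generate_cohort(config.cohort)
    split = make_test_split(cohort, config.n_test_per_site, seed=config.seed)
    dataset = Dataset(config.cohort, config.preprocess_size)
    eval_X, eval_y = dataset.materialize(split.test_patients)
    test_ids = sorted(p.patient_id for p in split.test_patients)

    results: list[ScenarioResult] = []
    failures: list[str] = []
    for spec in config.scenarios:
        for algorithm in config.algorithms:
            for local_epochs, rounds in config.epoch_schedules:
                try:
                    results.append(
                        run_scenario(
                            config, dataset, split, spec, algorithm, local_epochs, rounds
                        )
                    )
                except Exception as exc:  # grid continues past a failed cell
                    failures.append(
                        f"{spec.strategy}/{algorithm}/ep{local_epochs}: {exc}"
                    )

    # baselines, one per epoch schedule
    baselines: list[ScenarioResult] = []
    from .model import build_model

    for local_epochs, rounds in config.epoch_schedules:
        tc = config.train.with_(local_epochs=local_epochs)
        network = build_model(tc.arch, tc.init_seed, tc.input_size)
        for name, pool in (
            ("centralized", split.train_patients),
            (
                "single_site",
                [p for p in split.train_patients if p.site_of_origin == "private_like"],
            ),
        ):
            trial_aucs, reports, all_logs, all_scores = [], [], [], []
            for trial_seed in config.trial_seeds[: config.trials]:
                weights, logs = fedsim.run_centralized(
                    dataset.materialize(pool),
                    rounds,
                    tc,
                    eval_data=(eval_X, eval_y),
                    trial_seed=trial_seed,
                )
                probs, report = _evaluate_final(
                    dataset, split.test_patients, network, weights
                )
                trial_aucs.append(report.auc)
                reports.append(report)
                all_logs.append(logs)
                all_scores.append(probs)
            ss = dataset.scoreset(split.test_patients, all_scores[0])
            baselines.append(
                ScenarioResult(
                    scenario=name,
                    algorithm="-",
                    local_epochs=local_epochs,
                    rounds=rounds,
                    weighted_cs=1.0,
                    trial_aucs=trial_aucs,
                    trial_reports=reports,
                    mean_auc=float(np.mean(trial_aucs)),
                    auc_ci=evalstats.jackknife_ci(ss, evalstats.roc_auc),
                    round_logs=all_logs,
                    test_scores=all_scores,
                )
            )

    # imbalance grid (FedAvg, fixed rounds / local epochs)
    imb_rows = []
    tc = config.train.with_(local_epochs=config.imbalance_local_epochs)
    network = build_model(tc.arch, tc.init_seed, tc.input_size)
    for s0 in config.imbalance_s0_fractions:
        for alpha in config.imbalance_alphas:
            spec = PartitionSpec(
                "imbalance_scenario",
                n_sites=2,
                alpha=alpha,
                s0_fraction=s0,
                total_patients=config.imbalance_total_patients,
            )
            for trial_seed in config.trial_seeds[: config.trials]:
                sites = build_partition(split.train_patients, spec, seed=trial_seed)
                report = part.weighted_avg_cosine(sites)
                site_data = [
                    dataset.materialize(s.patients) for s in sites if s.n_i > 0
                ]
                weights, _ = fedsim.run_federated(
                    site_data,
                    "fedavg",
                    config.imbalance_rounds,
                    tc,
                    trial_seed=trial_seed,
                )
                probs, mrep = _evaluate_final(
                    dataset, split.test_patients, network, weights
                )
                imb_rows.append(
                    {
                        "s0_fraction": s0,
                        "alpha": alpha,
                        "weighted_cs": report.weighted_cs,
                        "accuracy": mrep.accuracy,
                        "auc": mrep.auc,
                        "trial_seed": trial_seed,
                    }
                )

    # DeLong: best federated scenario vs the single-site baseline
    delong = None
    fed_results = [r for r in results if r.algorithm in fedsim.ALGORITHMS]
    single = [b for b in baselines if b.scenario == "single_site"]
    if fed_results and single:
        best = max(fed_results, key=lambda r: r.mean_auc)
        ss_best = dataset.scoreset(split.test_patients, best.test_scores[0])
        ss_single = dataset.scoreset(split.test_patients, single[0].test_scores[0])
        res = evalstats.delong_test(ss_best, ss_single)
        delong = {
            "best_scenario": best.scenario,
            "best_algorithm": best.algorithm,
            "auc_best": res.auc_a,
            "auc_single_site": res.auc_b,
            "difference": res.difference,
            "z": res.z_statistic,
            "p_value": res.p_value,
        }

    _write_reports(config, results + baselines, imb_rows, delong, test_ids, failures)
    return {
        "results": results,
        "baselines": baselines,
        "imbalance": pd.DataFrame(imb_rows),
        "delong": delong,
        "failures": failures,
        "test_ids": test_ids,
    }


RESULTS_COLUMNS = [
    "scenario",
    "algorithm",
    "local_epochs",
    "rounds",
    "weighted_cs",
    "mean_auc",
    "auc_jackknife",
    "auc_ci_low",
    "auc_ci_high",
    "accuracy",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "trial_aucs",
]

ROUNDS_COLUMNS = [
    "scenario",
    "algorithm",
    "local_epochs",
    "trial",
    "round",
    "n",
    "accuracy",
    "auc",
]

IMBALANCE_COLUMNS = [
    "s0_fraction",
    "alpha",
    "weighted_cs",
    "accuracy",
    "auc",
    "trial_seed",
]


def _write_reports(config, all_results, imb_rows, delong, test_ids, failures) -> None:
    out = config.output_dir
    rows = []
    for r in all_results:
        rep = r.trial_reports[0]
        rows.append(
            {
                "scenario": r.scenario,
                "algorithm": r.algorithm,
                "local_epochs": r.local_epochs,
                "rounds": r.rounds,
                "weighted_cs": r.weighted_cs,
                "mean_auc": r.mean_auc,
                "auc_jackknife": r.auc_ci[0],
                "auc_ci_low": r.auc_ci[1],
                "auc_ci_high": r.auc_ci[2],
                "accuracy": rep.accuracy,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "ppv": rep.ppv,
                "npv": rep.npv,
                "trial_aucs": ";".join(f"{a:.6f}" for a in r.trial_aucs),
            }
        )
    pd.DataFrame(rows, columns=RESULTS_COLUMNS).to_csv(
        os.path.join(out, "results.csv"), index=False
    )
    rrows = []
    for r in all_results:
        for t, logs in enumerate(r.round_logs):
            for log in logs:
                rrows.append(
                    {
                        "scenario": r.scenario,
                        "algorithm": r.algorithm,
                        "local_epochs": r.local_epochs,
                        "trial": t,
                        "round": log.round_index,
                        "n": log.n,
                        "accuracy": log.accuracy,
                        "auc": log.auc,
                    }
                )
    pd.DataFrame(rrows, columns=ROUNDS_COLUMNS).to_csv(
        os.path.join(out, "rounds.csv"), index=False
    )
    pd.DataFrame(imb_rows, columns=IMBALANCE_COLUMNS).to_csv(
        os.path.join(out, "imbalance.csv"), index=False
    )
    meta = {"test_patient_ids": test_ids, "delong": delong, "failures": failures}
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


# ---------------------------------------------------------------------------
# desk-scale directional study
# ---------------------------------------------------------------------------


def directional_study(
    seed: int = 0,
    n_seeds: int = 5,
    rounds: int = 10,
    images_per_patient: int = 5,
    render_size: int = 64,
    input_size: int = 32,
) -> dict:
    """Mean test AUC of five training setups over ``n_seeds`` trial seeds.

    Setups: source-partition FedAvg, single-site baseline, quantity skew
    (Dirichlet beta=2), IID two-site scenario (alpha=1, balanced 84-patient
    global set), and the one-class-per-site extreme. Used to check the
    qualitative ordering of the study outcomes at desk scale.
    """
    cohort_cfg = CohortConfig.tiny(
        seed=seed, size=render_size, images_per_patient=images_per_patient
    )
    cohort = generate_cohort(cohort_cfg)
    split = make_test_split(cohort, 10, seed=seed)
    dataset = Dataset(cohort_cfg, (input_size, input_size))
    eval_data = dataset.materialize(split.test_patients)
    tc = TrainConfig(
        arch="tiny",
        input_size=(input_size, input_size),
        learning_rate=1e-3,
        local_epochs=1,
        init_seed=seed,
    )

    def fed_auc(sites, trial_seed):
        data = [dataset.materialize(s.patients) for s in sites if s.n_i > 0]
        _, logs = fedsim.run_federated(
            data, "fedavg", rounds, tc, eval_data=eval_data, trial_seed=trial_seed
        )
        return logs[-1].auc

    out: dict[str, list[float]] = {
        k: [] for k in ("source_fl", "single_site", "quantity_skew", "iid", "one_class")
    }
    alphas = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
    cs_by_alpha = {
        a: part.weighted_avg_cosine(
            part.imbalance_scenario(split.train_patients, 84, 0.5, a, 2, seed)
        ).weighted_cs
        for a in alphas
    }
    for k in range(n_seeds):
        ts = seed + 7919 * (k + 1)
        out["source_fl"].append(fed_auc(part.source_partition(split.train_patients), ts))
        _, logs = fedsim.run_single_site(
            split.train_patients, dataset.materialize, rounds, tc, eval_data, ts
        )
        out["single_site"].append(logs[-1].auc)
        out["quantity_skew"].append(
            fed_auc(part.dirichlet_quantity_partition(split.train_patients, 2, 2.0, ts), ts)
        )
        out["iid"].append(
            fed_auc(part.imbalance_scenario(split.train_patients, 84, 0.5, 1.0, 2, ts), ts)
        )
        out["one_class"].append(
            fed_auc(part.quantity_class_partition(split.train_patients, 2, 1), ts)
        )
    summary = {k: {"aucs": v, "mean": float(np.mean(v)), "se": float(np.std(v, ddof=1) / np.sqrt(len(v)))} for k, v in out.items()}
    summary["cs_by_alpha"] = cs_by_alpha
    return summary
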