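"""End-to-end study: four-setting comparison, mixture groups, transfer, contrast.

Protocol per cohort seed: render the phantom cohort under the four
reconstruction settings, extract the feature bank per setting, filter
features through the per-setting test-retest CCC criterion, run the
coarse-to-fine selection and SVM model build per setting, build ten
random mixture cohorts restricted to the features reproducible in all four
settings, compare models pairwise by paired bootstrap, transfer the best
model to every setting, and contrast the class medians of
``LoG_Entropy_Sigma2.5_2D`` per setting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import STUDY_CONFIG, FeatureBankConfig, extract_features
from .io_core import FeatureTable, read_volume
from .model import (
    ModelReport,
    build_optimal_model,
    compare_models,
    transfer_evaluate,
)
from .phantom import (
    SETTINGS,
    PhantomParams,
    generate_cohort_arrays,
    generate_scene,
    generate_test_retest,
    params_from_dict,
    params_to_dict,
)
from .reproducibility import filter_reproducible
from .selection import coarse_select

__all__ = [
    "StudyConfig",
    "StudyReport",
    "ENTROPY_FEATURE",
    "extract_table",
    "extract_cohort_tables",
    "retest_retained_features",
    "build_mixture_tables",
    "mixture_performance",
    "entropy_contrast",
    "run_study",
]

logger = logging.getLogger("reconradiomics.study")

ENTROPY_FEATURE = "LoG_Entropy_Sigma2.5_2D"


@dataclass
class StudyConfig:
    """Configuration of one full study run on the synthetic cohort."""

    n: int = 60
    prevalence: float = 0.5
    seed: int = 1
    n_retest: int = 20
    ccc_threshold: float = 0.9
    redundancy_threshold: float = 0.8
    redundancy_measure: str = "pearson"
    top_k: int = 10
    folds: int = 3
    C: float = 100.0
    kernel: str = "linear"
    n_bootstrap: int = 1000
    n_mixtures: int = 10
    transfer_from: str | None = None  # default: best homogeneous setting
    manifest_path: str | None = None  # real volumes on disk instead of phantoms
    params: PhantomParams = field(default_factory=PhantomParams)
    bank: FeatureBankConfig = field(default_factory=lambda: STUDY_CONFIG)

    @staticmethod
    def from_dict(d: dict) -> "StudyConfig":
        d = dict(d)
        params = params_from_dict(d.pop("params", {}))
        bank_dict = d.pop("bank", {})
        bank = FeatureBankConfig(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in bank_dict.items()
        }) if bank_dict else STUDY_CONFIG
        known = {f.name for f in dataclasses.fields(StudyConfig)}
        cfg = StudyConfig(**{k: v for k, v in d.items() if k in known and k not in ("params", "bank")})
        cfg.params = params
        cfg.bank = bank
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = params_to_dict(self.params)
        d["bank"] = dataclasses.asdict(self.bank)
        return d


@dataclass
class StudyReport:
    """Results of one study run; every number traces to a pipeline stage."""

    models: dict[str, ModelReport]
    mixture_mean_auc: float
    mixture_aucs: list[float]
    pairwise_p: dict[str, float]
    transfer_from: str
    transfer_auc: dict[str, float]
    entropy_medians: dict[str, dict[str, float]]
    retained_features: dict[str, list[str]]
    config: dict
    seed: int

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, report in self.models.items():
            rows.append(
                {
                    "setting": name,
                    "cv_auc": report.auc_summary.auc,
                    "ci_low": report.auc_summary.ci_low,
                    "ci_high": report.auc_summary.ci_high,
                    "n_features": len(report.spec.features),
                    "ranker": report.ranker,
                    "sv_fraction_pct": report.sv_fraction_pct,
                    "n_retained": len(self.retained_features[name]),
                }
            )
        rows.append(
            {
                "setting": "Mixture",
                "cv_auc": self.mixture_mean_auc,
                "ci_low": float("nan"),
                "ci_high": float("nan"),
                "n_features": 0,
                "ranker": "",
                "sv_fraction_pct": float("nan"),
                "n_retained": 0,
            }
        )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "models": {
                name: {
                    "cv_auc": r.auc_summary.auc,
                    "ci": [r.auc_summary.ci_low, r.auc_summary.ci_high],
                    "features": r.spec.features,
                    "ranker": r.ranker,
                    "n_support": r.spec.n_support,
                    "sv_fraction_pct": r.sv_fraction_pct,
                    "n_retained_features": len(self.retained_features[name]),
                }
                for name, r in self.models.items()
            },
            "mixture": {"mean_auc": self.mixture_mean_auc, "aucs": self.mixture_aucs},
            "pairwise_p": self.pairwise_p,
            "transfer": {"from": self.transfer_from, "auc": self.transfer_auc},
            "entropy_medians": self.entropy_medians,
            "config": self.config,
            "seed": self.seed,
        }

    def save(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)
        self.summary_frame().to_csv(os.path.join(out_dir, "summary.csv"), index=False)


def _fingerprint(array: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(array).tobytes()).hexdigest()[:12]


def _stage(name: str, seed: int, payload: np.ndarray | None = None) -> None:
    extra = f" hash={_fingerprint(payload)}" if payload is not None else ""
    logger.info("stage=%s seed=%d%s", name, seed, extra)


# ---------------------------------------------------------------------------
# Feature-table assembly
# ---------------------------------------------------------------------------

def extract_table(
    volumes_and_masks: list[tuple],
    patient_ids: list[str],
    labels: np.ndarray,
    bank: FeatureBankConfig,
) -> FeatureTable:
    """Extract the bank for a list of (volume, mask) pairs into one table."""
    rows = []
    names: list[str] | None = None
    for volume, mask in volumes_and_masks:
        vector = extract_features(volume, mask, bank)
        if names is None:
            names = list(vector)
        rows.append([vector[n] for n in names])
    return FeatureTable(
        patient_ids=patient_ids,
        feature_names=names or [],
        values=np.asarray(rows),
        labels=labels,
    )


def extract_cohort_tables(config: StudyConfig) -> dict[str, FeatureTable]:
    """Render the synthetic cohort and extract one feature table per setting."""
    per_setting: dict[str, list] = {s.name: [] for s in SETTINGS}
    patient_ids: list[str] = []
    labels: list[int] = []
    for pid, label, rendered in generate_cohort_arrays(
        config.n, config.prevalence, config.params, config.seed
    ):
        patient_ids.append(pid)
        labels.append(label)
        for sname, pair in rendered.items():
            per_setting[sname].append(pair)
    labels_arr = np.asarray(labels)
    tables = {
        sname: extract_table(pairs, patient_ids, labels_arr, config.bank)
        for sname, pairs in per_setting.items()
    }
    for sname, table in tables.items():
        _stage(f"extract[{sname}]", config.seed, table.values)
    return tables


def extract_cohort_tables_from_manifest(
    manifest, bank: FeatureBankConfig
) -> dict[str, FeatureTable]:
    """Extract per-setting tables for a cohort of real volumes on disk."""
    tables = {}
    labels = manifest.labels
    for sname in manifest.settings():
        pairs = []
        for entry in manifest.entries:
            volume, mask = read_volume(entry.volumes[sname], entry.masks[sname])
            pairs.append((volume, mask))
        tables[sname] = extract_table(pairs, manifest.patient_ids, labels, bank)
    return tables


def retest_retained_features(config: StudyConfig) -> dict[str, list[str]]:
    """Per-setting reproducible feature names from phantom test-retest pairs.

    Emulates a same-settings repeat-scan dataset: fresh lesions (both
    classes), each imaged twice under the same setting with noise,
    repositioning and re-segmentation perturbations; features retained iff
    CCC > the configured threshold under that setting.
    """
    retained: dict[str, list[str]] = {}
    base = int(np.random.SeedSequence([config.seed, 909]).generate_state(1)[0] % (2**31))
    for s in SETTINGS:
        firsts, seconds, ids, labels = [], [], [], []
        for i in range(config.n_retest):
            scene_seed = base + 1000 * SETTINGS.index(s) + i
            scene = generate_scene(i % 2, config.params, seed=scene_seed)
            pair = generate_test_retest(scene, s, seed=scene_seed)
            firsts.append(pair.first)
            seconds.append(pair.second)
            ids.append(f"R{i:03d}")
            labels.append(i % 2)
        labels_arr = np.asarray(labels)
        test = extract_table(firsts, ids, labels_arr, config.bank)
        retest = extract_table(seconds, ids, labels_arr, config.bank)
        report = filter_reproducible(test, retest, threshold=config.ccc_threshold)
        retained[s.name] = report.retained
        _stage(f"ccc[{s.name}]", config.seed, np.asarray(list(report.values.values())))
    return retained


# ---------------------------------------------------------------------------
# Mixture experiment
# ---------------------------------------------------------------------------

def build_mixture_tables(
    four_tables: dict[str, FeatureTable],
    common_features: list[str],
    n_mixtures: int = 10,
    seed: int = 0,
) -> list[FeatureTable]:
    """Random mixture cohorts: per patient, one uniformly chosen setting.

    Columns are restricted to the features reproducible in all four
    settings; each mixture row is bit-identical to the corresponding row of
    one source table.
    """
    if not common_features:
        raise ValueError("common feature set is empty")
    names = list(four_tables)
    tables = [four_tables[n].subset(common_features) for n in names]
    first = tables[0]
    for t in tables[1:]:
        if t.patient_ids != first.patient_ids:
            raise ValueError("all settings must cover the same patients in order")
    rng = np.random.default_rng(int(seed) % (2**31))
    mixtures = []
    for _ in range(n_mixtures):
        choice = rng.integers(0, len(tables), size=first.n_patients)
        values = np.array(
            [tables[choice[i]].values[i] for i in range(first.n_patients)]
        )
        mixtures.append(
            FeatureTable(
                patient_ids=list(first.patient_ids),
                feature_names=list(common_features),
                values=values,
                labels=first.labels.copy(),
            )
        )
    return mixtures


def mixture_performance(
    mixtures: list[FeatureTable],
    labels: np.ndarray | None = None,
    config: StudyConfig | None = None,
) -> tuple[float, list[float]]:
    """Run the selection + model build on each mixture; mean of the AUCs."""
    if not mixtures:
        raise ValueError("need at least one mixture table")
    config = config or StudyConfig()
    aucs = []
    for i, table in enumerate(mixtures):
        y = np.asarray(table.labels if labels is None else labels, dtype=int)
        lists = coarse_select(
            table, y, threshold=config.redundancy_threshold,
            top_k=config.top_k, measure=config.redundancy_measure,
        )
        report = build_optimal_model(
            table, y, lists, folds=config.folds, C=config.C,
            B=config.n_bootstrap, seed=config.seed, kernel=config.kernel,
            setting=f"Mixture{i}",
        )
        aucs.append(report.auc_summary.auc)
    return float(np.mean(aucs)), aucs


def entropy_contrast(
    tables: dict[str, FeatureTable],
    labels: np.ndarray | None = None,
    feature: str = ENTROPY_FEATURE,
) -> dict[str, dict[str, float]]:
    """Class medians of the LoG-entropy heterogeneity feature per setting."""
    out: dict[str, dict[str, float]] = {}
    for name, table in tables.items():
        y = np.asarray(table.labels if labels is None else labels, dtype=int)
        column = table.column(feature)  # raises KeyError if missing
        out[name] = {
            "mutant": float(np.median(column[y == 1])),
            "wild_type": float(np.median(column[y == 0])),
        }
    return out


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_study(
    config: StudyConfig | dict | None = None,
    tables: dict[str, FeatureTable] | None = None,
    retained: dict[str, list[str]] | None = None,
) -> StudyReport:
    """Execute the full study protocol and assemble the report.

    ``tables`` / ``retained`` may be supplied to reuse a previous extraction
    (they are recomputed from the phantom generator otherwise).
    """
    if isinstance(config, dict):
        config = StudyConfig.from_dict(config)
    config = config or StudyConfig()

    if tables is None:
        if config.manifest_path:
            from .io_core import read_manifest

            manifest = read_manifest(config.manifest_path)
            tables = extract_cohort_tables_from_manifest(manifest, config.bank)
        else:
            tables = extract_cohort_tables(config)
    if retained is None:
        retained = retest_retained_features(config)
    labels = tables[SETTINGS[0].name].labels

    models: dict[str, ModelReport] = {}
    for s in SETTINGS:
        table = tables[s.name].subset(retained[s.name])
        lists = coarse_select(
            table, labels, threshold=config.redundancy_threshold,
            top_k=config.top_k, measure=config.redundancy_measure,
        )
        models[s.name] = build_optimal_model(
            table, labels, lists, folds=config.folds, C=config.C,
            B=config.n_bootstrap, seed=config.seed, kernel=config.kernel,
            setting=s.name,
        )
        _stage(f"model[{s.name}]", config.seed, models[s.name].cv.scores)

    common = [
        f for f in retained[SETTINGS[0].name]
        if all(f in retained[s.name] for s in SETTINGS[1:])
    ]
    mixtures = build_mixture_tables(
        tables, common, n_mixtures=config.n_mixtures, seed=config.seed
    )
    mixture_mean, mixture_aucs = mixture_performance(mixtures, labels, config)
    _stage("mixture", config.seed, np.asarray(mixture_aucs))

    pairwise: dict[str, float] = {}
    names = [s.name for s in SETTINGS]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairwise[f"{a} vs {b}"] = compare_models(
                models[a].cv, models[b].cv, labels,
                B=config.n_bootstrap, seed=config.seed,
            )

    transfer_from = config.transfer_from or max(
        models, key=lambda n: models[n].auc_summary.auc
    )
    transfer = transfer_evaluate(models[transfer_from].spec, tables, labels)
    _stage("transfer", config.seed, np.asarray(list(transfer.values())))

    medians = entropy_contrast(tables, labels)

    return StudyReport(
        models=models,
        mixture_mean_auc=mixture_mean,
        mixture_aucs=mixture_aucs,
        pairwise_p=pairwise,
        transfer_from=transfer_from,
        transfer_auc=transfer,
        entropy_medians=medians,
        retained_features=retained,
        config=config.to_dict(),
        seed=config.seed,
    )
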