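"""Evaluation protocol: stratified cross-validation, SMOTE baseline,
multi-variant experiment runs and grid search.

The protocol mirrors common practice for small clinical imaging cohorts:
k-fold cross-validation stratified jointly on the disease label and every
sensitive attribute (each fold keeps the same class and group proportions),
with each fold serving once as the held-out 20% test split at k = 5, and the
whole procedure repeated over several seeds; results are reported as
mean ± sample standard deviation across seeds.

SMOTE (synthetic minority oversampling) is provided as an imbalance
baseline: new minority points are convex combinations of a minority sample
and one of its k nearest minority neighbors.  It is intended for tabular
features such as pooled embeddings, not raw pixels.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .cae_extractor import CAEConfig, pretrain_cae
from .cohort_io import Cohort
from .fairness_metrics import (embedding_attribute_correlation, metrics_report,
                               prediction_table)
from .mdann_core import MDANNConfig, build_mdann, embed, predict, train_mdann
from .synthetic_cohort import AttributeSpec, BiasSpec, generate_cohort

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "stratified_kfold",
    "smote_oversample",
    "run_experiment",
    "grid_search",
    "attribute_target_cohort",
    "imbalance_recovery_study",
    "fairness_recovery_study",
]


@dataclass
class ExperimentConfig:
    """A full comparison: cohort recipe, model variants, protocol settings."""

    bias_spec: BiasSpec = field(default_factory=BiasSpec)
    variants: dict[str, MDANNConfig] = field(default_factory=dict)
    cae_config: CAEConfig = field(default_factory=CAEConfig)
    cae_epochs: int = 15
    folds: int = 5
    test_fraction: float = 0.2
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    eval_folds: int | None = None   # evaluate only the first m folds (desk-scale)

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if len(self.seeds) < 1:
            raise ValueError("need at least one seed")
        if not self.variants:
            raise ValueError("need at least one model variant")
        if round(1.0 / self.test_fraction) != self.folds:
            warnings.warn(
                f"test_fraction {self.test_fraction} is not 1/folds; folds take "
                f"precedence (each fold is the held-out split once)",
                UserWarning, stacklevel=2)


@dataclass
class ExperimentResult:
    cells: pd.DataFrame      # one row per variant x seed x fold x metric
    summary: pd.DataFrame    # mean +/- std across seeds per variant x metric
    failures: list[str]


def stratified_kfold(labels: np.ndarray, coded_attributes: np.ndarray,
                     k: int, seed: int) -> np.ndarray:
    """Fold assignment stratified on the joint (label, attributes) cells.

    Within each joint stratum, samples are dealt round-robin across folds
    after a seeded shuffle, so per-fold stratum counts differ by at most 1.
    Strata smaller than ``k`` are merged into their label-only stratum (with
    a warning); the folds always partition the index set.
    """
    labels = np.asarray(labels).ravel()
    coded = np.atleast_2d(np.asarray(coded_attributes))
    if coded.shape[0] != labels.size:
        coded = coded.reshape(labels.size, -1)
    n = labels.size
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    keys = [tuple([int(labels[i])] + [int(v) for v in coded[i]]) for i in range(n)]
    strata: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        strata.setdefault(key, []).append(i)
    merged: dict[tuple, list[int]] = {}
    for key, idx in strata.items():
        if len(idx) < k:
            warnings.warn(
                f"stratum {key} has only {len(idx)} samples (< k={k}); merging "
                f"into its label-only stratum", UserWarning, stacklevel=2)
            merged.setdefault(("label", key[0]), []).extend(idx)
        else:
            merged[key] = idx
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=np.int64)
    for key in sorted(merged, key=str):
        idx = np.asarray(merged[key])
        idx = idx[rng.permutation(idx.size)]
        for j, i in enumerate(idx):
            assignment[i] = j % k
    return assignment


def smote_oversample(features: np.ndarray, labels: np.ndarray,
                     ratio: float = 0.5, k_neighbors: int = 5,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class by convex interpolation.

    New minority points are ``x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``,
    where ``x_nn`` is one of the ``k_neighbors`` nearest minority neighbors
    (Euclidean) of minority sample ``x``.  Sampling stops when the minority
    count reaches ``round(ratio * n_majority)``; if it already does, the
    input is returned unchanged.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).ravel()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("minority class needs at least 2 samples for SMOTE")
    target = int(round(ratio * n_maj))
    if n_min >= target:
        return X, y
    Xmin = X[y == minority]
    k = min(k_neighbors, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
    neighbors = nn.kneighbors(Xmin, return_distance=False)[:, 1:]
    rng = np.random.default_rng(seed)
    new_points = []
    for _ in range(target - n_min):
        i = int(rng.integers(n_min))
        j = int(neighbors[i, rng.integers(k)])
        u = rng.uniform()
        new_points.append(Xmin[i] + u * (Xmin[j] - Xmin[i]))
    X_out = np.vstack([X, np.asarray(new_points)])
    y_out = np.concatenate([y, np.full(len(new_points), minority, dtype=y.dtype)])
    return X_out, y_out


def _evaluate_cell(cohort: Cohort, cae_model, variant: MDANNConfig,
                   train_idx: np.ndarray, test_idx: np.ndarray,
                   seed: int) -> dict[str, float]:
    model = build_mdann(variant, cae_model, seed=seed)
    train_mdann(model, cohort, train_idx, val_idx=test_idx, seed=seed)
    scores, y_hat = predict(model, cohort.images[test_idx],
                            threshold=variant.threshold)
    attrs = {name: cohort.coded_attributes[test_idx, i]
             for i, name in enumerate(cohort.attribute_names)}
    table = prediction_table(cohort.labels[test_idx], y_hat, scores, attrs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        report = metrics_report(table, cohort.attribute_names)
        embeddings = embed(model, cohort.images[test_idx])
        for i, name in enumerate(cohort.attribute_names):
            r = embedding_attribute_correlation(embeddings,
                                                cohort.coded_attributes[test_idx, i])
            report[f"emb_r[{name}]"] = r
            report[f"|emb_r|[{name}]"] = abs(r)
    return report


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run every variant over the shared folds and seeds; aggregate.

    For each variant x seed x fold: generate the cohort (per seed), pretrain
    the autoencoder on the training split (shared across variants), train the
    adversarial model, evaluate held-out predictions (ACC/AUC/F1, per-attribute
    DI/EO/TNRD and embedding-attribute correlations).  Seed-level values are
    fold means; the summary reports their mean and sample standard deviation
    (n-1) across seeds.  Deterministic given the config.
    """
    rows = []
    failures: list[str] = []
    cae_cfg = replace(config.cae_config, epochs=config.cae_epochs)
    m_folds = config.eval_folds or config.folds
    for seed in config.seeds:
        spec = replace(config.bias_spec, seed=int(seed))
        cohort = generate_cohort(spec)
        fold_of = stratified_kfold(cohort.labels, cohort.coded_attributes,
                                   config.folds, seed=seed)
        for fold in range(m_folds):
            test_idx = np.flatnonzero(fold_of == fold)
            train_idx = np.flatnonzero(fold_of != fold)
            cae_model = pretrain_cae(cohort.subset(train_idx), cae_cfg, seed=seed)
            for name, variant in config.variants.items():
                try:
                    report = _evaluate_cell(cohort, cae_model, variant,
                                            train_idx, test_idx, seed)
                except Exception as exc:  # record and continue
                    failures.append(f"variant={name} seed={seed} fold={fold}: {exc}")
                    continue
                for metric, value in report.items():
                    rows.append({"variant": name, "seed": seed, "fold": fold,
                                 "metric": metric, "value": value})
    cells = pd.DataFrame(rows)
    if cells.empty:
        return ExperimentResult(cells, cells, failures)
    seed_level = (cells.groupby(["variant", "metric", "seed"], sort=False)["value"]
                  .mean().reset_index())
    summary = (seed_level.groupby(["variant", "metric"], sort=False)["value"]
               .agg(mean="mean", std=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
               .reset_index())
    return ExperimentResult(cells, summary, failures)


def attribute_target_cohort(cohort: Cohort, attribute: str) -> Cohort:
    """A copy of the cohort whose prediction label is a coded attribute.

    Used to study classifier behavior on heavily imbalanced targets: the
    attribute's minority (coded 1) becomes the positive class.
    """
    i = cohort.attribute_names.index(attribute)
    phenotype = cohort.phenotype.copy()
    phenotype["label"] = cohort.coded_attributes[:, i]
    return Cohort(images=cohort.images, phenotype=phenotype, coding=cohort.coding,
                  coded_attributes=cohort.coded_attributes,
                  attribute_names=list(cohort.attribute_names))


def imbalance_recovery_study(seeds=(0, 1, 2, 3, 4), n: int = 400,
                             epochs: int = 30, cae_epochs: int = 15,
                             imbalance_ratio: float = 12.33) -> dict:
    """Saddle loss vs weighted cross-entropy on a ~12:1 imbalanced target.

    Per seed: generate a cohort with one heavily imbalanced attribute whose
    corner signature has heterogeneous amplitude (so the task is not
    separable), predict the attribute itself (K = 0), and evaluate held-out
    AUC and minority-class recall for each loss.  Returns per-seed arrays
    and their means.
    """
    from sklearn.metrics import recall_score, roc_auc_score

    aucs: dict[str, list[float]] = {"minimax": [], "weighted_ce": []}
    recalls: dict[str, list[float]] = {"minimax": [], "weighted_ce": []}
    for seed in seeds:
        spec = BiasSpec(
            n=n, image_size=(32, 32), seed=int(seed),
            attributes=[AttributeSpec("target", imbalance_ratio, 0.0,
                                      amplitude=0.15, amplitude_sd=0.10)])
        cohort = attribute_target_cohort(generate_cohort(spec), "target")
        folds = stratified_kfold(cohort.labels, cohort.coded_attributes, 5,
                                 seed=int(seed))
        train_idx = np.flatnonzero(folds != 0)
        test_idx = np.flatnonzero(folds == 0)
        cae_cfg = CAEConfig(depth=2, base_channels=8, input_size=(32, 32),
                            epochs=cae_epochs)
        cae_model = pretrain_cae(cohort.subset(train_idx), cae_cfg, seed=int(seed))
        for loss in ("minimax", "weighted_ce"):
            variant = MDANNConfig(encoder=cae_cfg, n_adversarial=0,
                                  predictor_loss=loss, epochs=epochs)
            model = build_mdann(variant, cae_model, seed=int(seed))
            train_mdann(model, cohort, train_idx, val_idx=test_idx,
                        seed=int(seed))
            scores, y_hat = predict(model, cohort.images[test_idx])
            truth = cohort.labels[test_idx]
            aucs[loss].append(float(roc_auc_score(truth, scores)))
            recalls[loss].append(float(recall_score(truth, y_hat)))
    return {
        "auc": {k: np.asarray(v) for k, v in aucs.items()},
        "minority_recall": {k: np.asarray(v) for k, v in recalls.items()},
        "auc_mean": {k: float(np.mean(v)) for k, v in aucs.items()},
        "minority_recall_mean": {k: float(np.mean(v)) for k, v in recalls.items()},
    }


def fairness_recovery_study(seeds=(0, 1, 2, 3, 4), n: int = 300,
                            epochs: int = 60, cae_epochs: int = 12,
                            eval_folds: int = 3) -> dict:
    """Two adversarial components vs none on a doubly-confounded cohort.

    The cohort carries two sensitive attributes (3:1 and 4:1) with bias
    strength 0.8.  Per seed, fold-averaged held-out metrics are compared
    between K = 2 (with the stabilized adversarial recipe: lambda 3, norm
    cap 1.5, two-time-scale ACs) and K = 0: the embedding-attribute |r|,
    the DI deviation |DI - 1| and EO, each averaged over the two attributes.
    Returns the per-seed values and directional win counts.
    """
    encoder = CAEConfig(depth=2, base_channels=8, input_size=(32, 32))
    variants = {
        "K0": MDANNConfig(encoder=encoder, n_adversarial=0, epochs=epochs),
        "K2": MDANNConfig(encoder=encoder, n_adversarial=2, epochs=epochs,
                          reversal_lambda=3.0, reversal_norm_cap=1.5,
                          ac_lr_scale=5.0),
    }
    spec = BiasSpec(n=n, image_size=(32, 32),
                    attributes=[AttributeSpec("sex", 3.0, 0.8),
                                AttributeSpec("hand", 4.0, 0.8)])
    config = ExperimentConfig(bias_spec=spec, variants=variants,
                              cae_config=encoder, cae_epochs=cae_epochs,
                              folds=5, seeds=tuple(int(s) for s in seeds),
                              eval_folds=eval_folds)
    result = run_experiment(config)
    per_seed = (result.cells.groupby(["variant", "metric", "seed"],
                                     sort=False)["value"].mean())
    out: dict[str, dict[str, np.ndarray]] = {}
    attrs = ("sex", "hand")
    for variant in ("K0", "K2"):
        emb = [np.mean([per_seed[(variant, f"|emb_r|[{a}]", s)] for a in attrs])
               for s in seeds]
        di = [np.mean([abs(per_seed[(variant, f"DI[{a}]", s)] - 1.0)
                       for a in attrs]) for s in seeds]
        eo = [np.mean([per_seed[(variant, f"EO[{a}]", s)] for a in attrs])
              for s in seeds]
        auc = [per_seed[(variant, "AUC", s)] for s in seeds]
        out[variant] = {"emb_r": np.asarray(emb), "di_dev": np.asarray(di),
                        "eo": np.asarray(eo), "auc": np.asarray(auc)}
    out["wins"] = {
        "emb_r": int((out["K2"]["emb_r"] < out["K0"]["emb_r"]).sum()),
        "di_dev": int((out["K2"]["di_dev"] < out["K0"]["di_dev"]).sum()),
        "eo": int((out["K2"]["eo"] < out["K0"]["eo"]).sum()),
    }
    out["n_seeds"] = len(tuple(seeds))
    out["failures"] = result.failures
    return out


def grid_search(config: ExperimentConfig, grid: dict[str, list],
                base_variant: str | None = None
                ) -> tuple[MDANNConfig, pd.DataFrame]:
    """Exhaustive sweep over MDANN hyperparameters; select by mean test AUC.

    ``grid`` maps MDANNConfig field names to candidate values.  Every
    candidate runs under the shared folds and seeds; ties keep the first
    candidate in deterministic grid order.  Returns the winning config and
    the full sweep table.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    if base_variant is None:
        base_variant = next(iter(config.variants))
    base = config.variants[base_variant]
    names = list(grid)
    rows = []
    best: tuple[float, int, MDANNConfig] | None = None
    for rank, values in enumerate(itertools.product(*(grid[n] for n in names))):
        candidate = replace(base, **dict(zip(names, values)))
        sweep_cfg = replace(config, variants={"candidate": candidate})
        result = run_experiment(sweep_cfg)
        auc_rows = result.summary.query("metric == 'AUC'")
        auc = float(auc_rows["mean"].iloc[0]) if len(auc_rows) else float("nan")
        rows.append({**dict(zip(names, values)), "mean_AUC": auc})
        if np.isfinite(auc) and (best is None or auc > best[0]):
            best = (auc, rank, candidate)
    sweep = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError("every grid candidate failed")
    return best[2], sweep
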