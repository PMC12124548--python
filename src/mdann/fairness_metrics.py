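"""Group fairness metrics and standard classification metrics.

A prediction table holds, per sample, the ground truth ``y``, the hard
prediction ``y_hat``, the continuous score, and one binary group column per
sensitive attribute (minority coded 1, majority 0).  The favored outcome is
``y_hat = 1``.

Metrics:

* Disparate impact (DI): ratio of selection rates,
  ``Pr(y_hat=1 | minority) / Pr(y_hat=1 | majority)``; 1 means parity.
* Equal opportunity (EO): difference in true-positive rates between minority
  and majority groups; 0 means parity.  Reported as an absolute value by
  default, with a signed variant (positive = higher TPR for the minority).
* TNR disparity (TNRD): the analogous difference in true-negative rates.

Undefined rates (an empty conditioning cell, e.g. a group with no true
positives) yield NaN with a warning rather than an exception so that
batch reporting over many seeds never aborts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import f1_score, roc_auc_score

__all__ = [
    "prediction_table",
    "disparate_impact",
    "equal_opportunity",
    "tnr_disparity",
    "classification_metrics",
    "embedding_attribute_correlation",
    "metrics_report",
]

_CORE_COLUMNS = ("y", "y_hat", "score")


def prediction_table(y, y_hat, score, attributes: dict[str, np.ndarray],
                     sample_id=None) -> pd.DataFrame:
    """Assemble and validate a prediction table.

    Columns: ``sample_id, y, y_hat, score, <one column per attribute>``.
    """
    y = np.asarray(y).ravel()
    y_hat = np.asarray(y_hat).ravel()
    score = np.asarray(score, dtype=float).ravel()
    n = y.size
    if not (y_hat.size == n and score.size == n):
        raise ValueError("y, y_hat and score must have equal length")
    for name, arr in (("y", y), ("y_hat", y_hat)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    if sample_id is None:
        sample_id = [f"S{i:05d}" for i in range(n)]
    table = pd.DataFrame({"sample_id": sample_id, "y": y.astype(int),
                          "y_hat": y_hat.astype(int), "score": score})
    for name, arr in attributes.items():
        arr = np.asarray(arr).ravel()
        if arr.size != n:
            raise ValueError(f"attribute {name!r} has wrong length")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"attribute {name!r} must be coded 0/1")
        table[name] = arr.astype(int)
    return table


def _group_masks(table: pd.DataFrame, attribute: str) -> tuple[np.ndarray, np.ndarray]:
    if attribute not in table.columns or attribute in _CORE_COLUMNS:
        raise KeyError(f"unknown attribute column {attribute!r}")
    d = table[attribute].to_numpy()
    minority, majority = d == 1, d == 0
    if not minority.any() or not majority.any():
        raise ValueError(f"attribute {attribute!r} has an empty group")
    return minority, majority


def _rate(mask_num: np.ndarray, mask_den: np.ndarray, what: str) -> float:
    den = int(mask_den.sum())
    if den == 0:
        warnings.warn(f"{what} undefined (empty conditioning cell); returning NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return float(mask_num[mask_den].mean())


def disparate_impact(table: pd.DataFrame, attribute: str) -> float:
    """Selection-rate ratio ``Sr_minority / Sr_majority``; 1 = parity."""
    minority, majority = _group_masks(table, attribute)
    selected = table["y_hat"].to_numpy() == 1
    sr_min = _rate(selected, minority, "minority selection rate")
    sr_maj = _rate(selected, majority, "majority selection rate")
    if sr_maj == 0.0:
        warnings.warn("majority selection rate is 0; DI undefined, returning NaN",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return sr_min / sr_maj


def _tpr_difference(table: pd.DataFrame, attribute: str, on_label: int) -> float:
    """Minority minus majority rate of predicting ``on_label`` among ``y == on_label``."""
    minority, majority = _group_masks(table, attribute)
    y = table["y"].to_numpy()
    correct = table["y_hat"].to_numpy() == on_label
    cond = y == on_label
    kind = "TPR" if on_label == 1 else "TNR"
    r_min = _rate(correct, minority & cond, f"minority {kind}")
    r_maj = _rate(correct, majority & cond, f"majority {kind}")
    return r_min - r_maj


def equal_opportunity(table: pd.DataFrame, attribute: str, signed: bool = False) -> float:
    """|TPR_minority - TPR_majority| (signed variant: minority minus majority)."""
    diff = _tpr_difference(table, attribute, on_label=1)
    return diff if signed else abs(diff)


def tnr_disparity(table: pd.DataFrame, attribute: str, signed: bool = False) -> float:
    """|TNR_minority - TNR_majority| (signed variant: minority minus majority)."""
    diff = _tpr_difference(table, attribute, on_label=0)
    return diff if signed else abs(diff)


def classification_metrics(table: pd.DataFrame) -> dict[str, float]:
    """ACC, AUC (Mann-Whitney, ties count 1/2) and F1 on the favored class."""
    y = table["y"].to_numpy()
    y_hat = table["y_hat"].to_numpy()
    score = table["score"].to_numpy()
    acc = float((y == y_hat).mean())
    if y.min() == y.max():
        warnings.warn("AUC undefined for single-class truth; returning NaN",
                      RuntimeWarning, stacklevel=2)
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y, score))
    f1 = float(f1_score(y, y_hat, zero_division=0.0))
    return {"ACC": acc, "AUC": auc, "F1": f1}


def embedding_attribute_correlation(embeddings: np.ndarray, attribute: np.ndarray) -> float:
    """Signed Pearson r between per-sample aggregated embeddings and a group code.

    Each sample's embedding (any shape) is aggregated to the arithmetic mean
    over all of its dimensions, producing one scalar per individual; the
    Pearson correlation between those scalars and the 0/1 attribute vector
    measures how much group information survives in the representation.
    """
    emb = np.asarray(embeddings, dtype=float)
    att = np.asarray(attribute).ravel()
    if emb.shape[0] != att.size:
        raise ValueError("embeddings and attribute must agree on sample count")
    if att.size < 3:
        raise ValueError("need at least 3 samples for a correlation")
    agg = emb.reshape(emb.shape[0], -1).mean(axis=1)
    if np.ptp(agg) == 0 or np.ptp(att) == 0:
        warnings.warn("constant input; Pearson r undefined, returning NaN",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(agg, att.astype(float)).statistic)


def metrics_report(table: pd.DataFrame, attributes: list[str]) -> dict[str, float]:
    """Flat metric dictionary: global ACC/AUC/F1 plus per-attribute DI/EO/TNRD."""
    report = dict(classification_metrics(table))
    for attr in attributes:
        report[f"DI[{attr}]"] = disparate_impact(table, attr)
        report[f"EO[{attr}]"] = equal_opportunity(table, attr)
        report[f"TNRD[{attr}]"] = tnr_disparity(table, attr)
    return report
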