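"""Synthetic imaging cohorts with controllable demographic bias.

Real clinical imaging cohorts of the kind this package targets (disease
classification from brain MRI slices with demographically imbalanced
phenotypes) are access-restricted, so every downstream module is exercised
on generated cohorts that emulate their structure:

* a binary disease label with controllable prevalence;
* a localized disease signal: a centered blob whose per-subject amplitude is
  drawn from a label-conditional Gaussian (amplitude heterogeneity emulates
  biological variability and keeps the classification problem imperfect);
* per-attribute spatial nuisance patterns: each sensitive attribute owns one
  image corner whose amplitude depends on the attribute value (crisply
  decodable, like scanner or demographic signatures), so a shortcut learner
  can exploit it and an encoder can, in principle, disentangle it from the
  centered disease signal;
* majority:minority imbalance per attribute (minority count =
  round(n / (ratio + 1)), minority coded 1);
* attribute-label confounding: with ``bias_strength`` b, the expected
  fraction of the minority group drawn from the positive class is
  ``(1 - b) * prevalence + b``, so at b=0 the attribute is independent of
  the label by construction and at b=1 the minority group is drawn entirely
  from positives (subject to group sizes).

Generation is bit-reproducible given the spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import Cohort, apply_coding, code_attributes

__all__ = [
    "AttributeSpec",
    "BiasSpec",
    "attribute_region",
    "generate_cohort",
    "oracle_shortcut_score",
]

_CORNERS = ("top-left", "top-right", "bottom-left", "bottom-right")


@dataclass(frozen=True)
class AttributeSpec:
    """One sensitive attribute: name, majority:minority ratio, confounding.

    ``amplitude`` overrides the cohort-level nuisance amplitude for this
    attribute's corner pattern; ``amplitude_sd`` adds per-subject amplitude
    heterogeneity (default 0: a crisp, scanner-signature-like pattern).
    """

    name: str
    imbalance_ratio: float = 3.0
    bias_strength: float = 0.0
    amplitude: float | None = None
    amplitude_sd: float = 0.0

    def __post_init__(self):
        if self.imbalance_ratio < 1.0:
            raise ValueError("imbalance_ratio must be >= 1")
        if not 0.0 <= self.bias_strength <= 1.0:
            raise ValueError("bias_strength must lie in [0, 1]")
        if self.amplitude_sd < 0.0:
            raise ValueError("amplitude_sd must be >= 0")


@dataclass
class BiasSpec:
    """Full recipe for one synthetic cohort."""

    n: int = 200
    image_size: tuple[int, int] = (32, 32)
    label_prevalence: float = 0.5
    attributes: list[AttributeSpec] = field(default_factory=list)
    noise_sd: float = 0.05
    seed: int = 0
    # signal geometry/strength (defaults emulate a weak heterogeneous disease
    # effect vs salient, crisply decodable nuisance patterns — the regime in
    # which shortcut learning and loss choice matter)
    label_amplitude: float = 0.06
    attribute_amplitude: float = 0.30
    amplitude_sd: float = 0.10
    background: float = 0.35

    def __post_init__(self):
        self.attributes = [a if isinstance(a, AttributeSpec) else AttributeSpec(*a)
                           for a in self.attributes]
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0.0 <= self.label_prevalence <= 1.0:
            raise ValueError("label_prevalence must lie in [0, 1]")
        if len(self.attributes) > len(_CORNERS):
            raise ValueError(f"at most {len(_CORNERS)} attributes supported")
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise ValueError("attribute names must be unique")


def attribute_region(image_size: tuple[int, int], index: int) -> tuple[slice, slice]:
    """The corner block owned by attribute ``index`` (its nuisance region)."""
    h, w = image_size
    bh, bw = max(h // 3, 1), max(w // 3, 1)
    if index >= len(_CORNERS):
        raise ValueError(f"attribute index {index} exceeds available corners")
    corner = _CORNERS[index]
    rows = slice(0, bh) if corner.startswith("top") else slice(h - bh, h)
    cols = slice(0, bw) if corner.endswith("left") else slice(w - bw, w)
    return rows, cols


def _label_blob(image_size: tuple[int, int]) -> np.ndarray:
    """Centered Gaussian bump with unit peak — the disease signal template."""
    h, w = image_size
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    sigma = min(h, w) / 5.0
    return np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)))


def _assign_binary(rng: np.random.Generator, n: int, count_ones: int,
                   labels: np.ndarray, bias_strength: float) -> np.ndarray:
    """Assign ``count_ones`` minority memberships, tilted toward positives."""
    n_pos = int(labels.sum())
    n_neg = n - n_pos
    prevalence = n_pos / n
    target_pos = int(round(count_ones * ((1.0 - bias_strength) * prevalence
                                         + bias_strength)))
    target_pos = min(max(target_pos, count_ones - n_neg), n_pos, count_ones)
    target_neg = count_ones - target_pos
    out = np.zeros(n, dtype=np.int64)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    out[rng.choice(pos_idx, size=target_pos, replace=False)] = 1
    out[rng.choice(neg_idx, size=target_neg, replace=False)] = 1
    return out


def generate_cohort(spec: BiasSpec) -> Cohort:
    """Generate a cohort from a :class:`BiasSpec`; bit-reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    h, w = spec.image_size

    n_pos = int(round(n * spec.label_prevalence))
    labels = np.zeros(n, dtype=np.int64)
    labels[rng.permutation(n)[:n_pos]] = 1

    attribute_values = {}
    for attr in spec.attributes:
        m = int(round(n / (attr.imbalance_ratio + 1.0)))
        if m < 1 or n - m < 1:
            raise ValueError(
                f"attribute {attr.name!r}: ratio {attr.imbalance_ratio} implies "
                f"an empty group at n={n}")
        attribute_values[attr.name] = _assign_binary(rng, n, m, labels,
                                                     attr.bias_strength)

    images = np.full((n, h, w), spec.background)
    images += rng.normal(0.0, spec.noise_sd, size=(n, h, w))

    blob = _label_blob((h, w))
    amp_label = rng.normal(spec.label_amplitude * labels, spec.amplitude_sd)
    images += amp_label[:, None, None] * blob[None, :, :]

    for k, attr in enumerate(spec.attributes):
        rows, cols = attribute_region((h, w), k)
        a = attribute_values[attr.name]
        base = spec.attribute_amplitude if attr.amplitude is None else attr.amplitude
        amp = base * a.astype(np.float64)
        if attr.amplitude_sd > 0:
            amp = rng.normal(amp, attr.amplitude_sd)
        images[:, rows, cols] += amp[:, None, None]

    np.clip(images, 0.0, 1.0, out=images)

    phenotype = pd.DataFrame({
        "sample_id": [f"S{i + 1:05d}" for i in range(n)],
        "label": labels,
        **attribute_values,
    })
    names = [a.name for a in spec.attributes]
    coding = code_attributes(phenotype, names)
    coded = apply_coding(phenotype, coding, names)
    return Cohort(images=images, phenotype=phenotype, coding=coding,
                  coded_attributes=coded, attribute_names=names)


def oracle_shortcut_score(cohort: Cohort, attribute: str) -> np.ndarray:
    """Mean intensity over an attribute's known nuisance region, per sample.

    A deliberately biased predictor: it reads only the attribute's corner
    block, so its predictions track group membership by construction.  Used
    to validate that the fairness metrics detect injected bias.
    """
    if attribute not in cohort.attribute_names:
        raise KeyError(f"unknown attribute {attribute!r}; "
                       f"cohort has {cohort.attribute_names}")
    index = cohort.attribute_names.index(attribute)
    rows, cols = attribute_region(cohort.image_size, index)
    return cohort.images[:, rows, cols].mean(axis=(1, 2))
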