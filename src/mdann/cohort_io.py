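"""Cohort data model and I/O.

A cohort bundles grayscale 2-D images with a phenotype table (sample id,
binary disease label, one column per sensitive attribute) and a
majority/minority coding of each attribute: the larger category of an
attribute is coded 0 (majority), the smaller 1 (minority), and the
imbalance ratio ``count_majority / count_minority`` is recorded.

Formats: images as a compressed NPZ bundle with a single ``images`` array of
shape (n, H, W) (a directory of lossless grayscale PNGs ordered by sample id
is also accepted); phenotype as delimited text with header
``sample_id,label,<attr...>`` (comma default, tab accepted); the coding as a
JSON sidecar.  An optional adapter extracts 2-D slices from volumetric
neuroimaging (NIfTI) files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AttributeCode",
    "AttributeCoding",
    "Cohort",
    "read_phenotype",
    "code_attributes",
    "apply_coding",
    "read_cohort",
    "write_cohort",
    "extract_slice_from_volume",
]


@dataclass(frozen=True)
class AttributeCode:
    """Majority/minority coding of one binary sensitive attribute."""

    majority_value: object
    minority_value: object
    imbalance_ratio: float

    def __post_init__(self):
        if self.imbalance_ratio < 1.0:
            raise ValueError("imbalance_ratio must be >= 1")


AttributeCoding = dict[str, AttributeCode]


@dataclass
class Cohort:
    """Images + phenotype + per-attribute majority/minority coding."""

    images: np.ndarray                 # (n, H, W), intensities in [0, 1]
    phenotype: pd.DataFrame            # sample_id, label, raw attribute columns
    coding: AttributeCoding
    coded_attributes: np.ndarray       # (n, K) binary, column order = attribute_names
    attribute_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim != 3:
            raise ValueError("images must be a rank-3 array (n, H, W)")
        n = self.images.shape[0]
        if len(self.phenotype) != n:
            raise ValueError("image count must equal phenotype row count")
        if not np.isfinite(self.images).all():
            raise ValueError("image intensities must be finite")
        if self.images.size and (self.images.min() < 0 or self.images.max() > 1):
            raise ValueError("image intensities must lie in [0, 1]")
        _validate_phenotype(self.phenotype, self.attribute_names)
        expected = apply_coding(self.phenotype, self.coding, self.attribute_names)
        if not np.array_equal(np.asarray(self.coded_attributes), expected):
            raise ValueError("coded_attributes inconsistent with coding/phenotype")
        self.coded_attributes = expected

    @property
    def n(self) -> int:
        return self.images.shape[0]

    @property
    def image_size(self) -> tuple[int, int]:
        return self.images.shape[1], self.images.shape[2]

    @property
    def labels(self) -> np.ndarray:
        return self.phenotype["label"].to_numpy().astype(int)

    def subset(self, indices) -> "Cohort":
        indices = np.asarray(indices)
        return Cohort(
            images=self.images[indices],
            phenotype=self.phenotype.iloc[indices].reset_index(drop=True),
            coding=self.coding,
            coded_attributes=self.coded_attributes[indices],
            attribute_names=list(self.attribute_names),
        )


def _validate_phenotype(phenotype: pd.DataFrame, attribute_names: list[str]) -> None:
    for col in ("sample_id", "label"):
        if col not in phenotype.columns:
            raise ValueError(f"phenotype is missing required column {col!r}")
    if phenotype["sample_id"].duplicated().any():
        dups = phenotype.loc[phenotype["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    labels = phenotype["label"].to_numpy()
    if not np.isin(labels, (0, 1)).all():
        bad = sorted(set(labels) - {0, 1})
        raise ValueError(f"labels must be binary 0/1; found {bad}")
    for attr in attribute_names:
        if attr not in phenotype.columns:
            raise ValueError(f"phenotype is missing attribute column {attr!r}")
        if phenotype[attr].isna().any():
            raise ValueError(f"attribute {attr!r} has missing values")


def read_phenotype(path: Path | str) -> pd.DataFrame:
    """Read a delimited phenotype table (comma default, tab accepted)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table = pd.read_csv(path, sep=sep)
    if "sample_id" not in table.columns and "\t" in str(table.columns[0]):
        table = pd.read_csv(path, sep="\t")
    return table


def code_attributes(phenotype: pd.DataFrame, attribute_names: list[str]) -> AttributeCoding:
    """Derive the majority(0)/minority(1) coding from observed counts.

    Each attribute must have exactly two observed categories.  On a tie the
    lexicographically smaller category (by string form) is coded as the
    majority, with a warning.
    """
    _validate_phenotype(phenotype, attribute_names)
    coding: AttributeCoding = {}
    for attr in attribute_names:
        counts = phenotype[attr].value_counts()
        if len(counts) != 2:
            raise ValueError(
                f"attribute {attr!r} has {len(counts)} categories "
                f"({list(counts.index)}); pre-binarize to exactly 2")
        (v1, c1), (v2, c2) = counts.items()
        if c1 == c2:
            warnings.warn(
                f"attribute {attr!r}: exact 50/50 split; coding the "
                f"lexicographically smaller category as majority",
                UserWarning, stacklevel=2)
            majority, minority = sorted((v1, v2), key=str)
            c_maj = c_min = c1
        else:
            majority, minority = (v1, v2) if c1 > c2 else (v2, v1)
            c_maj, c_min = max(c1, c2), min(c1, c2)
        coding[attr] = AttributeCode(majority_value=majority, minority_value=minority,
                                     imbalance_ratio=c_maj / c_min)
    return coding


def apply_coding(phenotype: pd.DataFrame, coding: AttributeCoding,
                 attribute_names: list[str]) -> np.ndarray:
    """Map raw attribute values to the binary minority=1 / majority=0 code."""
    columns = []
    for attr in attribute_names:
        code = coding[attr]
        values = phenotype[attr]
        known = values.isin([code.majority_value, code.minority_value])
        if not known.all():
            bad = sorted(set(values[~known]), key=str)
            raise ValueError(f"attribute {attr!r}: values {bad} not in coding")
        columns.append((values == code.minority_value).to_numpy().astype(np.int64))
    if not columns:
        return np.zeros((len(phenotype), 0), dtype=np.int64)
    return np.column_stack(columns)


def _scale_unit(images: np.ndarray) -> np.ndarray:
    """Per-cohort global min-max scaling to [0, 1]; constant input maps to 0."""
    images = np.asarray(images, dtype=np.float64)
    lo, hi = images.min(), images.max()
    if 0.0 <= lo and hi <= 1.0:
        return images
    if hi == lo:
        return np.zeros_like(images)
    return (images - lo) / (hi - lo)


def _read_images(image_path: Path) -> tuple[np.ndarray, list[str] | None]:
    """Read an image bundle; returns (images, ids or None for NPZ bundles)."""
    if image_path.is_dir():
        import imageio.v3 as iio

        files = sorted(image_path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG files found in {image_path}")
        arrays, ids = [], []
        for f in files:
            arr = np.asarray(iio.imread(f), dtype=np.float64)
            if arr.ndim != 2:
                raise ValueError(f"{f} is not a single-channel grayscale image")
            arrays.append(arr)
            ids.append(f.stem)
        return np.stack(arrays), ids
    with np.load(image_path) as bundle:
        if "images" not in bundle:
            raise ValueError(f"{image_path} has no 'images' array")
        images = bundle["images"]
        ids = [str(s) for s in bundle["sample_id"]] if "sample_id" in bundle else None
    if images.ndim != 3:
        raise ValueError("'images' must have shape (n, H, W)")
    return images.astype(np.float64), ids


def read_cohort(image_path: Path | str, phenotype_path: Path | str,
                attribute_names: list[str],
                coding: AttributeCoding | None = None) -> Cohort:
    """Read a cohort, matching images to phenotype rows by sample id.

    Rows follow phenotype order.  NPZ bundles without a ``sample_id`` array
    are assumed to be stored in phenotype order.  Intensities are min-max
    scaled to [0, 1] when outside that range.  If ``coding`` is None it is
    read from a ``coding.json`` sidecar next to the images when present,
    otherwise derived from the observed counts.
    """
    image_path, phenotype_path = Path(image_path), Path(phenotype_path)
    phenotype = read_phenotype(phenotype_path)
    _validate_phenotype(phenotype, attribute_names)
    images, image_ids = _read_images(image_path)
    pheno_ids = [str(s) for s in phenotype["sample_id"]]
    if image_ids is not None:
        missing = sorted(set(pheno_ids) - set(image_ids))
        if missing:
            raise ValueError(f"phenotype ids without images: {missing}")
        extra = sorted(set(image_ids) - set(pheno_ids))
        if extra:
            raise ValueError(f"images without phenotype rows: {extra}")
        order = [image_ids.index(s) for s in pheno_ids]
        images = images[order]
    elif images.shape[0] != len(phenotype):
        raise ValueError(
            f"image bundle has {images.shape[0]} images but phenotype has "
            f"{len(phenotype)} rows and carries no sample ids to match by")
    images = _scale_unit(images)
    if coding is None:
        sidecar = image_path.parent / "coding.json" if image_path.is_file() \
            else image_path / "coding.json"
        coding = _read_coding(sidecar) if sidecar.exists() else \
            code_attributes(phenotype, attribute_names)
    coded = apply_coding(phenotype, coding, attribute_names)
    return Cohort(images=images, phenotype=phenotype, coding=coding,
                  coded_attributes=coded, attribute_names=list(attribute_names))


def _read_coding(path: Path) -> AttributeCoding:
    raw = json.loads(path.read_text())
    return {name: AttributeCode(**entry) for name, entry in raw.items()}


def write_cohort(cohort: Cohort, out_dir: Path | str) -> dict[str, str]:
    """Write a cohort as NPZ images + CSV phenotype + JSON coding sidecar.

    Returns a manifest mapping artifact names to file paths.  Read-back with
    :func:`read_cohort` reproduces images and coded attributes exactly.
    """
    if cohort.n == 0:
        raise ValueError("empty cohort")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images_path = out_dir / "images.npz"
    phenotype_path = out_dir / "phenotype.csv"
    coding_path = out_dir / "coding.json"
    try:
        np.savez_compressed(
            images_path, images=cohort.images,
            sample_id=np.asarray([str(s) for s in cohort.phenotype["sample_id"]]))
        cohort.phenotype.to_csv(phenotype_path, index=False)
        coding_path.write_text(json.dumps(
            {name: {"majority_value": _jsonable(c.majority_value),
                    "minority_value": _jsonable(c.minority_value),
                    "imbalance_ratio": c.imbalance_ratio}
             for name, c in cohort.coding.items()}, indent=2))
    except OSError as exc:
        raise OSError(f"failed writing cohort to {out_dir}: {exc}") from exc
    return {"images": str(images_path), "phenotype": str(phenotype_path),
            "coding": str(coding_path)}


def _jsonable(value):
    if isinstance(value, np.generic):
        return value.item()
    return value


def extract_slice_from_volume(volume_path: Path | str, axis: int = 2,
                              index: int | str = "middle") -> np.ndarray:
    """Extract one 2-D slice from a volumetric neuroimaging file.

    Convenience adapter only: the core pipeline operates on 2-D arrays, and
    how slices are derived from volumes is an explicit user choice.  The
    slice is min-max scaled to [0, 1]; a constant slice maps to zeros.
    """
    import nibabel as nib

    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    volume = np.asanyarray(nib.load(str(volume_path)).dataobj, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {volume.shape}")
    depth = volume.shape[axis]
    if index == "middle":
        index = depth // 2
    if not 0 <= int(index) < depth:
        raise IndexError(
            f"slice index {index} out of bounds for axis {axis} of volume "
            f"with shape {volume.shape}")
    sl = np.take(volume, int(index), axis=axis)
    return _scale_unit(sl)
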