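"""From labelled blobs to the seeds x bands matrix X and response vector Y.

The spectral signature of a seed is the mean reflectance of its pixels at each
band. Signatures are modelled on the raw reflectance scale: no SNV, derivative
or autoscaling is applied by default (a ``preprocess`` hook exists but is the
identity unless the caller supplies one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cube import MultispectralCube, WavelengthGrid
from .exceptions import SplitError, ValidationError
from .segmentation import BlobTable

__all__ = [
    "SpectraMatrix",
    "LabelVector",
    "DataSplit",
    "extract_mean_spectra",
    "stratified_split",
    "spectra_to_csv",
    "spectra_from_csv",
]


@dataclass(frozen=True)
class SpectraMatrix:
    """``n_seeds x n_bands`` matrix of mean reflectance signatures."""

    values: np.ndarray
    seed_ids: tuple[int, ...]
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValidationError(f"spectra matrix must be 2-D, got {v.shape}")
        if v.shape[0] != len(self.seed_ids):
            raise ValidationError("row count does not match seed_ids")
        if v.shape[1] != len(self.grid):
            raise ValidationError(
                f"{v.shape[1]} bands in matrix vs {len(self.grid)} in grid"
            )
        if not np.isfinite(v).all():
            raise ValidationError("spectra contain missing/non-finite values")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "seed_ids", tuple(int(s) for s in self.seed_ids))

    @property
    def n_seeds(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def take(self, idx: Sequence[int]) -> "SpectraMatrix":
        idx = np.asarray(idx, dtype=int)
        return SpectraMatrix(
            self.values[idx], tuple(np.asarray(self.seed_ids)[idx]), self.grid
        )


@dataclass(frozen=True)
class LabelVector:
    """Dummy-coded class responses aligned with a :class:`SpectraMatrix`.

    ``class_names[k]`` is the label coded as integer ``k`` (two-class models
    use 0/1, three-class models 0/1/2, and so on).
    """

    seed_ids: tuple[int, ...]
    class_names: tuple[str, ...]
    codes: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=int)
        if codes.ndim != 1 or codes.size != len(self.seed_ids):
            raise ValidationError("codes must align one-to-one with seed_ids")
        k = len(self.class_names)
        if codes.size and (codes.min() < 0 or codes.max() >= k):
            raise ValidationError(f"codes must lie in 0..{k - 1}")
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "seed_ids", tuple(int(s) for s in self.seed_ids))
        object.__setattr__(self, "class_names", tuple(self.class_names))

    @classmethod
    def from_labels(
        cls,
        seed_ids: Sequence[int],
        labels: Sequence[str],
        class_names: Sequence[str] | None = None,
    ) -> "LabelVector":
        """Build a dummy coding from string labels.

        ``class_names`` fixes the code order explicitly; by default classes
        are coded in order of first appearance.
        """
        labels = list(labels)
        if class_names is None:
            class_names = list(dict.fromkeys(labels))
        lut = {c: i for i, c in enumerate(class_names)}
        try:
            codes = np.array([lut[l] for l in labels], dtype=int)
        except KeyError as e:
            raise ValidationError(f"label {e} not in class_names {class_names}") from e
        return cls(tuple(seed_ids), tuple(class_names), codes)

    def __len__(self) -> int:
        return len(self.seed_ids)

    def counts(self) -> dict[str, int]:
        return {
            c: int((self.codes == k).sum()) for k, c in enumerate(self.class_names)
        }

    def take(self, idx: Sequence[int]) -> "LabelVector":
        idx = np.asarray(idx, dtype=int)
        return LabelVector(
            tuple(np.asarray(self.seed_ids)[idx]), self.class_names, self.codes[idx]
        )


@dataclass(frozen=True)
class DataSplit:
    """Disjoint training/validation partition with per-class bookkeeping."""

    training: tuple[SpectraMatrix, LabelVector]
    validation: tuple[SpectraMatrix, LabelVector]
    rng_seed: int

    @property
    def class_counts(self) -> pd.DataFrame:
        rows = []
        for side, (_, y) in (("training", self.training), ("validation", self.validation)):
            for cls, n in y.counts().items():
                rows.append({"set": side, "class": cls, "n": n})
        return pd.DataFrame(rows)


def extract_mean_spectra(
    cube: MultispectralCube,
    blobs: BlobTable,
    preprocess: Callable[[np.ndarray], np.ndarray] | None = None,
) -> SpectraMatrix:
    """Average each blob's pixels per band to get its reflectance signature.

    Row ``b`` is the arithmetic mean over blob ``b``'s pixels in each band;
    row order follows blob_id order (raster order of first pixels).

    ``preprocess`` optionally transforms the finished matrix (rows = seeds);
    the default is the identity — signatures stay on the raw reflectance scale.
    """
    h, w, _ = cube.shape
    rows = []
    ids = []
    for blob in blobs:
        if blob.area_px == 0:
            raise ValidationError(f"blob {blob.blob_id} is empty")
        if blob.rows.max() >= h or blob.cols.max() >= w:
            raise ValidationError(f"blob {blob.blob_id} exceeds cube bounds")
        rows.append(cube.pixels[blob.rows, blob.cols].mean(axis=0, dtype=np.float64))
        ids.append(blob.blob_id)
    values = np.vstack(rows) if rows else np.empty((0, cube.shape[2]))
    if preprocess is not None:
        values = np.asarray(preprocess(values), dtype=np.float64)
    return SpectraMatrix(values, tuple(ids), cube.grid)


def stratified_split(
    X: SpectraMatrix,
    Y: LabelVector,
    validation_fraction: float = 0.2,
    rng_seed: int = 0,
    validation_counts: Mapping[str, int] | None = None,
) -> DataSplit:
    """Stratified random train/validation split, reproducible from ``rng_seed``.

    Per class, ``round(validation_fraction * n_class)`` seeds go to the
    validation side (at least 1 when the fraction is positive). Explicit
    ``validation_counts`` per class override the fraction, which allows
    reproducing a published split's exact per-class counts when they do not
    fall on a single rounding rule.

    Raises
    ------
    SplitError
        If a class has fewer than 2 members while a validation side is
        requested (each side must see every class).
    """
    if not (0.0 <= validation_fraction < 1.0):
        raise SplitError("validation_fraction must lie in [0, 1)")
    if tuple(X.seed_ids) != tuple(Y.seed_ids):
        raise ValidationError("X and Y are not aligned on seed_ids")

    rng = np.random.default_rng(rng_seed)
    want_validation = validation_fraction > 0 or bool(validation_counts)
    val_idx: list[int] = []
    train_idx: list[int] = []
    for k, cls in enumerate(Y.class_names):
        members = np.flatnonzero(Y.codes == k)
        n = members.size
        if want_validation and n < 2:
            raise SplitError(
                f"class '{cls}' has {n} member(s); at least 2 are needed to split"
            )
        if validation_counts is not None:
            n_val = int(validation_counts.get(cls, 0))
            if not (0 <= n_val <= n):
                raise SplitError(f"validation count {n_val} invalid for class '{cls}' (n={n})")
        else:
            n_val = int(round(validation_fraction * n))
            if validation_fraction > 0:
                n_val = min(max(n_val, 1), n - 1)
        perm = rng.permutation(members)
        val_idx.extend(perm[:n_val].tolist())
        train_idx.extend(perm[n_val:].tolist())
    train_idx.sort()
    val_idx.sort()
    return DataSplit(
        training=(X.take(train_idx), Y.take(train_idx)),
        validation=(X.take(val_idx), Y.take(val_idx)),
        rng_seed=rng_seed,
    )


def spectra_to_csv(
    X: SpectraMatrix, path: str | Path, Y: LabelVector | None = None
) -> Path:
    """Write X (and optionally the class column) to CSV.

    Header: ``seed_id, wl_<nm>..., class``; wavelengths are printed without a
    trailing ``.0`` so the default grid yields ``wl_375 ... wl_970``.
    """
    cols = [f"wl_{w:g}" for w in X.grid.wavelengths_nm]
    df = pd.DataFrame(X.values, columns=cols)
    df.insert(0, "seed_id", X.seed_ids)
    if Y is not None:
        if tuple(Y.seed_ids) != tuple(X.seed_ids):
            raise ValidationError("X and Y are not aligned on seed_ids")
        df["class"] = [Y.class_names[c] for c in Y.codes]
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def spectra_from_csv(path: str | Path) -> tuple[SpectraMatrix, LabelVector | None]:
    """Read back a CSV written by :func:`spectra_to_csv`."""
    df = pd.read_csv(path)
    wl_cols = [c for c in df.columns if c.startswith("wl_")]
    grid = WavelengthGrid(tuple(float(c[3:]) for c in wl_cols))
    X = SpectraMatrix(df[wl_cols].to_numpy(), tuple(df["seed_id"]), grid)
    Y = None
    if "class" in df.columns:
        Y = LabelVector.from_labels(tuple(df["seed_id"]), df["class"].tolist())
    return X, Y
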