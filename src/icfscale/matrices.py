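"""Response-matrix containers shared by every pipeline stage.

Two containers cover the whole pipeline: :class:`OrdinalResponseMatrix` holds raw
ICF qualifier codes (0-4 severity, 8 "not specified", 9 "not applicable", or
missing), and :class:`BinaryResponseMatrix` holds the dichotomized
functioning/disabled codes that all Mokken and Rasch computations run on.
Both are thin wrappers around a numpy array plus person and item identifiers,
with CSV round-tripping through pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_ORDINAL_CODES = (0, 1, 2, 3, 4)
MISSING_CODES = (8, 9)


class ValidationError(ValueError):
    """Raised when an input matrix violates its coding contract."""


class PipelineError(RuntimeError):
    """Raised when a screening step leaves nothing to analyze."""


def _as_ids(ids, n: int, prefix: str) -> list[str]:
    if ids is None:
        return [f"{prefix}{i + 1}" for i in range(n)]
    ids = [str(x) for x in ids]
    if len(ids) != n:
        raise ValidationError(f"expected {n} {prefix!r} identifiers, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate {prefix!r} identifiers")
    return ids


@dataclass
class OrdinalResponseMatrix:
    """Persons x items matrix of qualifier codes with missing entries as NaN.

    ``values`` is a float array; codes 8/9 are kept verbatim until
    :func:`icfscale.shaping.recode_missing` converts them to NaN.
    """

    values: np.ndarray
    person_ids: list[str] = field(default=None)  # type: ignore[assignment]
    item_codes: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D persons x items array")
        n, k = self.values.shape
        self.person_ids = _as_ids(self.person_ids, n, "p")
        self.item_codes = _as_ids(self.item_codes, k, "item")
        self._validate_codes()

    def _validate_codes(self) -> None:
        vals = self.values
        ok = np.isnan(vals)
        for c in VALID_ORDINAL_CODES + MISSING_CODES:
            ok |= vals == c
        if not ok.all():
            p, i = np.argwhere(~ok)[0]
            raise ValidationError(
                f"invalid code {vals[p, i]!r} at person {self.person_ids[p]!r}, "
                f"item {self.item_codes[i]!r}"
            )

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """True where the entry is absent or carries a missing code (8/9)."""
        return np.isnan(self.values) | (self.values == 8) | (self.values == 9)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.person_ids, columns=self.item_codes)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OrdinalResponseMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            person_ids=list(frame.index.astype(str)),
            item_codes=list(frame.columns.astype(str)),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="person_id")

    @classmethod
    def read_csv(cls, path) -> "OrdinalResponseMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls.from_frame(frame)

    def copy(self) -> "OrdinalResponseMatrix":
        return OrdinalResponseMatrix(
            self.values.copy(), list(self.person_ids), list(self.item_codes)
        )


@dataclass
class BinaryResponseMatrix:
    """Complete persons x items matrix in {0, 1}: 1 = functioning, 0 = disabled."""

    values: np.ndarray
    person_ids: list[str] = field(default=None)  # type: ignore[assignment]
    item_codes: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValidationError("values must be a 2-D persons x items array")
        if np.isnan(np.asarray(vals, dtype=float)).any():
            raise ValidationError("binary matrix must have no missing entries")
        vals = vals.astype(int)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("binary matrix entries must be 0 or 1")
        self.values = vals
        n, k = vals.shape
        if n < 2 or k < 2:
            raise ValidationError("binary matrix needs at least 2 persons and 2 items")
        self.person_ids = _as_ids(self.person_ids, n, "p")
        self.item_codes = _as_ids(self.item_codes, k, "item")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def total_scores(self) -> np.ndarray:
        return self.values.sum(axis=1)

    @property
    def popularities(self) -> np.ndarray:
        """Per-item pass proportions (sample difficulty order statistic)."""
        return self.values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.person_ids, columns=self.item_codes)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BinaryResponseMatrix":
        return cls(
            values=frame.to_numpy(),
            person_ids=list(frame.index.astype(str)),
            item_codes=list(frame.columns.astype(str)),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="person_id")

    @classmethod
    def read_csv(cls, path) -> "BinaryResponseMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0))

    def select_items(self, codes) -> "BinaryResponseMatrix":
        idx = [self.item_codes.index(c) for c in codes]
        return BinaryResponseMatrix(
            self.values[:, idx], list(self.person_ids), [self.item_codes[i] for i in idx]
        )

    def copy(self) -> "BinaryResponseMatrix":
        return BinaryResponseMatrix(
            self.values.copy(), list(self.person_ids), list(self.item_codes)
        )
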