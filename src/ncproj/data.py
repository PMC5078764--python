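"""Typed containers for the matrices the pipeline consumes and produces.

All matrices carry explicit entity labels (miRNA or disease identifiers,
treated as opaque strings). Label order is part of the container identity:
it fixes row/column order everywhere downstream, so two matrices over the
same entities in different orders are deliberately *not* interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "EntityIndex",
    "SimilarityMatrix",
    "FamilyMatrix",
    "AssociationMatrix",
    "ScoreMatrix",
    "Dataset",
    "JaccardCounts",
    "SIMILARITY_ROLES",
    "SCORE_MODES",
]

#: Roles a similarity matrix can play in the pipeline. MM/DD are the external
#: (functional / semantic) similarities; NCM/NCD are Jaccard similarities of
#: association profiles; SM/SD are the integrated networks fed to the
#: projection step.
SIMILARITY_ROLES = ("MM", "DD", "NCM", "NCD", "SM", "SD")

SCORE_MODES = ("combined", "mirna_only", "disease_only")

_SYMMETRY_TOL = 1e-12
_RANGE_TOL = 1e-12


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


@dataclass(frozen=True)
class EntityIndex:
    """Ordered collection of unique entity labels defining matrix axes."""

    labels: tuple[str, ...]
    _positions: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.labels)
        object.__setattr__(self, "labels", labels)
        positions = {}
        for i, label in enumerate(labels):
            if label in positions:
                raise ValidationError(f"duplicate entity label: {label!r}")
            positions[label] = i
        object.__setattr__(self, "_positions", positions)

    @classmethod
    def from_iterable(cls, labels: Iterable[str]) -> "EntityIndex":
        return cls(tuple(labels))

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self._positions

    def __iter__(self):
        return iter(self.labels)

    def position(self, label: str) -> int:
        try:
            return self._positions[label]
        except KeyError:
            raise KeyError(f"unknown entity label: {label!r}") from None

    def positions(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self.position(l) for l in labels], dtype=np.intp)

    def subset(self, labels: Sequence[str]) -> "EntityIndex":
        """New index with `labels` in their current relative order."""
        keep = set(labels)
        return EntityIndex(tuple(l for l in self.labels if l in keep))


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric labeled matrix of similarities in [0, 1]."""

    index: EntityIndex
    values: np.ndarray
    role: str = "MM"

    def __post_init__(self) -> None:
        arr = _as_float_array(self.values, f"{self.role} matrix")
        n = len(self.index)
        if arr.shape != (n, n):
            raise ValidationError(
                f"{self.role} matrix shape {arr.shape} does not match "
                f"{n} labels"
            )
        if self.role not in SIMILARITY_ROLES:
            raise ValidationError(f"unknown similarity role: {self.role!r}")
        asym = np.max(np.abs(arr - arr.T)) if n else 0.0
        if asym > _SYMMETRY_TOL:
            i, j = np.unravel_index(np.argmax(np.abs(arr - arr.T)), arr.shape)
            raise ValidationError(
                f"{self.role} matrix asymmetric at "
                f"({self.index.labels[i]!r}, {self.index.labels[j]!r}): "
                f"|{arr[i, j]!r} - {arr[j, i]!r}| > {_SYMMETRY_TOL}"
            )
        if n and (arr.min() < -_RANGE_TOL or arr.max() > 1 + _RANGE_TOL):
            raise ValidationError(
                f"{self.role} matrix entries outside [0, 1]: "
                f"min={arr.min()!r}, max={arr.max()!r}"
            )
        arr = np.clip(arr, 0.0, 1.0)
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return len(self.index)

    def with_role(self, role: str) -> "SimilarityMatrix":
        return SimilarityMatrix(self.index, np.array(self.values), role)


@dataclass(frozen=True)
class FamilyMatrix:
    """Binary symmetric same-family indicator over miRNAs; diagonal is 1."""

    index: EntityIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        n = len(self.index)
        if arr.shape != (n, n):
            raise ValidationError(
                f"family matrix shape {arr.shape} does not match {n} labels"
            )
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError("family matrix entries must be 0 or 1")
        arr = arr.astype(np.int8)
        if not np.array_equal(arr, arr.T):
            raise ValidationError("family matrix must be symmetric")
        if n and not np.all(np.diag(arr) == 1):
            raise ValidationError("family matrix diagonal must be 1")
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @classmethod
    def identity(cls, index: EntityIndex) -> "FamilyMatrix":
        """All-singleton families (every miRNA only related to itself)."""
        return cls(index, np.eye(len(index), dtype=np.int8))

    @classmethod
    def from_families(
        cls, index: EntityIndex, family_of: dict
    ) -> "FamilyMatrix":
        """Build FAM(i,j)=1 iff i and j share a family.

        miRNAs absent from `family_of` are singletons.
        """
        n = len(index)
        fam = np.eye(n, dtype=np.int8)
        groups: dict = {}
        for label, family in family_of.items():
            if label in index:
                groups.setdefault(family, []).append(index.position(label))
        for members in groups.values():
            idx = np.array(members, dtype=np.intp)
            fam[np.ix_(idx, idx)] = 1
        return cls(index, fam)


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary miRNA x disease adjacency matrix of known associations."""

    mirna_index: EntityIndex
    disease_index: EntityIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        shape = (len(self.mirna_index), len(self.disease_index))
        if arr.shape != shape:
            raise ValidationError(
                f"association matrix shape {arr.shape} does not match "
                f"({shape[0]} miRNAs, {shape[1]} diseases)"
            )
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError("association matrix entries must be 0 or 1")
        arr = arr.astype(np.int8)
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    def pairs(self) -> list[tuple[str, str]]:
        """Known (miRNA, disease) label pairs, row-major order."""
        rows, cols = np.nonzero(self.values)
        return [
            (self.mirna_index.labels[i], self.disease_index.labels[j])
            for i, j in zip(rows, cols)
        ]


@dataclass(frozen=True)
class ScoreMatrix:
    """Real-valued miRNA x disease matrix of projection scores."""

    mirna_index: EntityIndex
    disease_index: EntityIndex
    values: np.ndarray
    mode: str = "combined"

    def __post_init__(self) -> None:
        arr = _as_float_array(self.values, "score matrix")
        shape = (len(self.mirna_index), len(self.disease_index))
        if arr.shape != shape:
            raise ValidationError(
                f"score matrix shape {arr.shape} does not match {shape}"
            )
        if self.mode not in SCORE_MODES:
            raise ValidationError(f"unknown score mode: {self.mode!r}")
        if arr.size and arr.min() < 0:
            raise ValidationError("score matrix entries must be >= 0")
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    def score(self, mirna: str, disease: str) -> float:
        return float(
            self.values[
                self.mirna_index.position(mirna),
                self.disease_index.position(disease),
            ]
        )


@dataclass(frozen=True)
class Dataset:
    """Aligned bundle of the four pipeline inputs.

    `fam` is optional: running without family information is a supported
    configuration, in which case FAM defaults to the identity (all
    singletons) wherever it is needed.
    """

    mm: SimilarityMatrix
    dd: SimilarityMatrix
    as_matrix: AssociationMatrix
    fam: Optional[FamilyMatrix] = None

    def __post_init__(self) -> None:
        if self.mm.index != self.as_matrix.mirna_index:
            raise ValidationError(
                "miRNA labels of MM and the association matrix differ"
            )
        if self.dd.index != self.as_matrix.disease_index:
            raise ValidationError(
                "disease labels of DD and the association matrix differ"
            )
        if self.fam is not None and self.fam.index != self.mm.index:
            raise ValidationError(
                "miRNA labels of FAM and MM differ"
            )

    @property
    def mirna_index(self) -> EntityIndex:
        return self.as_matrix.mirna_index

    @property
    def disease_index(self) -> EntityIndex:
        return self.as_matrix.disease_index

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_index)

    @property
    def n_disease(self) -> int:
        return len(self.disease_index)

    def family_values(self) -> np.ndarray:
        """FAM as an array, identity if no family information was supplied."""
        if self.fam is None:
            return np.eye(self.n_mirna, dtype=np.int8)
        return self.fam.values

    def replace_associations(self, values: np.ndarray) -> "Dataset":
        """Same entities and similarities, different association matrix."""
        return Dataset(
            mm=self.mm,
            dd=self.dd,
            fam=self.fam,
            as_matrix=AssociationMatrix(
                self.mirna_index, self.disease_index, values
            ),
        )


@dataclass(frozen=True)
class JaccardCounts:
    """Co-occurrence pattern counts between two binary profiles.

    n11 counts positions set in both profiles, n10 positions set only in the
    first, n01 positions set only in the second. Joint absences are ignored
    by the profile Jaccard measure.
    """

    n11: int
    n10: int
    n01: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01) < 0:
            raise ValidationError("Jaccard counts must be nonnegative")

    def jaccard(self, epsilon: float) -> float:
        return self.n11 / (self.n11 + self.n10 + self.n01 + epsilon)

    @classmethod
    def from_profiles(cls, u: np.ndarray, v: np.ndarray) -> "JaccardCounts":
        u = np.asarray(u, dtype=bool)
        v = np.asarray(v, dtype=bool)
        if u.shape != v.shape:
            raise ValidationError("profiles must have equal length")
        return cls(
            n11=int(np.sum(u & v)),
            n10=int(np.sum(u & ~v)),
            n01=int(np.sum(~u & v)),
        )
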