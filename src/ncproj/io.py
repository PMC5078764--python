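"""Readers and writers for the tab-separated dialects the tool exchanges.

Matrices travel as labeled TSV (header row of column labels, leading label
column); associations and family membership as two-column edge lists.
Label matching is exact string match after whitespace trimming — no case
folding, so e.g. ``hsa-mir-21`` and ``hsa-miR-21`` are distinct and
reconciling such source-database spelling variants is the caller's job.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import (
    AssociationMatrix,
    Dataset,
    EntityIndex,
    FamilyMatrix,
    ScoreMatrix,
    SimilarityMatrix,
    ValidationError,
)

__all__ = [
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_association_list",
    "write_association_list",
    "read_family_table",
    "read_score_matrix",
    "write_score_matrix",
    "align_dataset",
    "AlignmentReport",
    "write_rankings",
]

log = logging.getLogger(__name__)

# Input repair thresholds: asymmetry / range violations up to this size are
# treated as floating-point round-off and repaired; anything larger is a
# data error and rejected.
_REPAIR_TOL = 1e-8


def _read_labeled_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str).str.strip()
    df.columns = [str(c).strip() for c in df.columns]
    return df


def read_similarity_matrix(path, role: str = "MM") -> SimilarityMatrix:
    """Load a labeled square similarity matrix from TSV.

    Tiny asymmetries (<= 1e-8) are symmetrized by averaging, and entries
    within 1e-8 of the [0, 1] boundary are clamped; larger violations raise
    with the offending label pair or cell named.
    """
    df = _read_labeled_table(path)
    if df.shape[0] != df.shape[1]:
        raise ValidationError(
            f"{path}: similarity matrix must be square, got {df.shape}"
        )
    if list(df.index) != list(df.columns):
        raise ValidationError(
            f"{path}: row labels and column labels differ"
        )
    index = EntityIndex.from_iterable(df.index)
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric cell ({exc})") from exc
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"{path}: non-finite value at "
            f"({index.labels[i]!r}, {index.labels[j]!r})"
        )
    asym = np.abs(values - values.T)
    if values.size and asym.max() > _REPAIR_TOL:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValidationError(
            f"{path}: asymmetric pair "
            f"({index.labels[i]!r}, {index.labels[j]!r}): "
            f"{values[i, j]!r} vs {values[j, i]!r}"
        )
    values = (values + values.T) / 2.0
    if values.size and (
        values.min() < -_REPAIR_TOL or values.max() > 1 + _REPAIR_TOL
    ):
        flat = np.argmax(np.maximum(-values, values - 1))
        i, j = np.unravel_index(flat, values.shape)
        raise ValidationError(
            f"{path}: entry outside [0, 1] at "
            f"({index.labels[i]!r}, {index.labels[j]!r}): {values[i, j]!r}"
        )
    values = np.clip(values, 0.0, 1.0)
    return SimilarityMatrix(index, values, role)


def write_similarity_matrix(matrix: SimilarityMatrix, path) -> None:
    df = pd.DataFrame(
        matrix.values, index=matrix.index.labels, columns=matrix.index.labels
    )
    df.to_csv(path, sep="\t", float_format="%.12g")


def _read_pair_table(path, what: str) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) != 2 or not all(fields):
                raise ValidationError(
                    f"{path}:{lineno}: expected exactly two tab-separated "
                    f"fields, got {line!r}"
                )
            pairs.append((fields[0], fields[1]))
    if not pairs:
        raise ValidationError(f"{path}: empty {what} file")
    return pairs


def read_association_list(path) -> AssociationMatrix:
    """Load known associations from a two-column (miRNA, disease) TSV.

    A header line is tolerated (detected as the literal pair mirna/disease,
    case-insensitive). Duplicate pairs collapse to a single association.
    The resulting axes are the sorted distinct labels observed.
    """
    pairs = _read_pair_table(path, "association")
    first = (pairs[0][0].lower(), pairs[0][1].lower())
    if first in {("mirna", "disease"), ("mir", "disease")}:
        pairs = pairs[1:]
        if not pairs:
            raise ValidationError(f"{path}: no association rows after header")
    mirnas = EntityIndex.from_iterable(sorted({m for m, _ in pairs}))
    diseases = EntityIndex.from_iterable(sorted({d for _, d in pairs}))
    values = np.zeros((len(mirnas), len(diseases)), dtype=np.int8)
    for m, d in pairs:
        values[mirnas.position(m), diseases.position(d)] = 1
    return AssociationMatrix(mirnas, diseases, values)


def write_association_list(matrix: AssociationMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna\tdisease\n")
        for m, d in matrix.pairs():
            fh.write(f"{m}\t{d}\n")


def read_family_table(path, mirnas: Optional[EntityIndex] = None) -> FamilyMatrix:
    """Load family membership from a two-column (miRNA, family) TSV.

    If `mirnas` is given the matrix is built over that index, with miRNAs
    absent from the table as singleton families; otherwise the axis is the
    sorted miRNAs observed in the table. A miRNA mapped to two different
    families is an error.
    """
    pairs = _read_pair_table(path, "family")
    if (pairs[0][0].lower(), pairs[0][1].lower()) == ("mirna", "family"):
        pairs = pairs[1:]
        if not pairs:
            raise ValidationError(f"{path}: no family rows after header")
    family_of: dict[str, str] = {}
    for m, fam in pairs:
        if m in family_of and family_of[m] != fam:
            raise ValidationError(
                f"{path}: miRNA {m!r} listed with two families "
                f"({family_of[m]!r}, {fam!r})"
            )
        family_of[m] = fam
    if mirnas is None:
        mirnas = EntityIndex.from_iterable(sorted(family_of))
    return FamilyMatrix.from_families(mirnas, family_of)


def read_score_matrix(path, mode: str = "combined") -> ScoreMatrix:
    df = _read_labeled_table(path)
    return ScoreMatrix(
        EntityIndex.from_iterable(df.index),
        EntityIndex.from_iterable(df.columns),
        df.to_numpy(dtype=float),
        mode,
    )


def write_score_matrix(matrix: ScoreMatrix, path) -> None:
    df = pd.DataFrame(
        matrix.values,
        index=matrix.mirna_index.labels,
        columns=matrix.disease_index.labels,
    )
    df.to_csv(path, sep="\t", float_format="%.12g")


@dataclass
class AlignmentReport:
    """What align_dataset dropped to reach a common label set."""

    dropped_mirnas: list[str] = field(default_factory=list)
    dropped_diseases: list[str] = field(default_factory=list)
    dropped_associations: int = 0


def align_dataset(
    mm: SimilarityMatrix,
    dd: SimilarityMatrix,
    as_matrix: AssociationMatrix,
    fam: Optional[FamilyMatrix] = None,
    report: Optional[AlignmentReport] = None,
) -> Dataset:
    """Restrict all inputs to their common miRNA and disease labels.

    miRNA axis: intersection of MM and association labels (FAM is padded
    with singletons for miRNAs it does not cover). Disease axis:
    intersection of DD and association labels. Every dropped label and the
    number of dropped associations are logged (and recorded in `report` if
    supplied). Fails if fewer than 2 miRNAs or 2 diseases survive.
    """
    report = report if report is not None else AlignmentReport()
    mirna_common = set(mm.index.labels) & set(as_matrix.mirna_index.labels)
    disease_common = set(dd.index.labels) & set(as_matrix.disease_index.labels)
    if len(mirna_common) < 2 or len(disease_common) < 2:
        raise ValidationError(
            "label alignment leaves fewer than 2 miRNAs or 2 diseases "
            f"({len(mirna_common)} miRNAs, {len(disease_common)} diseases)"
        )
    # keep MM/DD label order for the surviving entities
    mirna_index = mm.index.subset(mirna_common)
    disease_index = dd.index.subset(disease_common)

    for label in mm.index.labels:
        if label not in mirna_common:
            report.dropped_mirnas.append(label)
    for label in as_matrix.mirna_index.labels:
        if label not in mirna_common:
            report.dropped_mirnas.append(label)
    for label in dd.index.labels:
        if label not in disease_common:
            report.dropped_diseases.append(label)
    for label in as_matrix.disease_index.labels:
        if label not in disease_common:
            report.dropped_diseases.append(label)

    mi = mm.index.positions(mirna_index.labels)
    mm_out = SimilarityMatrix(
        mirna_index, mm.values[np.ix_(mi, mi)], mm.role
    )
    di = dd.index.positions(disease_index.labels)
    dd_out = SimilarityMatrix(
        disease_index, dd.values[np.ix_(di, di)], dd.role
    )

    ai = as_matrix.mirna_index.positions(
        [l for l in mirna_index.labels]
    )
    aj = as_matrix.disease_index.positions(
        [l for l in disease_index.labels]
    )
    as_values = as_matrix.values[np.ix_(ai, aj)]
    report.dropped_associations = int(
        as_matrix.values.sum() - as_values.sum()
    )
    as_out = AssociationMatrix(mirna_index, disease_index, as_values)

    fam_out: Optional[FamilyMatrix] = None
    if fam is not None:
        family_of: dict[str, object] = {}
        covered = set(fam.index.labels) & mirna_common
        # recover membership groups from the indicator to re-project onto
        # the aligned index (singletons for uncovered miRNAs)
        fam_vals = fam.values
        seen: set[str] = set()
        group_id = 0
        for label in fam.index.labels:
            if label in seen or label not in covered:
                continue
            i = fam.index.position(label)
            members = [
                fam.index.labels[j]
                for j in np.nonzero(fam_vals[i])[0]
                if fam.index.labels[j] in covered
            ]
            for m in members:
                family_of[m] = f"g{group_id}"
                seen.add(m)
            group_id += 1
        fam_out = FamilyMatrix.from_families(mirna_index, family_of)

    for label in report.dropped_mirnas:
        log.info("alignment dropped miRNA %r", label)
    for label in report.dropped_diseases:
        log.info("alignment dropped disease %r", label)
    if report.dropped_associations:
        log.info(
            "alignment dropped %d associations", report.dropped_associations
        )
    return Dataset(mm=mm_out, dd=dd_out, as_matrix=as_out, fam=fam_out)


def write_rankings(rankings: Sequence, path) -> None:
    """Write ranked prediction records as TSV.

    Each record carries (rank, miRNA, disease, score); scores are printed
    with 6 significant digits. An empty record list yields a header-only
    file.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tmirna\tdisease\tscore\n")
        for rec in rankings:
            rank, mirna, disease, score = (
                rec if not hasattr(rec, "rank")
                else (rec.rank, rec.mirna, rec.disease, rec.score)
            )
            fh.write(f"{rank}\t{mirna}\t{disease}\t{score:.6g}\n")
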