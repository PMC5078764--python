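"""Network consistency projection scoring.

A candidate pair (miRNA i, disease j) is scored by how consistently the
similarity networks and the known association network point at each other.
In miRNA space, the row SM_i (the similarity profile of miRNA i over all
miRNAs) is projected onto the column AS_.j (the association profile of
disease j over all miRNAs): the scalar projection <SM_i, AS_.j> / |AS_.j|
is large when the miRNAs known to be associated with disease j are exactly
the miRNAs similar to i. Disease space mirrors this with SD columns and AS
rows. The two scalar projections are combined and normalized by

    ncp(i, j) = (ncp_m(i, j) + ncp_d(i, j)) / (|SM_i| + |SD_j|)

which lies in [0, 1] by Cauchy-Schwarz on nonnegative vectors. A
single-space score reduces to a plain cosine similarity: ncp_m / |SM_i| =
cos(SM_i, AS_.j).

Before projecting, every zero of the association matrix is replaced by a
small epsilon, so no row or column has zero norm. This is what makes the
method defined for an isolated disease (no known associations): its
epsilon column still has a direction, and the score degenerates gracefully
to a similarity-driven quantity instead of 0/0.

All norms are Euclidean; the cosine identity above only holds for the
Euclidean inner product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import (
    AssociationMatrix,
    Dataset,
    ScoreMatrix,
    SimilarityMatrix,
    ValidationError,
)
from .similarity import DEFAULT_EPSILON, IntegrationConfig

__all__ = [
    "ProjectionParts",
    "epsilon_substitute",
    "mirna_space_projection",
    "disease_space_projection",
    "combine_scores",
    "score_dataset",
    "score_arrays",
]


@dataclass(frozen=True)
class ProjectionParts:
    """Intermediates of the two-space projection.

    ncp_m(i, j) is bounded by |SM_i| and ncp_d(i, j) by |SD_j| (a scalar
    projection of a nonnegative vector never exceeds its length).
    """

    ncp_m: np.ndarray
    ncp_d: np.ndarray
    sm_row_norms: np.ndarray
    sd_col_norms: np.ndarray
    as_eps: np.ndarray


def epsilon_substitute(
    as_matrix: AssociationMatrix | np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
) -> np.ndarray:
    """Replace zeros of the binary association matrix with epsilon.

    The result has no zero row or column, so every vector norm used by the
    projections is strictly positive — including those of isolated
    diseases and of miRNAs with no known associations.
    """
    values = (
        as_matrix.values
        if isinstance(as_matrix, AssociationMatrix)
        else np.asarray(as_matrix)
    )
    if not epsilon > 0:
        raise ValidationError("epsilon must be positive")
    out = np.where(values == 1, 1.0, epsilon)
    return out


def mirna_space_projection(
    sm: SimilarityMatrix | np.ndarray, as_eps: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Scalar projection of every SM row onto every AS column.

    Returns ``(ncp_m, sm_row_norms)`` with
    ``ncp_m[i, j] = <SM_i, AS_.j> / |AS_.j|``.
    """
    sm_values = sm.values if isinstance(sm, SimilarityMatrix) else np.asarray(sm)
    as_eps = np.asarray(as_eps, dtype=float)
    if sm_values.shape[0] != as_eps.shape[0]:
        raise ValidationError(
            f"SM has {sm_values.shape[0]} miRNAs but the association matrix "
            f"has {as_eps.shape[0]} rows"
        )
    col_norms = np.linalg.norm(as_eps, axis=0)
    if np.any(col_norms == 0):
        j = int(np.argmin(col_norms))
        raise ValidationError(
            f"association column {j} has zero norm; was epsilon "
            "substitution applied?"
        )
    ncp_m = (sm_values @ as_eps) / col_norms[None, :]
    return ncp_m, np.linalg.norm(sm_values, axis=1)


def disease_space_projection(
    sd: SimilarityMatrix | np.ndarray, as_eps: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Scalar projection of every SD column onto every AS row.

    Returns ``(ncp_d, sd_col_norms)`` with
    ``ncp_d[i, j] = <SD_.j, AS_i.> / |AS_i.|``.
    """
    sd_values = sd.values if isinstance(sd, SimilarityMatrix) else np.asarray(sd)
    as_eps = np.asarray(as_eps, dtype=float)
    if sd_values.shape[0] != as_eps.shape[1]:
        raise ValidationError(
            f"SD has {sd_values.shape[0]} diseases but the association "
            f"matrix has {as_eps.shape[1]} columns"
        )
    row_norms = np.linalg.norm(as_eps, axis=1)
    if np.any(row_norms == 0):
        i = int(np.argmin(row_norms))
        raise ValidationError(
            f"association row {i} has zero norm; was epsilon "
            "substitution applied?"
        )
    ncp_d = (as_eps @ sd_values) / row_norms[:, None]
    return ncp_d, np.linalg.norm(sd_values, axis=0)


def combine_parts(parts: ProjectionParts, mode: str) -> np.ndarray:
    """Normalize and (for the combined mode) merge the two space scores."""
    sm_norms = parts.sm_row_norms
    sd_norms = parts.sd_col_norms
    if mode == "combined":
        denom = sm_norms[:, None] + sd_norms[None, :]
        if np.any(denom == 0):
            i = int(np.argmin(sm_norms + 0.0))
            raise ValidationError(
                "zero similarity norms make the combined score undefined "
                f"(first offending miRNA row index {i})"
            )
        return (parts.ncp_m + parts.ncp_d) / denom
    if mode == "mirna_only":
        if np.any(sm_norms == 0):
            i = int(np.argmin(sm_norms))
            raise ValidationError(
                f"miRNA row {i} of SM is all zeros; cosine undefined"
            )
        return parts.ncp_m / sm_norms[:, None]
    if mode == "disease_only":
        if np.any(sd_norms == 0):
            j = int(np.argmin(sd_norms))
            raise ValidationError(
                f"disease column {j} of SD is all zeros; cosine undefined"
            )
        return parts.ncp_d / sd_norms[None, :]
    raise ValidationError(f"unknown score mode: {mode!r}")


def combine_scores(
    parts: ProjectionParts,
    mode: str,
    mirna_index=None,
    disease_index=None,
) -> ScoreMatrix | np.ndarray:
    """Final normalized scores; a labeled ScoreMatrix if indexes are given."""
    values = combine_parts(parts, mode)
    if mirna_index is None or disease_index is None:
        return values
    return ScoreMatrix(mirna_index, disease_index, values, mode)


def score_arrays(
    mm: np.ndarray,
    dd: np.ndarray,
    fam: np.ndarray | None,
    as_binary: np.ndarray,
    config: IntegrationConfig,
    mode: str = "combined",
) -> np.ndarray:
    """Full scoring pipeline on raw arrays (no label bookkeeping).

    This is the hot path used once per cross-validation fold: Jaccard
    profile similarities from the binary association matrix, integration
    into SM and SD, epsilon substitution, projections, combination.
    """
    as_binary = np.asarray(as_binary)
    eps = config.epsilon
    profiles = as_binary.astype(np.float64)

    if config.use_sn:
        inter_m = profiles @ profiles.T
        deg_m = profiles.sum(axis=1)
        ncm = inter_m / (deg_m[:, None] + deg_m[None, :] - inter_m + eps)
        inter_d = profiles.T @ profiles
        deg_d = profiles.sum(axis=0)
        ncd = inter_d / (deg_d[:, None] + deg_d[None, :] - inter_d + eps)
    else:
        ncm = ncd = None

    sm_parts = [mm]
    sm_weights = [config.weight_mm]
    if config.use_sn:
        sm_parts.append(ncm)
        sm_weights.append(config.weight_ncm)
    if config.use_family:
        if fam is None:
            fam = np.eye(as_binary.shape[0])
        sm_parts.append(np.asarray(fam, dtype=np.float64))
        sm_weights.append(config.weight_fam)
    sm = sum(w * p for w, p in zip(sm_weights, sm_parts)) / sum(sm_weights)

    sd_parts = [dd]
    sd_weights = [config.weight_dd]
    if config.use_sn:
        sd_parts.append(ncd)
        sd_weights.append(config.weight_ncd)
    sd = sum(w * p for w, p in zip(sd_weights, sd_parts)) / sum(sd_weights)

    as_eps = np.where(as_binary == 1, 1.0, eps)
    col_norms = np.linalg.norm(as_eps, axis=0)
    row_norms = np.linalg.norm(as_eps, axis=1)
    ncp_m = (sm @ as_eps) / col_norms[None, :]
    ncp_d = (as_eps @ sd) / row_norms[:, None]
    parts = ProjectionParts(
        ncp_m=ncp_m,
        ncp_d=ncp_d,
        sm_row_norms=np.linalg.norm(sm, axis=1),
        sd_col_norms=np.linalg.norm(sd, axis=0),
        as_eps=as_eps,
    )
    return combine_parts(parts, mode)


def score_dataset(
    dataset: Dataset,
    config: IntegrationConfig | None = None,
    mode: str = "combined",
) -> ScoreMatrix:
    """Score every miRNA-disease pair of an aligned dataset.

    Deterministic for fixed inputs; output entries are in [0, 1].
    """
    config = config or IntegrationConfig()
    fam = dataset.family_values() if config.use_family else None
    values = score_arrays(
        dataset.mm.values,
        dataset.dd.values,
        fam,
        dataset.as_matrix.values,
        config,
        mode,
    )
    return ScoreMatrix(dataset.mirna_index, dataset.disease_index, values, mode)
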