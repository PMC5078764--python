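"""Scikit-learn style estimator wrapping the full scoring pipeline."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .data import (
    AssociationMatrix,
    Dataset,
    ScoreMatrix,
    ValidationError,
)
from .projection import (
    disease_space_projection,
    epsilon_substitute,
    mirna_space_projection,
    ProjectionParts,
    combine_parts,
)
from .similarity import DEFAULT_EPSILON, IntegrationConfig

__all__ = ["NetworkConsistencyProjection"]


class NetworkConsistencyProjection(BaseEstimator):
    """Network consistency projection scorer for bipartite link prediction.

    Fits on a binary miRNA x disease association matrix together with a
    miRNA-miRNA similarity matrix, a disease-disease similarity matrix and
    (optionally) a binary same-family indicator, and produces a dense
    score matrix over all pairs. Training is transductive: the entities
    seen at fit time are the entities that can be scored.

    Parameters
    ----------
    epsilon : float, default 1e-30
        Smoothing constant for Jaccard denominators and for the zero
        substitution of the association matrix before projection.
    use_sn : bool, default True
        Include the Jaccard similarities of association profiles (NCM and
        NCD) in the integrated networks.
    use_family : bool, default True
        Include the same-family indicator in the miRNA network (ignored
        when no family matrix is supplied at fit time).
    mode : {"combined", "mirna_only", "disease_only"}, default "combined"
        Which projection spaces enter the final score. Single-space modes
        reduce to plain cosine similarity between the similarity profile
        and the association profile.
    weight_mm, weight_ncm, weight_fam, weight_dd, weight_ncd : float
        Nonnegative component weights of the integration mean.

    Attributes
    ----------
    score_matrix_ : ndarray of shape (n_mirna, n_disease)
        Final normalized scores, all in [0, 1].
    sm_, sd_ : ndarray
        Integrated miRNA and disease similarity networks.
    ncm_, ncd_ : ndarray or None
        Association-profile Jaccard similarities (None when use_sn=False).
    mirna_index_, disease_index_ : EntityIndex or None
        Entity labels when fitted from labeled containers.

    Examples
    --------
    >>> import numpy as np
    >>> from ncproj import NetworkConsistencyProjection
    >>> AS = np.array([[1, 0], [0, 1], [1, 1]])
    >>> MM = np.eye(3); DD = np.eye(2)
    >>> model = NetworkConsistencyProjection(use_family=False)
    >>> scores = model.fit(AS, mirna_sim=MM, disease_sim=DD).score_matrix_
    >>> scores.shape
    (3, 2)
    """

    def __init__(
        self,
        *,
        epsilon: float = DEFAULT_EPSILON,
        use_sn: bool = True,
        use_family: bool = True,
        mode: str = "combined",
        weight_mm: float = 1.0,
        weight_ncm: float = 1.0,
        weight_fam: float = 1.0,
        weight_dd: float = 1.0,
        weight_ncd: float = 1.0,
    ) -> None:
        self.epsilon = epsilon
        self.use_sn = use_sn
        self.use_family = use_family
        self.mode = mode
        self.weight_mm = weight_mm
        self.weight_ncm = weight_ncm
        self.weight_fam = weight_fam
        self.weight_dd = weight_dd
        self.weight_ncd = weight_ncd

    # ------------------------------------------------------------------
    def _config(self, family_available: bool) -> IntegrationConfig:
        return IntegrationConfig(
            use_sn=self.use_sn,
            use_family=self.use_family and family_available,
            epsilon=self.epsilon,
            weight_mm=self.weight_mm,
            weight_ncm=self.weight_ncm,
            weight_fam=self.weight_fam,
            weight_dd=self.weight_dd,
            weight_ncd=self.weight_ncd,
        )

    def fit(self, X, y=None, *, mirna_sim=None, disease_sim=None, family=None):
        """Build the integrated networks and score every pair.

        Parameters
        ----------
        X : Dataset, AssociationMatrix, or binary array (n_mirna, n_disease)
            Known associations. When a :class:`Dataset` is passed the
            similarity and family inputs are taken from it and the keyword
            arguments must be omitted.
        y : ignored (sklearn API compatibility).
        mirna_sim, disease_sim : square arrays in [0, 1]
            External similarity matrices, required unless X is a Dataset.
        family : binary square array, optional
            Same-family indicator over miRNAs.
        """
        if isinstance(X, Dataset):
            if mirna_sim is not None or disease_sim is not None or family is not None:
                raise ValidationError(
                    "pass either a Dataset or raw matrices, not both"
                )
            mirna_index = X.mirna_index
            disease_index = X.disease_index
            as_binary = X.as_matrix.values
            mm = X.mm.values
            dd = X.dd.values
            fam = X.fam.values if X.fam is not None else None
        else:
            if isinstance(X, AssociationMatrix):
                mirna_index = X.mirna_index
                disease_index = X.disease_index
                as_binary = X.values
            else:
                mirna_index = disease_index = None
                as_binary = np.asarray(X)
            if mirna_sim is None or disease_sim is None:
                raise ValidationError(
                    "mirna_sim and disease_sim are required when X is not "
                    "a Dataset"
                )
            mm = np.asarray(mirna_sim, dtype=float)
            dd = np.asarray(disease_sim, dtype=float)
            fam = None if family is None else np.asarray(family)

        if as_binary.ndim != 2:
            raise ValidationError("association matrix must be 2-dimensional")
        if not np.isin(as_binary, (0, 1)).all():
            raise ValidationError("association matrix must be binary")
        n_m, n_d = as_binary.shape
        if mm.shape != (n_m, n_m):
            raise ValidationError(
                f"miRNA similarity shape {mm.shape} does not match "
                f"{n_m} miRNAs"
            )
        if dd.shape != (n_d, n_d):
            raise ValidationError(
                f"disease similarity shape {dd.shape} does not match "
                f"{n_d} diseases"
            )
        if fam is not None and fam.shape != (n_m, n_m):
            raise ValidationError(
                f"family matrix shape {fam.shape} does not match {n_m} miRNAs"
            )
        # when use_family is requested but no matrix supplied, fall back to
        # singleton families (identity) rather than failing: running with
        # and without family data are both supported configurations
        if self.use_family and fam is None:
            fam = np.eye(n_m, dtype=np.int8)
        config = self._config(family_available=True)

        as_bin = as_binary.astype(np.int8)
        profiles = as_bin.astype(np.float64)
        eps = config.epsilon
        if config.use_sn:
            inter_m = profiles @ profiles.T
            deg_m = profiles.sum(axis=1)
            ncm = inter_m / (deg_m[:, None] + deg_m[None, :] - inter_m + eps)
            inter_d = profiles.T @ profiles
            deg_d = profiles.sum(axis=0)
            ncd = inter_d / (deg_d[:, None] + deg_d[None, :] - inter_d + eps)
        else:
            ncm = ncd = None

        sm_parts = [(config.weight_mm, mm)]
        if config.use_sn:
            sm_parts.append((config.weight_ncm, ncm))
        if config.use_family:
            sm_parts.append((config.weight_fam, fam.astype(np.float64)))
        sm = sum(w * p for w, p in sm_parts) / sum(w for w, _ in sm_parts)

        sd_parts = [(config.weight_dd, dd)]
        if config.use_sn:
            sd_parts.append((config.weight_ncd, ncd))
        sd = sum(w * p for w, p in sd_parts) / sum(w for w, _ in sd_parts)

        as_eps = epsilon_substitute(as_bin, eps)
        ncp_m, sm_row_norms = mirna_space_projection(sm, as_eps)
        ncp_d, sd_col_norms = disease_space_projection(sd, as_eps)
        parts = ProjectionParts(
            ncp_m=ncp_m,
            ncp_d=ncp_d,
            sm_row_norms=sm_row_norms,
            sd_col_norms=sd_col_norms,
            as_eps=as_eps,
        )

        self.mirna_index_ = mirna_index
        self.disease_index_ = disease_index
        self.ncm_ = ncm
        self.ncd_ = ncd
        self.sm_ = sm
        self.sd_ = sd
        self.projection_parts_ = parts
        self.score_matrix_ = combine_parts(parts, self.mode)
        self.n_features_in_ = n_d
        return self

    def predict(self, pairs=None) -> np.ndarray:
        """Scores for (miRNA, disease) index pairs, or the full matrix.

        `pairs` is an array-like of shape (n, 2) of integer positions (or
        label pairs when the estimator was fitted from labeled
        containers); None returns the full score matrix.
        """
        check_is_fitted(self, "score_matrix_")
        if pairs is None:
            return self.score_matrix_
        pairs = list(pairs)
        out = np.empty(len(pairs))
        for k, (i, j) in enumerate(pairs):
            if isinstance(i, str):
                if self.mirna_index_ is None:
                    raise ValidationError(
                        "label lookup requires fitting from labeled inputs"
                    )
                i = self.mirna_index_.position(i)
                j = self.disease_index_.position(j)
            out[k] = self.score_matrix_[i, j]
        return out

    def score_matrix(self) -> ScoreMatrix:
        """Labeled ScoreMatrix (requires labeled fit inputs)."""
        check_is_fitted(self, "score_matrix_")
        if self.mirna_index_ is None:
            raise ValidationError(
                "labeled output requires fitting from labeled inputs"
            )
        return ScoreMatrix(
            self.mirna_index_,
            self.disease_index_,
            self.score_matrix_,
            self.mode,
        )
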