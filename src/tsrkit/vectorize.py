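"""Scikit-learn style front end: structures in, key-count matrix out.

:class:`TSRKeyVectorizer` plays the role a text ``CountVectorizer``
plays for documents: ``fit`` learns the discretization (bin boundaries
for MaxDist and Theta, pooled over the training structures, unless
fixed boundary tables are supplied) and the key vocabulary; ``transform``
turns structures into a sparse matrix of key occurrence counts.
``transform_keyvectors`` returns the richer :class:`~tsrkit.keys.KeyVector`
objects used by the similarity and mining modules.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .discretization import MAXDIST_BIN_COUNT, THETA_BIN_COUNT, fit_bins
from .keys import key_vector, pooled_geometry
from .labeling import build_label_scheme

__all__ = ["TSRKeyVectorizer"]


class TSRKeyVectorizer(BaseEstimator, TransformerMixin):
    """Transform Cα structures into TSR key-frequency vectors.

    Parameters
    ----------
    grouping : bool, default False
        Use the 13-category reduced amino-acid alphabet instead of the
        20-letter one.
    theta_bins, dist_bins : int
        Bin counts for Theta and MaxDist (defaults 29 and 35).
    theta_boundaries, dist_boundaries : BinBoundaries, optional
        Fixed boundary tables; when given, ``fit`` does not refit them
        (needed to reproduce keys produced with published boundaries).
    label_table : dict or path, optional
        Custom amino-acid → label mapping.

    Attributes
    ----------
    scheme_ : LabelScheme
    theta_bins_, dist_bins_ : BinBoundaries
    vocabulary_ : dict
        key → column index of the transform output.
    """

    def __init__(self, grouping=False, theta_bins=THETA_BIN_COUNT,
                 dist_bins=MAXDIST_BIN_COUNT, theta_boundaries=None,
                 dist_boundaries=None, label_table=None):
        self.grouping = grouping
        self.theta_bins = theta_bins
        self.dist_bins = dist_bins
        self.theta_boundaries = theta_boundaries
        self.dist_boundaries = dist_boundaries
        self.label_table = label_table

    def fit(self, X, y=None):
        X = list(X)
        if not X:
            raise ValueError("need at least one structure to fit")
        self.scheme_ = build_label_scheme(self.grouping, self.label_table)
        if self.theta_boundaries is not None and self.dist_boundaries is not None:
            self.theta_bins_ = self.theta_boundaries
            self.dist_bins_ = self.dist_boundaries
        else:
            maxdist_values, theta_values = pooled_geometry(X, self.scheme_)
            self.dist_bins_ = (
                self.dist_boundaries
                or fit_bins(maxdist_values, self.dist_bins, variable="maxdist")
            )
            self.theta_bins_ = (
                self.theta_boundaries
                or fit_bins(theta_values, self.theta_bins, variable="theta")
            )
        vocab: dict[int, int] = {}
        for kv in self.transform_keyvectors(X):
            for key in kv.counts:
                vocab.setdefault(key, len(vocab))
        # column order by key value, as CountVectorizer orders by term
        self.vocabulary_ = {k: i for i, k in enumerate(sorted(vocab))}
        return self

    def transform_keyvectors(self, X):
        """List of :class:`KeyVector` (vocabulary-unrestricted)."""
        check_is_fitted(self, "scheme_")
        return [
            key_vector(s, self.scheme_, self.theta_bins_, self.dist_bins_)
            for s in X
        ]

    def transform(self, X):
        """Sparse (n_structures, n_vocabulary) key-count matrix.

        Keys unseen during ``fit`` are ignored, mirroring text
        vectorizers.
        """
        check_is_fitted(self, "vocabulary_")
        vectors = self.transform_keyvectors(X)
        rows, cols, data = [], [], []
        for i, kv in enumerate(vectors):
            for key, count in kv.counts.items():
                j = self.vocabulary_.get(key)
                if j is not None:
                    rows.append(i)
                    cols.append(j)
                    data.append(count)
        return sp.csr_matrix(
            (data, (rows, cols)),
            shape=(len(vectors), len(self.vocabulary_)),
            dtype=np.int64,
        )

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "vocabulary_")
        return np.array([str(k) for k in sorted(self.vocabulary_)], dtype=object)
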