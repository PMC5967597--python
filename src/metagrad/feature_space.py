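"""Assembly and exploration of the 44-variable feature frame.

The per-study feature vector is partitioned into three frames:

* clinical (8): grade, volume, subtype, age, sex, SUVmax, SUVmean, TLG;
* structural (8): H0, H1 and the 25th/95th percentiles of the raw,
  normalized and uptake-weighted metabolic gradients;
* textural (28): asphericity, five PCA-morphology descriptors, twelve
  histogram features, eight GLCM features, two GLSZM features.

Exploration mirrors the usual workflow on such a table: Pearson
correlation of the continuous variables, scaled (correlation-based) PCA,
k-means clustering of the variables' coordinates in the retained principal
component subspace, and per-study cluster-centroid covariates (the mean of
the z-scored member variables of each cluster) for downstream risk models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .radiomics import texture_feature_names

CLINICAL_VARIABLES = ["grade", "volume", "subtype", "age", "sex", "SUVmax", "SUVmean", "TLG"]
STRUCTURAL_VARIABLES = ["H0", "H1", "g.0.25", "g.0.95", "g.n.0.25", "g.n.0.95",
                        "g.w.0.25", "g.w.0.95"]
CATEGORICAL_CLINICAL = {"grade": ("low", "intermediate", "high"),
                        "subtype": ("STS", "bone", "cartilage"),
                        "sex": ("F", "M")}


def feature_vocabulary() -> dict[str, str]:
    """Mapping variable name -> frame label for the full 44-word vocabulary."""
    vocab = {v: "clinical" for v in CLINICAL_VARIABLES}
    vocab.update({v: "structural" for v in STRUCTURAL_VARIABLES})
    vocab.update({v: "textural" for v in texture_feature_names()})
    return vocab


@dataclass
class FeatureTable:
    """Studies x variables table with per-variable frame labels.

    Categorical clinical variables (grade, subtype, sex) are stored as
    labels; :meth:`analysis_matrix` codes them numerically for correlation
    and PCA (grade ordinal low/intermediate/high -> 1/2/3; sex male
    indicator; subtype indicators against an STS baseline).
    """

    data: pd.DataFrame
    frames: dict[str, str] = field(default_factory=feature_vocabulary)

    def __post_init__(self):
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate variable names")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate study IDs")
        unknown = [c for c in self.data.columns if c not in self.frames]
        if unknown:
            raise ValueError(f"unknown variable names: {unknown}")

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]

    def frame(self, label: str) -> pd.DataFrame:
        cols = [c for c in self.data.columns if self.frames.get(c) == label]
        return self.data[cols]

    def analysis_matrix(self) -> pd.DataFrame:
        """Numeric matrix for correlation/PCA with categoricals coded.

        grade -> ordinal 1/2/3; sex -> male indicator; subtype -> bone and
        cartilage indicators (STS baseline).  Continuous variables pass
        through unchanged.
        """
        out = {}
        for c in self.data.columns:
            col = self.data[c]
            if c == "grade" and col.dtype == object:
                order = {g: i + 1 for i, g in enumerate(CATEGORICAL_CLINICAL["grade"])}
                out["grade"] = col.map(order).astype(float)
            elif c == "sex" and col.dtype == object:
                out["sex.male"] = (col == "M").astype(float)
            elif c == "subtype" and col.dtype == object:
                out["subtype.bone"] = (col == "bone").astype(float)
                out["subtype.cartilage"] = (col == "cartilage").astype(float)
            else:
                out[c] = pd.to_numeric(col)
        return pd.DataFrame(out, index=self.data.index)


def assemble_features(structural: dict[str, dict[str, float]],
                      radiomic: dict[str, dict[str, float]],
                      clinical: dict[str, dict] | pd.DataFrame | None = None) -> FeatureTable:
    """Build the 44-variable feature table from per-study records.

    ``structural`` and ``radiomic`` map study ID to name -> value dicts;
    ``clinical`` likewise (missing clinical values become NaN).  All
    records must share study IDs; unknown variable names raise.
    """
    if set(structural) != set(radiomic):
        raise ValueError("structural and radiomic records have mismatched study IDs")
    if isinstance(clinical, pd.DataFrame):
        clinical = clinical.to_dict(orient="index")
    clinical = clinical or {}
    vocab = feature_vocabulary()
    rows = {}
    for sid in structural:
        rec: dict[str, object] = {}
        rec.update(structural[sid])
        rec.update(radiomic[sid])
        rec.update(clinical.get(sid, {}))
        unknown = [k for k in rec if k not in vocab]
        if unknown:
            raise ValueError(f"unknown variable names for study {sid}: {unknown}")
        rows[sid] = {v: rec.get(v, np.nan) for v in vocab}
    table = pd.DataFrame.from_dict(rows, orient="index")[list(vocab)]
    return FeatureTable(table, vocab)


def correlation_matrix(table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of the continuous (nonconstant) variables.

    Constant variables are excluded (they have no defined correlation);
    the result is symmetric with unit diagonal.
    """
    mat = table.analysis_matrix() if isinstance(table, FeatureTable) else table
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 studies")
    keep = [c for c in mat.columns if np.nanstd(mat[c].to_numpy(dtype=float)) > 0]
    return mat[keep].corr(method="pearson")


@dataclass
class ClusterModel:
    """PCA loadings, retained components, variable clusters, centroid scores."""

    loadings: pd.DataFrame            # variables x retained components
    explained_fractions: np.ndarray   # all components, nonincreasing
    n_components: int
    assignment: pd.Series | None = None       # cluster id per variable
    centroids: pd.DataFrame | None = None     # studies x clusters


def pca_variables(table: FeatureTable | pd.DataFrame, var_frac: float = 0.95) -> ClusterModel:
    """Scaled (correlation-based) PCA of the feature table.

    Variables are z-scored (sample sd) so the PCA eigenstructure matches
    the correlation matrix; the smallest number of leading components whose
    explained-variance fractions sum to ``var_frac`` is retained.  Loadings
    are each variable's coordinates in the retained component space,
    component direction scaled by the component standard deviation.
    """
    mat = table.analysis_matrix() if isinstance(table, FeatureTable) else table
    if mat.shape[0] < 2:
        raise ValueError("need more than one study")
    x = mat.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = list(mat.columns[sd == 0])
        warnings.warn(f"excluding constant variables from PCA: {const}")
        mat = mat.drop(columns=const)
        x = mat.to_numpy(dtype=float)
        sd = x.std(axis=0, ddof=1)
    if mat.shape[1] < 2:
        raise ValueError("fewer than 2 standardizable variables")
    z = (x - x.mean(axis=0)) / sd
    pca = PCA()
    pca.fit(z)
    frac = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(frac), var_frac) + 1)
    k = min(k, frac.size)
    load = pca.components_[:k].T * np.sqrt(pca.explained_variance_[:k])
    loadings = pd.DataFrame(load, index=mat.columns,
                            columns=[f"PC{i+1}" for i in range(k)])
    return ClusterModel(loadings=loadings, explained_fractions=frac, n_components=k)


def cluster_variables(model: ClusterModel, k: int, seed: int = 0,
                      n_init: int = 25) -> ClusterModel:
    """k-means clustering of the PC-projected variables.

    Euclidean distance in the retained-component coordinate space; fixed
    seed and ``n_init`` restarts make the assignment reproducible.
    """
    p = model.loadings.shape[0]
    if k > p:
        raise ValueError(f"k={k} exceeds the number of variables ({p})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(model.loadings.to_numpy())
    model.assignment = pd.Series(labels, index=model.loadings.index, name="cluster")
    return model


def centroid_covariates(table: FeatureTable | pd.DataFrame,
                        assignment: pd.Series) -> pd.DataFrame:
    """Per-study cluster-centroid covariates.

    Each cluster's score is the mean of the z-scored member variables
    (the unweighted cluster recombination, scaled so cluster size does not
    inflate the covariate variance).  Raises on empty clusters.
    """
    mat = table.analysis_matrix() if isinstance(table, FeatureTable) else table
    missing = [v for v in assignment.index if v not in mat.columns]
    if missing:
        raise ValueError(f"assignment covers variables absent from the table: {missing}")
    x = mat[list(assignment.index)].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant variables cannot be standardized")
    z = (x - x.mean(axis=0)) / sd
    out = {}
    for c in sorted(assignment.unique()):
        members = np.asarray(assignment == c)
        if not members.any():
            raise ValueError(f"cluster {c} is empty")
        out[f"C{int(c) + 1}"] = z[:, members].mean(axis=1)
    return pd.DataFrame(out, index=mat.index)
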