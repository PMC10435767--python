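"""PCA of glycan variables and nearest-centroid placement of singletons.

Used to position a single child with a segmental chromosome-21 duplication
relative to the DS and euploid clusters: PCA is fitted on the cohort
(standardised scale, i.e. the correlation matrix), the singleton is
projected through the stored standardisation and loadings, and assigned to
the nearest group centroid in PC space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclass
class PCAModel:
    """Fitted PCA: standardisation constants, loadings, explained variance
    and training scores."""

    means: pd.Series
    sds: pd.Series            # all 1.0 when standardize=False
    loadings: pd.DataFrame    # components x variables, rows orthonormal
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame      # samples x components

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def fit_pca(matrix: pd.DataFrame, standardize: bool = True) -> PCAModel:
    """PCA by SVD of the centred (and optionally scaled) data.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive, making results deterministic across BLAS builds.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 variables")
    X = matrix.astype(float)
    means = X.mean(axis=0)
    if standardize:
        sds = X.std(axis=0, ddof=1)
        zero = sds[sds <= 0]
        if len(zero):
            raise ValueError(f"zero-variance variable(s): {list(zero.index)}")
    else:
        sds = pd.Series(1.0, index=X.columns)
    Z = (X - means) / sds

    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(Z.to_numpy())
    loadings = pca.components_
    # deterministic sign: largest |loading| positive per component
    for k in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[k]))
        if loadings[k, j] < 0:
            loadings[k] *= -1
            scores[:, k] *= -1

    comp_names = [f"PC{k + 1}" for k in range(loadings.shape[0])]
    return PCAModel(
        means=means,
        sds=sds,
        loadings=pd.DataFrame(loadings, index=comp_names, columns=X.columns),
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
    )


def transform(model: PCAModel, samples: pd.DataFrame) -> pd.DataFrame:
    """Project new samples through the model's standardisation + loadings."""
    missing = [v for v in model.means.index if v not in samples.columns]
    if missing:
        raise KeyError(f"sample(s) missing model variable(s): {missing}")
    Z = (samples[model.means.index].astype(float) - model.means) / model.sds
    scores = Z.to_numpy() @ model.loadings.to_numpy().T
    return pd.DataFrame(scores, index=samples.index, columns=model.loadings.index)


def project_and_assign(
    model: PCAModel,
    sample: pd.Series | pd.DataFrame,
    groups: pd.Series,
    k: int = 3,
) -> tuple[pd.Series, str, dict[str, float]]:
    """Project one sample and assign it to the nearest group centroid
    (Euclidean distance in the first ``k`` components of the stored
    training scores). Returns (scores, assigned group, distances)."""
    if k < 1 or k > model.n_components:
        raise ValueError(f"k={k} outside available components (1..{model.n_components})")
    if isinstance(sample, pd.Series):
        sample = sample.to_frame().T
    scores = transform(model, sample).iloc[0]
    use = [f"PC{j + 1}" for j in range(k)]
    groups = groups.loc[model.scores.index]
    distances: dict[str, float] = {}
    for g, idx in groups.groupby(groups).groups.items():
        centroid = model.scores.loc[idx, use].mean(axis=0)
        distances[str(g)] = float(np.linalg.norm(scores[use] - centroid))
    assigned = min(distances, key=distances.get)
    return scores, assigned, distances
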