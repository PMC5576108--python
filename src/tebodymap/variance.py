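"""Variance structure of the expression matrix: PVCA and sample clustering.

Principal variance component analysis (PVCA) combines principal components
analysis with variance components analysis: the leading principal
components of the sample-sample covariance (on the log2(RPKM + 1) view)
are each decomposed into variance components attributable to the design
factors (organ, age, sex, replicate and their pairwise interactions), the
per-component estimates are averaged with eigenvalue-fraction weights, and
the result is normalized (including the residual) to proportions summing
to 1.

Variance components per component are estimated with a MINQUE(0)-style
method-of-moments fit: solve tr(B_j B_k) sigma = y' B_j y over the random
effects j (B_j the doubly centered same-level indicator matrix), then
truncate negative estimates at zero. The estimator is deterministic and
needs no iterative optimization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

from .design import metadata_frame
from .expression import ExpressionMatrix

DEFAULT_EFFECTS = (
    "organ",
    "age",
    "sex",
    "replicate",
    "organ:age",
    "organ:sex",
    "age:sex",
)


class ConfoundedEffectsError(ValueError):
    """Two requested effects induce the identical sample partition."""


@dataclass
class PVCAResult:
    proportions: pd.Series  # effect (incl. 'residual') -> weighted proportion
    n_components: int
    variance_explained: float  # cumulative eigenvalue fraction of retained PCs
    per_component: pd.DataFrame  # raw variance components per retained PC

    def frame(self) -> pd.DataFrame:
        return self.proportions.rename("weighted_proportion").rename_axis("effect").reset_index()


def _effect_levels(meta: pd.DataFrame, effect: str) -> np.ndarray:
    cols = {"organ": "organ", "age": "stage_weeks", "sex": "sex", "replicate": "replicate"}
    parts = effect.split(":")
    vals = None
    for p in parts:
        if p not in cols:
            raise ValueError(f"unknown effect {p!r}")
        col = meta[cols[p]].astype(str)
        vals = col if vals is None else vals + "|" + col
    codes, _ = pd.factorize(vals)
    return codes


def pvca(
    matrix: ExpressionMatrix,
    effects: tuple[str, ...] = DEFAULT_EFFECTS,
    variance_threshold: float = 0.6,
) -> PVCAResult:
    """Weighted variance-component attribution of expression variance.

    ``variance_threshold`` is the cumulative eigenvalue fraction that the
    retained leading principal components must reach (default 0.6).
    """
    if not (0 < variance_threshold <= 1):
        raise ValueError("variance_threshold must be in (0, 1]")
    meta = metadata_frame(matrix.design).loc[matrix.rpkm.columns]
    codes = {e: _effect_levels(meta, e) for e in effects}
    for i, e1 in enumerate(effects):
        for e2 in effects[i + 1 :]:
            c1, c2 = codes[e1], codes[e2]
            # identical partitions <=> bijection between level codes
            if len(set(zip(c1, c2))) == max(len(set(c1)), len(set(c2))) and len(
                set(c1)
            ) == len(set(c2)):
                raise ConfoundedEffectsError(f"effects {e1!r} and {e2!r} are confounded")
        if len(set(codes[e1])) < 2:
            raise ValueError(f"effect {e1!r} has < 2 levels among the samples")

    log = matrix.log2.values  # features x samples
    X = log - log.mean(axis=1, keepdims=True)  # center each feature
    n = X.shape[1]
    cov = X.T @ X / (X.shape[0] - 1)  # sample-sample covariance
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    frac = eigval / eigval.sum()
    n_comp = int(np.searchsorted(np.cumsum(frac), variance_threshold) + 1)
    n_comp = min(n_comp, len(eigval))

    # doubly centered same-level indicator matrices, one per random effect
    P = np.eye(n) - np.ones((n, n)) / n
    Bs = []
    for e in effects:
        M = (codes[e][:, None] == codes[e][None, :]).astype(float)
        Bs.append(P @ M @ P)
    Bs.append(P @ P)  # residual (identity)
    k = len(Bs)
    S = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            S[i, j] = S[j, i] = np.sum(Bs[i] * Bs[j])  # tr(B_i B_j), symmetric

    names = list(effects) + ["residual"]
    comps = np.zeros((n_comp, k))
    for c in range(n_comp):
        y = eigvec[:, c]
        q = np.array([y @ B @ y for B in Bs])
        sol, *_ = np.linalg.lstsq(S, q, rcond=None)
        comps[c] = np.clip(sol, 0, None)

    weights = frac[:n_comp] / frac[:n_comp].sum()
    avg = (comps * weights[:, None]).sum(axis=0)
    if avg.sum() == 0:
        avg = np.append(np.zeros(k - 1), 1.0)
    props = pd.Series(avg / avg.sum(), index=names)
    per_component = pd.DataFrame(comps, columns=names)
    per_component.insert(0, "eigenvalue_fraction", frac[:n_comp])
    return PVCAResult(props, n_comp, float(np.cumsum(frac)[n_comp - 1]), per_component)


@dataclass
class ClusteringResult:
    linkage: np.ndarray  # scipy linkage matrix, (n_samples - 1) merges
    labels: pd.Series  # sample -> flat cluster label at k
    k: int
    ari: float  # agreement with organ labels


def cluster_samples(
    matrix: ExpressionMatrix,
    k: int | None = None,
    method: str = "average",
    metric: str = "euclidean",
) -> ClusteringResult:
    """Agglomerative clustering of sample columns on the log view.

    Average linkage with Euclidean distances by default. The tree is cut at
    ``k`` clusters (default: the number of organs) and agreement with the
    organ labels is reported as the adjusted Rand index.
    """
    design = matrix.design
    if k is None:
        k = len(design.organs)
    log = matrix.log2
    n = log.shape[1]
    if n < 2 or n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    Z = hierarchy.linkage(pdist(log.values.T, metric=metric), method=method)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    meta = metadata_frame(design).loc[log.columns]
    ari = adjusted_rand_score(meta["organ"].values, flat)
    return ClusteringResult(Z, pd.Series(flat, index=log.columns), k, float(ari))


def dendrogram_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def render(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        return f"({render(node.left)},{render(node.right)}):{node.dist:.6g}"

    return render(tree) + ";"
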