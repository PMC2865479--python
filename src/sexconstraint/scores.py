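"""Composite ornament scores from a species x trait measurement matrix.

Colour measurements mix reflectance summaries, patch extents and
categorical pattern codes, so the PCA runs on the correlation matrix
(each trait standardized to unit variance).  Components are retained by
the broken-stick criterion or, as an explicit fallback, the Kaiser
eigenvalue > 1 rule; the composite score of a species is the sum of its
retained component scores, each weighted by the component's eigenvalue.
Component signs are oriented so each retained component's loading sum is
positive, making larger composite scores mean more elaborate ornament.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CompositeScores:
    species: list[str]
    scores: np.ndarray
    n_retained: int
    variance_explained: float
    eigenvalues: np.ndarray
    criterion: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"species": self.species, "score": self.scores})


def broken_stick_expectations(p: int) -> np.ndarray:
    """Expected variance proportions of a randomly broken unit stick.

    The k-th largest of p pieces has expected share
    (1/p) * sum_{i=k..p} 1/i.
    """
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def broken_stick_retention(eigenvalues) -> int:
    """Components retained under the broken-stick criterion.

    Consecutive retention from the first component: the largest k such
    that every eigenvalue proportion up to k exceeds its broken-stick
    expectation.  A single-component spectrum is retained outright.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.size == 0:
        raise ValueError("empty eigenvalue vector")
    p = eig.size
    if p == 1:
        return 1
    props = eig / eig.sum()
    expect = broken_stick_expectations(p)
    k = 0
    for j in range(p):
        if props[j] > expect[j]:
            k += 1
        else:
            break
    return k


def kaiser_retention(eigenvalues) -> int:
    """Count of eigenvalues greater than 1 (correlation-matrix PCA)."""
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.size == 0:
        raise ValueError("empty eigenvalue vector")
    return int(np.count_nonzero(eig > 1.0))


_CRITERIA = {
    "broken_stick": broken_stick_retention,
    "kaiser": kaiser_retention,
}


def correlation_pca(values: np.ndarray):
    """Eigendecomposition of the trait correlation matrix.

    Returns (eigenvalues descending, loadings (p x p, columns are
    components), standardized data).  Eigenvalues sum to the trait
    count.  Trait columns must have nonzero variance.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("need a 2-D species x trait matrix")
    if np.isnan(x).any():
        raise ValueError("measurement matrix contains missing values")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(np.flatnonzero(sd == 0))
        raise ValueError(f"zero-variance trait column(s) at {bad}")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False).reshape(x.shape[1], x.shape[1])
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # orient: positive loading sum per component
    signs = np.where(eigvec.sum(axis=0) < 0, -1.0, 1.0)
    return eigval, eigvec * signs, z


def composite_score(matrix: pd.DataFrame,
                    criterion: str = "broken_stick") -> CompositeScores:
    """Eigenvalue-weighted sum of retained PC scores per species.

    ``matrix`` is a DataFrame with a 'species' column (or species index)
    and one column per trait; an optional 'sex' column is carried along
    but ignored (male and female rows share one PCA space so their
    scores are comparable).  Raises if the criterion retains no
    component, naming the Kaiser fallback.
    """
    if criterion not in _CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    df = matrix.copy()
    if "species" in df.columns:
        species = [str(s) for s in df.pop("species")]
    else:
        species = [str(s) for s in df.index]
    if "sex" in df.columns:
        df = df.drop(columns=["sex"])
    if df.shape[1] < 1:
        raise ValueError("no trait columns")
    trait_order = sorted(df.columns)  # column-order invariance
    eigval, eigvec, z = correlation_pca(df[trait_order].to_numpy())
    k = _CRITERIA[criterion](eigval)
    if k == 0:
        raise ValueError(
            f"no significant components under {criterion!r}; consider "
            "criterion='kaiser' (eigenvalue > 1)"
        )
    pc_scores = z @ eigvec[:, :k]
    scores = pc_scores @ eigval[:k]
    return CompositeScores(
        species=species,
        scores=np.asarray(scores, dtype=float),
        n_retained=k,
        variance_explained=float(eigval[:k].sum() / eigval.sum()),
        eigenvalues=eigval,
        criterion=criterion,
    )
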