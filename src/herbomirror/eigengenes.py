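"""SVD eigengene analysis of expression matrices.

Writing the genes x arrays matrix X = U D V^T, the rows of V^T are the
*eigengenes* (characteristic expression patterns across arrays) and the
columns of U the *eigenarrays*. Without mean centering, the first
eigengene of an all-positive matrix is close to constant across arrays —
it captures the shared expression baseline and carries no contrast
between arrays. The remaining components are summarized by their
eigen-fractions p_k = sigma_k^2 / sum sigma^2 and by the normalized
Shannon entropy d of those fractions: d = 0 when one component dominates,
d = 1 when variation is spread uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exprproc import ExpressionMatrix

__all__ = [
    "EigenDecomposition",
    "EntropySummary",
    "svd_decompose",
    "eigen_fractions",
    "shannon_entropy",
    "filter_component",
    "constant_component_candidates",
]


@dataclass
class EigenDecomposition:
    eigenarrays: np.ndarray  # genes x components (left singular vectors)
    singular_values: np.ndarray  # nonincreasing, nonnegative
    eigengenes: np.ndarray  # components x arrays (rows of V^T)
    source_shape: tuple[int, int]

    def reconstruct(self) -> np.ndarray:
        return (self.eigenarrays * self.singular_values) @ self.eigengenes


@dataclass
class EntropySummary:
    fractions: np.ndarray
    entropy_d: float
    excluded: tuple[int, ...]


def _as_array(x: ExpressionMatrix | np.ndarray) -> np.ndarray:
    v = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("matrix entries must be finite")
    return v


def svd_decompose(
    x: ExpressionMatrix | np.ndarray,
    center: bool = False,
    scale: bool = False,
) -> EigenDecomposition:
    """Exact SVD of the expression matrix, by default uncentered/unscaled.

    ``center``/``scale`` operate per gene (row) when requested. Components
    are ordered by singular value; signs are fixed so each eigengene's
    largest-magnitude entry is positive, making plots reproducible.
    """
    v = _as_array(x).copy()
    if center:
        v -= v.mean(axis=1, keepdims=True)
    if scale:
        sd = v.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        v /= sd
    u, s, vt = np.linalg.svd(v, full_matrices=False)
    for k in range(s.size):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    return EigenDecomposition(
        eigenarrays=u, singular_values=s, eigengenes=vt, source_shape=v.shape
    )


def eigen_fractions(
    d: EigenDecomposition, exclude: tuple[int, ...] | list[int] = ()
) -> EntropySummary:
    """Eigen-fractions p_k over retained components, with their entropy.

    ``exclude`` lists 0-based component indices removed before the
    fractions are formed: p_k = sigma_k^2 / sum over retained sigma_j^2.
    Excluding a component from the fractions is numerically identical to
    removing its rank-1 term from the matrix and refitting.
    """
    exclude = tuple(sorted(set(int(i) for i in exclude)))
    m = d.singular_values.size
    for i in exclude:
        if not 0 <= i < m:
            raise ValueError(f"component index {i} out of range")
    retained = [k for k in range(m) if k not in exclude]
    if not retained:
        raise ValueError("cannot exclude every component")
    s2 = d.singular_values[retained] ** 2
    total = s2.sum()
    if total == 0:
        raise ValueError("retained components carry no variance")
    fractions = s2 / total
    return EntropySummary(
        fractions=fractions, entropy_d=shannon_entropy(fractions), excluded=exclude
    )


def shannon_entropy(fractions: np.ndarray) -> float:
    """Normalized Shannon entropy d = -(1/ln m) * sum p_k ln p_k in [0, 1].

    m is the number of fractions; 0*ln 0 is taken as 0; a single fraction
    gives d = 0 by convention (the normalizer ln 1 would vanish).
    """
    p = np.asarray(fractions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if np.any(p < 0):
        raise ValueError("fractions must be nonnegative")
    m = p.size
    if m == 1:
        return 0.0
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(m))


def filter_component(
    x: ExpressionMatrix | np.ndarray, k: int
) -> ExpressionMatrix | np.ndarray:
    """Remove the rank-1 contribution of component ``k``: x - s_k u_k v_k^T."""
    v = _as_array(x)
    d = svd_decompose(v)
    if not 0 <= k < d.singular_values.size:
        raise ValueError(f"component index {k} out of range")
    filtered = v - d.singular_values[k] * np.outer(d.eigenarrays[:, k], d.eigengenes[k])
    if isinstance(x, ExpressionMatrix):
        return ExpressionMatrix(filtered, x.probeset_ids, x.array_ids, x.condition)
    return filtered


def constant_component_candidates(
    d: EigenDecomposition, cv_threshold: float = 0.25
) -> list[int]:
    """Flag eigengenes that barely differentiate between arrays.

    A component whose eigengene has a coefficient of variation across
    arrays below ``cv_threshold`` (entries nearly constant, same sign) is
    a candidate "baseline" component to exclude from entropy summaries.
    """
    out = []
    for k in range(d.singular_values.size):
        g = d.eigengenes[k]
        mean = np.abs(g.mean())
        if mean == 0:
            continue
        if g.std() / mean < cv_threshold and (np.all(g >= 0) or np.all(g <= 0)):
            out.append(k)
    return out
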