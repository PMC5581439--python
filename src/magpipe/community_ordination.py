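"""Community ordination: Bray-Curtis dissimilarity, NMDS and RDA.

Implements the three ordination primitives used to compare microbial
communities and functional (GH-family) profiles between samples:

* **Bray-Curtis dissimilarity** between count rows,
  ``d(i, j) = 1 - 2 sum_k min(x_ik, x_jk) / (sum_k x_ik + sum_k x_jk)``.
* **Non-metric multidimensional scaling (NMDS)** minimising Kruskal
  stress-1 by iterative majorization (SMACOF) with monotone (isotonic)
  regression of configuration distances on the input dissimilarities;
  best of several random starts, the first start seeded from classical
  metric scaling.
* **Redundancy analysis (RDA)**: least-squares regression of a centred
  response matrix on (dummy-coded, centred) constraints followed by an
  eigendecomposition of the fitted-value covariance; the constrained
  variance fraction is the trace ratio fitted/total.

All three operate on pandas DataFrames with sample row labels;
dissimilarities are exchanged as ``skbio.DistanceMatrix``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import skbio
from sklearn.isotonic import IsotonicRegression

logger = logging.getLogger("magpipe")


@dataclass
class OrdinationResult:
    """Sample coordinates plus method-specific diagnostics.

    ``stress``/``stress_history`` are set by NMDS; ``eigenvalues`` and
    ``constrained_fraction`` by RDA.
    """

    method: str
    coordinates: pd.DataFrame
    stress: float | None = None
    stress_history: list[float] = field(default_factory=list)
    eigenvalues: np.ndarray | None = None
    constrained_fraction: float | None = None


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------


def bray_curtis(counts: pd.DataFrame) -> skbio.DistanceMatrix:
    """Bray-Curtis dissimilarity between the rows of a count matrix.

    Counts must be non-negative and no row may be all-zero (the
    dissimilarity is undefined for empty communities).
    """
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    sums = x.sum(axis=1)
    if (sums == 0).any():
        bad = counts.index[int(np.argmax(sums == 0))]
        raise ValueError(f"row {bad!r} is all zero; Bray-Curtis undefined")
    # sum_k |x_ik - x_jk| == (s_i + s_j) - 2 sum_k min(x_ik, x_jk)
    diff = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    denom = sums[:, None] + sums[None, :]
    d = diff / denom
    np.fill_diagonal(d, 0.0)
    return skbio.DistanceMatrix(d, ids=[str(i) for i in counts.index])


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


def _condensed(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def _pair_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return _condensed(np.sqrt((diff**2).sum(axis=2)))


def _stress1(dist: np.ndarray, disp: np.ndarray) -> float:
    denom = float((dist**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dist - disp) ** 2).sum() / denom))


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson metric scaling: first k principal coordinates of d."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)


def _smacof_single(
    delta: np.ndarray,
    init: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, list[float]]:
    """One NMDS run: majorization with isotonic disparities.

    Returns the configuration, its final stress-1 and the per-iteration
    stress sequence (non-increasing: an iteration that would raise the
    stress restores the previous configuration and stops).
    """
    n = init.shape[0]
    x = init.copy()
    x_prev = x
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    order = np.argsort(delta, kind="stable")
    history: list[float] = []
    prev_stress = np.inf
    eps = np.finfo(float).eps
    for _ in range(max_iter):
        dist = _pair_distances(x)
        disp = np.empty_like(dist)
        disp[order] = iso.fit_transform(delta[order], dist[order])
        # scale disparities to the scale of the distances
        ss = (disp**2).sum()
        if ss > 0:
            disp = disp * np.sqrt((dist**2).sum() / ss)
        stress = _stress1(dist, disp)
        if stress > prev_stress:
            break  # majorization stalled; keep the previous configuration
        history.append(stress)
        x_prev = x
        if prev_stress - stress < tol and np.isfinite(prev_stress):
            prev_stress = stress
            break
        prev_stress = stress
        # Guttman transform
        ratio = np.zeros_like(dist)
        nz = dist > eps
        ratio[nz] = disp[nz] / dist[nz]
        b = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        b[iu] = -ratio
        b = b + b.T
        np.fill_diagonal(b, -b.sum(axis=1))
        x = b @ x / n
    return x_prev, prev_stress if np.isfinite(prev_stress) else 0.0, history


def nmds(
    d: skbio.DistanceMatrix,
    k_axes: int = 2,
    n_starts: int = 8,
    max_iter: int = 500,
    tol: float = 1e-12,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    Minimises Kruskal stress-1 over ``n_starts`` runs (the first
    initialised by classical metric scaling, the rest random) and
    returns the best configuration, centred and rotated to principal
    axes with deterministic signs.  Deterministic under a fixed seed.
    """
    dm = np.asarray(d.data, dtype=float)
    n = dm.shape[0]
    if n < 3:
        raise ValueError("NMDS needs at least 3 samples")
    rng = np.random.default_rng(seed)
    delta = _condensed(dm)
    best: tuple[np.ndarray, float, list[float]] | None = None
    for start in range(n_starts):
        if start == 0:
            init = _classical_scaling(dm, k_axes)
            if init.shape[1] < k_axes:  # degenerate metric init
                pad = rng.uniform(-1, 1, size=(n, k_axes - init.shape[1]))
                init = np.hstack([init, pad])
        else:
            init = rng.uniform(-1.0, 1.0, size=(n, k_axes))
        x, stress, history = _smacof_single(delta, init, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, history)
    x, stress, history = best
    x = x - x.mean(axis=0)
    # rotate to principal axes; fix signs so each axis' largest-|.| entry > 0
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for j in range(x.shape[1]):
        if x[np.argmax(np.abs(x[:, j])), j] < 0:
            x[:, j] = -x[:, j]
    coords = pd.DataFrame(
        x,
        index=pd.Index(list(d.ids), name="sample"),
        columns=[f"NMDS{i + 1}" for i in range(k_axes)],
    )
    return OrdinationResult(
        method="nmds", coordinates=coords, stress=stress, stress_history=history
    )


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------


def dummy_code(constraints: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code categorical constraint columns (drop-first per factor)."""
    return pd.get_dummies(constraints, drop_first=True, dtype=float)


def rda(response: pd.DataFrame, constraints: pd.DataFrame) -> OrdinationResult:
    """Redundancy analysis of a response matrix under linear constraints.

    Response columns are centred and regressed on the centred,
    dummy-coded constraints by least squares; the covariance of the
    fitted values is eigendecomposed to give the constrained axes.
    ``constrained_fraction`` is fitted variance over total variance.
    Rank-deficient constraint columns are dropped with a warning.
    """
    if list(response.index) != list(constraints.index):
        if set(response.index) != set(constraints.index):
            raise ValueError("response and constraints must share row ids")
        constraints = constraints.loc[response.index]
    y = response.to_numpy(dtype=float)
    yc = y - y.mean(axis=0)
    xdf = dummy_code(constraints)
    x = xdf.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    # drop rank-deficient columns via pivoted QR
    q, r, piv = scipy.linalg.qr(xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(xc.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    keep = sorted(piv[i] for i in range(len(diag)) if diag[i] > tol)
    if len(keep) < xc.shape[1]:
        dropped = [xdf.columns[i] for i in range(xc.shape[1]) if i not in keep]
        logger.warning("rda: dropping redundant constraint columns: %s",
                       ", ".join(map(str, dropped)))
        xc = xc[:, keep]
    coef, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ coef
    n = y.shape[0]
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    eigenvalues = (s[:rank] ** 2) / (n - 1)
    site_scores = u[:, :rank] * s[:rank]
    total = float((yc**2).sum())
    constrained = float((fitted**2).sum())
    fraction = constrained / total if total > 0 else 0.0
    coords = pd.DataFrame(
        site_scores,
        index=pd.Index(list(response.index), name="sample"),
        columns=[f"RDA{i + 1}" for i in range(rank)],
    )
    return OrdinationResult(
        method="rda",
        coordinates=coords,
        eigenvalues=eigenvalues,
        constrained_fraction=fraction,
    )


def variable_loadings(
    data: pd.DataFrame, result: OrdinationResult
) -> pd.DataFrame:
    """Correlation of each data column with each ordination axis.

    Used to draw variable arrows over an ordination plot; columns with
    zero variance get zero loadings.
    """
    coords = result.coordinates.loc[data.index]
    out = pd.DataFrame(index=data.columns, columns=coords.columns, dtype=float)
    for var in data.columns:
        v = data[var].to_numpy(dtype=float)
        for axis in coords.columns:
            a = coords[axis].to_numpy()
            if v.std() == 0 or a.std() == 0:
                out.loc[var, axis] = 0.0
            else:
                out.loc[var, axis] = float(np.corrcoef(v, a)[0, 1])
    return out
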