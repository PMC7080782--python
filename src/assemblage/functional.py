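"""Composition-function coupling statistics.

Covers the functional side of the pipeline: water-subtracted substrate
(EcoPlate-style) profiles, CO2 variance dynamics across microcosms,
Mantel and Procrustes (PROTEST) permutation tests relating composition
to function, projected cumulative enzyme activity (strain activity
weighted by ASV frequency), and plain/intercept-free OLS summaries.

Both permutation tests are one-tailed for positive association and use
the add-one rule p = (1 + #{permuted >= observed}) / (n_perm + 1), so p
can never be 0 and the attainable minimum is 1/(n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import DissimilarityMatrix, OrdinationResult
from .io import ActivityTable, Co2Table, FunctionProfileTable, MicrocosmSeries


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass
class ProcrustesResult:
    correlation: float
    m12_squared: float
    p_value: float
    n_permutations: int
    seed: int


def process_function_profiles(raw: pd.DataFrame, water_column: str = "water"):
    """Subtract the water control from each substrate response, clipping at
    zero.  ``raw`` is indexed by (microcosm_id, day) with substrate columns
    plus the water-control column.  Returns (FunctionProfileTable,
    n_clipped)."""
    if water_column not in raw.columns:
        raise ValueError(f"missing water control column {water_column!r}")
    substrates = [c for c in raw.columns if c != water_column]
    vals = raw[substrates].to_numpy(float) - raw[[water_column]].to_numpy(float)
    n_clipped = int(np.sum(vals < 0))
    vals = np.clip(vals, 0.0, None)
    index = [(str(m), int(d)) for m, d in raw.index]
    return FunctionProfileTable(index=index, substrate_ids=substrates, values=vals), n_clipped


def co2_variance_series(co2: Co2Table) -> dict[int, float]:
    """Sample variance (n-1 denominator) of percent CO2 across microcosms,
    per day; days with fewer than two values are skipped with a warning."""
    df = co2.to_frame().reset_index()
    out: dict[int, float] = {}
    for day, grp in df.groupby("day", sort=True):
        if len(grp) < 2:
            warnings.warn(f"day {day}: fewer than 2 microcosms, skipped")
            continue
        out[int(day)] = float(grp["percent_co2"].var(ddof=1))
    return out


def _aligned_condensed(d1: DissimilarityMatrix, d2: DissimilarityMatrix):
    if set(d1.sample_ids) != set(d2.sample_ids):
        raise ValueError("mismatched sample sets")
    if d1.sample_ids != d2.sample_ids:
        d2 = d2.reorder(d1.sample_ids)
    return d1, d2


def mantel_test(d1: DissimilarityMatrix, d2: DissimilarityMatrix,
                n_perm: int = 9999, seed: int = 0,
                method: str = "pearson") -> MantelResult:
    """Mantel permutation test for positive association between two distance
    matrices over the same samples.  r is the Pearson (or Spearman)
    correlation of strictly-lower-triangle entries; the null permutes one
    matrix's rows and columns jointly."""
    d1, d2 = _aligned_condensed(d1, d2)
    n = d1.n
    if n < 4:
        raise ValueError("need at least 4 samples")
    iu = np.triu_indices(n, 1)
    x1 = d1.values[iu]
    x2 = d2.values[iu]
    if method == "spearman":
        x1 = stats.rankdata(x1)
        x2 = stats.rankdata(x2)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")

    a = x1 - x1.mean()
    na = float(np.sqrt(a @ a))
    nb = float(np.sqrt(np.sum((x2 - x2.mean()) ** 2)))
    if na == 0 or nb == 0:
        raise ValueError("a distance matrix has zero variance")
    # Joint row/column permutation only permutes the triangle entries, so
    # the centered norm of the permuted triangle is invariant; with ``a``
    # centered, each permuted r is just a gather plus a dot product.
    mat2 = np.zeros((n, n))
    mat2[iu] = x2
    mat2 = mat2 + mat2.T
    r_obs = float(a @ x2 / (na * nb))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p_idx = rng.permutation(n)
        b = mat2[p_idx[iu[0]], p_idx[iu[1]]]
        if a @ b / (na * nb) >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p_value=float(p), n_permutations=n_perm, seed=seed)


def _standardize(coords: np.ndarray) -> np.ndarray:
    x = coords - coords.mean(axis=0)
    norm = np.sqrt(np.sum(x**2))
    if norm == 0:
        raise ValueError("degenerate configuration: all points coincide")
    return x / norm


def _procrustes_m12sq(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Procrustes m12^2 between centered, unit-scaled configs."""
    s = np.linalg.svd(a.T @ b, compute_uv=False)
    return float(max(0.0, 1.0 - s.sum() ** 2))


def procrustes_test(a: OrdinationResult, b: OrdinationResult,
                    n_perm: int = 999, seed: int = 0) -> ProcrustesResult:
    """PROTEST: optimal superposition of two ordinations of the same samples,
    significance by row permutation of one configuration."""
    if a.sample_ids != b.sample_ids:
        if set(a.sample_ids) != set(b.sample_ids):
            raise ValueError("mismatched sample sets")
        idx = [b.sample_ids.index(s) for s in a.sample_ids]
        b = OrdinationResult(list(a.sample_ids), b.coordinates[idx], b.method, b.stress)
    xa = np.asarray(a.coordinates, dtype=float)
    xb = np.asarray(b.coordinates, dtype=float)
    if xa.shape != xb.shape:
        raise ValueError("dimension mismatch between configurations")
    n = xa.shape[0]
    xa = _standardize(xa)
    xb = _standardize(xb)
    if n == 2:
        warnings.warn("2-point configurations are degenerate: correlation is always 1")
    m12 = _procrustes_m12sq(xa, xb)
    corr = float(np.sqrt(1.0 - m12))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        c = np.sqrt(1.0 - _procrustes_m12sq(xa, xb[perm]))
        if c >= corr:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return ProcrustesResult(correlation=corr, m12_squared=m12, p_value=float(p),
                            n_permutations=n_perm, seed=seed)


def cumulative_activity(activity: ActivityTable, series: MicrocosmSeries,
                        enzyme: str = "endochitinase") -> dict[int, float]:
    """Projected community activity per day: sum over ASVs of strain
    activity times ASV relative abundance (ASVs without a measured strain
    contribute 0)."""
    act = np.array([activity.activity(a, enzyme) for a in series.asv_ids])
    values = series.rel_abundance @ act
    return {int(d): float(v) for d, v in zip(series.days, values)}


def linear_fit(x, y, with_intercept: bool = True):
    """OLS of y on x; returns (coefficients, r_squared, p_value).

    Without an intercept the slope is sum(xy)/sum(x^2) and R^2 is computed
    against the uncentered total sum of squares; p-values come from the
    F statistic in both cases.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length x and y with at least 3 points")
    n = x.size
    if with_intercept:
        if np.ptp(x) == 0:
            raise ValueError("degenerate x: zero variance")
        res = stats.linregress(x, y)
        return (float(res.slope), float(res.intercept)), float(res.rvalue**2), float(res.pvalue)
    beta = float(x @ y / (x @ x))
    resid = y - beta * x
    ss_res = float(resid @ resid)
    ss_tot = float(y @ y)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    df_res = n - 1
    if ss_res == 0:
        return (beta,), r2, 0.0
    f_stat = (ss_tot - ss_res) / (ss_res / df_res)
    p = float(stats.f.sf(f_stat, 1, df_res))
    return (beta,), r2, p


def function_dissimilarity(table: FunctionProfileTable,
                           metric: str = "braycurtis") -> DissimilarityMatrix:
    """Bray-Curtis (default) dissimilarities between substrate profiles;
    sample ids are "microcosm|day" strings."""
    from .diversity import dissimilarity_matrix

    ids = [f"{m}|{d}" for m, d in table.index]
    return dissimilarity_matrix(table.values, sample_ids=ids, metric=metric)
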