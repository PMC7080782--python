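"""Context dependence of ASV trajectories across microcosms.

The central question: is the trajectory of an ASV set by its identity
or by the community it finds itself in?  The tools here are (i) CLR
transformation of count time series (never-observed ASVs removed per
microcosm, one pseudo-read added to the rest), (ii) Pearson
correlations of the same ASV's CLR series across microcosm pairs,
compared between replicate pairs started from the same inoculum,
pairs from different inocula, and a count-matched random-ASV-pair
null, (iii) coupling between compositional divergence and trajectory
divergence (cosine distance), and (iv) a shared-fate null model
P(n) = f^(n-1) for an ASV having the same fate in all n microcosms
it occupies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .diversity import bray_curtis
from .extinction import experiment_extinction_records
from .io import Experiment, MicrocosmSeries

SAME_INOCULUM = "same_inoculum"
DIFFERENT_INOCULUM = "different_inoculum"
RANDOM_PAIR = "random_pair"


@dataclass
class TrajectoryCorrelation:
    asv_id: str  # "asvA|asvB" for random pairs
    pair: tuple[str, str]  # series labels
    category: str
    pearson_r: float
    n_timepoints: int


@dataclass
class FateTable:
    fate: dict  # (asv_id, series label) -> "survivor" | "extinct"
    occupancy: dict  # asv_id -> number of series whose baseline pool holds it


@dataclass
class CouplingPoint:
    pair: tuple[str, str]
    mean_bray_curtis_final: float
    mean_cosine_distance: float
    n_shared_asvs: int


class CLRTransformer:
    """Centered log-ratio transform of one microcosm's count matrix.

    ``fit`` records which ASVs were ever observed in the microcosm (the
    rest are removed, not zero-padded); ``transform`` adds ``pseudocount``
    reads to every retained cell and centers log counts per timepoint.
    With ``pseudocount=0`` the transform is exactly scale-invariant per
    timepoint; the default 1 pseudo-read accounts for abundances below
    the detection threshold.
    """

    def __init__(self, pseudocount: float = 1.0):
        self.pseudocount = pseudocount

    def get_params(self, deep: bool = True) -> dict:
        return {"pseudocount": self.pseudocount}

    def set_params(self, **params) -> "CLRTransformer":
        self.pseudocount = params.pop("pseudocount", self.pseudocount)
        if params:
            raise ValueError(f"unknown parameters {sorted(params)}")
        return self

    def fit(self, counts: np.ndarray) -> "CLRTransformer":
        counts = np.asarray(counts, dtype=float)
        self.retained_ = np.flatnonzero(counts.sum(axis=0) > 0)
        if self.retained_.size == 0:
            raise ValueError("no ASV ever observed")
        return self

    def transform(self, counts: np.ndarray) -> np.ndarray:
        counts = np.asarray(counts, dtype=float)[:, self.retained_]
        shifted = counts + self.pseudocount
        if np.any(shifted <= 0):
            raise ValueError("zero counts require a positive pseudocount")
        logs = np.log(shifted)
        return logs - logs.mean(axis=1, keepdims=True)

    def fit_transform(self, counts: np.ndarray) -> np.ndarray:
        return self.fit(counts).transform(counts)


def clr_transform(series: MicrocosmSeries, pseudocount: float = 1.0):
    """CLR matrix for one series; returns (matrix, retained asv_ids)."""
    tf = CLRTransformer(pseudocount=pseudocount)
    mat = tf.fit_transform(series.counts)
    kept = [series.asv_ids[j] for j in tf.retained_]
    return mat, kept


def _pair_category(a: MicrocosmSeries, b: MicrocosmSeries) -> str:
    return SAME_INOCULUM if a.inoculum_id == b.inoculum_id else DIFFERENT_INOCULUM


def _pearson(x: np.ndarray, y: np.ndarray, min_var: float) -> float | None:
    if x.var() < min_var or y.var() < min_var:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def trajectory_correlations(exp: Experiment, window: tuple[int, int] | None = None,
                            min_var: float = 1e-12, seed: int = 0,
                            n_random: int | None = None,
                            persistence_day: int | None = 21) -> list[TrajectoryCorrelation]:
    """Same-ASV CLR trajectory correlations for every microcosm pair, plus a
    count-matched random-ASV-pair null (distinct ASVs, different microcosms,
    seeded).  ``window`` restricts to days in [lo, hi]; series pairs must
    share >= 3 sampled days.  Zero-variance series are skipped, not scored 0.

    Only ASVs persisting past ``persistence_day`` (detected at a later day)
    in both series of a pair are compared: early-extinct ASVs share a
    near-deterministic decline to the detection floor that would swamp
    every category with spurious positive correlations.  Pass
    ``persistence_day=None`` to disable the filter.
    """
    clr: dict[str, tuple[np.ndarray, dict, np.ndarray, set]] = {}
    for s in exp.series:
        mat, kept = clr_transform(s)
        days = s.days
        if persistence_day is None:
            persisting = set(kept)
        else:
            late = s.days > persistence_day
            persisting = {a for j, a in enumerate(s.asv_ids)
                          if s.counts[late, j].sum() > 0}
        if window is not None:
            lo, hi = window
            sel = (days >= lo) & (days <= hi)
            if not sel.any():
                raise ValueError("window selects no sampled days")
            mat, days = mat[sel], days[sel]
        clr[s.label] = (mat, {a: j for j, a in enumerate(kept)}, days, persisting)

    out: list[TrajectoryCorrelation] = []
    series = exp.series
    for i in range(len(series)):
        for j in range(i + 1, len(series)):
            a, b = series[i], series[j]
            mat_a, idx_a, days_a, pers_a = clr[a.label]
            mat_b, idx_b, days_b, pers_b = clr[b.label]
            shared_days, ia, ib = np.intersect1d(days_a, days_b, return_indices=True)
            if len(shared_days) < 3:
                continue
            cat = _pair_category(a, b)
            for asv in sorted(idx_a.keys() & idx_b.keys()):
                if asv not in pers_a or asv not in pers_b:
                    continue
                r = _pearson(mat_a[ia, idx_a[asv]], mat_b[ib, idx_b[asv]], min_var)
                if r is None:
                    continue
                out.append(TrajectoryCorrelation(asv, (a.label, b.label), cat, r,
                                                 len(shared_days)))

    n_target = n_random if n_random is not None else len(out)
    rng = np.random.default_rng(seed)
    attempts = 0
    drawn = 0
    while drawn < n_target and attempts < 50 * max(n_target, 1):
        attempts += 1
        i, j = rng.choice(len(series), size=2, replace=False)
        a, b = series[i], series[j]
        if a.microcosm_id == b.microcosm_id:
            continue
        mat_a, idx_a, days_a, pers_a = clr[a.label]
        mat_b, idx_b, days_b, pers_b = clr[b.label]
        shared_days, ia, ib = np.intersect1d(days_a, days_b, return_indices=True)
        if len(shared_days) < 3:
            continue
        asv_a = list(idx_a)[int(rng.integers(len(idx_a)))]
        asv_b = list(idx_b)[int(rng.integers(len(idx_b)))]
        if asv_a == asv_b:
            continue
        if asv_a not in pers_a or asv_b not in pers_b:
            continue
        r = _pearson(mat_a[ia, idx_a[asv_a]], mat_b[ib, idx_b[asv_b]], min_var)
        if r is None:
            continue
        out.append(TrajectoryCorrelation(f"{asv_a}|{asv_b}", (a.label, b.label),
                                         RANDOM_PAIR, r, len(shared_days)))
        drawn += 1
    return out


def distribution_summary(rs) -> tuple[float, float]:
    """(mean, mode) of a correlation-coefficient sample; the mode is the
    argmax of a Silverman-bandwidth Gaussian KDE on a 512-point grid over
    [-1, 1]."""
    rs = np.asarray(list(rs), dtype=float)
    if rs.size < 5:
        raise ValueError("need at least 5 values")
    mean = float(rs.mean())
    if np.ptp(rs) < 1e-12:
        return mean, float(rs[0])
    grid = np.linspace(-1.0, 1.0, 512)
    kde = stats.gaussian_kde(rs, bw_method="silverman")
    dens = kde(grid)
    return mean, float(grid[int(np.argmax(dens))])


def cosine_similarity(x, y) -> float:
    """sum(x*y) / (||x|| ||y||); scale-invariant, and timepoints where one
    series is zero contribute nothing to the inner product."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(x, y) / (nx * ny))


def composition_trajectory_coupling(exp: Experiment, equilibration_day: int = 21,
                                    final_day_only: bool = False):
    """Fig.-3e-style coupling: per microcosm pair, mean Bray-Curtis between
    final compositions vs mean cosine distance between shared-ASV
    relative-abundance trajectories; intercept-free fit of cosine distance
    on Bray-Curtis.  Returns (points, beta, r_squared_uncentered)."""
    series = exp.series
    points: list[CouplingPoint] = []
    for i in range(len(series)):
        for j in range(i + 1, len(series)):
            a, b = series[i], series[j]
            shared_days, ia, ib = np.intersect1d(a.days, b.days, return_indices=True)
            late = shared_days > equilibration_day
            if final_day_only:
                late = shared_days == shared_days.max()
            if not late.any():
                continue
            union = sorted(set(a.asv_ids) | set(b.asv_ids))
            pos_a = {asv: k for k, asv in enumerate(a.asv_ids)}
            pos_b = {asv: k for k, asv in enumerate(b.asv_ids)}
            bc_vals = []
            for da, db in zip(ia[late], ib[late]):
                va = np.zeros(len(union))
                vb = np.zeros(len(union))
                for k, asv in enumerate(union):
                    if asv in pos_a:
                        va[k] = a.rel_abundance[da, pos_a[asv]]
                    if asv in pos_b:
                        vb[k] = b.rel_abundance[db, pos_b[asv]]
                bc_vals.append(bray_curtis(va, vb))
            cos_vals = []
            for asv in sorted(set(a.asv_ids) & set(b.asv_ids)):
                xa = a.rel_abundance[ia, pos_a[asv]]
                xb = b.rel_abundance[ib, pos_b[asv]]
                # persisted past equilibration in at least one of the pair
                if not (xa[late].sum() > 0 or xb[late].sum() > 0):
                    continue
                if xa.sum() == 0 or xb.sum() == 0:
                    continue
                cos_vals.append(1.0 - cosine_similarity(xa, xb))
            if not cos_vals:
                continue
            points.append(CouplingPoint((a.label, b.label), float(np.mean(bc_vals)),
                                        float(np.mean(cos_vals)), len(cos_vals)))
    if len(points) < 3:
        raise ValueError("need >= 3 microcosm pairs with shared persisting ASVs")
    x = np.array([p.mean_bray_curtis_final for p in points])
    y = np.array([p.mean_cosine_distance for p in points])
    if x @ x == 0:  # identical compositions everywhere: points at the origin
        ss = float(y @ y)
        return points, 0.0, 1.0 if ss == 0 else 0.0
    beta = float(x @ y / (x @ x))
    ss_res = float(np.sum((y - beta * x) ** 2))
    ss_tot = float(np.sum(y**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return points, beta, r2


def classify_fates(exp: Experiment, baseline_transfer: int = 1,
                   treatment: str | None = None) -> FateTable:
    """survivor iff censored at the final transfer, extinct otherwise;
    occupancy = number of series whose baseline pool contains the ASV."""
    records = experiment_extinction_records(exp, baseline_transfer, treatment)
    fate: dict = {}
    occupancy: dict = {}
    for r in records:
        label = f"{r.microcosm_id}-{r.treatment[0].upper()}"
        fate[(r.asv_id, label)] = "survivor" if r.censored else "extinct"
        occupancy[r.asv_id] = occupancy.get(r.asv_id, 0) + 1
    return FateTable(fate=fate, occupancy=occupancy)


def shared_fate_null(n: int, f: float = 0.5) -> float:
    """Null probability f^(n-1) that an ASV found in n microcosms has the
    same fate in all of them."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0, 1]")
    return float(f ** (n - 1))


def shared_fate_test(table: FateTable, f: float = 0.5) -> dict:
    """Per occupancy level n >= 2: observed fraction of ASVs with one fate
    across all n microcosms vs the null f^(n-1), with an exact one-sided
    binomial p-value.  Returns {n: (observed_fraction, null_prob, p_value,
    n_asvs)}."""
    if not table.fate:
        raise ValueError("empty fate table")
    by_asv: dict = {}
    for (asv, _label), fate in table.fate.items():
        by_asv.setdefault(asv, []).append(fate)
    levels: dict = {}
    for asv, fates in by_asv.items():
        n = len(fates)
        if n < 2:
            continue
        levels.setdefault(n, []).append(len(set(fates)) == 1)
    out = {}
    for n in sorted(levels):
        same = levels[n]
        k, m = int(np.sum(same)), len(same)
        null = shared_fate_null(n, f)
        p = stats.binomtest(k, m, null, alternative="greater").pvalue
        out[n] = (k / m, null, float(p), m)
    return out
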