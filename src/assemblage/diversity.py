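"""Richness, effective species number, Bray-Curtis machinery and ordination.

Richness uses a detection-limit back-fill: an ASV detected at any later
timepoint of a microcosm is counted as present at earlier timepoints,
so richness curves are non-increasing by construction.  Ordination
defaults to classical scaling (PCoA), which is deterministic and exact
on Euclidean input; non-metric MDS (Kruskal stress-1, seeded restarts)
is available for parity with vegan-style analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .io import Experiment, MicrocosmSeries


@dataclass
class DissimilarityMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries in scipy's condensed order."""
        return squareform(self.values, checks=False)

    def reorder(self, sample_ids: list[str]) -> "DissimilarityMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DissimilarityMatrix(list(sample_ids), self.values[np.ix_(idx, idx)])


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray
    method: str  # "pcoa" | "nmds"
    stress: float | None = None
    eigenvalues: np.ndarray | None = None
    n_negative_eigenvalues: int = 0


def backfilled_presence(series: MicrocosmSeries) -> np.ndarray:
    """Boolean (timepoints x ASVs): present if detected at this or any
    later timepoint."""
    detected = series.counts > 0
    return np.flip(np.logical_or.accumulate(np.flip(detected, axis=0), axis=0), axis=0)


def backfilled_richness(series: MicrocosmSeries) -> np.ndarray:
    """Detection-limit-corrected richness per timepoint (non-increasing)."""
    return backfilled_presence(series).sum(axis=1)


def effective_species(rel_row) -> float:
    """exp(Shannon index) of a relative-abundance vector (zeros excluded)."""
    x = np.asarray(rel_row, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative relative abundances")
    if abs(x.sum() - 1.0) > 1e-9:
        raise ValueError("relative abundances must sum to 1")
    x = x[x > 0]
    return float(np.exp(-np.sum(x * np.log(x))))


def bray_curtis(x, y) -> float:
    """1 - 2 sum(min(x, y)) / (sum x + sum y) for non-negative vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("Bray-Curtis requires non-negative entries")
    total = x.sum() + y.sum()
    if total == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / total)


_METRICS = {"braycurtis", "euclidean", "cityblock"}


def dissimilarity_matrix(samples: np.ndarray, sample_ids: list[str] | None = None,
                         metric: str = "braycurtis") -> DissimilarityMatrix:
    """Pairwise dissimilarities over rows (samples aligned on a shared
    feature axis, absent features as zeros)."""
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    samples = np.asarray(samples, dtype=float)
    if sample_ids is None:
        sample_ids = [str(i) for i in range(samples.shape[0])]
    d = squareform(pdist(samples, metric=metric))
    return DissimilarityMatrix(list(sample_ids), d)


def adjacent_dissimilarity(series: MicrocosmSeries, metric: str = "braycurtis") -> np.ndarray:
    """Dissimilarity between each consecutive pair of sampled days."""
    if series.n_timepoints < 2:
        raise ValueError("need at least two timepoints")
    rows = series.rel_abundance
    if metric == "braycurtis":
        return np.array([bray_curtis(rows[i], rows[i + 1])
                         for i in range(len(rows) - 1)])
    d = dissimilarity_matrix(rows, metric=metric).values
    return np.array([d[i, i + 1] for i in range(len(rows) - 1)])


def occupancy_summary(exp: Experiment, at_day: int, treatment: str | None = None):
    """Per-ASV (number of microcosms occupied, mean relative abundance where
    present) at ``at_day``."""
    selected = [s for s in exp.series if treatment is None or s.treatment == treatment]
    occ: dict[str, list[float]] = {}
    for s in selected:
        if at_day not in s.days:
            raise ValueError(f"day {at_day} not sampled in {s.label}")
        i = int(np.flatnonzero(s.days == at_day)[0])
        for j, asv in enumerate(s.asv_ids):
            if s.counts[i, j] > 0:
                occ.setdefault(asv, []).append(float(s.rel_abundance[i, j]))
    return {asv: (len(v), float(np.mean(v))) for asv, v in occ.items()}


# ---------------------------------------------------------------------------
# ordination


class PCoA:
    """Classical scaling (principal coordinates) on a dissimilarity matrix.

    Double-centers -D^2/2, keeps the top-k positive-eigenvalue axes
    (negative eigenvalues are dropped and counted, no Cailliez
    correction).  Deterministic; exact on Euclidean input.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components}

    def set_params(self, **params) -> "PCoA":
        self.n_components = params.pop("n_components", self.n_components)
        if params:
            raise ValueError(f"unknown parameters {sorted(params)}")
        return self

    def fit_transform(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        n = d.shape[0]
        if self.n_components >= n:
            raise ValueError("n_components must be < number of samples")
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (d**2) @ J
        evals, evecs = eigh((B + B.T) / 2.0)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        self.eigenvalues_ = evals
        self.n_negative_eigenvalues_ = int(np.sum(evals < -1e-10 * max(1.0, abs(evals[0]))))
        pos = evals[: self.n_components]
        if pos.max() <= 1e-12:
            raise ValueError("degenerate dissimilarity matrix: no positive axes")
        coords = evecs[:, : self.n_components] * np.sqrt(np.clip(pos, 0.0, None))
        self.embedding_ = coords
        return coords


class NMDS:
    """Non-metric MDS (Kruskal stress-1) with seeded multiple restarts."""

    def __init__(self, n_components: int = 2, n_restarts: int = 10,
                 max_iter: int = 300, seed: int = 0):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components, "n_restarts": self.n_restarts,
                "max_iter": self.max_iter, "seed": self.seed}

    def set_params(self, **params) -> "NMDS":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit_transform(self, d: np.ndarray) -> np.ndarray:
        from sklearn.manifold import MDS

        d = np.asarray(d, dtype=float)
        if self.n_components >= d.shape[0]:
            raise ValueError("n_components must be < number of samples")
        rng = np.random.default_rng(self.seed)
        best, best_stress = None, np.inf
        for _ in range(self.n_restarts):
            state = int(rng.integers(2**31))
            mds = MDS(n_components=self.n_components, metric_mds=False,
                      metric="precomputed", n_init=1, init="random",
                      max_iter=self.max_iter, normalized_stress=True,
                      random_state=state)
            coords = mds.fit_transform(d)
            if mds.stress_ < best_stress:
                best, best_stress = coords, float(mds.stress_)
        self.embedding_ = best
        self.stress_ = best_stress
        return best


def ordinate(d: DissimilarityMatrix, k: int = 2, method: str = "pcoa",
             seed: int = 0, n_restarts: int = 10) -> OrdinationResult:
    """Embed a dissimilarity matrix in k dimensions."""
    vals = d.values
    off_diag = vals[np.triu_indices(d.n, 1)]
    if off_diag.size and np.ptp(off_diag) == 0 and off_diag[0] == 0:
        raise ValueError("degenerate dissimilarity matrix: all samples identical")
    if method == "pcoa":
        est = PCoA(n_components=k)
        coords = est.fit_transform(vals)
        return OrdinationResult(d.sample_ids, coords, "pcoa",
                                eigenvalues=est.eigenvalues_,
                                n_negative_eigenvalues=est.n_negative_eigenvalues_)
    if method == "nmds":
        est = NMDS(n_components=k, n_restarts=n_restarts, seed=seed)
        coords = est.fit_transform(vals)
        return OrdinationResult(d.sample_ids, coords, "nmds", stress=est.stress_)
    raise ValueError(f"unknown ordination method {method!r}")


def richness_regression(exp: Experiment, day_x: int, day_y: int,
                        treatment: str | None = None):
    """OLS (with intercept) of back-filled richness at ``day_y`` on that at
    ``day_x`` across microcosms; returns (slope, intercept, r_squared, p_value)."""
    xs, ys = [], []
    for s in exp.series:
        if treatment is not None and s.treatment != treatment:
            continue
        if day_x not in s.days or day_y not in s.days:
            raise ValueError(f"days {day_x}/{day_y} not sampled in {s.label}")
        rich = backfilled_richness(s)
        xs.append(rich[int(np.flatnonzero(s.days == day_x)[0])])
        ys.append(rich[int(np.flatnonzero(s.days == day_y)[0])])
    if len(xs) < 3:
        raise ValueError("need at least 3 microcosms")
    res = stats.linregress(xs, ys)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)
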