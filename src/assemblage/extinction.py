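"""Geometric extinction-time null model and richness-decay machinery.

The null model: every ASV that is destined to go extinct in a given
community does so with a fixed per-transfer probability ``p``, so its
extinction transfer T (measured from a baseline transfer) is geometric,

    P(T = t) = p (1 - p)^(t-1),   t = 1, 2, ...

The maximum-likelihood estimate is p_hat = 1 / mean(t).  Whether one
shared rate suffices for all microcosms, or each needs its own, is
decided with a Bayesian Information Criterion written on the
log-likelihood scale,

    B_k = ln(n) * k - L(data | {p}_k),

with k the number of rate parameters and n the number of microcosms;
the winner has the smaller B, and exp((B_loser - B_winner) / 2) is the
relative likelihood of the winning model.  A ``conventional=True`` flag
switches to the textbook BIC (penalty on -2L, n = number of
observations).

ASVs still present at the final transfer are right-censored: the model
is explicitly conditional on eventual extinction, so censored records
never enter the likelihood; their fraction is the survival fraction
``s`` of the richness-decay curve  s + (1-s)(1-p)^t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .diversity import backfilled_presence
from .io import Experiment, MicrocosmSeries


@dataclass
class ExtinctionRecord:
    asv_id: str
    microcosm_id: str
    treatment: str
    extinction_transfer: int | None  # None => right-censored (survived)

    @property
    def censored(self) -> bool:
        return self.extinction_transfer is None


@dataclass
class GeometricFit:
    p_hat: float
    mean_time: float
    log_likelihood: float
    n_obs: int


@dataclass
class ModelComparison:
    bic_common: float
    bic_individual: float
    k_common: int
    k_individual: int
    n_groups: int
    relative_likelihood: float
    winner: str  # "common" | "individual"
    common_fit: GeometricFit
    per_group_fits: dict


@dataclass
class RichnessDecayModel:
    survival_fraction: float
    extinction_rate: float


class GeometricExtinctionModel:
    """sklearn-style estimator for the geometric extinction-time model.

    Parameters
    ----------
    p : float or None
        Fix the rate instead of estimating it (used by goodness-of-fit
        against an external rate).

    Attributes (after ``fit``)
    --------------------------
    p_hat_ : float            MLE 1/mean(t) (or the fixed ``p``).
    mean_time_ : float
    log_likelihood_ : float
    n_obs_ : int
    """

    def __init__(self, p: float | None = None):
        self.p = p

    def get_params(self, deep: bool = True) -> dict:
        return {"p": self.p}

    def set_params(self, **params) -> "GeometricExtinctionModel":
        for k, v in params.items():
            if k != "p":
                raise ValueError(f"unknown parameter {k!r}")
            self.p = v
        return self

    def fit(self, times) -> "GeometricExtinctionModel":
        t = _check_times(times)
        self.mean_time_ = float(t.mean())
        self.p_hat_ = float(self.p) if self.p is not None else 1.0 / self.mean_time_
        self.log_likelihood_ = float(np.sum(np.log(geometric_pmf(self.p_hat_, t))))
        self.n_obs_ = len(t)
        return self

    def score(self, times) -> float:
        """Log-likelihood of ``times`` under the fitted rate."""
        t = _check_times(times)
        return float(np.sum(np.log(geometric_pmf(self.p_hat_, t))))

    def result_(self) -> GeometricFit:
        return GeometricFit(self.p_hat_, self.mean_time_, self.log_likelihood_, self.n_obs_)


def _check_times(times) -> np.ndarray:
    t = np.asarray(list(times), dtype=float)
    if t.size == 0:
        raise ValueError("need at least one uncensored extinction time")
    if np.any(t < 1) or not np.allclose(t, np.round(t)):
        raise ValueError("extinction times must be integers >= 1")
    return t.astype(int)


def geometric_pmf(p: float, t) -> np.ndarray | float:
    """P(T = t) = p (1-p)^(t-1) on support t = 1, 2, ..."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p={p} outside (0, 1]")
    t_arr = np.asarray(t)
    if np.any(t_arr < 1):
        raise ValueError("t must be >= 1")
    out = p * (1.0 - p) ** (t_arr - 1)
    return float(out) if np.isscalar(t) else out


def fit_geometric(times) -> GeometricFit:
    """MLE of the geometric rate: p_hat = 1 / mean extinction time."""
    return GeometricExtinctionModel().fit(times).result_()


def extinction_times(series: MicrocosmSeries, baseline_transfer: int = 1,
                     interval: int = 3) -> list[ExtinctionRecord]:
    """Per-ASV extinction transfers for one microcosm, detection-limit aware.

    The baseline pool is every ASV present at ``baseline_transfer`` after
    back-fill (a detection at any later timepoint implies presence now).
    The extinction transfer is the number of transfers survived past the
    baseline, t = first permanently-absent transfer - baseline; ASVs
    detected at the final transfer are censored, and ASVs seen only
    before the baseline (e.g. Day-0 transients) are excluded.
    """
    transfers = series.transfer_indices(interval)
    if baseline_transfer not in transfers:
        raise ValueError(f"baseline transfer {baseline_transfer} not sampled")
    presence = backfilled_presence(series)
    base_row = int(np.searchsorted(transfers, baseline_transfer))
    detected = series.counts > 0
    records = []
    for j, asv in enumerate(series.asv_ids):
        if not presence[base_row, j]:
            continue
        if detected[-1, j]:
            t = None
        else:
            last = int(transfers[np.flatnonzero(presence[:, j])[-1]])
            t = (last + 1) - baseline_transfer
            if t < 1:  # present at baseline only via back-fill cannot reach here
                continue
        records.append(ExtinctionRecord(asv, series.microcosm_id, series.treatment, t))
    return records


def geometric_gof(times, p: float, min_expected: float = 5.0):
    """Pearson chi-squared goodness of fit of ``times`` to geometric(p).

    Bins are transfers 1, 2, ...; the right tail is pooled (with its full
    geometric tail mass) until every expected count is >= ``min_expected``;
    df = bins - 2 for the one estimated parameter.  Returns
    (chi2, df, p_value).
    """
    t = _check_times(times)
    n = len(t)
    tmax = int(t.max())
    obs = np.bincount(t, minlength=tmax + 1)[1:].astype(float)
    exp = n * geometric_pmf(p, np.arange(1, tmax + 1))
    # explicit open tail bin carrying the remaining geometric mass
    obs = np.append(obs, 0.0)
    exp = np.append(exp, n * (1.0 - p) ** tmax)
    # pool from the right until all expected counts clear the threshold
    while len(exp) > 2 and exp[-1] < min_expected:
        exp[-2] += exp[-1]
        obs[-2] += obs[-1]
        exp, obs = exp[:-1], obs[:-1]
    while len(exp) > 2 and exp.min() < min_expected:
        i = int(np.argmin(exp))
        j = i + 1 if i + 1 < len(exp) else i - 1
        exp[j] += exp[i]
        obs[j] += obs[i]
        exp, obs = np.delete(exp, i), np.delete(obs, i)
    if len(exp) < 2:
        raise ValueError("too few observations to form 2 bins")
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    df = max(len(exp) - 2, 1)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def compare_extinction_models(records_by_group: dict, conventional: bool = False) -> ModelComparison:
    """Common-rate vs per-microcosm-rate comparison by BIC.

    ``records_by_group`` maps group label -> list of uncensored extinction
    transfers.  Default scoring follows B_k = ln(n) k - L with n = number
    of groups; ``conventional=True`` uses ln(N) k - 2 L with N = total
    observations.
    """
    groups = {g: _check_times(ts) for g, ts in records_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(list(groups.values()))
    common = fit_geometric(pooled)
    per_group = {g: fit_geometric(ts) for g, ts in groups.items()}
    ll_ind = sum(f.log_likelihood for f in per_group.values())
    k_ind = len(groups)
    if conventional:
        n_pen = len(pooled)
        bic_c = np.log(n_pen) * 1 - 2 * common.log_likelihood
        bic_i = np.log(n_pen) * k_ind - 2 * ll_ind
    else:
        n_pen = len(groups)
        bic_c = np.log(n_pen) * 1 - common.log_likelihood
        bic_i = np.log(n_pen) * k_ind - ll_ind
    winner = "common" if bic_c <= bic_i else "individual"
    rel = relative_likelihood(bic_c, bic_i)
    return ModelComparison(bic_common=float(bic_c), bic_individual=float(bic_i),
                           k_common=1, k_individual=k_ind, n_groups=len(groups),
                           relative_likelihood=rel, winner=winner,
                           common_fit=common, per_group_fits=per_group)


def relative_likelihood(bic_a: float, bic_b: float) -> float:
    """Evidence ratio exp(|BIC difference| / 2) of the winner over the loser."""
    return float(np.exp(abs(bic_a - bic_b) / 2.0))


def expected_relative_richness(t, model: RichnessDecayModel):
    """Expected fraction of baseline richness surviving t transfers:
    s + (1 - s)(1 - p)^t."""
    t_arr = np.asarray(t)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    s, p = model.survival_fraction, model.extinction_rate
    out = s + (1.0 - s) * (1.0 - p) ** t_arr
    return float(out) if np.isscalar(t) else out


def estimate_decay_model(records: list[ExtinctionRecord]) -> RichnessDecayModel:
    """s = censored fraction of the pooled baseline pool; p = pooled MLE."""
    if not records:
        raise ValueError("no records")
    times = [r.extinction_transfer for r in records if not r.censored]
    n_cens = sum(r.censored for r in records)
    if not times:
        raise ValueError("all records censored: cannot fit extinction rate")
    fit = fit_geometric(times)
    return RichnessDecayModel(survival_fraction=n_cens / len(records),
                              extinction_rate=fit.p_hat)


def experiment_extinction_records(exp: Experiment, baseline_transfer: int = 1,
                                  treatment: str | None = None) -> list[ExtinctionRecord]:
    """Extinction records pooled over an experiment's series."""
    records = []
    for s in exp.series:
        if treatment is not None and s.treatment != treatment:
            continue
        records.extend(extinction_times(s, baseline_transfer,
                                        interval=exp.transfer_interval_days))
    return records


def records_by_microcosm(records: list[ExtinctionRecord]) -> dict:
    """Uncensored extinction times grouped by microcosm (for BIC comparison)."""
    out: dict = {}
    for r in records:
        if not r.censored:
            out.setdefault(r.microcosm_id, []).append(r.extinction_transfer)
    return out
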