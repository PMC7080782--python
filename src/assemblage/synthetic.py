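"""Seeded generator of microcosm experiments with known ground truth.

Emulates a serial-transfer study design: ~10 source communities
(inocula), each run as a filtered/unfiltered replicate pair, sampled at
Day 0 and after each of 21 transfers at 3-day intervals.  About half of
the ASVs present after the first transfer are destined for extinction,
with extinction transfers drawn from a geometric distribution with a
single common rate; survivors follow mean-reverting latent log-abundance
walks whose innovations are shared across replicate pairs (strongly) and
across inocula (weakly), producing the context-dependence structure the
analysis stages are meant to recover.  Substrate-use profiles are linear
in composition plus noise, so composition and function are coupled by
construction.

Every draw comes from one :class:`numpy.random.Generator` seeded once
per experiment, so whole generated objects are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ActivityTable, Co2Table, Experiment, FunctionProfileTable, MicrocosmSeries

SURVIVOR = "survivor"
DOOMED = "doomed"


class ConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults emulate the study design."""

    n_inocula: int = 10
    paired_treatments: bool = True
    n_transfers: int = 21
    transfer_interval_days: int = 3
    pool_size: int = 300
    initial_richness_range: tuple[int, int] = (20, 80)
    day0_transient_fraction: float = 1.0
    survival_fraction: float = 0.5
    extinction_rate: float = 0.3
    replicate_fate_agreement: float = 0.9
    fate_identity_correlation: float = 0.3
    context_correlation: float = 0.3
    replicate_correlation: float = 0.95
    walk_reversion: float = 0.4
    walk_noise: float = 0.5
    read_depth: int = 50000
    n_substrates: int = 31
    substrate_sparsity: float = 0.3
    function_noise: float = 0.05
    couple_occupancy_abundance: bool = True
    co2_level: float = 2.0
    co2_sd_day0: float = 0.8
    co2_sd_later: float = 0.1
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("day0_transient_fraction", "survival_fraction",
                     "replicate_fate_agreement", "fate_identity_correlation",
                     "context_correlation", "replicate_correlation",
                     "substrate_sparsity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.extinction_rate <= 1.0:
            raise ConfigError(f"extinction_rate={self.extinction_rate} outside (0, 1]")
        for name in ("n_inocula", "n_transfers", "pool_size", "read_depth",
                     "n_substrates"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        lo, hi = self.initial_richness_range
        if not (0 < lo <= hi):
            raise ConfigError("initial_richness_range must satisfy 0 < lo <= hi")
        if hi > self.pool_size:
            raise ConfigError("initial richness exceeds pool_size: infeasible")


@dataclass
class GroundTruth:
    """The generator's hidden state, for recovery tests."""

    fate: dict  # (asv_id, microcosm_id, treatment) -> SURVIVOR | DOOMED
    extinction_transfer: dict  # same key -> int >= 1, defined exactly for DOOMED
    substrate_vectors: pd.DataFrame  # pool ASVs x substrates
    activities: pd.DataFrame  # pool ASVs x enzyme classes
    membership: dict = field(default_factory=dict)  # (microcosm_id, treatment) -> list of asv_ids
    config: SyntheticConfig | None = None


def simulate_extinction_times(n: int, p: float, cap: int | None, seed: int) -> np.ndarray:
    """i.i.d. geometric({1, 2, ...}) extinction transfers; values above ``cap``
    are redrawn (truncation by rejection, not censoring)."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p={p} outside (0, 1]")
    rng = np.random.default_rng(seed)
    return _draw_truncated_geometric(rng, n, p, cap)


def _draw_truncated_geometric(rng, n, p, cap):
    t = rng.geometric(p, size=n)
    if cap is not None:
        while True:
            over = t > cap
            if not over.any():
                break
            t[over] = rng.geometric(p, size=int(over.sum()))
    return t


def sample_reads(true_rel: np.ndarray, depth: int, seed: int) -> np.ndarray:
    """Per-row multinomial read sampling; detection = count >= 1."""
    true_rel = np.atleast_2d(np.asarray(true_rel, dtype=float))
    sums = true_rel.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError("rows of true_rel must sum to 1")
    rng = np.random.default_rng(seed)
    return np.vstack([rng.multinomial(depth, row / row.sum()) for row in true_rel])


def simulate_survivor_trajectories(cfg: SyntheticConfig, membership, fates, seed):
    """Latent log-abundance matrices for every series (see module docstring).

    ``membership`` maps (microcosm_id, treatment) -> list of pool ASV
    indices; ``fates`` carries per-entry fate and extinction transfer.
    Returns dict (microcosm_id, treatment) -> (n_transfers+1, n_member)
    latent matrix with -inf marking absence.  Exposed separately so the
    correlation structure can be tested on the latents directly.
    """
    rng = np.random.default_rng(seed)
    return _trajectories(cfg, membership, fates, rng,
                         mu=_default_mu(cfg, rng), l0_jitter=None)


def _default_mu(cfg, rng):
    return rng.normal(0.0, 1.0, size=cfg.pool_size)


def _trajectories(cfg, membership, fates, rng, mu, l0_jitter=None):
    """Shared-innovation mean-reverting walks.

    Innovation for series (inoculum i, treatment) at step t for ASV a:
        e = sqrt(rho_rep) * e_inoc + sqrt(1 - rho_rep) * eta_series
        e_inoc = sqrt(rho_ctx) * g_asv + sqrt(1 - rho_ctx) * h_inoc
    so the same ASV's innovations correlate at exactly rho_rep between
    replicate pairs and at rho_ctx between inocula.
    Doomed ASVs follow a deterministic log-linear ramp from their initial
    level to a detection-floor latent at their extinction transfer, and
    are absent (-inf) afterwards.
    """
    T = cfg.n_transfers
    th, sg = cfg.walk_reversion, cfg.walk_noise
    r_rep, r_ctx = cfg.replicate_correlation, cfg.context_correlation
    floor = float(np.mean(mu)) - 4.0

    series_keys = sorted(membership)
    inocula = sorted({k[0] for k in series_keys})
    # innovation streams, drawn in a fixed order for reproducibility
    g = rng.standard_normal((cfg.pool_size, T))
    h = {i: rng.standard_normal((cfg.pool_size, T)) for i in inocula}
    eta = {k: rng.standard_normal((cfg.pool_size, T)) for k in series_keys}
    if l0_jitter is None:
        l0_jitter = {i: rng.normal(0.0, 0.5, size=cfg.pool_size) for i in inocula}

    out = {}
    for key in series_keys:
        inoc, _tr = key
        members = np.asarray(membership[key], dtype=int)
        e_inoc = np.sqrt(r_ctx) * g + np.sqrt(1 - r_ctx) * h[inoc]
        e = np.sqrt(r_rep) * e_inoc + np.sqrt(1 - r_rep) * eta[key]
        lat = np.full((T + 1, len(members)), -np.inf)
        l0 = mu[members] + l0_jitter[inoc][members]
        lat[0] = l0
        for j, a in enumerate(members):
            fate, tau = fates[(a,) + key]
            if fate == SURVIVOR:
                l = l0[j]
                for t in range(1, T + 1):
                    l = l + th * (mu[a] - l) + sg * e[a, t - 1]
                    lat[t, j] = l
            else:
                # linear latent ramp: present through transfer tau, gone after
                for t in range(1, T + 1):
                    if t <= tau:
                        lat[t, j] = l0[j] + (floor - l0[j]) * t / tau
        out[key] = lat
    return out


def generate_experiment(cfg: SyntheticConfig):
    """Generate (Experiment, FunctionProfileTable, Co2Table, ActivityTable,
    GroundTruth) under ``cfg``, deterministically in ``cfg.rng_seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    pool_ids = [f"ASV{i:04d}" for i in range(cfg.pool_size)]

    # heavy-tailed occupancy weights: few core ASVs, most rare
    w = rng.lognormal(mean=0.0, sigma=1.5, size=cfg.pool_size)
    pw = w / w.sum()
    mu = 0.8 * (np.log(w) - np.log(w).mean()) if cfg.couple_occupancy_abundance \
        else rng.normal(0.0, 1.0, size=cfg.pool_size)

    lo, hi = cfg.initial_richness_range
    treatments = ["filtered", "unfiltered"] if cfg.paired_treatments else ["filtered"]

    # per-ASV survival propensity: Beta with mean s and variance
    # c * s(1-s), so the same ASV's fates in two inocula correlate at c
    # while the marginal survival probability stays exactly s
    s_frac, c = cfg.survival_fraction, cfg.fate_identity_correlation
    if c == 0.0 or s_frac in (0.0, 1.0):
        survival_propensity = np.full(cfg.pool_size, s_frac)
    elif c >= 1.0:
        survival_propensity = (rng.random(cfg.pool_size) < s_frac).astype(float)
    else:
        nu = 1.0 / c - 1.0
        survival_propensity = rng.beta(s_frac * nu, (1.0 - s_frac) * nu,
                                       size=cfg.pool_size)

    membership: dict = {}
    transients: dict = {}
    fates: dict = {}
    inocula = []
    for i in range(cfg.n_inocula):
        inoc = f"M{i + 1:02d}"
        inocula.append(inoc)
        R = int(rng.integers(lo, hi + 1))
        members = np.sort(rng.choice(cfg.pool_size, size=R, replace=False, p=pw))
        n_tr = int(round(cfg.day0_transient_fraction * R))
        rest = np.setdiff1d(np.arange(cfg.pool_size), members)
        n_tr = min(n_tr, len(rest))
        trans = np.sort(rng.choice(rest, size=n_tr, replace=False,
                                   p=pw[rest] / pw[rest].sum()))
        base_fate = np.where(rng.random(R) < survival_propensity[members],
                             SURVIVOR, DOOMED)
        base_tau = _draw_truncated_geometric(rng, R, cfg.extinction_rate, cfg.n_transfers)
        for tr in treatments:
            membership[(inoc, tr)] = members
            transients[(inoc, tr)] = trans
            if tr == "filtered":
                fate_tr, tau_tr = base_fate, base_tau
            else:
                # on disagreement the replicate redraws from the ASV's own
                # propensity, so marginals (and the s = 1 boundary) are kept
                agree = rng.random(R) < cfg.replicate_fate_agreement
                redraw = np.where(rng.random(R) < survival_propensity[members],
                                  SURVIVOR, DOOMED)
                fate_tr = np.where(agree, base_fate, redraw)
                # re-draw times where the replicate's fate disagrees
                tau_tr = np.where(agree, base_tau,
                                  _draw_truncated_geometric(rng, R, cfg.extinction_rate,
                                                            cfg.n_transfers))
            for j, a in enumerate(members):
                fates[(a, inoc, tr)] = (str(fate_tr[j]), int(tau_tr[j]))

    l0_jitter = {i: rng.normal(0.0, 0.5, size=cfg.pool_size) for i in inocula}
    latents = _trajectories(cfg, membership, fates, rng, mu=mu, l0_jitter=l0_jitter)

    series = []
    truth_fate, truth_tau = {}, {}
    for (inoc, tr), lat in sorted(latents.items()):
        members = membership[(inoc, tr)]
        trans = transients[(inoc, tr)]
        all_idx = np.concatenate([members, trans])
        asv_ids = [pool_ids[a] for a in all_idx]
        T = cfg.n_transfers
        days = np.arange(T + 1) * cfg.transfer_interval_days
        full = np.full((T + 1, len(all_idx)), -np.inf)
        full[:, : len(members)] = lat
        # transients: present only at Day 0, at modest abundance
        full[0, len(members):] = mu[trans] - 1.0 + rng.normal(0.0, 0.5, size=len(trans))
        rel = _softmax_rows(full)
        counts = np.vstack([rng.multinomial(cfg.read_depth, row) for row in rel])
        series.append(
            MicrocosmSeries(microcosm_id=inoc, inoculum_id=inoc, treatment=tr,
                            days=days, asv_ids=asv_ids, counts=counts)
        )
        for a in members:
            fate, tau = fates[(a, inoc, tr)]
            key = (pool_ids[a], inoc, tr)
            truth_fate[key] = fate
            if fate == DOOMED:
                truth_tau[key] = tau

    exp = Experiment(series=series, transfer_interval_days=cfg.transfer_interval_days,
                     n_transfers=cfg.n_transfers)

    # per-ASV sparse substrate-use vectors and enzyme activities
    active = rng.random((cfg.pool_size, cfg.n_substrates)) < cfg.substrate_sparsity
    u = np.where(active, rng.uniform(0.2, 1.2, size=active.shape), 0.0)
    substrate_ids = [f"S{j + 1:02d}" for j in range(cfg.n_substrates)]
    uvec = pd.DataFrame(u, index=pool_ids, columns=substrate_ids)

    enzymes = list(ActivityTable.ENZYMES)
    act = np.zeros((cfg.pool_size, len(enzymes)))
    hot = rng.random(cfg.pool_size) < 0.2  # few strains carry hydrolytic activity
    for j in range(len(enzymes)):
        act[hot, j] = rng.lognormal(mean=1.0, sigma=1.0, size=int(hot.sum()))
    act_df = pd.DataFrame(act, index=pool_ids, columns=enzymes)

    truth = GroundTruth(fate=truth_fate, extinction_transfer=truth_tau,
                        substrate_vectors=uvec, activities=act_df,
                        membership={(i, t): [pool_ids[a] for a in m]
                                    for (i, t), m in membership.items()},
                        config=cfg)

    functions, co2 = generate_function_data(cfg, exp, truth,
                                            seed=int(rng.integers(2**31)))
    activity_table = ActivityTable(asv_ids=pool_ids, activities=act_df)
    return exp, functions, co2, activity_table, truth


def _softmax_rows(latent: np.ndarray) -> np.ndarray:
    out = np.zeros_like(latent)
    for i, row in enumerate(latent):
        finite = np.isfinite(row)
        if not finite.any():
            continue
        z = np.exp(row[finite] - row[finite].max())
        out[i, finite] = z / z.sum()
    return out


def generate_function_data(cfg: SyntheticConfig, exp: Experiment, truth: GroundTruth,
                           seed: int):
    """Substrate profiles linear in composition (plus noise) and CO2 series
    with inflated Day-0 variance, emulating convergent respiration."""
    rng = np.random.default_rng(seed)
    u = truth.substrate_vectors
    f_index, f_values = [], []
    c_index, c_values = [], []
    for s in exp.series:
        U = u.loc[s.asv_ids].to_numpy()
        for i, day in enumerate(s.days):
            prof = s.rel_abundance[i] @ U
            prof = prof + rng.normal(0.0, cfg.function_noise, size=prof.shape)
            f_index.append((s.microcosm_id + "-" + s.treatment[0].upper(), int(day)))
            f_values.append(np.clip(prof, 0.0, None))
            sd = cfg.co2_sd_day0 if day == 0 else cfg.co2_sd_later
            c_index.append((s.microcosm_id + "-" + s.treatment[0].upper(), int(day)))
            c_values.append(max(0.0, cfg.co2_level + rng.normal(0.0, sd)))
    functions = FunctionProfileTable(index=f_index,
                                     substrate_ids=list(u.columns),
                                     values=np.vstack(f_values))
    co2 = Co2Table(index=c_index, percent_co2=np.array(c_values))
    return functions, co2
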