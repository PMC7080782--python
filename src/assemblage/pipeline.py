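"""End-to-end orchestration: extinction -> diversity -> context -> function.

``run_pipeline`` produces a flat, schema-stable summary dict holding the
headline statistics of every stage (extinction rates and BIC comparison,
survival fraction, richness regression, correlation-category
means/modes, coupling R^2, Mantel and Procrustes results), written as
versioned JSON with sorted keys so identical seeds give byte-identical
reports.

A single top-level seed is expanded into per-stage sub-seeds with
``numpy.random.SeedSequence(seed).generate_state(...)`` (stage order:
simulate, context, mantel, procrustes), so stages are individually
reproducible and never share streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import context as ctx
from . import diversity as dv
from . import extinction as ext
from . import functional as fn
from .io import Experiment, read_abundance_long, read_activity_table, read_co2_table, read_function_table
from .synthetic import SyntheticConfig, generate_experiment

SCHEMA_VERSION = "assemblage-summary v1"

REQUIRED_KEYS = (
    "schema",
    "seed",
    "p_hat_common",
    "p_hat_per_microcosm",
    "bic_common",
    "bic_individual",
    "relative_likelihood",
    "bic_winner",
    "survival_fraction",
    "equilibrium_relative_richness",
    "richness_regression_r_squared",
    "richness_regression_p_value",
    "correlation_mean_same_inoculum",
    "correlation_mode_same_inoculum",
    "correlation_mean_different_inoculum",
    "correlation_mode_different_inoculum",
    "correlation_mean_random_pair",
    "correlation_mode_random_pair",
    "coupling_r_squared",
    "coupling_beta",
    "mantel_r",
    "mantel_p_value",
    "procrustes_correlation",
    "procrustes_p_value",
)


@dataclass
class PipelineConfig:
    """Exactly one of ``simulate`` / ``abundance_path`` must be set."""

    simulate: SyntheticConfig | None = None
    abundance_path: str | None = None
    function_path: str | None = None
    co2_path: str | None = None
    activity_path: str | None = None
    baseline_transfer: int = 1
    equilibration_day: int = 21
    analysis_treatment: str | None = "filtered"
    n_perm_mantel: int = 9999
    n_perm_procrustes: int = 999
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def validate(self) -> None:
        if (self.simulate is None) == (self.abundance_path is None):
            raise ValueError("set exactly one of simulate / abundance_path")


def stage_seeds(seed: int) -> dict[str, int]:
    """Documented expansion of the top-level seed into per-stage sub-seeds."""
    state = np.random.SeedSequence(seed).generate_state(4, dtype=np.uint32)
    names = ("simulate", "context", "mantel", "procrustes")
    return {name: int(s >> 1) for name, s in zip(names, state)}


def equilibrium_relative_richness(exp: Experiment, treatment: str | None = None,
                                  last_n: int = 5) -> float:
    """Mean over microcosms of back-filled richness normalized by the
    transfer-1 value, averaged over the last ``last_n`` transfers."""
    ratios = []
    for s in exp.series:
        if treatment is not None and s.treatment != treatment:
            continue
        rich = dv.backfilled_richness(s)
        transfers = s.transfer_indices(exp.transfer_interval_days)
        base = rich[np.flatnonzero(transfers == 1)[0]]
        if base == 0:
            continue
        ratios.append(float(np.mean(rich[-last_n:])) / base)
    if not ratios:
        raise ValueError("no usable series")
    return float(np.mean(ratios))


def run_pipeline(cfg: PipelineConfig) -> dict:
    cfg.validate()
    seeds = stage_seeds(cfg.seed)

    if cfg.simulate is not None:
        sim = cfg.simulate
        sim.rng_seed = seeds["simulate"]
        exp, functions, co2, activities, _truth = generate_experiment(sim)
    else:
        exp = read_abundance_long(cfg.abundance_path)
        functions = read_function_table(cfg.function_path) if cfg.function_path else None
        co2 = read_co2_table(cfg.co2_path) if cfg.co2_path else None
        activities = read_activity_table(cfg.activity_path) if cfg.activity_path else None

    treatment = cfg.analysis_treatment
    if treatment is not None and not any(s.treatment == treatment for s in exp.series):
        treatment = None

    summary: dict = {"schema": SCHEMA_VERSION, "seed": cfg.seed}

    # --- extinction stage -------------------------------------------------
    records = ext.experiment_extinction_records(exp, cfg.baseline_transfer, treatment)
    by_group = ext.records_by_microcosm(records)
    comparison = ext.compare_extinction_models(by_group)
    decay = ext.estimate_decay_model(records)
    summary["p_hat_common"] = comparison.common_fit.p_hat
    summary["p_hat_per_microcosm"] = {
        g: f.p_hat for g, f in sorted(comparison.per_group_fits.items())
    }
    summary["bic_common"] = comparison.bic_common
    summary["bic_individual"] = comparison.bic_individual
    summary["relative_likelihood"] = comparison.relative_likelihood
    summary["bic_winner"] = comparison.winner
    summary["survival_fraction"] = decay.survival_fraction

    # --- diversity stage --------------------------------------------------
    summary["equilibrium_relative_richness"] = equilibrium_relative_richness(exp, treatment)
    day_x = exp.transfer_interval_days * 1
    day_y = exp.transfer_interval_days * exp.n_transfers
    _, _, r2, pval = dv.richness_regression(exp, day_x, day_y, treatment)
    summary["richness_regression_r_squared"] = r2
    summary["richness_regression_p_value"] = pval

    # --- context stage ----------------------------------------------------
    corrs = ctx.trajectory_correlations(exp, seed=seeds["context"])
    for cat in (ctx.SAME_INOCULUM, ctx.DIFFERENT_INOCULUM, ctx.RANDOM_PAIR):
        rs = [c.pearson_r for c in corrs if c.category == cat]
        if len(rs) >= 5:
            mean, mode = ctx.distribution_summary(rs)
        else:  # e.g. unpaired designs have no same-inoculum pairs
            mean = mode = None
        summary[f"correlation_mean_{cat}"] = mean
        summary[f"correlation_mode_{cat}"] = mode
    _points, beta, r2c = ctx.composition_trajectory_coupling(exp, cfg.equilibration_day)
    summary["coupling_r_squared"] = r2c
    summary["coupling_beta"] = beta

    # --- function stage ---------------------------------------------------
    if functions is not None:
        comp_d, fun_d = _paired_dissimilarities(exp, functions)
        mantel = fn.mantel_test(comp_d, fun_d, n_perm=cfg.n_perm_mantel,
                                seed=seeds["mantel"])
        summary["mantel_r"] = mantel.r
        summary["mantel_p_value"] = mantel.p_value
        comp_f, fun_f = _paired_dissimilarities(exp, functions, final_day_only=True)
        ord_c = dv.ordinate(comp_f, k=2, method="pcoa")
        ord_f = dv.ordinate(fun_f, k=2, method="pcoa")
        proc = fn.procrustes_test(ord_c, ord_f, n_perm=cfg.n_perm_procrustes,
                                  seed=seeds["procrustes"])
        summary["procrustes_correlation"] = proc.correlation
        summary["procrustes_p_value"] = proc.p_value
    else:
        summary["mantel_r"] = None
        summary["mantel_p_value"] = None
        summary["procrustes_correlation"] = None
        summary["procrustes_p_value"] = None

    if co2 is not None:
        var = fn.co2_variance_series(co2)
        summary["co2_variance_by_day"] = {str(k): v for k, v in sorted(var.items())}
    return summary


def _paired_dissimilarities(exp: Experiment, functions, final_day_only: bool = False):
    """Bray-Curtis matrices for composition and function over the samples
    present in both modalities (paired by series label and day)."""
    fun_keys = {(m, d): i for i, (m, d) in enumerate(functions.index)}
    union_asvs = sorted({a for s in exp.series for a in s.asv_ids})
    pos = {a: k for k, a in enumerate(union_asvs)}
    rows_c, rows_f, ids = [], [], []
    for s in exp.series:
        days = s.days
        if final_day_only:
            days = days[-1:]
        for day in days:
            key = (s.label, int(day))
            if key not in fun_keys:
                continue
            i = int(np.flatnonzero(s.days == day)[0])
            if s.counts[i].sum() == 0:
                continue
            v = np.zeros(len(union_asvs))
            for j, a in enumerate(s.asv_ids):
                v[pos[a]] = s.rel_abundance[i, j]
            rows_c.append(v)
            rows_f.append(functions.values[fun_keys[key]])
            ids.append(f"{key[0]}|{key[1]}")
    if len(ids) < 4:
        raise ValueError("fewer than 4 samples shared between modalities")
    comp_d = dv.dissimilarity_matrix(np.vstack(rows_c), sample_ids=ids)
    fun_d = dv.dissimilarity_matrix(np.vstack(rows_f), sample_ids=ids)
    return comp_d, fun_d


def write_report(summary: dict, path) -> None:
    """Write the summary as versioned JSON with stable key order."""
    missing = [k for k in REQUIRED_KEYS if k not in summary]
    if missing:
        raise ValueError(f"summary missing keys: {missing}")
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        summary = json.load(fh)
    if summary.get("schema") != SCHEMA_VERSION:
        raise ValueError(f"unexpected schema {summary.get('schema')!r}")
    return summary
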