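"""Seed-replicated simulation studies over the full pipeline.

Each function regenerates its inputs from an explicit seed, runs the
relevant pipeline stage end to end, and returns summary statistics: kinetic
parameter recovery, test calibration (ANOVA type-I rate, genotype-screen
false-flag rate and power), the panel-scale pipeline round trip, and the
canopy cost of slow NPQ relaxation.  These back the replication script and
the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import canopy as cp
from .environment import compute_vpd
from .fluorescence import average_replicates, compute_npq, qc_filter
from .kinetics import KineticsTruth, relaxation_curve
from .multivariate import CanonicalCorrelation
from .relaxation import RelaxationModel, fit_relaxation, fit_traces
from .screening import GenotypeScreen
from .stats import anova_gxe
from .synthetic import ExperimentDesign, PARAM_NAMES, generate_experiment, generate_trace, panel_design, parameter_table

__all__ = [
    "recovery_study",
    "anova_calibration_study",
    "screen_calibration_study",
    "panel_pipeline_study",
    "canopy_loss_study",
    "cca_oracle_check",
]

CANON_TRUTH = KineticsTruth(a_qe=2.0, a_qm=1.6, a_qi=0.5, tau_qe=1.0, tau_qm=23.0, induction_tau=1.5)

TWO_YEAR_DAYS = ("2021-07-01", "2021-07-08", "2021-07-15", "2022-07-01", "2022-07-08", "2022-07-15")


def recovery_study(n_seeds: int = 200, noise_cv: float = 0.02, seed: int = 0) -> dict:
    """Relaxation-parameter recovery from synthesized traces.

    Returns the worst relative error of the five parameters on a noiseless
    trace, and the median absolute relative error of tau_qE over
    ``n_seeds`` noisy traces (light-off anchor on — the better estimator).
    """
    truth = CANON_TRUTH
    s0 = compute_npq(generate_trace(truth, noise_cv=0.0, seed=0))
    f0 = fit_relaxation(s0)
    noiseless_err = max(
        abs(f0.a_qe - truth.a_qe) / truth.a_qe,
        abs(f0.a_qm - truth.a_qm) / truth.a_qm,
        abs(f0.a_qi - truth.a_qi) / truth.a_qi,
        abs(f0.tau_qe - truth.tau_qe) / truth.tau_qe,
        abs(f0.tau_qm - truth.tau_qm) / truth.tau_qm,
    )
    ss = np.random.SeedSequence([seed, 101])
    errs = []
    for child in ss.spawn(n_seeds):
        rng = np.random.default_rng(child)
        s = compute_npq(generate_trace(truth, noise_cv=noise_cv, seed=rng))
        fit = fit_relaxation(s, include_light_off=True)
        errs.append(abs(fit.tau_qe - truth.tau_qe) / truth.tau_qe)
    return {
        "noiseless_max_rel_err": float(noiseless_err),
        "tau_qe_median_abs_rel_err": float(np.median(errs)),
        "n_seeds": n_seeds,
    }


def anova_calibration_study(n_seeds: int = 500, seed: int = 0, alpha: float = 0.05) -> dict:
    """Type-I error of the genotype term under zero genotype effects."""
    days = tuple(f"2021-07-{d:02d}" for d in (1, 6, 11, 16))
    rej = 0
    base = seed * 100003
    for k in range(n_seeds):
        des = ExperimentDesign(
            genotypes=("RC", "G1", "G2", "G3", "G4", "G5"),
            plots_per_genotype=5,
            disks_per_plot=1,
            sampling_days=days,
            plot_sd=0.0,
            disk_sd=0.05,
            day_sd=0.05,
            seed=(base + k) % (2**31),
        )
        tab = parameter_table(des)
        rej += anova_gxe(tab, "a_qi")["p"]["genotype"] < alpha
    return {"type_i_rate": rej / n_seeds, "n_seeds": n_seeds}


def screen_calibration_study(n_seeds: int = 100, seed: int = 0, effect: float = -0.10) -> dict:
    """False-flag rate (null) and power (injected a_qI effect) of the
    nested-AIC mixed-model screen on the two-year field design."""
    base = seed * 100003
    detected = 0
    for k in range(n_seeds):
        des = ExperimentDesign(
            genotypes=("RC", "G1", "G2", "G3", "G4"),
            sampling_days=TWO_YEAR_DAYS,
            genotype_effects={"G2": {"a_qi": effect}},
            plot_sd=0.03,
            disk_sd=0.05,
            seed=(base + k) % (2**31),
        )
        screen = GenotypeScreen(parameter="a_qi").fit(parameter_table(des))
        flagged = screen.flagged_
        detected += "G2" in flagged.index and flagged.loc["G2", "sign"] == np.sign(effect)
    false_frac = []
    for k in range(n_seeds):
        des = ExperimentDesign(
            genotypes=("RC", "G1", "G2", "G3", "G4"),
            sampling_days=TWO_YEAR_DAYS,
            plot_sd=0.03,
            disk_sd=0.05,
            seed=(base + 50000 + k) % (2**31),
        )
        screen = GenotypeScreen(parameter="a_qi").fit(parameter_table(des))
        false_frac.append(len(screen.flagged_) / 4.0)
    return {
        "power": detected / n_seeds,
        "false_flag_rate": float(np.mean(false_frac)),
        "n_seeds": n_seeds,
    }


PANEL_PARAMS = ("a_qe", "tau_qe", "a_qm", "tau_qm", "a_qi", "max_npq")


def panel_pipeline_study(seed: int = 0, n_genotypes: int = 41) -> dict:
    """Full pipeline round trip on a realistic 41-genotype panel.

    Traces are synthesized from genotype-level truths spanning published
    field ranges (five plots x five disks x two sampling days per genotype,
    2% fluorescence noise), then pushed through NPQ computation, relaxation
    fitting, quality filtering, replicate averaging and genotype means.
    Returns the recovered genotype-mean summaries and their deviation from
    the generating truth.
    """
    des = panel_design(n_genotypes=n_genotypes, seed=seed)
    traces, truth = generate_experiment(des)
    fits = fit_traces(traces)
    kept, log = qc_filter(fits)
    plots = average_replicates(kept)
    gmeans = plots.groupby("genotype")[list(PANEL_PARAMS)].mean()
    tmeans = truth.groupby("genotype")[list(PANEL_PARAMS)].mean()
    rel_dev = ((gmeans - tmeans) / tmeans).abs()
    return {
        "n_disks": len(fits),
        "n_excluded": len(log),
        "tau_qm_range": (float(gmeans["tau_qm"].min()), float(gmeans["tau_qm"].max())),
        "tau_qm_median": float(gmeans["tau_qm"].median()),
        "tau_qe_median": float(gmeans["tau_qe"].median()),
        "tau_qe_spread_pct": float(
            100.0 * (gmeans["tau_qe"].max() - gmeans["tau_qe"].min()) / gmeans["tau_qe"].max()
        ),
        "a_qi_median": float(gmeans["a_qi"].median()),
        "max_npq_max": float(gmeans["max_npq"].max()),
        "median_abs_rel_dev": {p: float(rel_dev[p].median()) for p in PANEL_PARAMS},
        "genotype_means": gmeans,
        "truth_means": tmeans,
    }


def canopy_loss_study(seed: int = 0, n_pixels: int = 200, dt_s: float = 10.0) -> pd.DataFrame:
    """% daily canopy assimilation losses from slow NPQ relaxation.

    Compares the slowest, mean and reference kinetic parameter sets against
    the fastest observed set on a synthetic intermittently-cloudy day and a
    clear day, over a stochastic sun/shade canopy light field.
    """
    scenarios = {
        "fastest": cp.NPQKinetics(tau_qe=0.93, tau_qm=19.95),
        "slowest": cp.NPQKinetics(tau_qe=1.29, tau_qm=29.23),
        "mean": cp.NPQKinetics(tau_qe=1.05, tau_qm=23.51),
        "RC": cp.NPQKinetics(tau_qe=1.05, tau_qm=23.51),
    }
    t_s, par_cloudy = cp.synthetic_day_par(cloudy=True, seed=seed * 7 + 5)
    _, par_sunny = cp.synthetic_day_par(cloudy=False)
    days = {}
    ground = {}
    for label, par in (("cloudy", par_cloudy), ("sunny", par_sunny)):
        pixels, s_ground = cp.canopy_light_field(t_s, par, n_pixels=n_pixels, seed=seed * 11 + 2)
        days[label] = pixels
        ground[label] = s_ground
    return cp.loss_report(scenarios, days, ground["cloudy"], reference="fastest", dt_s=dt_s)


def cca_oracle_check(seed: int = 0, n: int = 80, p: int = 6, q: int = 6) -> float:
    """Max |difference| between the CCA implementation and the brute-force
    eigen-decomposition of Sxx^-1 Sxy Syy^-1 Syx on a random fixture."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    Y = X @ rng.standard_normal((p, q)) + 0.7 * rng.standard_normal((n, q))
    cca = CanonicalCorrelation().fit(X, Y)
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    M = np.linalg.solve(Xs.T @ Xs, Xs.T @ Ys) @ np.linalg.solve(Ys.T @ Ys, Ys.T @ Xs)
    ev = np.sort(np.linalg.eigvals(M).real)[::-1][: len(cca.correlations_)]
    oracle = np.sqrt(np.clip(ev, 0.0, 1.0))
    return float(np.max(np.abs(cca.correlations_ - oracle)))
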