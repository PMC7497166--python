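"""Calibration and recovery experiments on the synthetic generator.

Each function runs many independent replicates of a simulation scenario and
summarises how an estimator behaves under known truth: bias of the IVW
estimate and coverage of its 95% interval under valid instruments, type-I
error of the MR-Egger intercept under the no-pleiotropy null, how often the
weighted median beats IVW when 40% of instruments carry directional
pleiotropy, and how often colocalisation assigns ≥0.80 posterior mass to the
generating hypothesis. Replicate seeds are split deterministically from one
master seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import mr_estimators as mr
from .colocalisation import ColocResult, coloc_posteriors
from .synthetic_data import Pleiotropy, SimConfig, simulate_coloc_region, simulate_harmonised

#: strong-instrument study conditions for estimator calibration: 20 valid
#: SNPs explaining 10% of exposure variance in a large exposure GWAS, scored
#: against a large case-control outcome sample
CALIBRATION_CONFIG = SimConfig(
    m_snps=20,
    maf=0.3,
    ld_rho=0.0,
    n_exposure=200_000,
    n_outcome=100_000,
    exposure_h2=0.1,
)

#: regional conditions for coloc calibration: 200 SNPs on a 5 kb grid under
#: AR(1) LD rho=0.9, protein GWAS n=30k vs case-control n=100k
COLOC_REGION_CONFIG = SimConfig(
    m_snps=200,
    maf=0.3,
    ld_rho=0.9,
    n_exposure=30_000,
    n_outcome=100_000,
)

#: separation giving causal-pair r^2 ~ 0.034 (< 0.05) under the rho=0.9/5kb grid
DISTINCT_SEPARATION_BP = 80_000


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) % (2**31)


def ivw_calibration(
    n_reps: int,
    causal_effect: float,
    seed: int,
    config: SimConfig = CALIBRATION_CONFIG,
) -> dict:
    """Bias and 95%-CI coverage of IVW random effects under valid instruments."""
    seeds = _replicate_seeds(seed, n_reps)
    estimates = np.empty(n_reps)
    covered = np.empty(n_reps, dtype=bool)
    z_fixed = np.empty(n_reps)
    for i, s in enumerate(seeds):
        hset, _ = simulate_harmonised(replace(config, seed=int(s), causal_effect=causal_effect))
        est = mr.ivw(hset, effects="multiplicative_random")
        estimates[i] = est.beta
        covered[i] = est.ci_low <= causal_effect <= est.ci_high
        fe = mr.ivw(hset, effects="fixed")
        z_fixed[i] = (fe.beta - causal_effect) / fe.se
    return {
        "mean_estimate": float(estimates.mean()),
        "sd_estimate": float(estimates.std(ddof=1)),
        "mc_se_of_mean": float(estimates.std(ddof=1) / np.sqrt(n_reps)),
        "coverage_pct": float(100.0 * covered.mean()),
        "z_fixed": z_fixed,
        "n_reps": n_reps,
    }


def egger_type1_rate(n_reps: int, seed: int, config: SimConfig = CALIBRATION_CONFIG) -> float:
    """Rejection rate (%) of the Egger intercept test at alpha=0.05 under the
    no-pleiotropy null (true causal effect 0.3)."""
    seeds = _replicate_seeds(seed, n_reps)
    rejected = 0
    for s in seeds:
        hset, _ = simulate_harmonised(replace(config, seed=int(s), causal_effect=0.3))
        if mr.mr_egger(hset).intercept_pvalue < 0.05 :
            rejected += 1
    return 100.0 * rejected / n_reps


def weighted_median_robustness(n_reps: int, seed: int, config: SimConfig = CALIBRATION_CONFIG) -> dict:
    """How often the weighted median lands closer to truth than IVW when 40%
    of SNPs carry large directional pleiotropy."""
    truth = 0.3
    cfg = replace(
        config,
        causal_effect=truth,
        invalid_fraction=0.4,
        pleiotropy=Pleiotropy.directional(mean=0.08, sd=0.02),
    )
    seeds = _replicate_seeds(seed, n_reps)
    wm_closer = 0
    wm_err = np.empty(n_reps)
    ivw_err = np.empty(n_reps)
    for i, s in enumerate(seeds):
        hset, _ = simulate_harmonised(replace(cfg, seed=int(s)))
        bx, sx = hset.beta_exposure, hset.se_exposure
        by, sy = hset.beta_outcome, hset.se_outcome
        ratios, weights = mr._ratio_weights(bx, sx, by, sy)
        wm_est = mr._weighted_median_point(ratios, weights)
        ivw_est = mr.ivw(hset).beta
        wm_err[i] = abs(wm_est - truth)
        ivw_err[i] = abs(ivw_est - truth)
        if wm_err[i] < ivw_err[i]:
            wm_closer += 1
    return {
        "wins_pct": 100.0 * wm_closer / n_reps,
        "median_wm_abs_error": float(np.median(wm_err)),
        "median_ivw_abs_error": float(np.median(ivw_err)),
        "n_reps": n_reps,
    }


def _coloc_once(seed: int, scenario: str, config: SimConfig) -> ColocResult:
    if scenario == "shared":
        r1, r2, _ = simulate_coloc_region(replace(config, seed=seed), shared=True)
    elif scenario == "distinct":
        r1, r2, _ = simulate_coloc_region(
            replace(config, seed=seed), shared=False, separation_bp=DISTINCT_SEPARATION_BP
        )
    elif scenario == "null":
        r1, r2, _ = simulate_coloc_region(replace(config, seed=seed), shared=True, z1=0.0, z2=0.0)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return coloc_posteriors(r1, r2)


def coloc_calibration(
    n_reps: int,
    seed: int,
    scenario: str,
    config: SimConfig = COLOC_REGION_CONFIG,
) -> dict:
    """Rate (%) at which the generating hypothesis receives posterior ≥ 0.80.

    Scenario → expected hypothesis: ``shared`` → H4, ``distinct`` → H3,
    ``null`` → H0.
    """
    target = {"shared": "pp4", "distinct": "pp3", "null": "pp0"}[scenario]
    seeds = _replicate_seeds(seed, n_reps)
    hits = 0
    mean_pp = 0.0
    for s in seeds:
        res = _coloc_once(int(s), scenario, config)
        val = getattr(res, target)
        mean_pp += val
        if val > 0.80:
            hits += 1
    return {
        "rate_pct": 100.0 * hits / n_reps,
        "mean_pp": mean_pp / n_reps,
        "target": target,
        "n_reps": n_reps,
    }


def null_z_sample(n_reps: int, seed: int, config: SimConfig = CALIBRATION_CONFIG) -> np.ndarray:
    """Fixed-effect IVW z-statistics under the global null (no causal effect,
    no pleiotropy) — standard normal when the generator is calibrated."""
    seeds = _replicate_seeds(seed, n_reps)
    z = np.empty(n_reps)
    for i, s in enumerate(seeds):
        hset, _ = simulate_harmonised(replace(config, seed=int(s), causal_effect=0.0))
        est = mr.ivw(hset, effects="fixed")
        z[i] = est.beta / est.se
    return z
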