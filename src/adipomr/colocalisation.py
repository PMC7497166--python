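"""Bayesian colocalisation of two regional association profiles.

Under the assumption of at most one causal variant per trait in the region,
five hypotheses partition the causal configurations: H0 (neither trait
associated), H1/H2 (only trait 1 / only trait 2), H3 (both associated,
different causal variants), H4 (both associated, one shared causal variant).

Per-SNP evidence is the Wakefield approximate Bayes factor. With z = β/se,
V = se² and a normal effect prior of SD ``prior_sd`` (W = prior_sd²,
r = W/(V+W)):

    log ABF = ½·log(1−r) + z²·r/2

Hypothesis weights are prior-weighted sums of ABFs accumulated entirely in
log space (log-sum-exp), so arbitrarily strong signals cannot overflow.
Posterior probabilities are the normalised weights; by convention a posterior
of ≥0.80 supports a configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .errors import DomainError, MissingSNPError
from .harmonisation import RegionData
from .sumstats_io import LDMatrix

#: default effect-prior SDs per trait type: 0.15 on a quantitative (SD-unit)
#: trait, 0.20 on a case-control (log-odds) trait
DEFAULT_PRIOR_SD = {"quantitative": 0.15, "case_control": 0.20}


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP priors: causal for trait 1 (p1), trait 2 (p2), or both (p12)."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if not (0.0 < self.p12 <= min(self.p1, self.p2)):
            raise DomainError("priors must satisfy 0 < p12 <= min(p1, p2)")
        if not (self.p1 + self.p2 + self.p12 < 1.0):
            raise DomainError("p1 + p2 + p12 must stay below 1")


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities of H0–H4 with the priors and region used."""

    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_snps: int
    priors: ColocPriors
    window: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        pp = self.pp
        if np.any(pp < 0) or np.any(pp > 1):
            raise DomainError("posterior probabilities must lie in [0, 1]")
        if abs(float(pp.sum()) - 1.0) > 1e-10:
            raise DomainError("posterior probabilities must sum to 1 within 1e-10")

    @property
    def pp(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


def wakefield_log_abf(beta, se, prior_sd: float):
    """Log approximate Bayes factor for association at one SNP (vectorised).

    Positive values favour association; at z = 0 the value is
    ½·log(1−r) < 0, and as V ≫ W the data become uninformative and the log
    ABF tends to 0.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise DomainError("se must be positive")
    if not (prior_sd > 0):
        raise DomainError("prior_sd must be positive")
    v = se**2
    w = prior_sd**2
    r = w / (v + w)
    z = beta / se
    out = 0.5 * np.log1p(-r) + 0.5 * z**2 * r
    return out if out.ndim else float(out)


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) − exp(b)) for a ≥ b, −inf when the difference underflows."""
    d = b - a
    if d >= 0.0:
        return -np.inf
    with np.errstate(divide="ignore"):
        return a + float(np.log1p(-np.exp(d)))


def posteriors_from_log_abf(
    lbf1: np.ndarray, lbf2: np.ndarray, priors: ColocPriors | None = None
) -> np.ndarray:
    """Posterior probabilities [pp0..pp4] from per-SNP log ABFs of two traits.

    Hypothesis weights are per-SNP-prior-weighted sums of ABFs:
    H1 ∝ p1·Σᵢ ABF1ᵢ, H2 ∝ p2·Σᵢ ABF2ᵢ, H4 ∝ p12·Σᵢ ABF1ᵢ·ABF2ᵢ,
    H3 ∝ p1·p2·Σ_{i≠j} ABF1ᵢ·ABF2ⱼ, H0 ∝ 1 — all in log space.
    """
    priors = priors or ColocPriors()
    lbf1 = np.asarray(lbf1, dtype=float)
    lbf2 = np.asarray(lbf2, dtype=float)
    if lbf1.shape != lbf2.shape or lbf1.ndim != 1 or lbf1.size == 0:
        raise DomainError("log ABF vectors must be 1-D, non-empty and equal length")
    lse1 = float(logsumexp(lbf1))
    lse2 = float(logsumexp(lbf2))
    lse12 = float(logsumexp(lbf1 + lbf2))
    l0 = 0.0
    l1 = np.log(priors.p1) + lse1
    l2 = np.log(priors.p2) + lse2
    l3 = np.log(priors.p1) + np.log(priors.p2) + _log_diff_exp(lse1 + lse2, lse12)
    l4 = np.log(priors.p12) + lse12
    ls = np.array([l0, l1, l2, l3, l4])
    pp = np.exp(ls - logsumexp(ls))
    return pp / pp.sum()


def coloc_posteriors(
    region1: RegionData,
    region2: RegionData,
    priors: ColocPriors | None = None,
    prior_sd1: float | None = None,
    prior_sd2: float | None = None,
) -> ColocResult:
    """Posterior probabilities of H0–H4 for two regional profiles.

    Regions are intersected on SNP id (positional matching is not attempted);
    effect priors default by trait type (:data:`DEFAULT_PRIOR_SD`).
    """
    priors = priors or ColocPriors()
    ids2 = {r.snp_id: r for r in region2.records}
    shared = [(r, ids2[r.snp_id]) for r in region1.records if r.snp_id in ids2]
    if not shared:
        raise MissingSNPError("regions share no SNP ids")
    sd1 = prior_sd1 if prior_sd1 is not None else DEFAULT_PRIOR_SD[region1.trait_type]
    sd2 = prior_sd2 if prior_sd2 is not None else DEFAULT_PRIOR_SD[region2.trait_type]
    lbf1 = wakefield_log_abf(
        np.array([a.beta for a, _ in shared]), np.array([a.se for a, _ in shared]), sd1
    )
    lbf2 = wakefield_log_abf(
        np.array([b.beta for _, b in shared]), np.array([b.se for _, b in shared]), sd2
    )
    pp = posteriors_from_log_abf(lbf1, lbf2, priors)
    return ColocResult(
        pp0=float(pp[0]),
        pp1=float(pp[1]),
        pp2=float(pp[2]),
        pp3=float(pp[3]),
        pp4=float(pp[4]),
        n_snps=len(shared),
        priors=priors,
        window=region1.window,
    )


def _minus_log10_p(record) -> float:
    p = record.pvalue
    if p is not None and np.isfinite(p) and p > 0:
        # recompute from z below the representable range; the stored p saturates
        if p > 1e-300:
            return float(-np.log10(p))
    z = record.beta / record.se
    return float(-(np.log(2.0) + stats.norm.logsf(abs(z))) / np.log(10.0))


def regional_plot_data(region: RegionData) -> pd.DataFrame:
    """Regional Manhattan plot data: one (snp_id, pos, minus_log10_p) row per
    SNP, sorted by position. −log10 p is recomputed from the normal z when the
    stored p-value has saturated."""
    rows = sorted(region.records, key=lambda r: (r.pos, r.snp_id))
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in rows],
            "pos": [r.pos for r in rows],
            "minus_log10_p": [_minus_log10_p(r) for r in rows],
        }
    )


def secondary_peaks(
    region: RegionData,
    ld: LDMatrix,
    log10_margin: float = 2.0,
    r2_max: float = 0.1,
) -> list[str]:
    """SNPs that challenge the single-causal-variant assumption.

    Returns ids whose −log10 p is within ``log10_margin`` of the lead SNP's
    but whose r² with the lead is below ``r2_max`` — i.e. apparently
    independent secondary signals a user should inspect (mirroring visual
    inspection of regional Manhattan plots).
    """
    mlp = np.array([_minus_log10_p(r) for r in region.records])
    lead_i = int(np.argmax(mlp))
    lead_id = region.records[lead_i].snp_id
    ids = [r.snp_id for r in region.records]
    sub = ld.subset([s for s in ids if s in set(ld.snp_ids)])
    index = {s: i for i, s in enumerate(sub.snp_ids)}
    if lead_id not in index:
        return []
    out = []
    for i, rec in enumerate(region.records):
        if rec.snp_id == lead_id or rec.snp_id not in index:
            continue
        if mlp[i] >= mlp[lead_i] - log10_margin and sub.r2[index[lead_id], index[rec.snp_id]] < r2_max:
            out.append(rec.snp_id)
    return out
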