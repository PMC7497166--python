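"""Config-driven orchestration of the full MR + colocalisation study design.

For every (risk factor, endpoint) pair the runner selects the instrument,
harmonises alleles, routes to the primary estimator implied by the instrument
shape — single SNP → Wald ratio, correlated multi-SNP set →
correlation-adjusted IVW, independent multi-SNP set → IVW multiplicative
random effects — and, whenever the instrument has ≥3 independent SNPs, runs
the MR-Egger and weighted-median sensitivity estimators plus leave-one-out.

Multiple testing is controlled per endpoint with a Bonferroni threshold of
alpha divided by the number of risk factors; colocalisation (±100 kb around
the exposure's top SNP) follows up any pair showing nominal evidence of
association (p < 0.05 by default).

A structured JSON-lines run log records per-stage seeds, SNP drop reasons and
the residual dispersion φ of every random-effects fit, so the underdispersion
floor can be audited after the fact. A stage failure is recorded for its pair
and does not abort the remaining pairs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import colocalisation as coloc
from . import harmonisation as harm
from . import mr_estimators as mr
from .errors import AdipoMRError, DomainError, EmptyInputError
from .sumstats_io import AssociationRecord, LDMatrix, read_ld_matrix, read_sumstats

_FLOAT_FMT = "%.10g"
_DIAG_FMT = "%.17g"  # diagnostics must round-trip estimates exactly


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m across m risk factors (per endpoint)."""
    if m < 1:
        raise DomainError("number of risk factors must be at least 1")
    if not (0.0 < alpha < 1.0):
        raise DomainError("alpha must lie in (0, 1)")
    return alpha / m


def route_estimator(n_snp: int, correlated: bool) -> str:
    """Total routing table from instrument shape to primary estimator."""
    if n_snp < 1:
        raise DomainError("cannot route an empty instrument")
    if n_snp == 1:
        return "wald"
    return "ivw_corr" if correlated else "ivw_re"


def _pair_seed(seed: int, *labels: str) -> int:
    """Deterministic per-pair sub-seed (stable across runs and pair order)."""
    return zlib.crc32(("|".join((str(seed),) + labels)).encode()) % (2**31)


@dataclass(frozen=True)
class FactorConfig:
    trait_id: str
    sumstats: Path
    instrument: harm.InstrumentSpec
    ld: Path | None = None
    trait_type: str = "quantitative"
    unit_note: str = ""


@dataclass(frozen=True)
class EndpointConfig:
    trait_id: str
    sumstats: Path
    trait_type: str = "case_control"


@dataclass(frozen=True)
class StudyConfig:
    """The full study layout: risk factors × endpoints plus control parameters."""

    risk_factors: tuple[FactorConfig, ...]
    endpoints: tuple[EndpointConfig, ...]
    alpha: float = 0.05
    coloc_trigger_p: float = 0.05
    coloc_window_bp: int = 100_000
    seed: int = 0
    n_boot: int = 1000

    def __post_init__(self) -> None:
        if not self.risk_factors or not self.endpoints:
            raise DomainError("a study needs at least one risk factor and one endpoint")
        if not (0.0 < self.alpha < 1.0):
            raise DomainError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent
        factors = []
        for f in raw["risk_factors"]:
            inst = dict(f["instrument"])
            tss = inst.pop("gene_tss", None)
            spec = harm.InstrumentSpec(
                mode=inst.get("mode", "polygenic"),
                p_threshold=float(inst.get("p_threshold", 5e-8)),
                r2_threshold=float(inst.get("r2_threshold", 0.01)),
                cis_window_bp=int(inst.get("cis_window_bp", 1_000_000)),
                gene_tss=(str(tss["chrom"]), int(tss["pos"])) if tss else None,
            )
            factors.append(
                FactorConfig(
                    trait_id=f["trait_id"],
                    sumstats=base / f["sumstats"],
                    ld=(base / f["ld"]) if f.get("ld") else None,
                    instrument=spec,
                    trait_type=f.get("trait_type", "quantitative"),
                    unit_note=f.get("unit_note", ""),
                )
            )
        endpoints = [
            EndpointConfig(
                trait_id=e["trait_id"],
                sumstats=base / e["sumstats"],
                trait_type=e.get("trait_type", "case_control"),
            )
            for e in raw["endpoints"]
        ]
        return cls(
            risk_factors=tuple(factors),
            endpoints=tuple(endpoints),
            alpha=float(raw.get("alpha", 0.05)),
            coloc_trigger_p=float(raw.get("coloc_trigger_p", 0.05)),
            coloc_window_bp=int(raw.get("coloc_window_bp", 100_000)),
            seed=int(raw.get("seed", 0)),
            n_boot=int(raw.get("n_boot", 1000)),
        )


@dataclass
class StudyReport:
    """All study outputs: primary/sensitivity/strength tables, coloc, run log."""

    primary: pd.DataFrame
    sensitivity: pd.DataFrame
    strength: pd.DataFrame
    leave_one_out: pd.DataFrame
    coloc: pd.DataFrame
    log_records: list[dict] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for name, df in (
            ("primary", self.primary),
            ("sensitivity", self.sensitivity),
            ("strength", self.strength),
            ("leave_one_out", self.leave_one_out),
            ("coloc", self.coloc),
        ):
            p = out / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
            paths[name] = p
        log_path = out / "run_log.jsonl"
        with log_path.open("w") as fh:
            for rec in self.log_records:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
        paths["run_log"] = log_path
        return paths

    @property
    def all_ok(self) -> bool:
        return bool((self.primary["status"] == "ok").all())


def _estimate_row(est: mr.MREstimate, extra: Mapping | None = None) -> dict:
    orr, lo, hi = mr.to_odds_ratio(est)
    row = {
        "risk_factor": est.exposure,
        "endpoint": est.outcome,
        "method": est.method,
        "n_snp": est.n_snp,
        "beta": est.beta,
        "se": est.se,
        "OR": orr,
        "CI_low": lo,
        "CI_high": hi,
        "pvalue": est.pvalue,
        "dispersion": est.dispersion,
        "cochran_q": est.cochran_q if est.cochran_q is not None else np.nan,
    }
    if extra:
        row.update(extra)
    return row


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full study and return a :class:`StudyReport`."""
    log: list[dict] = []
    primary_rows: list[dict] = []
    sens_rows: list[dict] = []
    strength_rows: list[dict] = []
    loo_rows: list[dict] = []
    coloc_rows: list[dict] = []
    m_factors = len(config.risk_factors)
    bonf = bonferroni_threshold(config.alpha, m_factors)

    endpoint_data: dict[str, list[AssociationRecord]] = {}
    for ep in config.endpoints:
        endpoint_data[ep.trait_id] = read_sumstats(
            ep.sumstats, trait_id=ep.trait_id, trait_type=ep.trait_type
        )

    for factor in config.risk_factors:
        exposure_all = read_sumstats(
            factor.sumstats,
            trait_id=factor.trait_id,
            trait_type=factor.trait_type,
            unit_note=factor.unit_note,
        )
        ld_full: LDMatrix | None = read_ld_matrix(factor.ld) if factor.ld else None
        instrument = harm.select_instrument(exposure_all, factor.instrument, ld_full)
        log.append(
            {
                "stage": "select_instrument",
                "risk_factor": factor.trait_id,
                "n_candidates": len(exposure_all),
                "n_selected": len(instrument),
                "mode": factor.instrument.mode,
                "r2_threshold": factor.instrument.r2_threshold,
            }
        )
        if instrument:
            try:
                r2 = mr.r2_from_sumstats(instrument)
                n_min = float(min(r.n for r in instrument))
                st = mr.instrument_strength(r2, n_min, len(instrument))
                strength_rows.append(
                    {
                        "risk_factor": factor.trait_id,
                        "n_snp": len(instrument),
                        "r2": st.r2,
                        "f_stat": st.f_stat,
                        "n": st.n,
                    }
                )
            except AdipoMRError as exc:
                log.append({"stage": "strength", "risk_factor": factor.trait_id, "error": str(exc)})

        for ep in config.endpoints:
            pair = {"risk_factor": factor.trait_id, "endpoint": ep.trait_id}
            if not instrument:
                primary_rows.append(
                    {**pair, "method": "none", "n_snp": 0, "beta": np.nan, "se": np.nan,
                     "OR": np.nan, "CI_low": np.nan, "CI_high": np.nan, "pvalue": np.nan,
                     "dispersion": np.nan, "cochran_q": np.nan,
                     "bonferroni_threshold": bonf, "significance": "not_estimated",
                     "status": "no_instrument"}
                )
                continue
            try:
                ld_inst = ld_full.subset([r.snp_id for r in instrument]) if ld_full else None
                hset = harm.harmonise_pair(instrument, endpoint_data[ep.trait_id], ld=ld_inst)
                dropped = {s: f for s, f in hset.provenance.items() if f.startswith("dropped")}
                correlated = hset.max_offdiag_r2 >= 0.01
                method = route_estimator(len(hset), correlated)
                if method == "wald":
                    est = mr.wald_ratio(hset)
                elif method == "ivw_corr":
                    est = mr.ivw_correlated(hset)
                else:
                    est = mr.ivw(hset, effects="multiplicative_random")
                est = est.with_labels(factor.trait_id, ep.trait_id)
                sig = "pass" if est.pvalue < bonf else ("nominal" if est.pvalue < 0.05 else "null")
                primary_rows.append(
                    _estimate_row(est, {"bonferroni_threshold": bonf, "significance": sig, "status": "ok"})
                )
                log.append(
                    {
                        "stage": "primary",
                        **pair,
                        "method": est.method,
                        "n_snp": len(hset),
                        "dropped": dropped,
                        "dispersion": est.dispersion,
                        "pvalue": est.pvalue,
                    }
                )
                if len(hset) >= 3 and not correlated:
                    seed = _pair_seed(config.seed, factor.trait_id, ep.trait_id)
                    egger = mr.mr_egger(hset)
                    sens_rows.append(
                        _estimate_row(
                            egger.slope.with_labels(factor.trait_id, ep.trait_id),
                            {
                                "egger_intercept": egger.intercept,
                                "egger_intercept_se": egger.intercept_se,
                                "egger_intercept_pvalue": egger.intercept_pvalue,
                            },
                        )
                    )
                    wm = mr.weighted_median(hset, n_boot=config.n_boot, seed=seed)
                    sens_rows.append(_estimate_row(wm.with_labels(factor.trait_id, ep.trait_id)))
                    for left_out, sub_est in mr.leave_one_out(hset):
                        loo_rows.append(
                            _estimate_row(
                                sub_est.with_labels(factor.trait_id, ep.trait_id),
                                {"left_out_snp": left_out},
                            )
                        )
                    log.append({"stage": "sensitivity", **pair, "weighted_median_seed": seed,
                                "egger_dispersion": egger.slope.dispersion})
                if est.pvalue < config.coloc_trigger_p:
                    top = min(
                        (r for r in instrument if r.snp_id in hset.snp_ids),
                        key=lambda r: (r.pvalue, r.snp_id),
                    )
                    region1 = harm.extract_region(exposure_all, top.snp_id, config.coloc_window_bp)
                    region2 = harm.extract_region(
                        endpoint_data[ep.trait_id], top.snp_id, config.coloc_window_bp
                    )
                    res = coloc.coloc_posteriors(region1, region2)
                    peaks: list[str] = []
                    if ld_full is not None:
                        try:
                            reg_ld = ld_full.subset(list(region1.snp_ids))
                            peaks = coloc.secondary_peaks(region1, reg_ld)
                        except AdipoMRError:
                            peaks = []
                    coloc_rows.append(
                        {
                            **pair,
                            "index_snp": top.snp_id,
                            "n_snps": res.n_snps,
                            "pp0": res.pp0,
                            "pp1": res.pp1,
                            "pp2": res.pp2,
                            "pp3": res.pp3,
                            "pp4": res.pp4,
                            "secondary_peaks": ";".join(peaks),
                        }
                    )
                    log.append({"stage": "coloc", **pair, "index_snp": top.snp_id,
                                "pp4": res.pp4, "secondary_peaks": peaks})
            except AdipoMRError as exc:
                primary_rows.append(
                    {**pair, "method": "none", "n_snp": 0, "beta": np.nan, "se": np.nan,
                     "OR": np.nan, "CI_low": np.nan, "CI_high": np.nan, "pvalue": np.nan,
                     "dispersion": np.nan, "cochran_q": np.nan,
                     "bonferroni_threshold": bonf, "significance": "not_estimated",
                     "status": f"failed: {exc}"}
                )
                log.append({"stage": "primary", **pair, "error": str(exc)})

    def _frame(rows: list[dict], columns: list[str]) -> pd.DataFrame:
        df = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)
        sort_cols = [c for c in ("risk_factor", "endpoint", "method", "left_out_snp") if c in columns]
        return df.sort_values(sort_cols, kind="stable").reset_index(drop=True)

    est_cols = ["risk_factor", "endpoint", "method", "n_snp", "beta", "se", "OR",
                "CI_low", "CI_high", "pvalue", "dispersion", "cochran_q"]
    report = StudyReport(
        primary=_frame(primary_rows, est_cols + ["bonferroni_threshold", "significance", "status"]),
        sensitivity=_frame(
            sens_rows, est_cols + ["egger_intercept", "egger_intercept_se", "egger_intercept_pvalue"]
        ),
        strength=_frame(strength_rows, ["risk_factor", "n_snp", "r2", "f_stat", "n"]),
        leave_one_out=_frame(loo_rows, est_cols + ["left_out_snp"]),
        coloc=_frame(
            coloc_rows,
            ["risk_factor", "endpoint", "index_snp", "n_snps", "pp0", "pp1", "pp2", "pp3", "pp4",
             "secondary_peaks"],
        ),
        log_records=log,
    )
    return report


def diagnostics_bundle(
    hset: harm.HarmonisedSet,
    estimates: Mapping[str, object],
    out_dir: str | Path,
) -> dict[str, Path] | None:
    """Write scatter/forest/funnel data tables for a multi-SNP instrument.

    ``estimates`` maps method labels to results; recognised keys are ``ivw``
    (:class:`~adipomr.mr_estimators.MREstimate`), ``egger``
    (:class:`~adipomr.mr_estimators.EggerResult`) and ``weighted_median``.
    Single-SNP instruments are skipped with a log notice (returns None).
    Fitted slopes are embedded in the scatter table so plots can be rebuilt
    from the files alone.
    """
    import logging

    if len(hset) < 2:
        logging.getLogger(__name__).info("diagnostics skipped: single-SNP instrument")
        return None
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ivw_est = estimates.get("ivw")
    egger = estimates.get("egger")
    wm = estimates.get("weighted_median")
    scatter = pd.DataFrame(
        {
            "snp_id": hset.snp_ids,
            "beta_exposure": hset.beta_exposure,
            "se_exposure": hset.se_exposure,
            "beta_outcome": hset.beta_outcome,
            "se_outcome": hset.se_outcome,
        }
    )
    if ivw_est is not None:
        scatter["slope_ivw"] = ivw_est.beta
    if egger is not None:
        scatter["slope_egger"] = egger.slope.beta
        scatter["intercept_egger"] = egger.intercept
    if wm is not None:
        scatter["slope_weighted_median"] = wm.beta
    paths["scatter"] = out / "scatter.tsv"
    scatter.to_csv(paths["scatter"], sep="\t", index=False, float_format=_DIAG_FMT)

    z = mr.Z975
    wald_rows = []
    for i in range(len(hset)):
        est = mr.wald_ratio(hset.subset([i]))
        wald_rows.append(
            {"snp_id": hset.snp_ids[i], "beta": est.beta, "se": est.se,
             "ci_low": est.beta - z * est.se, "ci_high": est.beta + z * est.se}
        )
    combined = ivw_est if ivw_est is not None else mr.ivw(hset)
    forest = pd.DataFrame(
        wald_rows
        + [{"snp_id": "combined", "beta": combined.beta, "se": combined.se,
            "ci_low": combined.ci_low, "ci_high": combined.ci_high}]
    )
    paths["forest"] = out / "forest.tsv"
    forest.to_csv(paths["forest"], sep="\t", index=False, float_format=_DIAG_FMT)

    funnel = pd.DataFrame(
        {
            "snp_id": [r["snp_id"] for r in wald_rows],
            "beta": [r["beta"] for r in wald_rows],
            "precision": [1.0 / r["se"] for r in wald_rows],
        }
    )
    paths["funnel"] = out / "funnel.tsv"
    funnel.to_csv(paths["funnel"], sep="\t", index=False, float_format=_DIAG_FMT)
    return paths
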