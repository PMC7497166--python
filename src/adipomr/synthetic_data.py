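"""Synthetic two-sample GWAS summary statistics with known ground truth.

Summary statistics are simulated directly from their asymptotic sampling
distributions rather than from individual-level genotypes: per-allele marginal
estimates are drawn as multivariate normal around the LD-projected true
effects, with SE 1/sqrt(2·maf·(1−maf)·n) for a unit-variance quantitative
trait and 1/sqrt(2·maf·(1−maf)·n·cf·(1−cf)) on the log-odds scale for a
case-control trait with case fraction cf. This is orders of magnitude faster
and sufficient for estimator testing.

Effect alleles are oriented trait-increasing (non-negative joint exposure
effects), the usual convention when instrumenting a measured protein, so that
"directional" pleiotropy really is directional with respect to the instrument.

LD is an AR(1) correlation field (default ρ = 0.9 per 5 kb grid step) or any
explicit :class:`~adipomr.sumstats_io.LDMatrix`. All randomness flows from a
single seed through counter-based (Philox) streams split per operation, so a
given configuration reproduces byte-identical outputs.

:func:`make_fixture_tables` writes a self-contained toy study — seven risk
factors × three breast-cancer endpoints, mirroring a protein-instrument MR
study design — including one genuinely causal exposure/endpoint pair (shared
causal variants) and one genomically confounded pair (distinct causal variants
in LD), with the generating truth recorded in YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigError
from .harmonisation import HarmonisedSet, RegionData
from .mr_estimators import two_sided_p
from .sumstats_io import AssociationRecord, LDMatrix, write_ld_matrix, write_sumstats


@dataclass(frozen=True)
class Pleiotropy:
    """Direct SNP-outcome effects bypassing the exposure (per-allele log-odds)."""

    kind: str = "none"  # none | balanced | directional
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional"):
            raise ConfigError(f"unknown pleiotropy kind {self.kind!r}")
        if self.kind == "balanced" and self.mean != 0.0:
            raise ConfigError("balanced pleiotropy must have zero mean")

    @classmethod
    def none(cls) -> "Pleiotropy":
        return cls("none")

    @classmethod
    def balanced(cls, sd: float) -> "Pleiotropy":
        return cls("balanced", 0.0, sd)

    @classmethod
    def directional(cls, mean: float, sd: float) -> "Pleiotropy":
        return cls("directional", mean, sd)


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for a two-sample summary-statistics simulation.

    ``exposure_h2`` is the variance in the (unit-variance) exposure explained
    jointly by the instrument SNPs; ``causal_effect`` is the true effect of a
    one-SD exposure increase on the outcome (log-odds for a case-control
    outcome); ``invalid_fraction`` of SNPs receive the configured pleiotropic
    direct effects.
    """

    seed: int = 0
    m_snps: int = 20
    maf: float | tuple[float, ...] = 0.3
    ld_rho: float = 0.0
    ld: LDMatrix | None = None
    n_exposure: int = 30_000
    n_outcome: int = 100_000
    case_fraction: float = 0.5
    outcome_trait_type: str = "case_control"
    causal_effect: float = 0.0
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy.none)
    invalid_fraction: float = 0.0
    exposure_h2: float = 0.1
    spacing_bp: int = 5_000
    chrom: str = "1"
    start_pos: int = 1_000_000

    def __post_init__(self) -> None:
        if self.m_snps < 1:
            raise ConfigError("m_snps must be at least 1")
        maf = np.atleast_1d(np.asarray(self.maf, dtype=float))
        if maf.size not in (1, self.m_snps):
            raise ConfigError("maf must be scalar or one value per SNP")
        if np.any(maf <= 0) or np.any(maf > 0.5):
            raise ConfigError("maf values must lie in (0, 0.5]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigError("ld_rho must lie in [0, 1)")
        if self.ld is not None and len(self.ld) != self.m_snps:
            raise ConfigError("explicit LD matrix size must equal m_snps")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ConfigError("sample sizes must be positive")
        if not (0.0 < self.case_fraction < 1.0):
            raise ConfigError("case_fraction must lie in (0, 1)")
        if self.outcome_trait_type not in ("quantitative", "case_control"):
            raise ConfigError("outcome_trait_type must be quantitative or case_control")
        if not (0.0 <= self.invalid_fraction <= 1.0):
            raise ConfigError("invalid_fraction must lie in [0, 1]")
        if not (0.0 < self.exposure_h2 < 1.0):
            raise ConfigError("exposure_h2 must lie in (0, 1)")
        if self.spacing_bp <= 0:
            raise ConfigError("spacing_bp must be positive")

    @property
    def maf_array(self) -> np.ndarray:
        return np.broadcast_to(np.atleast_1d(np.asarray(self.maf, dtype=float)), (self.m_snps,)).copy()


@dataclass(frozen=True)
class SyntheticTruth:
    """The generating parameters, recorded exactly as drawn.

    Together with the configuration these suffice to recompute every expected
    estimate analytically (true marginal effects and SEs are stored).
    """

    causal_effect: float
    pleiotropy: np.ndarray  # per-SNP per-allele direct outcome effects
    beta_exposure_joint: np.ndarray
    beta_exposure_marginal: np.ndarray
    beta_outcome_marginal: np.ndarray
    se_exposure: np.ndarray
    se_outcome: np.ndarray
    maf: np.ndarray
    invalid_index: tuple[int, ...] = ()
    shared_variant: bool | None = None
    causal_positions: tuple[int, ...] = ()
    signal_z: tuple[float, float] | None = None


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    """Split ``n`` independent counter-based streams off one seed."""
    return [np.random.Generator(np.random.Philox(child)) for child in np.random.SeedSequence(seed).spawn(n)]


def ar1_correlation(m: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix: r_ij = rho^|i-j| (positive definite for rho in [0,1))."""
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :]) if rho > 0 else np.eye(m)


def _cholesky(sigma: np.ndarray) -> np.ndarray:
    for jitter in (0.0, 1e-12, 1e-10, 1e-8):
        try:
            return np.linalg.cholesky(sigma + jitter * np.eye(sigma.shape[0]) if jitter else sigma)
        except np.linalg.LinAlgError:
            continue
    raise ConfigError("LD matrix is not positive semidefinite")


def _effective_n(n: int, trait_type: str, case_fraction: float) -> float:
    return n * case_fraction * (1.0 - case_fraction) if trait_type == "case_control" else float(n)


def simulate_summary_arrays(config: SimConfig) -> dict:
    """Core array-level simulation (fast path; no record objects built).

    Returns a dict with observed ``bx_hat/se_x/by_hat/se_y``, the LD matrix
    used, SNP metadata and a :class:`SyntheticTruth`.
    """
    m = config.m_snps
    maf = config.maf_array
    d = np.sqrt(2.0 * maf * (1.0 - maf))
    sigma = config.ld.r if config.ld is not None else ar1_correlation(m, config.ld_rho)
    identity_ld = config.ld is None and config.ld_rho == 0.0
    chol = None if identity_ld else _cholesky(sigma)
    s_eff, s_inv, s_x, s_y = _streams(config.seed, 4)

    # trait-increasing effect-allele orientation: non-negative joint effects
    b_raw = np.abs(s_eff.standard_normal(m))
    scale = b_raw @ sigma @ b_raw
    b_std = b_raw * np.sqrt(config.exposure_h2 / scale)
    beta_joint = b_std / d
    marg_std = sigma @ b_std
    beta_marginal = marg_std / d

    se_x = 1.0 / (d * np.sqrt(config.n_exposure))
    noise_x = s_x.standard_normal(m)
    bx_hat = beta_marginal + se_x * (noise_x if identity_ld else chol @ noise_x)

    alpha = np.zeros(m)
    invalid_idx: tuple[int, ...] = ()
    if config.pleiotropy.kind != "none" and config.invalid_fraction > 0:
        n_inv = int(round(config.invalid_fraction * m))
        idx = np.sort(s_inv.choice(m, size=n_inv, replace=False))
        invalid_idx = tuple(int(i) for i in idx)
        alpha[idx] = s_inv.normal(config.pleiotropy.mean, config.pleiotropy.sd, size=n_inv)

    g_std = (config.causal_effect * beta_joint + alpha) * d
    gamma_marginal = (sigma @ g_std) / d
    neff = _effective_n(config.n_outcome, config.outcome_trait_type, config.case_fraction)
    se_y = 1.0 / (d * np.sqrt(neff))
    noise_y = s_y.standard_normal(m)
    by_hat = gamma_marginal + se_y * (noise_y if identity_ld else chol @ noise_y)

    positions = config.start_pos + config.spacing_bp * np.arange(m)
    snp_ids = tuple(f"rs{i + 1:05d}" for i in range(m))
    truth = SyntheticTruth(
        causal_effect=config.causal_effect,
        pleiotropy=alpha,
        beta_exposure_joint=beta_joint,
        beta_exposure_marginal=beta_marginal,
        beta_outcome_marginal=gamma_marginal,
        se_exposure=se_x,
        se_outcome=se_y,
        maf=maf,
        invalid_index=invalid_idx,
    )
    return {
        "snp_ids": snp_ids,
        "positions": positions,
        "maf": maf,
        "sigma": sigma,
        "bx_hat": bx_hat,
        "se_x": se_x,
        "by_hat": by_hat,
        "se_y": se_y,
        "truth": truth,
    }


def simulate_harmonised(config: SimConfig) -> tuple[HarmonisedSet, SyntheticTruth]:
    """Simulate and return directly as a :class:`HarmonisedSet` (fast path for
    estimator calibration loops)."""
    arr = simulate_summary_arrays(config)
    ld = None
    if config.ld is not None or config.ld_rho > 0:
        ld = LDMatrix(arr["snp_ids"], arr["sigma"])
    hset = HarmonisedSet(
        snp_ids=arr["snp_ids"],
        beta_exposure=arr["bx_hat"],
        se_exposure=arr["se_x"],
        beta_outcome=arr["by_hat"],
        se_outcome=arr["se_y"],
        eaf=arr["maf"],
        ld=ld,
    )
    return hset, arr["truth"]


def _records(
    arr_ids: Sequence[str],
    chrom: str,
    positions: np.ndarray,
    maf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: float,
    trait_id: str,
    trait_type: str,
    unit_note: str = "",
) -> list[AssociationRecord]:
    return [
        AssociationRecord(
            snp_id=str(sid),
            chrom=chrom,
            pos=int(p),
            effect_allele="A",
            other_allele="G",
            beta=float(b),
            se=float(s),
            pvalue=two_sided_p(b / s),
            n=float(n),
            eaf=float(f),
            trait_id=trait_id,
            trait_type=trait_type,
            unit_note=unit_note,
        )
        for sid, p, f, b, s in zip(arr_ids, positions, maf, beta, se)
    ]


def simulate_two_sample_gwas(
    config: SimConfig,
) -> tuple[list[AssociationRecord], list[AssociationRecord], SyntheticTruth]:
    """Simulate exposure and outcome summary statistics in two independent samples."""
    arr = simulate_summary_arrays(config)
    exposure = _records(
        arr["snp_ids"], config.chrom, arr["positions"], arr["maf"],
        arr["bx_hat"], arr["se_x"], config.n_exposure, "exposure", "quantitative", "SD",
    )
    outcome = _records(
        arr["snp_ids"], config.chrom, arr["positions"], arr["maf"],
        arr["by_hat"], arr["se_y"], config.n_outcome, "outcome", config.outcome_trait_type,
        "natural-log odds" if config.outcome_trait_type == "case_control" else "SD",
    )
    return exposure, outcome, arr["truth"]


def simulate_coloc_region(
    config: SimConfig,
    shared: bool,
    separation_bp: int = 80_000,
    z1: float = 8.0,
    z2: float = 8.0,
) -> tuple[RegionData, RegionData, SyntheticTruth]:
    """Simulate two regional association profiles over a common SNP grid.

    Each trait has one causal variant; the same SNP iff ``shared``. Signal
    sizes are the causal variants' expected z-scores (``z1``/``z2``; zero for
    a null region). Z-profiles are propagated through the AR(1) LD field and
    observed with LD-correlated noise.
    """
    m = config.m_snps
    if m < 10:
        raise ConfigError("coloc regions need at least 10 SNPs")
    steps, rem = divmod(separation_bp, config.spacing_bp)
    if rem:
        raise ConfigError("separation_bp must be a multiple of spacing_bp")
    c1 = m // 2
    c2 = c1 if shared else c1 + steps
    if not shared and not (0 <= c2 < m):
        raise ConfigError("separation exceeds the region span")
    maf = config.maf_array
    d = np.sqrt(2.0 * maf * (1.0 - maf))
    sigma = config.ld.r if config.ld is not None else ar1_correlation(m, config.ld_rho)
    chol = _cholesky(sigma)
    s1, s2 = _streams(config.seed, 2)
    mu1 = z1 * sigma[:, c1]
    mu2 = z2 * sigma[:, c2]
    zhat1 = mu1 + chol @ s1.standard_normal(m)
    zhat2 = mu2 + chol @ s2.standard_normal(m)
    se1 = 1.0 / (d * np.sqrt(config.n_exposure))
    neff = _effective_n(config.n_outcome, config.outcome_trait_type, config.case_fraction)
    se2 = 1.0 / (d * np.sqrt(neff))
    positions = config.start_pos + config.spacing_bp * np.arange(m)
    ids = tuple(f"rs{i + 1:05d}" for i in range(m))
    recs1 = _records(ids, config.chrom, positions, maf, zhat1 * se1, se1,
                     config.n_exposure, "trait1", "quantitative")
    recs2 = _records(ids, config.chrom, positions, maf, zhat2 * se2, se2,
                     config.n_outcome, "trait2", config.outcome_trait_type)
    window = (config.chrom, int(positions[0]), int(positions[-1]))
    region1 = RegionData("trait1", tuple(recs1), window, index_snp=ids[int(np.argmax(np.abs(zhat1)))])
    region2 = RegionData("trait2", tuple(recs2), window, index_snp=ids[int(np.argmax(np.abs(zhat2)))])
    truth = SyntheticTruth(
        causal_effect=0.0,
        pleiotropy=np.zeros(m),
        beta_exposure_joint=np.zeros(m),
        beta_exposure_marginal=mu1 * se1,
        beta_outcome_marginal=mu2 * se2,
        se_exposure=se1,
        se_outcome=se2,
        maf=maf,
        shared_variant=bool(shared) if (z1 != 0 or z2 != 0) else None,
        causal_positions=(int(positions[c1]), int(positions[c2])),
        signal_z=(z1, z2),
    )
    return region1, region2, truth


# --------------------------------------------------------------------------
# self-contained toy study: 7 risk factors x 3 breast-cancer endpoints
# --------------------------------------------------------------------------

#: name, exposure-GWAS sample size, number of loci, total instrument R²,
#: instrument mode, causal variants per locus, unit note
STUDY_FACTORS = (
    ("adiponectin", 30708, 8, 0.016, "polygenic", 1, "natural-log"),
    ("crp", 204402, 10, 0.035, "polygenic", 1, "natural-log"),
    ("hgf", 3301, 1, 0.020, "monogenic_cis", 1, "SD"),
    ("il6", 133449, 1, 0.002, "monogenic_cis_corr", 3, "natural-log"),
    ("leptin_receptor", 3301, 1, 0.54, "monogenic_cis", 1, "SD"),
    ("pai1", 30395, 3, 0.0064, "polygenic", 1, "natural-log"),
    ("resistin", 3301, 1, 0.030, "monogenic_cis", 1, "SD"),
)

#: endpoint name, cases, controls
STUDY_ENDPOINTS = (
    ("overall", 122_977, 105_974),
    ("er_positive", 69_501, 105_974),
    ("er_negative", 21_468, 105_974),
)

#: truly causal exposure->endpoint effects (log-odds per exposure unit),
#: acting through the instrument SNPs (shared causal variants)
STUDY_CAUSAL = {("pai1", "overall"): 0.6}

#: genomic confounding: the endpoint has its own causal variant in LD with the
#: exposure's index SNP (distinct variants -> an MR hit that must not colocalise)
STUDY_CONFOUNDED = {("hgf", "er_negative"): {"offset_steps": 6, "z_out": 10.0}}

_M_PER_LOCUS = 41  # SNPs per locus; at 5 kb spacing the locus spans the ±100 kb window
_LOCUS_RHO = 0.9  # AR(1) LD per grid step within a locus; zero across loci


def _flip_record(rec: AssociationRecord) -> AssociationRecord:
    """Report the same association on the opposite effect allele."""
    return AssociationRecord(
        snp_id=rec.snp_id,
        chrom=rec.chrom,
        pos=rec.pos,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        se=rec.se,
        pvalue=rec.pvalue,
        n=rec.n,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
        trait_id=rec.trait_id,
        trait_type=rec.trait_type,
        unit_note=rec.unit_note,
    )


def make_fixture_tables(out_dir: str | Path, seed: int = 0) -> dict:
    """Write a self-contained toy study to ``out_dir``.

    Produces one exposure TSV and one signed-r LD TSV per risk factor, one
    outcome TSV per endpoint, the generating truth (``truth.yaml``) and a
    ready-to-run study configuration (``study.yaml``). Re-running with the
    same seed reproduces every file byte for byte.
    """
    out = Path(out_dir)
    (out / "exposures").mkdir(parents=True, exist_ok=True)
    (out / "outcomes").mkdir(parents=True, exist_ok=True)
    (out / "ld").mkdir(parents=True, exist_ok=True)

    spacing = 5_000
    m = _M_PER_LOCUS
    sigma = ar1_correlation(m, _LOCUS_RHO)
    chol = np.linalg.cholesky(sigma)
    center = m // 2

    n_factors = len(STUDY_FACTORS)
    # streams: per-factor maf/exposure noise, per (factor, endpoint) outcome
    # noise, one flip stream
    streams = _streams(seed, 2 * n_factors + 3 * n_factors + 1)
    flip_stream = streams[-1]

    endpoint_records: dict[str, list[AssociationRecord]] = {ep: [] for ep, _, _ in STUDY_ENDPOINTS}
    truth: dict = {
        "seed": seed,
        "spacing_bp": spacing,
        "locus_rho": _LOCUS_RHO,
        "snps_per_locus": m,
        "factors": {},
        "causal_effects": {f"{e}->{o}": v for (e, o), v in STUDY_CAUSAL.items()},
        "confounded": [],
    }
    manifest: dict = {"exposures": {}, "outcomes": {}, "ld": {}}
    study_factors_cfg = []
    locus_counter = 0

    for fi, (name, n_gwas, n_loci, r2_total, mode, causals_per_locus, unit_note) in enumerate(STUDY_FACTORS):
        maf_stream = streams[2 * fi]
        x_stream = streams[2 * fi + 1]
        b_std = float(np.sqrt(r2_total / (n_loci * causals_per_locus)))
        factor_truth: dict = {
            "n_gwas": n_gwas, "r2_total": r2_total, "mode": mode, "loci": [],
            "per_causal_beta_std": b_std,
        }
        exposure_records: list[AssociationRecord] = []
        locus_meta = []  # (ids, chrom, positions, maf, causal_local_idx)
        for li in range(n_loci):
            g = locus_counter
            locus_counter += 1
            chrom = str(g % 22 + 1)
            base = 10_000_000 + (g // 22) * 30_000_000
            positions = base + spacing * np.arange(m)
            ids = tuple(f"rs{g + 1:03d}{i:03d}" for i in range(m))
            maf = maf_stream.uniform(0.1, 0.5, size=m)
            d = np.sqrt(2.0 * maf * (1.0 - maf))
            if causals_per_locus == 1:
                causal_idx = [center]
            else:
                causal_idx = [center - 10 * (causals_per_locus // 2) + 10 * j for j in range(causals_per_locus)]
            z_joint = np.zeros(m)
            z_joint[causal_idx] = b_std * np.sqrt(n_gwas)
            mu = sigma @ z_joint
            z_obs = mu + chol @ x_stream.standard_normal(m)
            se = 1.0 / (d * np.sqrt(n_gwas))
            exposure_records.extend(
                _records(ids, chrom, positions, maf, z_obs * se, se, n_gwas, name, "quantitative", unit_note)
            )
            locus_meta.append((ids, chrom, positions, maf, causal_idx, z_joint))
            factor_truth["loci"].append(
                {
                    "chrom": chrom,
                    "start": int(positions[0]),
                    "end": int(positions[-1]),
                    "causal_snps": [ids[i] for i in causal_idx],
                    "causal_z": float(b_std * np.sqrt(n_gwas)),
                }
            )

        exp_path = out / "exposures" / f"{name}.tsv"
        write_sumstats(exposure_records, exp_path)
        manifest["exposures"][name] = exp_path

        # block-diagonal signed-r LD over this factor's SNPs
        total = m * n_loci
        big = np.zeros((total, total))
        all_ids: list[str] = []
        for li, (ids, *_rest) in enumerate(locus_meta):
            big[li * m : (li + 1) * m, li * m : (li + 1) * m] = sigma
            all_ids.extend(ids)
        np.fill_diagonal(big, 1.0)
        ld_path = out / "ld" / f"{name}.tsv"
        write_ld_matrix(LDMatrix(tuple(all_ids), big), ld_path)
        manifest["ld"][name] = ld_path

        # outcome associations for this factor's SNPs, per endpoint
        for ei, (ep, cases, controls) in enumerate(STUDY_ENDPOINTS):
            y_stream = streams[2 * n_factors + 3 * fi + ei]
            n_total = cases + controls
            cf = cases / n_total
            neff = n_total * cf * (1.0 - cf)
            theta = STUDY_CAUSAL.get((name, ep), 0.0)
            conf = STUDY_CONFOUNDED.get((name, ep))
            for li, (ids, chrom, positions, maf, causal_idx, z_joint_x) in enumerate(locus_meta):
                d = np.sqrt(2.0 * maf * (1.0 - maf))
                z_joint_y = np.zeros(m)
                if theta:
                    # causal: outcome signal flows through the exposure's variants
                    z_joint_y[causal_idx] = theta * b_std * np.sqrt(neff)
                if conf is not None and li == 0:
                    ci = center + int(conf["offset_steps"])
                    z_joint_y[ci] = conf["z_out"]
                    truth["confounded"].append(
                        {
                            "exposure": name,
                            "endpoint": ep,
                            "outcome_causal_snp": ids[ci],
                            "exposure_index_snp": ids[center],
                            "r_between": float(_LOCUS_RHO ** conf["offset_steps"]),
                        }
                    )
                mu = sigma @ z_joint_y
                z_obs = mu + chol @ y_stream.standard_normal(m)
                se = 1.0 / (d * np.sqrt(neff))
                recs = _records(
                    ids, chrom, positions, maf, z_obs * se, se, n_total, ep, "case_control", "natural-log odds"
                )
                # report a random subset on the opposite effect allele so
                # harmonisation has real work to do
                flips = flip_stream.random(m) < 0.3
                endpoint_records[ep].extend(
                    _flip_record(r) if fl else r for r, fl in zip(recs, flips)
                )

        truth["factors"][name] = factor_truth
        tss_chrom, tss_pos = locus_meta[0][1], int(locus_meta[0][2][center])
        instrument_cfg = {
            "mode": "monogenic_cis" if mode.startswith("monogenic") else "polygenic",
            "p_threshold": 5e-8,
            "r2_threshold": 0.15 if mode == "monogenic_cis_corr" else 0.01,
            "cis_window_bp": 1_000_000,
        }
        if instrument_cfg["mode"] == "monogenic_cis":
            instrument_cfg["gene_tss"] = {"chrom": tss_chrom, "pos": tss_pos}
        study_factors_cfg.append(
            {
                "trait_id": name,
                "sumstats": f"exposures/{name}.tsv",
                "ld": f"ld/{name}.tsv",
                "trait_type": "quantitative",
                "unit_note": unit_note,
                "instrument": instrument_cfg,
            }
        )

    for ep, cases, controls in STUDY_ENDPOINTS:
        path = out / "outcomes" / f"{ep}.tsv"
        write_sumstats(endpoint_records[ep], path)
        manifest["outcomes"][ep] = path

    truth_path = out / "truth.yaml"
    truth_path.write_text(yaml.safe_dump(truth, sort_keys=True))
    study_cfg = {
        "seed": seed,
        "alpha": 0.05,
        "coloc_trigger_p": 0.05,
        "coloc_window_bp": 100_000,
        "risk_factors": study_factors_cfg,
        "endpoints": [
            {"trait_id": ep, "sumstats": f"outcomes/{ep}.tsv", "trait_type": "case_control"}
            for ep, _, _ in STUDY_ENDPOINTS
        ],
    }
    study_path = out / "study.yaml"
    study_path.write_text(yaml.safe_dump(study_cfg, sort_keys=True))
    manifest["truth"] = truth_path
    manifest["study"] = study_path
    return manifest
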