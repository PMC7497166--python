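"""Instrument construction, LD clumping, allele harmonisation and region extraction.

Instruments are built either in ``monogenic_cis`` mode (genome-wide-significant
variants within a fixed window of a gene's transcription start site, as for
single-protein cis instruments) or ``polygenic`` mode (cis and trans variants
combined). Candidates below the significance threshold are removed, then
greedily clumped on LD so no retained pair exceeds the r² ceiling.

Harmonisation places SNP-exposure and SNP-outcome effects on a common effect
allele. Alleles reported on opposite strands are complemented; palindromic
(A/T, C/G) variants, whose strand cannot be inferred from the alleles, are
resolved by allele frequency when both frequencies fall outside a configurable
band around 0.5 and dropped otherwise. Instruments missing from the outcome
sample are dropped and flagged — no proxy-SNP search is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, HarmonisationError, MissingSNPError
from .sumstats_io import AssociationRecord, LDMatrix

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: provenance flags assigned per exposure SNP during harmonisation
FLAG_KEPT = "kept"
FLAG_FLIPPED = "flipped"
FLAG_DROPPED_PALINDROMIC = "dropped_palindromic"
FLAG_DROPPED_MISSING_OUTCOME = "dropped_missing_outcome"
FLAG_DROPPED_MISMATCH = "dropped_allele_mismatch"


@dataclass(frozen=True)
class InstrumentSpec:
    """How to build an instrument for one risk factor.

    ``p_threshold`` defaults to genome-wide significance (5e-8);
    ``r2_threshold`` to 0.01 for independent sets (use 0.15 for weakly
    correlated cis sets); ``cis_window_bp`` to 1 Mb around the transcription
    start site, which is required in (and only in) ``monogenic_cis`` mode.
    """

    mode: str
    p_threshold: float = 5e-8
    r2_threshold: float = 0.01
    cis_window_bp: int = 1_000_000
    gene_tss: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("monogenic_cis", "polygenic"):
            raise ConfigError(f"unknown instrument mode {self.mode!r}")
        if not (0.0 < self.p_threshold < 1.0):
            raise ConfigError("p_threshold must lie in (0, 1)")
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ConfigError("r2_threshold must lie in (0, 1]")
        if self.cis_window_bp <= 0:
            raise ConfigError("cis_window_bp must be > 0")
        if (self.gene_tss is None) == (self.mode == "monogenic_cis"):
            raise ConfigError("gene_tss is required iff mode == 'monogenic_cis'")
        if self.gene_tss is not None:
            object.__setattr__(self, "gene_tss", (str(self.gene_tss[0]), int(self.gene_tss[1])))


@dataclass
class HarmonisedSet:
    """Exposure/outcome effect pairs on a common effect-allele orientation.

    Arrays are aligned; ``ld``, when present, is restricted to exactly the kept
    SNP ids in order. ``provenance`` records the fate of every exposure SNP
    offered to harmonisation, including the dropped ones.
    """

    snp_ids: tuple[str, ...]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    eaf: np.ndarray  # exposure-side effect-allele frequency; NaN when missing
    ld: LDMatrix | None = None
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.snp_ids = tuple(str(s) for s in self.snp_ids)
        for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome", "eaf"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.snp_ids),):
                raise HarmonisationError(f"{name} length does not match snp_ids")
            setattr(self, name, arr)
        if len(self.snp_ids) < 1:
            raise HarmonisationError("a harmonised set needs at least one kept SNP")
        if np.any(self.se_exposure < 0) or np.any(self.se_outcome <= 0):
            raise HarmonisationError("outcome SEs must be positive and exposure SEs non-negative")
        if self.ld is not None and self.ld.snp_ids != self.snp_ids:
            raise HarmonisationError("LD matrix ids must equal the kept SNP ids, in order")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def subset(self, indices: Sequence[int]) -> "HarmonisedSet":
        idx = list(indices)
        ids = tuple(self.snp_ids[i] for i in idx)
        return HarmonisedSet(
            snp_ids=ids,
            beta_exposure=self.beta_exposure[idx],
            se_exposure=self.se_exposure[idx],
            beta_outcome=self.beta_outcome[idx],
            se_outcome=self.se_outcome[idx],
            eaf=self.eaf[idx],
            ld=self.ld.subset(list(ids)) if self.ld is not None else None,
            provenance={s: self.provenance.get(s, FLAG_KEPT) for s in ids},
        )

    @property
    def max_offdiag_r2(self) -> float:
        """Largest pairwise r² among kept SNPs (0 when no LD matrix / single SNP)."""
        if self.ld is None or len(self) < 2:
            return 0.0
        r2 = self.ld.r2.copy()
        np.fill_diagonal(r2, 0.0)
        return float(r2.max())


@dataclass(frozen=True)
class RegionData:
    """A regional slice of one trait's associations around an index SNP."""

    trait_id: str
    records: tuple[AssociationRecord, ...]
    window: tuple[str, int, int]  # chrom, start, end (closed interval)
    index_snp: str | None = None

    def __post_init__(self) -> None:
        recs = tuple(self.records)
        ids = [r.snp_id for r in recs]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate SNP ids in region")
        chrom, start, end = self.window
        for r in recs:
            if r.chrom != chrom or not (start <= r.pos <= end):
                raise ConfigError(f"SNP {r.snp_id} at {r.chrom}:{r.pos} outside window {self.window}")
        object.__setattr__(self, "records", recs)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(r.snp_id for r in self.records)

    @property
    def pos(self) -> np.ndarray:
        return np.array([r.pos for r in self.records], dtype=int)

    @property
    def beta(self) -> np.ndarray:
        return np.array([r.beta for r in self.records], dtype=float)

    @property
    def se(self) -> np.ndarray:
        return np.array([r.se for r in self.records], dtype=float)

    @property
    def pvalue(self) -> np.ndarray:
        return np.array([r.pvalue for r in self.records], dtype=float)

    @property
    def trait_type(self) -> str:
        return self.records[0].trait_type if self.records else "quantitative"


def _chrom_key(chrom: str) -> tuple[int, str]:
    # numeric chromosomes sort numerically, others lexically after them
    return (0, f"{int(chrom):03d}") if chrom.isdigit() else (1, chrom)


def _tie_key(r: AssociationRecord) -> tuple:
    return (r.pvalue, _chrom_key(r.chrom), r.pos, r.snp_id)


def clump(
    records: Sequence[AssociationRecord],
    ld: LDMatrix,
    r2_threshold: float,
) -> list[AssociationRecord]:
    """Greedy p-value clumping: keep a SNP iff its r² with every SNP already
    kept stays below ``r2_threshold``.

    Candidates are visited in ascending p-value; exact p ties are broken by
    (chrom, pos, snp_id) so the result is deterministic and invariant to input
    row order.
    """
    index = {s: i for i, s in enumerate(ld.snp_ids)}
    missing = [r.snp_id for r in records if r.snp_id not in index]
    if missing:
        raise MissingSNPError(f"SNPs absent from LD matrix: {missing}")
    r2 = ld.r2
    kept: list[AssociationRecord] = []
    kept_idx: list[int] = []
    for rec in sorted(records, key=_tie_key):
        i = index[rec.snp_id]
        if all(r2[i, j] < r2_threshold for j in kept_idx):
            kept.append(rec)
            kept_idx.append(i)
    return kept


def select_instrument(
    records: Sequence[AssociationRecord],
    spec: InstrumentSpec,
    ld: LDMatrix | None = None,
) -> list[AssociationRecord]:
    """Select instrument SNPs: significance filter, optional cis-window filter,
    then LD clumping.

    An empty result is legal and signals that the trait is not instrumentable
    at the configured thresholds. The cis window is the closed interval
    ``[tss - w, tss + w]`` on the TSS chromosome.
    """
    sig = [r for r in records if r.pvalue < spec.p_threshold]
    if spec.mode == "monogenic_cis":
        chrom, tss = spec.gene_tss  # type: ignore[misc]
        lo, hi = tss - spec.cis_window_bp, tss + spec.cis_window_bp
        sig = [r for r in sig if r.chrom == chrom and lo <= r.pos <= hi]
    if len(sig) <= 1:
        return sorted(sig, key=_tie_key)
    if ld is None:
        raise MissingSNPError("an LD matrix is required to clump multiple candidate SNPs")
    return clump(sig, ld, spec.r2_threshold)


def _orient_outcome(
    exp: AssociationRecord, out: AssociationRecord, band: tuple[float, float]
) -> tuple[str, float, float | None]:
    """Return (flag, harmonised outcome beta, harmonised outcome eaf)."""
    ea, oa = exp.effect_allele, exp.other_allele
    oea, ooa = out.effect_allele, out.other_allele
    if exp.is_palindromic:
        # the allele pair is its own strand complement: labels give orientation
        # up to strand, frequencies must finish the job
        if (oea, ooa) == (ea, oa):
            beta, eaf_out, flipped = out.beta, out.eaf, False
        elif (oea, ooa) == (oa, ea):
            beta = -out.beta
            eaf_out = None if out.eaf is None else 1.0 - out.eaf
            flipped = True
        else:
            return FLAG_DROPPED_MISMATCH, 0.0, None
        lo, hi = band
        if exp.eaf is None or eaf_out is None:
            return FLAG_DROPPED_PALINDROMIC, 0.0, None
        if not (exp.eaf <= lo or exp.eaf >= hi) or not (eaf_out <= lo or eaf_out >= hi):
            return FLAG_DROPPED_PALINDROMIC, 0.0, None
        if (exp.eaf - 0.5) * (eaf_out - 0.5) < 0:
            beta, eaf_out, flipped = -beta, 1.0 - eaf_out, True
        return (FLAG_FLIPPED if flipped else FLAG_KEPT), beta, eaf_out
    # non-palindromic: try as-reported, then the strand complement
    for cand_ea, cand_oa, strand_flipped in (
        (oea, ooa, False),
        (COMPLEMENT[oea], COMPLEMENT[ooa], True),
    ):
        if (cand_ea, cand_oa) == (ea, oa):
            return FLAG_KEPT, out.beta, out.eaf
        if (cand_ea, cand_oa) == (oa, ea):
            eaf_out = None if out.eaf is None else 1.0 - out.eaf
            return FLAG_FLIPPED, -out.beta, eaf_out
    return FLAG_DROPPED_MISMATCH, 0.0, None


def harmonise_pair(
    exposure: Sequence[AssociationRecord],
    outcome: Iterable[AssociationRecord],
    palindrome_eaf_band: tuple[float, float] = (0.42, 0.58),
    ld: LDMatrix | None = None,
) -> HarmonisedSet:
    """Harmonise exposure instrument SNPs against outcome records.

    ``palindrome_eaf_band`` is the open frequency interval around 0.5 inside
    which palindromic SNPs are considered unresolvable and dropped; a
    frequency exactly on the band edge counts as outside (resolvable).
    ``ld``, when supplied, is restricted to the kept SNPs.
    """
    out_by_id: dict[str, AssociationRecord] = {}
    for r in outcome:
        out_by_id.setdefault(r.snp_id, r)
    provenance: dict[str, str] = {}
    ids: list[str] = []
    bx, sx, by, sy, eaf = [], [], [], [], []
    for exp in exposure:
        o = out_by_id.get(exp.snp_id)
        if o is None:
            provenance[exp.snp_id] = FLAG_DROPPED_MISSING_OUTCOME
            continue
        flag, beta_out, _eaf_out = _orient_outcome(exp, o, palindrome_eaf_band)
        provenance[exp.snp_id] = flag
        if flag not in (FLAG_KEPT, FLAG_FLIPPED):
            continue
        ids.append(exp.snp_id)
        bx.append(exp.beta)
        sx.append(exp.se)
        by.append(beta_out)
        sy.append(o.se)
        eaf.append(np.nan if exp.eaf is None else exp.eaf)
    if not ids:
        raise HarmonisationError(f"no SNPs survived harmonisation (flags: {provenance})")
    sub_ld = ld.subset(ids) if ld is not None else None
    return HarmonisedSet(
        snp_ids=tuple(ids),
        beta_exposure=np.array(bx),
        se_exposure=np.array(sx),
        beta_outcome=np.array(by),
        se_outcome=np.array(sy),
        eaf=np.array(eaf),
        ld=sub_ld,
        provenance=provenance,
    )


def extract_region(
    all_records: Sequence[AssociationRecord],
    index_snp: str,
    window_bp: int,
    trait_id: str | None = None,
) -> RegionData:
    """Slice records to the closed interval ±``window_bp`` around ``index_snp``."""
    anchor = next((r for r in all_records if r.snp_id == index_snp), None)
    if anchor is None:
        raise MissingSNPError(f"index SNP {index_snp!r} not found")
    lo, hi = anchor.pos - window_bp, anchor.pos + window_bp
    recs = sorted(
        (r for r in all_records if r.chrom == anchor.chrom and lo <= r.pos <= hi),
        key=lambda r: (r.pos, r.snp_id),
    )
    return RegionData(
        trait_id=trait_id if trait_id is not None else anchor.trait_id,
        records=tuple(recs),
        window=(anchor.chrom, lo, hi),
        index_snp=index_snp,
    )
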