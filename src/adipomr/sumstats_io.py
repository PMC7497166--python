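"""Reading, validating and writing GWAS summary-statistic tables and LD matrices.

The exchange format is a headered, tab-delimited table with one row per SNP.
Default column names are ``SNP CHR POS EA OA EAF BETA SE P N``; any other
naming can be mapped through a :class:`SchemaConfig` (optionally loaded from
YAML). Alleles are normalised to upper case at read time; strand flips are
*not* applied here — allele orientation is owned by :mod:`adipomr.harmonisation`.

LD files store the signed correlation ``r`` (not r²), with SNP ids as the first
row and first column, so downstream correlation-adjusted estimators can use the
sign; r² is derived on demand.

Positions are 1-based and regional windows elsewhere in the package are closed
intervals, following GWAS convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, EmptyInputError, MissingSNPError, SchemaError

log = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
TRAIT_TYPES = ("quantitative", "case_control")

#: canonical field -> default column header
DEFAULT_COLUMNS: Mapping[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}

REQUIRED_FIELDS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
    "n",
)
OPTIONAL_FIELDS = ("eaf",)


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP's marginal association with one trait.

    ``beta`` is the per-effect-allele estimate in trait units (log-odds for
    ``case_control`` traits). ``eaf`` may be ``None``; a missing frequency
    disables palindromic-SNP resolution for that SNP during harmonisation.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    n: float
    eaf: float | None = None
    trait_id: str = ""
    trait_type: str = "quantitative"
    unit_note: str = ""

    def violations(self) -> list[str]:
        """Return human-readable invariant violations (empty list when valid)."""
        out: list[str] = []
        if self.effect_allele not in VALID_ALLELES:
            out.append(f"effect_allele {self.effect_allele!r} not in A/C/G/T")
        if self.other_allele not in VALID_ALLELES:
            out.append(f"other_allele {self.other_allele!r} not in A/C/G/T")
        if self.effect_allele == self.other_allele:
            out.append("effect_allele equals other_allele")
        if not (isinstance(self.pos, (int, np.integer)) and self.pos >= 1):
            out.append(f"pos {self.pos!r} must be an integer >= 1")
        if not (math.isfinite(self.beta)):
            out.append(f"beta {self.beta!r} is not finite")
        if not (math.isfinite(self.se) and self.se > 0):
            out.append(f"se {self.se!r} must be finite and > 0")
        if not (0.0 < self.pvalue <= 1.0):
            out.append(f"pvalue {self.pvalue!r} must lie in (0, 1]")
        if not (math.isfinite(self.n) and self.n > 0):
            out.append(f"n {self.n!r} must be > 0")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            out.append(f"eaf {self.eaf!r} must lie in [0, 1]")
        if self.trait_type not in TRAIT_TYPES:
            out.append(f"trait_type {self.trait_type!r} not in {TRAIT_TYPES}")
        return out

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class RowProblem:
    """Row-indexed diagnostic for a rejected summary-statistics row."""

    row: int  # 1-based data-row number (header excluded)
    snp_id: str
    message: str


@dataclass(frozen=True)
class SchemaConfig:
    """Column-name mapping plus missing-value and allele-case policy."""

    columns: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMNS))
    na_tokens: tuple[str, ...] = ("", "NA", "NaN", "nan", ".")
    allele_case: str = "upper"

    def __post_init__(self) -> None:
        missing = [f for f in REQUIRED_FIELDS if f not in self.columns]
        if missing:
            raise SchemaError(f"schema maps no column for required fields: {missing}")
        names = list(self.columns.values())
        dupes = {c for c in names if names.count(c) > 1}
        if dupes:
            raise SchemaError(f"schema maps several fields to the same column(s): {sorted(dupes)}")
        if self.allele_case not in ("upper", "preserve"):
            raise SchemaError(f"allele_case must be 'upper' or 'preserve', got {self.allele_case!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SchemaConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            columns={**DEFAULT_COLUMNS, **raw.get("columns", {})},
            na_tokens=tuple(raw.get("na_tokens", ("", "NA", "NaN", "nan", "."))),
            allele_case=raw.get("allele_case", "upper"),
        )


@dataclass(frozen=True)
class LDMatrix:
    """Square matrix of signed LD correlations, keyed by SNP id.

    The constructor enforces symmetry within 1e-8 (then symmetrises exactly),
    sets the diagonal to 1 and rejects entries outside [-1, 1].
    """

    snp_ids: tuple[str, ...]
    r: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.snp_ids)
        r = np.array(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise DomainError(f"LD matrix must be square, got shape {r.shape}")
        if r.shape[0] != len(ids):
            raise DomainError("LD matrix dimensions do not match the number of SNP ids")
        if len(set(ids)) != len(ids):
            raise DomainError("duplicate SNP ids in LD matrix")
        asym = np.max(np.abs(r - r.T)) if r.size else 0.0
        if asym > 1e-8:
            raise DomainError(f"LD matrix asymmetric beyond tolerance 1e-8 (max |r - r.T| = {asym:g})")
        r = (r + r.T) / 2.0
        np.fill_diagonal(r, 1.0)
        if np.any(np.abs(r) > 1.0 + 1e-12):
            raise DomainError("LD correlations must lie in [-1, 1]")
        r = np.clip(r, -1.0, 1.0)
        r.flags.writeable = False
        object.__setattr__(self, "snp_ids", ids)
        object.__setattr__(self, "r", r)

    def __len__(self) -> int:
        return len(self.snp_ids)

    @property
    def r2(self) -> np.ndarray:
        """Element-wise squared correlations."""
        return self.r**2

    def subset(self, ids: Sequence[str]) -> "LDMatrix":
        """Restrict (and reorder) to ``ids``; raises if any id is absent."""
        index = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise MissingSNPError(f"SNP ids absent from LD matrix: {missing}")
        take = [index[s] for s in ids]
        return LDMatrix(tuple(ids), self.r[np.ix_(take, take)])


def _parse_float(token: str, schema: SchemaConfig) -> float | None:
    if token in schema.na_tokens:
        return None
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"non-numeric value {token!r}")


def read_sumstats_checked(
    path: str | Path,
    schema: SchemaConfig | None = None,
    *,
    trait_id: str | None = None,
    trait_type: str = "quantitative",
    unit_note: str = "",
) -> tuple[list[AssociationRecord], list[RowProblem]]:
    """Read a summary-statistics TSV, returning (valid records, row diagnostics).

    Row order is preserved. Rows violating record invariants (or with
    unparseable numeric fields) are rejected individually and reported with
    their 1-based data-row number; structural problems (missing mapped columns,
    empty file) raise instead.
    """
    schema = schema or SchemaConfig()
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path} contains no data rows")
    missing_cols = [c for f, c in schema.columns.items() if f in REQUIRED_FIELDS and c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path} lacks mapped columns: {missing_cols}")
    has_eaf = schema.columns.get("eaf") in df.columns
    tid = trait_id if trait_id is not None else path.stem

    records: list[AssociationRecord] = []
    problems: list[RowProblem] = []
    col = schema.columns
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        snp = str(row_d[col["snp_id"]])
        try:
            pos_raw = row_d[col["pos"]]
            pos_f = float(pos_raw)
            if not pos_f.is_integer():
                raise ValueError(f"position {pos_raw!r} is not an integer")
            beta = _parse_float(row_d[col["beta"]], schema)
            se = _parse_float(row_d[col["se"]], schema)
            pvalue = _parse_float(row_d[col["pvalue"]], schema)
            n = _parse_float(row_d[col["n"]], schema)
            if None in (beta, se, pvalue, n):
                raise ValueError("missing value in required numeric field")
            eaf = _parse_float(row_d[col["eaf"]], schema) if has_eaf else None
        except ValueError as exc:
            problems.append(RowProblem(i, snp, str(exc)))
            continue
        ea = str(row_d[col["effect_allele"]])
        oa = str(row_d[col["other_allele"]])
        if schema.allele_case == "upper":
            ea, oa = ea.upper(), oa.upper()
        rec = AssociationRecord(
            snp_id=snp,
            chrom=str(row_d[col["chrom"]]),
            pos=int(pos_f),
            effect_allele=ea,
            other_allele=oa,
            beta=beta,
            se=se,
            pvalue=pvalue,
            n=n,
            eaf=eaf,
            trait_id=tid,
            trait_type=trait_type,
            unit_note=unit_note,
        )
        bad = rec.violations()
        if bad:
            problems.append(RowProblem(i, snp, "; ".join(bad)))
        else:
            records.append(rec)
    return records, problems


def read_sumstats(
    path: str | Path,
    schema: SchemaConfig | None = None,
    *,
    trait_id: str | None = None,
    trait_type: str = "quantitative",
    unit_note: str = "",
    strict: bool = False,
) -> list[AssociationRecord]:
    """Read a summary-statistics TSV into :class:`AssociationRecord` objects.

    Invalid rows are dropped with a logged, row-indexed warning; with
    ``strict=True`` any invalid row raises :class:`~adipomr.errors.SchemaError`.
    """
    records, problems = read_sumstats_checked(
        path, schema, trait_id=trait_id, trait_type=trait_type, unit_note=unit_note
    )
    for p in problems:
        msg = f"{path}: row {p.row} ({p.snp_id}) rejected: {p.message}"
        if strict:
            raise SchemaError(msg)
        log.warning(msg)
    return records


def write_sumstats(
    records: Iterable[AssociationRecord],
    path: str | Path,
    schema: SchemaConfig | None = None,
) -> Path:
    """Write records to a TSV in the schema's column layout (default layout by default).

    Floats are written with ``%.10g`` so a read→write→read round trip preserves
    values to that precision; missing eaf is written as ``NA``.
    """
    schema = schema or SchemaConfig()
    col = schema.columns
    path = Path(path)
    fields = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "eaf", "beta", "se", "pvalue", "n"]
    header = "\t".join(col[f] for f in fields)
    lines = [header]
    for r in records:
        lines.append(
            "\t".join(
                (
                    r.snp_id,
                    r.chrom,
                    str(int(r.pos)),
                    r.effect_allele,
                    r.other_allele,
                    "NA" if r.eaf is None else f"{r.eaf:.10g}",
                    f"{r.beta:.10g}",
                    f"{r.se:.10g}",
                    f"{r.pvalue:.10g}",
                    f"{r.n:.10g}",
                )
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_ld_matrix(path: str | Path, expected_ids: Sequence[str] | None = None) -> LDMatrix:
    """Read a signed-r LD TSV (ids in first row and column).

    When ``expected_ids`` is given the matrix is restricted and reordered to
    those ids; an id absent from the file raises
    :class:`~adipomr.errors.MissingSNPError`.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise SchemaError(f"{path}: LD row and column SNP ids differ")
    ld = LDMatrix(tuple(df.index), df.to_numpy(dtype=float))
    if expected_ids is not None:
        ld = ld.subset(list(expected_ids))
    return ld


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> Path:
    path = Path(path)
    lines = ["\t".join(("SNP",) + ld.snp_ids)]
    for sid, row in zip(ld.snp_ids, ld.r):
        lines.append(sid + "\t" + "\t".join(f"{v:.10g}" for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_results_table(estimates: Sequence, path: str | Path) -> Path:
    """Write MR estimates as a study results TSV (one row per factor×endpoint×method).

    Columns: risk_factor, endpoint, method, n_snp, beta, se, OR, CI_low,
    CI_high, pvalue. Odds ratios and their CI bounds are formatted to 2
    decimals, p-values to 2 significant figures; rows are sorted by
    (risk factor, endpoint, method) so output is deterministic.
    """
    ests = list(estimates)
    if not ests:
        raise EmptyInputError("no estimates to write")
    z = 1.959963984540054  # norm.ppf(0.975)
    rows = []
    for e in ests:
        rows.append(
            (
                e.exposure,
                e.outcome,
                e.method,
                int(e.n_snp),
                e.beta,
                e.se,
                math.exp(e.beta),
                math.exp(e.beta - z * e.se),
                math.exp(e.beta + z * e.se),
                e.pvalue,
            )
        )
    rows.sort(key=lambda t: (t[0], t[1], t[2]))
    path = Path(path)
    lines = ["\t".join(("risk_factor", "endpoint", "method", "n_snp", "beta", "se", "OR", "CI_low", "CI_high", "pvalue"))]
    for rf, ep, m, k, b, s, orr, lo, hi, p in rows:
        lines.append(f"{rf}\t{ep}\t{m}\t{k}\t{b:.6g}\t{s:.6g}\t{orr:.2f}\t{lo:.2f}\t{hi:.2f}\t{p:.2g}")
    path.write_text("\n".join(lines) + "\n")
    return path
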