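"""GWAS summary-statistics I/O and validation.

A trait's summary statistics are held as a :class:`GwasDataset`: a pandas
DataFrame with one row per SNP plus trait metadata. Canonical columns are

    snp_id, chrom, pos, effect_allele, other_allele, eaf, beta, se, pval, n

where ``beta`` is the per-effect-allele association estimate, ``se`` its
standard error, ``eaf`` the effect-allele frequency and ``n`` the GWAS sample
size. Coordinates are 1-based. Only biallelic SNPs (single-letter A/C/G/T
alleles) are accepted; indels and multi-allelic rows are rejected at read
time, matching SNP-only instrument usage.

Auxiliary tables: a sparse pairwise LD table (absent pair => r2 = 0) used by
clumping, and a confounder-annotation table standing in for a PhenoScanner
lookup (SNP -> traits such as age, BMI, sex, weight).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, SchemaError

CANONICAL_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

VALID_ALLELES = frozenset("ACGT")

TRAIT_TYPES = ("continuous", "binary")


@dataclass
class ValidationReport:
    """Outcome of validating a summary-statistics table.

    ``failures`` lists (snp_id, reason) for every rejected or flagged row;
    ``duplicates`` lists snp_ids appearing more than once.
    """

    n_records: int = 0
    n_valid: int = 0
    failures: list[tuple[str, str]] = field(default_factory=list)
    duplicates: list[str] = field(default_factory=list)
    missing_eaf: list[str] = field(default_factory=list)

    @property
    def n_failures(self) -> int:
        return len(self.failures)

    def ok(self) -> bool:
        return not self.failures and not self.duplicates


@dataclass
class GwasDataset:
    """Summary statistics for one trait.

    ``records`` carries the canonical columns above; ``case_fraction`` is
    required for (and only for) binary traits, where ``beta`` is on the
    log-odds scale.
    """

    trait_name: str
    records: pd.DataFrame
    trait_type: str = "continuous"
    case_fraction: float | None = None
    validation: ValidationReport | None = None

    def __post_init__(self):
        if self.trait_type not in TRAIT_TYPES:
            raise ValueError(f"trait_type must be one of {TRAIT_TYPES}")
        if self.trait_type == "binary":
            if self.case_fraction is None:
                raise ValueError("binary trait requires case_fraction")
            if not 0.0 < self.case_fraction < 1.0:
                raise ValueError("case_fraction must lie in (0, 1)")
        elif self.case_fraction is not None:
            raise ValueError("case_fraction only applies to binary traits")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(missing[0])

    @property
    def n_snps(self) -> int:
        return len(self.records)

    def snp_ids(self) -> set[str]:
        return set(self.records["snp_id"])

    def subset(self, snp_ids) -> "GwasDataset":
        """Dataset restricted to ``snp_ids`` (original row order kept)."""
        keep = self.records["snp_id"].isin(set(snp_ids))
        return dataclasses.replace(
            self, records=self.records.loc[keep].reset_index(drop=True),
            validation=None,
        )


def _row_failures(df: pd.DataFrame) -> list[tuple[int, str, str]]:
    """Invariant violations per row: (positional index, snp_id, reason)."""
    out: list[tuple[int, str, str]] = []
    ea = df["effect_allele"].astype(str)
    oa = df["other_allele"].astype(str)
    eaf = pd.to_numeric(df["eaf"], errors="coerce")
    se = pd.to_numeric(df["se"], errors="coerce")
    pval = pd.to_numeric(df["pval"], errors="coerce")
    n = pd.to_numeric(df["n"], errors="coerce")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    for i in range(len(df)):
        sid = str(df["snp_id"].iloc[i])
        a1, a2 = ea.iloc[i], oa.iloc[i]
        if a1 not in VALID_ALLELES or a2 not in VALID_ALLELES:
            out.append((i, sid, f"invalid alleles {a1}/{a2} (SNPs only)"))
            continue
        if a1 == a2:
            out.append((i, sid, "identical alleles"))
            continue
        if not np.isnan(eaf.iloc[i]) and not (0.0 < eaf.iloc[i] < 1.0):
            out.append((i, sid, f"eaf {eaf.iloc[i]} outside (0,1)"))
            continue
        if not (se.iloc[i] > 0):
            out.append((i, sid, f"se {se.iloc[i]} not positive"))
            continue
        if not (0.0 < pval.iloc[i] <= 1.0):
            out.append((i, sid, f"pval {pval.iloc[i]} outside (0,1]"))
            continue
        if not (n.iloc[i] > 0):
            out.append((i, sid, f"n {n.iloc[i]} not positive"))
            continue
        if not (pos.iloc[i] >= 0):
            out.append((i, sid, f"pos {pos.iloc[i]} negative"))
            continue
    return out


def validate_dataset(ds: GwasDataset) -> ValidationReport:
    """Report duplicates and invariant violations; the dataset is unchanged."""
    df = ds.records
    report = ValidationReport(n_records=len(df))
    dup_mask = df["snp_id"].duplicated(keep=False)
    report.duplicates = sorted(df.loc[dup_mask, "snp_id"].unique().tolist())
    for dup in report.duplicates:
        report.failures.append((dup, "duplicate snp_id"))
    for _, sid, reason in _row_failures(df):
        report.failures.append((sid, reason))
    report.missing_eaf = df.loc[
        pd.to_numeric(df["eaf"], errors="coerce").isna(), "snp_id"
    ].tolist()
    for sid in report.missing_eaf:
        report.failures.append((sid, "missing eaf"))
    report.n_valid = report.n_records - len({f[0] for f in report.failures})
    return report


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return "\t"


def read_summary_stats(
    path,
    trait_name: str,
    trait_type: str = "continuous",
    column_map: dict[str, str] | None = None,
    case_fraction: float | None = None,
    allow_missing_eaf: bool = False,
) -> GwasDataset:
    """Read a delimited summary-statistics table into a validated dataset.

    Parameters
    ----------
    column_map
        Mapping canonical name -> column name in the file; canonical names
        absent from the map are looked up verbatim.
    allow_missing_eaf
        Accept rows with empty ``eaf`` (they are flagged in the validation
        report and unusable for R2/F or frequency checks).

    Rows violating record invariants are dropped and reported (with snp_id
    and reason) in ``dataset.validation``. Raises :class:`SchemaError` for a
    missing column and :class:`EmptyInputError` when no valid row remains.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    raw = pd.read_csv(
        path, sep=sep, dtype={"chrom": str}, float_precision="round_trip"
    )
    column_map = column_map or {}
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src not in raw.columns:
            raise SchemaError(canon, str(path))
        rename[src] = canon
    df = raw.rename(columns=rename)[list(CANONICAL_COLUMNS)].copy()
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    report = ValidationReport(n_records=len(df))
    bad_rows = _row_failures(df)
    if not allow_missing_eaf:
        seen = {i for i, _, _ in bad_rows}
        for i in np.flatnonzero(df["eaf"].isna().to_numpy()):
            if i not in seen:
                bad_rows.append((int(i), str(df["snp_id"].iloc[i]), "missing eaf"))
    report.failures = [(sid, reason) for _, sid, reason in bad_rows]
    drop_idx = [i for i, _, _ in bad_rows]
    df = df.drop(df.index[drop_idx]).reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)

    dup_mask = df["snp_id"].duplicated(keep=False)
    report.duplicates = sorted(df.loc[dup_mask, "snp_id"].unique().tolist())
    report.missing_eaf = df.loc[df["eaf"].isna(), "snp_id"].tolist()
    report.n_valid = len(df)
    if len(df) == 0:
        raise EmptyInputError(f"no valid summary-statistic row in {path}")
    return GwasDataset(
        trait_name=trait_name,
        records=df,
        trait_type=trait_type,
        case_fraction=case_fraction,
        validation=report,
    )


def write_summary_stats(ds: GwasDataset, path, sep: str = "\t") -> None:
    """Write the canonical columns as headered delimited text.

    Floats are written with 17 significant digits, so a write/read cycle
    reproduces every value bit-identically.
    """
    ds.records[list(CANONICAL_COLUMNS)].to_csv(
        path, sep=sep, index=False, float_format="%.17g"
    )


class LDTable:
    """Sparse symmetric pairwise r2 lookup; absent pairs are r2 = 0."""

    def __init__(self, entries=None):
        self._r2: dict[tuple[str, str], float] = {}
        for a, b, r2 in entries or []:
            self.add(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 {r2} outside [0,1]")
        self._r2[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def has(self, a: str, b: str) -> bool:
        return a == b or self._key(a, b) in self._r2

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def read_tsv(cls, path) -> "LDTable":
        df = pd.read_csv(path, sep=_sniff_sep(Path(path)))
        for col in ("snp_a", "snp_b", "r2"):
            if col not in df.columns:
                raise SchemaError(col, str(path))
        return cls(zip(df["snp_a"].astype(str), df["snp_b"].astype(str), df["r2"]))

    def write_tsv(self, path) -> None:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]
        pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(
            path, sep="\t", index=False
        )


class ConfounderTable:
    """SNP -> confounder-trait annotations (local PhenoScanner stand-in)."""

    def __init__(self, annotations: dict[str, list[str]] | None = None):
        self._ann: dict[str, list[str]] = {}
        for sid, traits in (annotations or {}).items():
            for t in traits:
                self.add(sid, t)

    def add(self, snp_id: str, trait: str) -> None:
        if not trait:
            raise ValueError("confounder trait name must be non-empty")
        self._ann.setdefault(snp_id, [])
        if trait not in self._ann[snp_id]:
            self._ann[snp_id].append(trait)

    def traits(self, snp_id: str) -> list[str]:
        return list(self._ann.get(snp_id, []))

    def is_annotated(self, snp_id: str) -> bool:
        return snp_id in self._ann

    def __len__(self) -> int:
        return len(self._ann)

    @classmethod
    def read_tsv(cls, path) -> "ConfounderTable":
        df = pd.read_csv(path, sep=_sniff_sep(Path(path)))
        for col in ("snp_id", "trait"):
            if col not in df.columns:
                raise SchemaError(col, str(path))
        table = cls()
        for sid, trait in zip(df["snp_id"].astype(str), df["trait"].astype(str)):
            table.add(sid, trait)
        return table

    def write_tsv(self, path) -> None:
        rows = [
            (sid, t) for sid in sorted(self._ann) for t in self._ann[sid]
        ]
        pd.DataFrame(rows, columns=["snp_id", "trait"]).to_csv(
            path, sep="\t", index=False
        )
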