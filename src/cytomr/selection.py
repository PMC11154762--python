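"""Instrument selection: the six-step SNP filtration pipeline.

Candidate instruments for an exposure are SNPs below a genome-wide
significance threshold (p < 5e-8 for the primary "Analysis A"; the looser
p < 5e-6 defines "Analysis B" when too few SNPs survive the stricter cut).
Candidates then pass six filters, each logged per SNP:

1. **LD clumping** (r2 < 0.01 within a 10,000 kb window) — greedy by
   ascending p-value, keeping index SNPs only;
2. **cross-exposure exclusivity** — SNPs instrumenting more than one
   exposure are removed from all of them;
3. **confounder associations** — SNPs annotated to confounder traits
   (age, BMI, sex, weight, ...) are removed;
4. **palindrome removal** during allele harmonization (:mod:`.harmonize`);
5. **outcome association** — harmonized instruments with outcome
   p < 5e-5 are removed (they may act directly on the outcome);
6. **MR-PRESSO outliers** (:mod:`.presso`), run when at least four
   instruments survive.

All p-value comparisons are strict (<); boundary values survive.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import pandas as pd

from .exceptions import EmptySelectionError, InsufficientInstrumentsError
from .filterlog import KEPT, REMOVED, FilterLog, FilterLogEntry
from .harmonize import harmonize_pair
from .presso import presso_test
from .sumstats import ConfounderTable, GwasDataset, LDTable


@dataclass
class SelectionConfig:
    """Tunable thresholds of the selection pipeline.

    ``min_instruments`` defaults to 3, the smallest count at which IVW,
    MR-Egger and the weighted median are all defined.
    """

    p_exposure_threshold: float = 5e-8
    clump_r2: float = 0.01
    clump_window_kb: int = 10000
    p_outcome_threshold: float = 5e-5
    drop_palindromic: bool = True
    min_instruments: int = 3
    presso_k_sim: int = 1000
    presso_outlier_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("p_exposure_threshold", "p_outcome_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        if not 0.0 <= self.clump_r2 <= 1.0:
            raise ValueError("clump_r2 must lie in [0,1]")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be positive")


def select_instruments(
    exposure: GwasDataset, threshold: float
) -> tuple[GwasDataset, list[FilterLogEntry]]:
    """Keep records with exposure p strictly below ``threshold`` (step 0).

    Raises :class:`EmptySelectionError` when nothing survives, so callers
    can fall back to a looser threshold.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    keep = exposure.records["pval"] < threshold
    entries = [
        FilterLogEntry(
            0,
            sid,
            KEPT if k else REMOVED,
            f"exposure p {'<' if k else '>='} {threshold:g}",
        )
        for sid, k in zip(exposure.records["snp_id"], keep)
    ]
    if not keep.any():
        raise EmptySelectionError(threshold)
    return exposure.subset(exposure.records.loc[keep, "snp_id"]), entries


def clump(
    ds: GwasDataset,
    ld: LDTable,
    r2_threshold: float = 0.01,
    window_kb: int = 10000,
    log: FilterLog | None = None,
) -> tuple[GwasDataset, list[FilterLogEntry]]:
    """Greedy LD clumping (step 1).

    SNPs ordered by ascending p-value (ties broken lexicographically by
    snp_id); each index SNP removes same-chromosome SNPs within
    ``window_kb`` kilobases whose r2 with it is >= ``r2_threshold``. LD
    pairs absent from the table count as r2 = 0 (tallied on
    ``log.missing_ld_pairs`` when a log is supplied).
    """
    df = ds.records.sort_values(["pval", "snp_id"], kind="stable")
    window_bp = window_kb * 1000
    pending = list(df.itertuples(index=False))
    entries: list[FilterLogEntry] = []
    kept_ids: list[str] = []
    while pending:
        index_snp = pending.pop(0)
        kept_ids.append(index_snp.snp_id)
        entries.append(FilterLogEntry(1, index_snp.snp_id, KEPT, "index SNP"))
        survivors = []
        for other in pending:
            if (
                other.chrom == index_snp.chrom
                and abs(int(other.pos) - int(index_snp.pos)) <= window_bp
            ):
                if not ld.has(index_snp.snp_id, other.snp_id) and log is not None:
                    log.missing_ld_pairs += 1
                r2 = ld.r2(index_snp.snp_id, other.snp_id)
                if r2 >= r2_threshold:
                    entries.append(
                        FilterLogEntry(
                            1,
                            other.snp_id,
                            REMOVED,
                            f"r2={r2:g} with index {index_snp.snp_id}",
                        )
                    )
                    continue
            survivors.append(other)
        pending = survivors
    return ds.subset(kept_ids), entries


def filter_cross_exposure(
    per_exposure_instruments: dict[str, set[str]],
) -> tuple[dict[str, set[str]], list[FilterLogEntry]]:
    """Remove SNPs instrumenting more than one exposure (step 2)."""
    if not per_exposure_instruments:
        raise ValueError("at least one exposure required")
    counts: dict[str, int] = {}
    for ids in per_exposure_instruments.values():
        for sid in ids:
            counts[sid] = counts.get(sid, 0) + 1
    shared = {sid for sid, c in counts.items() if c >= 2}
    entries: list[FilterLogEntry] = []
    out: dict[str, set[str]] = {}
    for name, ids in per_exposure_instruments.items():
        out[name] = ids - shared
        for sid in sorted(ids):
            if sid in shared:
                others = sorted(
                    n
                    for n, s in per_exposure_instruments.items()
                    if sid in s and n != name
                )
                entries.append(
                    FilterLogEntry(
                        2, sid, REMOVED, f"also instruments {', '.join(others)}"
                    )
                )
            else:
                entries.append(FilterLogEntry(2, sid, KEPT, "exposure-specific"))
    return out, entries


def filter_confounders(
    ds: GwasDataset, conf: ConfounderTable
) -> tuple[GwasDataset, list[FilterLogEntry]]:
    """Remove SNPs with any confounder annotation (step 3)."""
    entries: list[FilterLogEntry] = []
    kept = []
    for sid in ds.records["snp_id"]:
        traits = conf.traits(sid)
        if traits:
            entries.append(
                FilterLogEntry(3, sid, REMOVED, f"associated with {', '.join(traits)}")
            )
        else:
            kept.append(sid)
            entries.append(FilterLogEntry(3, sid, KEPT, "no confounder annotation"))
    return ds.subset(kept), entries


def filter_outcome_associated(
    instruments: pd.DataFrame, p_outcome_threshold: float = 5e-5
) -> tuple[pd.DataFrame, list[FilterLogEntry]]:
    """Remove harmonized instruments with outcome p strictly below the
    threshold (step 5)."""
    keep = instruments["pval_out"] >= p_outcome_threshold
    entries = [
        FilterLogEntry(
            5,
            sid,
            KEPT if k else REMOVED,
            f"outcome p {'>=' if k else '<'} {p_outcome_threshold:g}",
        )
        for sid, k in zip(instruments["snp_id"], keep)
    ]
    return instruments.loc[keep].reset_index(drop=True), entries


def apply_selection_pipeline(
    exposure: GwasDataset,
    outcome: GwasDataset,
    ld: LDTable | None = None,
    conf: ConfounderTable | None = None,
    cross_exposure_context: dict[str, set[str]] | None = None,
    cfg: SelectionConfig | None = None,
) -> tuple[pd.DataFrame, FilterLog]:
    """Run the full filtration pipeline for one exposure-outcome pair.

    ``cross_exposure_context`` maps *other* exposures' names to their
    post-clumping instrument sets; the current exposure's candidates that
    appear in any of them are removed at step 2. Raises
    :class:`EmptySelectionError` / :class:`InsufficientInstrumentsError`
    when too few instruments remain (the orchestration layer converts
    these into a pair status).
    """
    ld = ld or LDTable()
    conf = conf or ConfounderTable()
    cfg = cfg or SelectionConfig()
    log = FilterLog()

    selected, entries = select_instruments(exposure, cfg.p_exposure_threshold)
    log.extend(entries)

    selected, entries = clump(
        selected, ld, cfg.clump_r2, cfg.clump_window_kb, log=log
    )
    log.extend(entries)

    context = dict(cross_exposure_context or {})
    context.pop(exposure.trait_name, None)
    other_ids: dict[str, set[str]] = {}
    for name, ids in context.items():
        for sid in ids:
            other_ids.setdefault(sid, set()).add(name)
    kept = []
    for sid in selected.records["snp_id"]:
        if sid in other_ids:
            log.append(
                2, sid, REMOVED,
                f"also instruments {', '.join(sorted(other_ids[sid]))}",
            )
        else:
            kept.append(sid)
            log.append(2, sid, KEPT, "exposure-specific")
    selected = selected.subset(kept)

    selected, entries = filter_confounders(selected, conf)
    log.extend(entries)

    instruments, entries = harmonize_pair(
        selected, outcome, drop_palindromic=cfg.drop_palindromic
    )
    log.extend(entries)

    instruments, entries = filter_outcome_associated(
        instruments, cfg.p_outcome_threshold
    )
    log.extend(entries)

    if len(instruments) >= 4:
        result = presso_test(
            instruments,
            k_sim=cfg.presso_k_sim,
            outlier_alpha=cfg.presso_outlier_alpha,
            seed=cfg.seed,
        )
        for sid in instruments["snp_id"]:
            if sid in result.outliers:
                adj = result.per_snp.set_index("snp_id").loc[sid, "pval_adj"]
                log.append(6, sid, REMOVED, f"MR-PRESSO outlier (adj p={adj:.3g})")
            else:
                log.append(6, sid, KEPT, "not an outlier")
        if result.outliers:
            keep = ~instruments["snp_id"].isin(result.outliers)
            instruments = instruments.loc[keep].reset_index(drop=True)

    if len(instruments) < cfg.min_instruments:
        raise InsufficientInstrumentsError(len(instruments), cfg.min_instruments)
    return instruments, log


def make_config(label: str) -> SelectionConfig:
    """Preset selection config for Analysis A (5e-8) or B (5e-6)."""
    thresholds = {"A": 5e-8, "B": 5e-6}
    if label not in thresholds:
        raise ValueError("label must be 'A' or 'B'")
    return SelectionConfig(p_exposure_threshold=thresholds[label])


def config_replace(cfg: SelectionConfig, **changes) -> SelectionConfig:
    return dataclasses.replace(cfg, **changes)
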