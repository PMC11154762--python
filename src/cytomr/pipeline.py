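"""Bidirectional, dual-threshold orchestration over exposure-outcome grids.

``run_pair`` pushes one exposure-outcome pair through instrument selection,
the three estimators and the sensitivity diagnostics. ``run_bidirectional``
runs every exposure x outcome pair forward, then swaps roles (each outcome
trait instrumented as an exposure) and assigns a directionality verdict per
pair: "unidirectional" when only the forward direction is significant,
"bidirectional" when both are (the pattern seen for one chemokine-mobility
pair in the motivating study).

Significance is nominal p < alpha (default 0.05) with no multiple-testing
correction across the grid — faithful to common MR practice and a
documented caveat; a Benjamini-Hochberg-adjusted matrix is additionally
emitted for reference but never drives the significance mask.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, estimates_to_frame, ivw, mr_egger, weighted_median
from .exceptions import CytomrError, EmptySelectionError, InsufficientInstrumentsError
from .filterlog import FilterLog
from .presso import PressoResult, presso_test
from .selection import SelectionConfig, apply_selection_pipeline, clump, select_instruments
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats import ConfounderTable, GwasDataset, LDTable

ANALYSIS_THRESHOLDS = {"A": 5e-8, "B": 5e-6}

STATUS_OK = "ok"
STATUS_INSUFFICIENT = "insufficient_instruments"


@dataclass
class AnalysisSpec:
    """Complete description of one analysis run."""

    exposures: list[GwasDataset]
    outcomes: list[GwasDataset]
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    label: str | None = None  # "A" (5e-8) or "B" (5e-6) preset
    significance_alpha: float = 0.05
    ld: LDTable = field(default_factory=LDTable)
    confounders: ConfounderTable = field(default_factory=ConfounderTable)
    seed: int = 0
    n_boot_median: int = 1000

    def __post_init__(self):
        if self.label is not None:
            expected = ANALYSIS_THRESHOLDS.get(self.label)
            if expected is None:
                raise ValueError("label must be 'A', 'B' or None")
            if self.selection.p_exposure_threshold != expected:
                raise ValueError(
                    f"Analysis {self.label} requires exposure threshold {expected:g}"
                )

    @classmethod
    def preset(cls, label: str, exposures, outcomes, **kwargs) -> "AnalysisSpec":
        sel = kwargs.pop("selection", None) or SelectionConfig(
            p_exposure_threshold=ANALYSIS_THRESHOLDS[label]
        )
        return cls(
            exposures=exposures, outcomes=outcomes, selection=sel, label=label, **kwargs
        )


@dataclass
class PairResult:
    """Everything computed for one exposure-outcome pair in one direction."""

    exposure: str
    outcome: str
    direction: str  # "forward" or "reverse"
    status: str
    estimates: list[MREstimate] = field(default_factory=list)
    sensitivity: SensitivityReport | None = None
    presso: PressoResult | None = None
    filter_log: FilterLog | None = None
    n_instruments: int = 0

    def estimate(self, method: str) -> MREstimate | None:
        for est in self.estimates:
            if est.method == method:
                return est
        return None

    def to_frame(self) -> pd.DataFrame:
        df = estimates_to_frame(self.estimates, self.exposure, self.outcome)
        df.insert(2, "direction", self.direction)
        return df


def _pair_seed(base: int, exposure: str, outcome: str, direction: str) -> int:
    tag = zlib.crc32(f"{exposure}|{outcome}|{direction}".encode())
    return int((base * 1_000_003 + tag) % (2**31 - 1))


def run_pair(
    exposure: GwasDataset,
    outcome: GwasDataset,
    direction: str,
    spec: AnalysisSpec,
    cross_exposure_context: dict[str, set[str]] | None = None,
) -> PairResult:
    """Select instruments, estimate and run diagnostics for one pair.

    Too few surviving instruments becomes ``status =
    "insufficient_instruments"`` rather than an exception; the primary
    inference is multiplicative-random-effects IVW at
    ``spec.significance_alpha``.
    """
    seed = _pair_seed(spec.seed, exposure.trait_name, outcome.trait_name, direction)
    cfg = dataclasses.replace(spec.selection, seed=seed)
    try:
        instruments, log = apply_selection_pipeline(
            exposure,
            outcome,
            ld=spec.ld,
            conf=spec.confounders,
            cross_exposure_context=cross_exposure_context,
            cfg=cfg,
        )
    except (EmptySelectionError, InsufficientInstrumentsError):
        return PairResult(
            exposure=exposure.trait_name,
            outcome=outcome.trait_name,
            direction=direction,
            status=STATUS_INSUFFICIENT,
        )
    estimates = [
        ivw(instruments, mode="multiplicative_random"),
        ivw(instruments, mode="fixed"),
        mr_egger(instruments),
        weighted_median(instruments, n_boot=spec.n_boot_median, seed=seed),
    ]
    if outcome.trait_type == "binary":
        for est in estimates:
            est.with_or_scale()
    presso = None
    if len(instruments) >= 4:
        presso = presso_test(
            instruments,
            k_sim=cfg.presso_k_sim,
            outlier_alpha=cfg.presso_outlier_alpha,
            seed=seed,
        )
    sens = sensitivity_report(
        instruments,
        alpha=spec.significance_alpha,
        trait_type=outcome.trait_type,
        case_fraction=outcome.case_fraction,
    )
    return PairResult(
        exposure=exposure.trait_name,
        outcome=outcome.trait_name,
        direction=direction,
        status=STATUS_OK,
        estimates=estimates,
        sensitivity=sens,
        presso=presso,
        filter_log=log,
        n_instruments=len(instruments),
    )


def _instrument_context(
    datasets: list[GwasDataset], spec: AnalysisSpec
) -> dict[str, set[str]]:
    """Post-clumping candidate instrument sets per trait (for step 2)."""
    context: dict[str, set[str]] = {}
    for ds in datasets:
        try:
            selected, _ = select_instruments(ds, spec.selection.p_exposure_threshold)
            clumped, _ = clump(
                selected,
                spec.ld,
                spec.selection.clump_r2,
                spec.selection.clump_window_kb,
            )
            context[ds.trait_name] = clumped.snp_ids()
        except EmptySelectionError:
            context[ds.trait_name] = set()
    return context


def run_bidirectional(spec: AnalysisSpec) -> tuple[list[PairResult], pd.DataFrame]:
    """Run every pair forward and reverse; return results and verdicts.

    The verdict per (exposure, outcome) pair compares multiplicative
    random-effects IVW p-values at ``spec.significance_alpha``:
    "unidirectional" (forward significant only), "bidirectional" (both),
    "reverse_only", "none", or "undetermined" when the forward pair had too
    few instruments.
    """
    if not spec.exposures or not spec.outcomes:
        raise CytomrError("need at least one exposure and one outcome")
    fwd_context = _instrument_context(spec.exposures, spec)
    rev_context = _instrument_context(spec.outcomes, spec)

    results: list[PairResult] = []
    for exposure in spec.exposures:
        for outcome in spec.outcomes:
            results.append(
                run_pair(exposure, outcome, "forward", spec, fwd_context)
            )
    for outcome in spec.outcomes:
        for exposure in spec.exposures:
            results.append(
                run_pair(outcome, exposure, "reverse", spec, rev_context)
            )

    alpha = spec.significance_alpha
    index = {(r.exposure, r.outcome, r.direction): r for r in results}
    rows = []
    for exposure in spec.exposures:
        for outcome in spec.outcomes:
            fwd = index[(exposure.trait_name, outcome.trait_name, "forward")]
            rev = index[(outcome.trait_name, exposure.trait_name, "reverse")]
            fwd_p = _ivw_pval(fwd)
            rev_p = _ivw_pval(rev)
            fwd_sig = fwd_p is not None and fwd_p < alpha
            rev_sig = rev_p is not None and rev_p < alpha
            if fwd.status != STATUS_OK:
                verdict = "undetermined"
            elif fwd_sig and rev_sig:
                verdict = "bidirectional"
            elif fwd_sig:
                verdict = "unidirectional"
            elif rev_sig:
                verdict = "reverse_only"
            else:
                verdict = "none"
            rows.append(
                dict(
                    exposure=exposure.trait_name,
                    outcome=outcome.trait_name,
                    forward_pval=fwd_p,
                    reverse_pval=rev_p,
                    verdict=verdict,
                )
            )
    return results, pd.DataFrame(rows)


def _ivw_pval(result: PairResult) -> float | None:
    est = result.estimate("ivw_mre")
    return est.pval if est is not None else None


@dataclass
class ResultsMatrix:
    """P-value matrix (exposures x outcomes) with significance mask."""

    pvals: pd.DataFrame
    mask: pd.DataFrame  # boolean; NA where the pair is missing/insufficient
    fdr: pd.DataFrame  # BH-adjusted p-values, reference only


def results_matrix(
    results: list[PairResult],
    method: str = "ivw_mre",
    direction: str = "forward",
    alpha: float = 0.05,
) -> ResultsMatrix:
    """Assemble the heatmap-style p-value matrix for one direction.

    The mask marks cells with p < alpha; pairs missing or with
    insufficient instruments are NA, distinct from non-significant.
    """
    subset = [r for r in results if r.direction == direction]
    exposures = list(dict.fromkeys(r.exposure for r in subset))
    outcomes = list(dict.fromkeys(r.outcome for r in subset))
    pvals = pd.DataFrame(np.nan, index=exposures, columns=outcomes)
    for r in subset:
        est = r.estimate(method)
        if r.status == STATUS_OK and est is not None:
            pvals.loc[r.exposure, r.outcome] = est.pval
    mask = pvals < alpha
    mask = mask.astype(object)
    mask[pvals.isna()] = pd.NA
    flat = pvals.to_numpy().ravel()
    ok = ~np.isnan(flat)
    adj = np.full_like(flat, np.nan)
    if ok.sum():
        adj[ok] = stats.false_discovery_control(flat[ok], method="bh")
    fdr = pd.DataFrame(
        adj.reshape(pvals.shape), index=pvals.index, columns=pvals.columns
    )
    return ResultsMatrix(pvals=pvals, mask=mask, fdr=fdr)


def write_results(
    results: list[PairResult],
    verdicts: pd.DataFrame,
    out_dir,
    alpha: float = 0.05,
) -> None:
    """Serialize a full run: estimates TSV, matrices, verdicts, filter logs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = [r.to_frame() for r in results if r.estimates]
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(
            out_dir / "estimates.tsv", sep="\t", index=False
        )
    matrix = results_matrix(results, alpha=alpha)
    matrix.pvals.to_csv(out_dir / "pval_matrix.tsv", sep="\t")
    matrix.mask.to_csv(out_dir / "significance_mask.tsv", sep="\t")
    matrix.fdr.to_csv(out_dir / "fdr_matrix.tsv", sep="\t")
    verdicts.to_csv(out_dir / "verdicts.tsv", sep="\t", index=False)
    logs = []
    for r in results:
        if r.filter_log is not None:
            df = r.filter_log.to_frame()
            df.insert(0, "direction", r.direction)
            df.insert(0, "outcome", r.outcome)
            df.insert(0, "exposure", r.exposure)
            logs.append(df)
    if logs:
        pd.concat(logs, ignore_index=True).to_csv(
            out_dir / "filter_log.tsv", sep="\t", index=False
        )
    summary = dict(
        n_pairs=len(results),
        n_ok=sum(r.status == STATUS_OK for r in results),
        n_insufficient=sum(r.status == STATUS_INSUFFICIENT for r in results),
    )
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
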