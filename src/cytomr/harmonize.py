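"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR needs both studies' effects expressed per copy of the same
effect allele. For each SNP present in both datasets the outcome record is
reconciled to the exposure orientation:

* same alleles (possibly on the opposite strand, i.e. reverse-complemented)
  -> outcome effect kept as is;
* swapped alleles (again possibly strand-flipped) -> outcome beta negated and
  the instrument flagged ``flipped``;
* anything else -> irreconcilable, dropped and logged.

Palindromic SNPs (A/T or C/G) cannot be strand-resolved from alleles alone
and are removed outright by default — no frequency-based rescue is
attempted. Harmonization and palindrome removal together form step 4 of the
selection pipeline.

Harmonized instruments are returned as a DataFrame sorted by ``snp_id`` with
columns: snp_id, chrom, pos, effect_allele, other_allele, eaf_exp, beta_exp,
se_exp, pval_exp, n_exp, beta_out, se_out, pval_out, n_out, flipped,
palindromic.
"""

from __future__ import annotations

import pandas as pd

from .exceptions import CytomrError
from .filterlog import KEPT, REMOVED, FilterLogEntry
from .sumstats import VALID_ALLELES, GwasDataset

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

HARMONIZED_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf_exp",
    "beta_exp",
    "se_exp",
    "pval_exp",
    "n_exp",
    "beta_out",
    "se_out",
    "pval_out",
    "n_out",
    "flipped",
    "palindromic",
)

STEP_HARMONIZE = 4


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the unordered allele pair is {A,T} or {C,G}."""
    ea, oa = str(effect_allele).upper(), str(other_allele).upper()
    if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
        raise CytomrError(f"invalid allele symbol in pair {effect_allele}/{other_allele}")
    if ea == oa:
        raise CytomrError("alleles must differ")
    return COMPLEMENT[ea] == oa


def _reconcile(exp_ea, exp_oa, out_ea, out_oa):
    """How the outcome alleles relate to the exposure alleles.

    Returns "same", "swap" or None (irreconcilable). Strand flips
    (reverse complement) are treated as the same variant; for palindromic
    pairs "same" and strand-"swap" coincide, but those SNPs are dropped
    before this distinction could matter.
    """
    if (out_ea, out_oa) == (exp_ea, exp_oa):
        return "same"
    if (out_ea, out_oa) == (exp_oa, exp_ea):
        return "swap"
    c_ea, c_oa = COMPLEMENT[exp_ea], COMPLEMENT[exp_oa]
    if (out_ea, out_oa) == (c_ea, c_oa):
        return "same"
    if (out_ea, out_oa) == (c_oa, c_ea):
        return "swap"
    return None


def harmonize_pair(
    exposure: GwasDataset,
    outcome: GwasDataset,
    drop_palindromic: bool = True,
) -> tuple[pd.DataFrame, list[FilterLogEntry]]:
    """Align shared SNPs on the exposure's effect allele.

    Only SNPs present in both datasets are returned. EAF is carried from the
    exposure study. Output is sorted by snp_id, so the result is independent
    of input row order. Drops are logged, never raised.
    """
    exp = exposure.records.set_index("snp_id", drop=False)
    out = outcome.records.set_index("snp_id", drop=False)
    entries: list[FilterLogEntry] = []
    rows = []
    for sid in exp.index:
        if sid not in out.index:
            entries.append(
                FilterLogEntry(STEP_HARMONIZE, sid, REMOVED, "absent in outcome dataset")
            )
            continue
        e = exp.loc[sid]
        o = out.loc[sid]
        ea, oa = e["effect_allele"], e["other_allele"]
        if is_palindromic(ea, oa):
            if drop_palindromic:
                entries.append(
                    FilterLogEntry(
                        STEP_HARMONIZE, sid, REMOVED, f"palindromic alleles {ea}/{oa}"
                    )
                )
                continue
            palindromic = True
        else:
            palindromic = False
        rel = _reconcile(ea, oa, o["effect_allele"], o["other_allele"])
        if rel is None:
            entries.append(
                FilterLogEntry(
                    STEP_HARMONIZE,
                    sid,
                    REMOVED,
                    "irreconcilable alleles "
                    f"{ea}/{oa} vs {o['effect_allele']}/{o['other_allele']}",
                )
            )
            continue
        flipped = rel == "swap"
        beta_out = -float(o["beta"]) if flipped else float(o["beta"])
        rows.append(
            dict(
                snp_id=sid,
                chrom=e["chrom"],
                pos=int(e["pos"]),
                effect_allele=ea,
                other_allele=oa,
                eaf_exp=float(e["eaf"]),
                beta_exp=float(e["beta"]),
                se_exp=float(e["se"]),
                pval_exp=float(e["pval"]),
                n_exp=int(e["n"]),
                beta_out=beta_out,
                se_out=float(o["se"]),
                pval_out=float(o["pval"]),
                n_out=int(o["n"]),
                flipped=flipped,
                palindromic=palindromic,
            )
        )
        entries.append(FilterLogEntry(STEP_HARMONIZE, sid, KEPT, "harmonized"))
    if rows:
        df = pd.DataFrame(rows).sort_values("snp_id").reset_index(drop=True)
    else:
        df = pd.DataFrame(columns=list(HARMONIZED_COLUMNS))
    return df[list(HARMONIZED_COLUMNS)], entries
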