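"""Per-step provenance of instrument filtering.

Every SNP entering the selection pipeline is logged at every step it reaches,
either as ``kept`` or ``removed`` with a human-readable reason, so the final
instrument list can be audited step by step (the machine twin of a
"SNPs removed at each selection step" supplementary table).

Step numbering: 0 = exposure significance threshold, 1 = LD clumping,
2 = cross-exposure exclusivity, 3 = confounder associations, 4 = harmonization
and palindrome removal, 5 = outcome association, 6 = MR-PRESSO outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

STEP_NAMES = {
    0: "exposure significance",
    1: "LD clumping",
    2: "cross-exposure exclusivity",
    3: "confounder association",
    4: "harmonization / palindromes",
    5: "outcome association",
    6: "MR-PRESSO outliers",
}

KEPT = "kept"
REMOVED = "removed"


@dataclass(frozen=True)
class FilterLogEntry:
    step: int
    snp_id: str
    action: str  # "kept" or "removed"
    reason: str


class FilterLog:
    """Ordered collection of :class:`FilterLogEntry` with query helpers."""

    def __init__(self, entries: list[FilterLogEntry] | None = None):
        self.entries: list[FilterLogEntry] = list(entries) if entries else []
        #: count of within-window SNP pairs whose LD was absent from the
        #: supplied table and therefore treated as r2 = 0
        self.missing_ld_pairs: int = 0

    def append(self, step: int, snp_id: str, action: str, reason: str = "") -> None:
        self.entries.append(FilterLogEntry(step, snp_id, action, reason))

    def extend(self, entries) -> None:
        for e in entries:
            self.entries.append(e)

    def removed(self, step: int | None = None) -> list[str]:
        return [
            e.snp_id
            for e in self.entries
            if e.action == REMOVED and (step is None or e.step == step)
        ]

    def kept(self, step: int | None = None) -> list[str]:
        return [
            e.snp_id
            for e in self.entries
            if e.action == KEPT and (step is None or e.step == step)
        ]

    def steps(self) -> list[int]:
        return sorted({e.step for e in self.entries})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.step, e.snp_id, e.action, e.reason) for e in self.entries],
            columns=["step", "snp_id", "action", "reason"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.entries)

    def __repr__(self) -> str:  # pragma: no cover
        return f"FilterLog({len(self.entries)} entries, steps {self.steps()})"
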