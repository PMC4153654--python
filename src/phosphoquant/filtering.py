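"""PSM quality filtering and target-decoy FDR estimation.

Four sequential quality rules are applied to Mascot-style PSMs, in the fixed
order (i) precursor mass error, (ii) ion score, (iii) peptide length,
(iv) search-engine rank; each rejected PSM is attributed to the first rule it
fails.  Decoy PSMs (matches to reversed database entries) flow through the
rules so the surviving decoy count estimates the false discovery rate of the
accepted target set, but they are never part of the accepted output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .psm_io import PsmRecord

#: Rule names in evaluation order.
RULES = ("mass_error", "ion_score", "length", "rank")


@dataclass
class FilterConfig:
    """Thresholds for the four PSM quality rules.

    All comparisons are inclusive: a PSM at exactly the threshold passes
    (score >= 20, |ppm| <= 10, length >= 6, rank == 1 by default).
    """

    max_abs_mass_error_ppm: float = 10.0
    min_ion_score: float = 20.0
    min_peptide_length: int = 6
    required_rank: int = 1
    max_fdr: float = 0.01

    def __post_init__(self) -> None:
        if self.max_abs_mass_error_ppm <= 0:
            raise ValueError("max_abs_mass_error_ppm must be positive")
        if self.min_ion_score <= 0:
            raise ValueError("min_ion_score must be positive")
        if self.min_peptide_length <= 0 or self.required_rank <= 0:
            raise ValueError("length/rank thresholds must be positive")
        if not 0 < self.max_fdr < 1:
            raise ValueError("max_fdr must lie in (0, 1)")


@dataclass
class FilterReport:
    """Accounting of one filtering pass: n_input = n_accepted + n_decoy_passed
    + sum of per-rule rejections (first-failing-rule attribution)."""

    n_input: int = 0
    n_accepted: int = 0
    n_decoy_passed: int = 0
    counts_per_rule: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in RULES}
    )
    estimated_fdr: float = 0.0
    fdr_exceeded: bool = False

    def to_lines(self) -> list[str]:
        lines = [f"PSMs in: {self.n_input}"]
        for rule in RULES:
            lines.append(f"  rejected by {rule}: {self.counts_per_rule[rule]}")
        lines.append(f"decoys passing all rules: {self.n_decoy_passed}")
        lines.append(f"accepted target PSMs: {self.n_accepted}")
        lines.append(f"estimated FDR: {self.estimated_fdr:.4f}")
        if self.fdr_exceeded:
            lines.append("WARNING: estimated FDR exceeds the configured maximum")
        return lines


def first_failing_rule(psm: PsmRecord, cfg: FilterConfig) -> str | None:
    """Name of the first rule the PSM fails, or None if it passes all four."""
    if abs(psm.mass_error_ppm) > cfg.max_abs_mass_error_ppm:
        return "mass_error"
    if psm.ion_score < cfg.min_ion_score:
        return "ion_score"
    if len(psm.sequence) < cfg.min_peptide_length:
        return "length"
    if psm.rank != cfg.required_rank:
        return "rank"
    return None


def apply_filters(
    psms: Sequence[PsmRecord], cfg: FilterConfig | None = None
) -> tuple[list[PsmRecord], FilterReport]:
    """Apply the four quality rules and estimate the FDR of the result.

    Returns the accepted *target* PSMs and a :class:`FilterReport`.  Decoys
    that survive all rules enter the FDR estimate but not the accepted list.
    The report only warns (``fdr_exceeded``) when the estimate is above
    ``cfg.max_fdr``; re-thresholding is an explicit, separate step
    (:func:`threshold_for_fdr`).
    """
    cfg = cfg or FilterConfig()
    report = FilterReport(n_input=len(psms))
    accepted: list[PsmRecord] = []
    passed_decoys: list[PsmRecord] = []
    for psm in psms:
        rule = first_failing_rule(psm, cfg)
        if rule is not None:
            report.counts_per_rule[rule] += 1
        elif psm.is_decoy:
            passed_decoys.append(psm)
        else:
            accepted.append(psm)
    report.n_accepted = len(accepted)
    report.n_decoy_passed = len(passed_decoys)
    report.estimated_fdr = len(passed_decoys) / max(1, len(accepted))
    report.fdr_exceeded = report.estimated_fdr > cfg.max_fdr
    return accepted, report


def estimate_fdr(psms: Sequence[PsmRecord], score_threshold: float) -> float:
    """Decoy-based FDR at a score threshold.

    FDR = (#decoys with score >= threshold) / max(1, #targets with score >=
    threshold); the simple decoy/target count, not the concatenated-database
    2d/(t+d) variant.
    """
    decoys = sum(
        1 for p in psms if p.is_decoy and p.ion_score >= score_threshold
    )
    targets = sum(
        1 for p in psms if not p.is_decoy and p.ion_score >= score_threshold
    )
    return decoys / max(1, targets)


def threshold_for_fdr(
    psms: Sequence[PsmRecord], max_fdr: float
) -> float | None:
    """Lowest observed ion score whose running FDR is <= ``max_fdr``.

    Scores are scanned in descending order; because the decoy/target ratio is
    not pointwise monotone, the scan keeps the lowest threshold at which the
    running estimate is still within the budget.  Returns None when no
    threshold achieves it.
    """
    scored = sorted({p.ion_score for p in psms}, reverse=True)
    best: float | None = None
    n_decoy = n_target = 0
    idx = 0
    ordered = sorted(psms, key=lambda p: p.ion_score, reverse=True)
    for threshold in scored:
        while idx < len(ordered) and ordered[idx].ion_score >= threshold:
            if ordered[idx].is_decoy:
                n_decoy += 1
            else:
                n_target += 1
            idx += 1
        if n_decoy / max(1, n_target) <= max_fdr:
            best = threshold
    return best
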