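"""Triplex ratio computation, median normalization against non-phosphopeptides,
PSM-to-site aggregation and significance calling.

Channel layout: the light channel carries the wild-type (WT) condition and is
the common denominator; medium/light is the NS/WT ratio and heavy/light the
LS/WT ratio.  Unequal total input per channel (the mixing factors) is removed
by dividing every phosphopeptide ratio by the median ratio of all
non-phosphopeptide PSMs, after which the non-phosphopeptide Log2 median is
exactly zero per channel and any constant rescaling of a channel cancels.

Aggregation to unique phosphopeptides/sites: normalized ratios are averaged
arithmetically across a group's quantifiable PSMs and the Log2 of the mean is
reported.  When a peptide has both localized and ambiguous evidence, only the
localized PSMs are used; when no PSM reaches the localization cutoff, all are
used and the site is reported as ambiguous.  |Log2| strictly greater than 1
is called a significant change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from dataclasses import replace as _dc_replace
from statistics import median
from typing import Sequence

from .localization import AMBIGUOUS, SiteAssignment, resolve_sites
from .psm_io import PsmRecord, annotate_peptide


@dataclass(frozen=True)
class RatioSet:
    """Raw or normalized channel ratios for one PSM; None = channel missing."""

    medium_over_light: float | None = None  # NS/WT
    heavy_over_light: float | None = None  # LS/WT

    def __post_init__(self) -> None:
        for v in (self.medium_over_light, self.heavy_over_light):
            if v is not None and v <= 0:
                raise ValueError("ratios must be strictly positive")

    @property
    def any_present(self) -> bool:
        return self.medium_over_light is not None or self.heavy_over_light is not None


@dataclass(frozen=True)
class NormalizationFactors:
    """Median non-phosphopeptide ratios per channel (the mixing factors)."""

    median_medium_over_light: float
    median_heavy_over_light: float
    n_nonphospho_used: int

    def __post_init__(self) -> None:
        if self.median_medium_over_light <= 0 or self.median_heavy_over_light <= 0:
            raise ValueError("normalization factors must be strictly positive")


@dataclass
class QuantifiedSite:
    """Aggregated, normalized Log2 ratios for one phosphopeptide/site group."""

    protein_name: str
    accession_field: str  # 'Q7T3L7;Q7ZWB1' style for shared peptides
    peptide_sequence: str
    sites: list[SiteAssignment] = field(default_factory=list)
    n_psms: int = 1
    log2_ns_wt: float | None = None
    log2_ls_wt: float | None = None
    significant_ns: bool = False
    significant_ls: bool = False
    quadrant: str | None = None
    site_source_label: str = ""
    site_human_label: str = ""

    @property
    def is_ambiguous(self) -> bool:
        return any(not s.is_localized for s in self.sites) or not self.sites

    @property
    def localized_peptide_positions(self) -> list[int]:
        return [
            s.peptide_position
            for s in self.sites
            if s.is_localized and s.peptide_position is not None
        ]

    @property
    def annotated_peptide(self) -> str:
        return annotate_peptide(
            self.peptide_sequence, self.localized_peptide_positions
        )

    def default_site_label(self) -> str:
        """Peptide-coordinate site label used before protein mapping."""
        if not self.sites:
            return ""
        labels = [s.label() for s in self.sites]
        if all(lbl == AMBIGUOUS for lbl in labels):
            return AMBIGUOUS
        return ", ".join(labels)


class QuantificationError(ValueError):
    pass


def compute_ratios(psm: PsmRecord) -> RatioSet:
    """Per-PSM channel/light ratios.

    Precomputed ratio columns, when present on the record, are used verbatim.
    Otherwise each ratio is quantity(channel) / quantity(light); a ratio with
    a missing numerator or denominator is missing.  Because light (WT) is the
    common denominator, a record without a light quantity has no usable
    ratios even if two channels are present.
    """
    if psm.ratio_medium_light is not None or psm.ratio_heavy_light is not None:
        return RatioSet(
            medium_over_light=psm.ratio_medium_light,
            heavy_over_light=psm.ratio_heavy_light,
        )
    q = psm.channel_quantity
    light = q.get("light")
    if light is None:
        return RatioSet()
    return RatioSet(
        medium_over_light=(q["medium"] / light) if q.get("medium") else None,
        heavy_over_light=(q["heavy"] / light) if q.get("heavy") else None,
    )


def compute_normalization(
    psms: Sequence[PsmRecord], min_nonphospho: int = 10
) -> NormalizationFactors:
    """Median channel/light ratios over non-phosphopeptide PSMs.

    Works at the PSM row level (not peptide-aggregated).  Raises when fewer
    than ``min_nonphospho`` non-phosphopeptide PSMs contribute to either
    channel; the threshold must then be lowered explicitly.
    """
    ml: list[float] = []
    hl: list[float] = []
    for psm in psms:
        if psm.is_phosphopeptide:
            continue
        ratios = compute_ratios(psm)
        if ratios.medium_over_light is not None:
            ml.append(ratios.medium_over_light)
        if ratios.heavy_over_light is not None:
            hl.append(ratios.heavy_over_light)
    n_used = min(len(ml), len(hl))
    if n_used < min_nonphospho:
        raise QuantificationError(
            f"only {n_used} non-phosphopeptide PSMs with usable ratios; "
            f"minimum is {min_nonphospho} — lower min_nonphospho explicitly "
            "if this is intended"
        )
    return NormalizationFactors(
        median_medium_over_light=median(ml),
        median_heavy_over_light=median(hl),
        n_nonphospho_used=n_used,
    )


def normalize(ratios: RatioSet, factors: NormalizationFactors) -> RatioSet:
    """Divide each present ratio by its channel's median factor."""
    ml = ratios.medium_over_light
    hl = ratios.heavy_over_light
    return RatioSet(
        medium_over_light=(
            ml / factors.median_medium_over_light if ml is not None else None
        ),
        heavy_over_light=(
            hl / factors.median_heavy_over_light if hl is not None else None
        ),
    )


def _site_group_key(sites: Sequence[SiteAssignment]) -> tuple:
    if not sites or any(not s.is_localized for s in sites):
        return ("ambiguous",)
    return tuple(sorted(s.peptide_position for s in sites))


def aggregate(
    psms: Sequence[PsmRecord],
    factors: NormalizationFactors,
    cutoff_pct: float = 75.0,
    inclusive: bool = True,
    method: str = "mean",
) -> list[QuantifiedSite]:
    """Aggregate accepted phosphopeptide PSMs to unique peptide/site groups.

    PSMs are grouped by (accession field, peptide sequence, resolved site
    set).  Within one peptide's evidence, localized-site PSMs supersede
    ambiguous ones: if any PSM of a (accession, peptide) pair is localized,
    only the localized groups are kept; otherwise all PSMs aggregate into a
    single ambiguous group.  Per channel, the group value is
    log2(mean of normalized ratios) (``method="median"`` substitutes the
    median) over the group's quantifiable PSMs.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"unknown aggregation method {method!r}")

    # (accession, sequence) -> site-key -> list of (psm, sites, normalized)
    peptides: dict[tuple[str, str], dict[tuple, list]] = {}
    for psm in psms:
        if not psm.is_phosphopeptide:
            continue
        ratios = compute_ratios(psm)
        if not psm.is_quantifiable or not ratios.any_present:
            continue
        sites = resolve_sites(psm, cutoff_pct=cutoff_pct, inclusive=inclusive)
        key = (psm.protein_accession, psm.sequence)
        skey = _site_group_key(sites)
        peptides.setdefault(key, {}).setdefault(skey, []).append(
            (psm, sites, normalize(ratios, factors))
        )

    out: list[QuantifiedSite] = []
    for (accession, sequence), groups in peptides.items():
        localized_keys = [k for k in groups if k != ("ambiguous",)]
        if localized_keys:
            chosen = {k: groups[k] for k in localized_keys}
        else:
            chosen = {("ambiguous",): groups[("ambiguous",)]}
        for skey, members in chosen.items():
            ns_vals = [
                r.medium_over_light
                for _, _, r in members
                if r.medium_over_light is not None
            ]
            ls_vals = [
                r.heavy_over_light
                for _, _, r in members
                if r.heavy_over_light is not None
            ]
            agg = (lambda v: sum(v) / len(v)) if method == "mean" else median
            first_psm, first_sites, _ = members[0]
            site = QuantifiedSite(
                protein_name=first_psm.protein_description
                or first_psm.protein_accession,
                accession_field=accession,
                peptide_sequence=sequence,
                sites=list(first_sites),
                n_psms=len(members),
                log2_ns_wt=math.log2(agg(ns_vals)) if ns_vals else None,
                log2_ls_wt=math.log2(agg(ls_vals)) if ls_vals else None,
            )
            site.site_source_label = site.default_site_label()
            out.append(site)
    return out


def call_significance(
    site: QuantifiedSite, threshold: float = 1.0
) -> QuantifiedSite:
    """Flag |Log2| strictly greater than ``threshold`` per channel; a missing
    Log2 is never significant.  Returns an updated copy."""
    ns = site.log2_ns_wt
    ls = site.log2_ls_wt
    return _dc_replace(
        site,
        significant_ns=ns is not None and abs(ns) > threshold,
        significant_ls=ls is not None and abs(ls) > threshold,
    )
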