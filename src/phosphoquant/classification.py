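"""Biological quadrant classification of quantified phosphosites.

The two Log2 axes (NS/WT on x, LS/WT on y) partition significantly changed
sites into quadrants with distinct mechanistic readings: a site dephosphory-
lated by an activated phosphatase (NS down) but accumulating when the
phosphatase is catalytically impaired (LS up) behaves as a direct substrate;
the opposite corner (NS up, LS down) fits a phosphatase-dependent downstream
event; concordant corners are shared NS/LS effects.  Sites significant in
only one channel, and unchanged sites, receive their own labels so the
classifier is total.
"""

from __future__ import annotations

from typing import Sequence

from .quantification import QuantifiedSite, _dc_replace

SUBSTRATE_MODEL = "substrate_model"  # NS down & LS up
DOWNSTREAM_MODEL = "downstream_model"  # NS up & LS down
SHARED_UP = "shared_up"
SHARED_DOWN = "shared_down"
NS_ONLY_UP = "ns_only_up"
NS_ONLY_DOWN = "ns_only_down"
LS_ONLY_UP = "ls_only_up"
LS_ONLY_DOWN = "ls_only_down"
UNCHANGED = "unchanged"

ALL_LABELS = (
    SUBSTRATE_MODEL,
    DOWNSTREAM_MODEL,
    SHARED_UP,
    SHARED_DOWN,
    NS_ONLY_UP,
    NS_ONLY_DOWN,
    LS_ONLY_UP,
    LS_ONLY_DOWN,
    UNCHANGED,
)


def classify_calls(
    sig_ns: bool, sig_ls: bool, ns_up: bool, ls_up: bool
) -> str:
    """Quadrant label as a pure function of the significance calls and signs.

    ``ns_up`` / ``ls_up`` are only consulted for significant channels.
    """
    if sig_ns and sig_ls:
        if ns_up and ls_up:
            return SHARED_UP
        if not ns_up and not ls_up:
            return SHARED_DOWN
        if not ns_up and ls_up:
            return SUBSTRATE_MODEL
        return DOWNSTREAM_MODEL
    if sig_ns:
        return NS_ONLY_UP if ns_up else NS_ONLY_DOWN
    if sig_ls:
        return LS_ONLY_UP if ls_up else LS_ONLY_DOWN
    return UNCHANGED


def classify(site: QuantifiedSite) -> QuantifiedSite:
    """Attach the quadrant label; significance must already be called."""
    label = classify_calls(
        site.significant_ns,
        site.significant_ls,
        (site.log2_ns_wt or 0.0) > 0,
        (site.log2_ls_wt or 0.0) > 0,
    )
    return _dc_replace(site, quadrant=label)


def rank_table(sites: Sequence[QuantifiedSite]) -> list[QuantifiedSite]:
    """Order sites the way the published table is printed: descending NS/WT
    Log2 with missing NS values last; stable tie-break by accession then
    peptide sequence."""
    return sorted(
        sites,
        key=lambda s: (
            s.log2_ns_wt is None,
            -(s.log2_ns_wt if s.log2_ns_wt is not None else 0.0),
            s.accession_field,
            s.peptide_sequence,
        ),
    )
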