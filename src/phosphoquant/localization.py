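"""Phosphosite localization: resolving site positions from phosphoRS-style
probabilities and mapping peptide coordinates onto protein sequences.

A phosphosite is *localized* when some candidate S/T/Y residue reaches the
probability cutoff (default 75%, inclusive); otherwise the site is
*ambiguous* and the search engine's reported position is kept only as a
provisional coordinate.  Localization probabilities are inputs — they come
from the upstream search pipeline and are never recomputed or invented here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .psm_io import ProteinRecord, PsmRecord

LOCALIZED = "localized"
AMBIGUOUS = "ambiguous"
AMBIGUOUS_ANNOTATED = "ambiguous-but-annotated"


@dataclass(frozen=True)
class SiteAssignment:
    """A phosphosite call on a protein.

    ``peptide_position`` indexes the peptide, ``protein_position`` the full
    protein, both 1-based.  ``protein_position`` may be None before the
    peptide has been mapped onto its protein.  ``probability_pct`` is absent
    for ambiguous assignments.
    """

    protein_accession: str
    peptide_sequence: str
    peptide_position: int
    residue: str
    status: str = LOCALIZED
    protein_position: int | None = None
    probability_pct: float | None = None
    mapping_ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.status not in (LOCALIZED, AMBIGUOUS, AMBIGUOUS_ANNOTATED):
            raise ValueError(f"bad status {self.status!r}")
        if self.residue not in "STY":
            raise ValueError(f"phosphosite residue must be S/T/Y, got {self.residue!r}")

    @property
    def is_localized(self) -> bool:
        return self.status == LOCALIZED

    def label(self) -> str:
        """Site label in the published style, e.g. ``Y716``; ``ambiguous``
        when the site could not be determined."""
        if self.status == AMBIGUOUS:
            return AMBIGUOUS
        if self.protein_position is None:
            return f"{self.residue}{self.peptide_position}(pep)"
        return f"{self.residue}{self.protein_position}"


def resolve_sites(
    psm: PsmRecord, cutoff_pct: float = 75.0, inclusive: bool = True
) -> list[SiteAssignment]:
    """Resolve each phospho moiety on a PSM to a localized or ambiguous site.

    For every phospho modification the candidate position with the highest
    probability is taken; the assignment is localized when that probability
    meets the cutoff (inclusively by default).  A tie at the cutoff between
    two candidates competing for the same moiety yields an ambiguous call —
    no arbitrary winner.  Candidates already consumed by a previous moiety of
    the same peptide are not reused.

    Returns one assignment per phospho moiety (empty list for
    non-phosphopeptides).  A PSM carrying more phospho groups than S/T/Y
    residues is inconsistent and raises ``ValueError``.
    """
    n_sty = sum(1 for aa in psm.sequence if aa in "STY")
    if psm.n_phospho > n_sty:
        raise ValueError(
            f"PSM {psm.psm_id}: {psm.n_phospho} phospho groups but only "
            f"{n_sty} S/T/Y residues"
        )

    def meets(p: float) -> bool:
        return p >= cutoff_pct if inclusive else p > cutoff_pct

    assignments: list[SiteAssignment] = []
    taken: set[int] = set()
    # reported positions in ascending order keeps resolution deterministic
    for reported_pos in psm.phospho_positions:
        candidates = {
            pos: prob
            for pos, prob in psm.site_probabilities.items()
            if pos not in taken
        }
        best_pos: int | None = None
        if candidates:
            top = max(candidates.values())
            winners = [p for p, pr in candidates.items() if pr == top]
            if meets(top) and len(winners) == 1:
                best_pos = winners[0]
        if best_pos is not None:
            taken.add(best_pos)
            assignments.append(
                SiteAssignment(
                    protein_accession=psm.protein_accession,
                    peptide_sequence=psm.sequence,
                    peptide_position=best_pos,
                    residue=psm.sequence[best_pos - 1],
                    status=LOCALIZED,
                    probability_pct=psm.site_probabilities[best_pos],
                )
            )
        else:
            residue = psm.sequence[reported_pos - 1]
            if residue not in "STY":
                # reported coordinate is off an S/T/Y; fall back to the top
                # candidate's residue letter if probabilities exist
                if candidates:
                    fallback = max(candidates, key=lambda p: (candidates[p], -p))
                    reported_pos = fallback
                    residue = psm.sequence[fallback - 1]
                else:
                    raise ValueError(
                        f"PSM {psm.psm_id}: phospho at non-S/T/Y position "
                        f"{reported_pos} with no candidates"
                    )
            assignments.append(
                SiteAssignment(
                    protein_accession=psm.protein_accession,
                    peptide_sequence=psm.sequence,
                    peptide_position=reported_pos,
                    residue=residue,
                    status=AMBIGUOUS,
                )
            )
    return assignments


def map_peptide_to_protein(peptide: str, protein: ProteinRecord) -> list[int]:
    """All 1-based start offsets of ``peptide`` in the protein sequence.

    Overlapping occurrences are reported.  Zero or multiple matches signal a
    mapping ambiguity to the caller (empty list / list of length > 1).
    """
    offsets: list[int] = []
    start = protein.sequence.find(peptide)
    while start != -1:
        offsets.append(start + 1)
        start = protein.sequence.find(peptide, start + 1)
    return offsets


def locate_assignment(
    assignment: SiteAssignment, protein: ProteinRecord
) -> SiteAssignment:
    """Fill in ``protein_position`` for an assignment by exact peptide search.

    protein_position = peptide start offset + peptide_position - 1.  When the
    peptide maps to several places (or nowhere) the first offset (or None) is
    used and ``mapping_ambiguous`` is set.  For a uniquely mapped, localized
    assignment the protein residue is checked against the assignment's
    residue letter.
    """
    offsets = map_peptide_to_protein(assignment.peptide_sequence, protein)
    if not offsets:
        return replace(assignment, protein_position=None, mapping_ambiguous=True)
    position = offsets[0] + assignment.peptide_position - 1
    if len(offsets) == 1 and assignment.is_localized:
        actual = protein.sequence[position - 1]
        if actual != assignment.residue:
            raise ValueError(
                f"residue mismatch: {assignment.residue} at protein position "
                f"{position} of {protein.accession} is {actual}"
            )
    return replace(
        assignment,
        protein_position=position,
        mapping_ambiguous=len(offsets) > 1,
    )


def per_accession_assignments(
    assignment: SiteAssignment, proteins: Sequence[ProteinRecord]
) -> list[SiteAssignment]:
    """Expand a shared-peptide assignment to one located assignment per
    accession (mirrors 'Cdk1; Cdk2 ... Y19; Y19' style result rows)."""
    out = []
    by_acc = {p.accession: p for p in proteins}
    for acc in assignment.protein_accession.split(";"):
        acc = acc.strip()
        if not acc:
            continue
        single = replace(assignment, protein_accession=acc)
        if acc in by_acc:
            single = locate_assignment(single, by_acc[acc])
        out.append(single)
    return out
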