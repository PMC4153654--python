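"""Cross-species phosphosite annotation.

Source-organism site positions are carried onto a human ortholog by global
pairwise alignment (Needleman-Wunsch with affine gaps; BLOSUM62, gap open 11,
extend 1 by default): the human residue aligned to the source position gives
the human site coordinate, or the site is unmapped when that column is a gap.
Protein assignment for unannotated peptides uses exact substring search over
the supplied proteome — tryptic peptides are exact subsequences of their
parent protein, so for identification purposes this matches what a BLAST
search of the peptide would return for exact hits.  Database lookups of the
"most commonly identified site" for ambiguous peptides are abstracted to an
offline, user-supplied two-column table so the pipeline runs hermetically.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .localization import AMBIGUOUS, AMBIGUOUS_ANNOTATED, SiteAssignment
from .psm_io import ProteinRecord


@dataclass(frozen=True)
class OrthologSiteMap:
    """Correspondence of one source-organism site to a human ortholog site."""

    source_accession: str
    human_accession: str
    source_position: int  # 1-based
    human_position: int | None  # None = aligned to a gap
    source_residue: str
    human_residue: str | None
    aligned_residue_match: bool
    alignment_identity_pct: float


def make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 11.0, gap_extend: float = 1.0
) -> Align.PairwiseAligner:
    """Global affine-gap protein aligner with the configured scoring."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def align_and_map(
    source: ProteinRecord,
    human: ProteinRecord,
    position: int,
    aligner: Align.PairwiseAligner | None = None,
) -> OrthologSiteMap:
    """Map a 1-based source-protein position onto the human ortholog.

    The best-scoring global alignment is computed; the alignment column
    holding ``position`` yields the human coordinate.  Identity percent is
    the fraction of matching residue pairs over columns where both sequences
    are aligned (gap columns excluded).
    """
    if not 1 <= position <= len(source.sequence):
        raise ValueError(
            f"position {position} outside {source.accession} "
            f"(length {len(source.sequence)})"
        )
    aligner = aligner or make_aligner()
    alignment = aligner.align(source.sequence, human.sequence)[0]

    pos0 = position - 1
    human_pos0: int | None = None
    matches = 0
    aligned_cols = 0
    for (s_start, s_end), (h_start, h_end) in zip(*alignment.aligned):
        for k in range(s_end - s_start):
            aligned_cols += 1
            if source.sequence[s_start + k] == human.sequence[h_start + k]:
                matches += 1
        if s_start <= pos0 < s_end:
            human_pos0 = h_start + (pos0 - s_start)
    identity = 100.0 * matches / aligned_cols if aligned_cols else 0.0

    source_res = source.sequence[pos0]
    human_res = human.sequence[human_pos0] if human_pos0 is not None else None
    return OrthologSiteMap(
        source_accession=source.accession,
        human_accession=human.accession,
        source_position=position,
        human_position=human_pos0 + 1 if human_pos0 is not None else None,
        source_residue=source_res,
        human_residue=human_res,
        aligned_residue_match=human_res == source_res,
        alignment_identity_pct=identity,
    )


def assign_protein_by_search(
    peptide: str, proteome: Sequence[ProteinRecord]
) -> list[str]:
    """Accessions of all proteome entries containing ``peptide`` exactly.

    Deterministic: hits are returned in proteome order.  Empty list when the
    peptide occurs nowhere.
    """
    if not proteome:
        raise ValueError("proteome is empty")
    return [p.accession for p in proteome if peptide in p.sequence]


class KnownSiteTableError(ValueError):
    pass


def read_known_site_table(path: str | Path) -> dict[str, int]:
    """Read the offline known-site table: TSV of peptide sequence -> preferred
    1-based site position within the peptide.  Duplicate peptide keys and
    malformed rows are fatal (message carries the row number)."""
    table: dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for i, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if i == 1 and row[0].strip().lower() in ("peptide", "sequence"):
                continue
            if len(row) < 2:
                raise KnownSiteTableError(f"row {i}: expected 2 columns")
            peptide = row[0].strip().upper()
            try:
                position = int(row[1])
            except ValueError as exc:
                raise KnownSiteTableError(
                    f"row {i}: bad position {row[1]!r}"
                ) from exc
            if position < 1:
                raise KnownSiteTableError(f"row {i}: position must be >= 1")
            if peptide in table:
                raise KnownSiteTableError(
                    f"row {i}: duplicate peptide key {peptide!r}"
                )
            table[peptide] = position
    return table


def apply_known_site_table(
    site: SiteAssignment, table: dict[str, int]
) -> SiteAssignment:
    """Annotate an ambiguous site from the known-site table.

    A matching peptide supplies its preferred position; the status becomes
    ``ambiguous-but-annotated`` (the localization evidence itself has not
    improved).  Localized sites and peptides absent from the table pass
    through unchanged.
    """
    if site.status != AMBIGUOUS:
        return site
    position = table.get(site.peptide_sequence)
    if position is None:
        return site
    if position > len(site.peptide_sequence):
        raise KnownSiteTableError(
            f"table position {position} outside peptide "
            f"{site.peptide_sequence!r}"
        )
    return replace(
        site,
        peptide_position=position,
        residue=site.peptide_sequence[position - 1],
        status=AMBIGUOUS_ANNOTATED,
        protein_position=None,  # must be re-located on the protein
    )
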