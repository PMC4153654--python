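"""Reading and writing of PSM export tables, FASTA collections and result tables.

The PSM reader targets Proteome-Discoverer-1.3-style delimited exports: one row
per peptide-spectrum match with the peptide sequence, a modification string,
per-channel quantities (or precomputed channel/light ratios), a Mascot ion
score, precursor mass error in ppm, and phosphoRS-style per-residue
localization probabilities.  Column names are configurable; the defaults below
follow the PD 1.3 export headers.  Decimal separator is configurable because
published tables in this field frequently use comma decimals.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

CHANNELS = ("light", "medium", "heavy")

MOD_KINDS = frozenset(
    {
        "phospho",
        "dimethyl_light",
        "dimethyl_medium",
        "dimethyl_heavy",
        "carbamidomethyl",
        "oxidation",
    }
)

#: Proteome Discoverer modification names -> canonical kinds.  The three
#: dimethyl isotopologues are distinguished by their isotope composition tags.
_PD_MOD_NAMES = {
    "phospho": "phospho",
    "dimethyl": "dimethyl_light",
    "dimethyl:2h(4)": "dimethyl_medium",
    "dimethyl:2h(6)13c(2)": "dimethyl_heavy",
    "carbamidomethyl": "carbamidomethyl",
    "oxidation": "oxidation",
}
_MOD_NAME_BY_KIND = {
    "phospho": "Phospho",
    "dimethyl_light": "Dimethyl",
    "dimethyl_medium": "Dimethyl:2H(4)",
    "dimethyl_heavy": "Dimethyl:2H(6)13C(2)",
    "carbamidomethyl": "Carbamidomethyl",
    "oxidation": "Oxidation",
}

#: Default column mapping (canonical field -> header in the file).
DEFAULT_COLUMNS: dict[str, str] = {
    "psm_id": "PSM ID",
    "sequence": "Sequence",
    "modifications": "Modifications",
    "protein_accession": "Protein Group Accessions",
    "protein_description": "Protein Descriptions",
    "is_decoy": "Decoy",
    "rank": "Rank",
    "ion_score": "IonScore",
    "mass_error_ppm": "DeltaM [ppm]",
    "retention_time_min": "RT [min]",
    "light": "Light",
    "medium": "Medium",
    "heavy": "Heavy",
    "ratio_medium_light": "Medium/Light",
    "ratio_heavy_light": "Heavy/Light",
    "site_probabilities": "phosphoRS Site Probabilities",
}

#: Columns that must be present in every PSM table.  Quantities and ratios are
#: individually optional (either representation is accepted) and validated
#: separately.
MANDATORY_FIELDS = (
    "psm_id",
    "sequence",
    "modifications",
    "protein_accession",
    "is_decoy",
    "rank",
    "ion_score",
    "mass_error_ppm",
    "site_probabilities",
)


class PsmTableError(ValueError):
    """Fatal problem in a PSM table (missing column, duplicate id, bad row)."""


class FastaError(ValueError):
    """Fatal problem in a FASTA input."""


@dataclass(frozen=True)
class Modification:
    """A single variable or fixed modification on a peptide.

    ``position`` is the 1-based residue index within the peptide, or the
    string ``"N-term"`` for amino-terminal labels.
    """

    position: int | str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in MOD_KINDS:
            raise ValueError(f"unknown modification kind: {self.kind!r}")
        if isinstance(self.position, str) and self.position != "N-term":
            raise ValueError(f"bad modification position: {self.position!r}")


@dataclass
class PsmRecord:
    """One peptide-spectrum match.

    ``channel_quantity`` maps each dimethyl channel to a positive abundance or
    ``None`` when the channel was not observed.  ``ratio_medium_light`` /
    ``ratio_heavy_light`` carry precomputed ratios when the export provides
    them; they take precedence over quantities downstream.
    ``site_probabilities`` maps candidate S/T/Y peptide positions (1-based) to
    phosphoRS-style percentages in [0, 100].
    """

    psm_id: str
    sequence: str
    modifications: list[Modification]
    protein_accession: str
    protein_description: str = ""
    is_decoy: bool = False
    rank: int = 1
    ion_score: float = 0.0
    mass_error_ppm: float = 0.0
    retention_time_min: float = 0.0
    channel_quantity: dict[str, float | None] = field(
        default_factory=lambda: {c: None for c in CHANNELS}
    )
    ratio_medium_light: float | None = None
    ratio_heavy_light: float | None = None
    site_probabilities: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for mod in self.modifications:
            if isinstance(mod.position, int) and not 1 <= mod.position <= n:
                raise ValueError(
                    f"PSM {self.psm_id}: modification position {mod.position} "
                    f"outside peptide of length {n}"
                )
        for pos in self.site_probabilities:
            if not 1 <= pos <= n or self.sequence[pos - 1] not in "STY":
                raise ValueError(
                    f"PSM {self.psm_id}: site probability at position {pos} "
                    "is not on an S/T/Y residue"
                )

    @property
    def accessions(self) -> list[str]:
        """Accession list for shared peptides ('Q7T3L7;Q7ZWB1' style cells)."""
        return [a.strip() for a in self.protein_accession.split(";") if a.strip()]

    @property
    def phospho_positions(self) -> list[int]:
        return sorted(
            m.position
            for m in self.modifications
            if m.kind == "phospho" and isinstance(m.position, int)
        )

    @property
    def n_phospho(self) -> int:
        return sum(1 for m in self.modifications if m.kind == "phospho")

    @property
    def is_phosphopeptide(self) -> bool:
        return self.n_phospho > 0

    @property
    def n_present_channels(self) -> int:
        return sum(1 for v in self.channel_quantity.values() if v is not None)

    @property
    def is_quantifiable(self) -> bool:
        """At most one missing channel, or precomputed ratios present."""
        if self.ratio_medium_light is not None or self.ratio_heavy_light is not None:
            return True
        return self.n_present_channels >= 2


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its organism role (source organism or human)."""

    accession: str
    organism_tag: str  # "source" | "human"
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - set("ACDEFGHIKLMNPQRSTVWYX")
        if bad:
            raise ValueError(
                f"{self.accession}: non-standard residues {sorted(bad)}"
            )


# ---------------------------------------------------------------------------
# value parsing helpers
# ---------------------------------------------------------------------------

_MINUS_VARIANTS = re.compile("[−–—]")  # −, –, — -> ASCII


def parse_decimal(text: str, decimal_comma: bool = False) -> float:
    """Parse a real number, tolerating typographic minus signs and, when
    ``decimal_comma`` is set, comma decimal separators (``"−1,91"`` -> -1.91).
    """
    s = _MINUS_VARIANTS.sub("-", text.strip())
    if decimal_comma:
        s = s.replace(",", ".")
    return float(s)


def _parse_optional_positive(text: str, decimal_comma: bool) -> float | None:
    """Channel quantities / ratios: empty or non-positive -> missing."""
    if text is None or str(text).strip() in ("", "nan", "NaN", "NA"):
        return None
    value = parse_decimal(str(text), decimal_comma)
    if not math.isfinite(value) or value <= 0:
        return None
    return value


_TRUE_TOKENS = {"true", "1", "yes", "y", "t"}
_FALSE_TOKENS = {"false", "0", "no", "n", "f", ""}


def _parse_bool(text: str) -> bool:
    token = str(text).strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise ValueError(f"cannot interpret {text!r} as a boolean")


_MOD_TOKEN = re.compile(r"^(?:(N-?Term)|([A-Z])(\d+))\(([^)]+)\)$", re.IGNORECASE)


def parse_modifications(text: str) -> list[Modification]:
    """Parse a PD-style modification string.

    Example: ``"N-Term(Dimethyl); K8(Dimethyl:2H(4)); Y7(Phospho)"``.
    Nested parentheses in isotope tags are handled by matching on the final
    closing bracket.
    """
    mods: list[Modification] = []
    if not text or not text.strip():
        return mods
    for raw in _split_mod_string(text):
        token = raw.strip()
        if not token:
            continue
        head, _, tail = token.partition("(")
        # strip only the final bracket: isotope tags nest parentheses,
        # e.g. "Dimethyl:2H(6)13C(2)"
        name = tail[:-1] if tail.endswith(")") else tail
        kind = _PD_MOD_NAMES.get(name.strip().lower())
        if kind is None:
            raise ValueError(f"unknown modification name in {token!r}")
        head = head.strip()
        if head.lower().replace("-", "") == "nterm":
            position: int | str = "N-term"
        else:
            m = re.match(r"^([A-Za-z])(\d+)$", head)
            if not m:
                raise ValueError(f"bad modification token {token!r}")
            position = int(m.group(2))
        mods.append(Modification(position=position, kind=kind))
    return mods


def _split_mod_string(text: str) -> Iterable[str]:
    """Split on ';' at bracket depth zero (isotope tags contain parentheses)."""
    depth = 0
    buf: list[str] = []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == ";" and depth == 0:
            yield "".join(buf)
            buf = []
        else:
            buf.append(ch)
    if buf:
        yield "".join(buf)


def format_modifications(mods: Sequence[Modification]) -> str:
    parts = []
    for m in mods:
        name = _MOD_NAME_BY_KIND[m.kind]
        if m.position == "N-term":
            parts.append(f"N-Term({name})")
        else:
            parts.append(f"X{m.position}({name})")
    return "; ".join(parts)


_PROB_TOKEN = re.compile(r"([A-Z])\((\d+)\)\s*:\s*([0-9.,−-]+)")


def parse_site_probabilities(text: str, decimal_comma: bool = False) -> dict[int, float]:
    """Parse phosphoRS-style probabilities: ``"Y(7): 98.2; S(8): 1.8"``."""
    probs: dict[int, float] = {}
    if not text or not str(text).strip():
        return probs
    for m in _PROB_TOKEN.finditer(str(text)):
        pos = int(m.group(2))
        probs[pos] = parse_decimal(m.group(3), decimal_comma)
    return probs


def format_site_probabilities(sequence: str, probs: Mapping[int, float]) -> str:
    return "; ".join(
        f"{sequence[pos - 1]}({pos}): {probs[pos]:g}" for pos in sorted(probs)
    )


# ---------------------------------------------------------------------------
# table reading
# ---------------------------------------------------------------------------


def read_psm_table(
    path: str | Path,
    dialect: str = "tsv",
    decimal_comma: bool = False,
    columns: Mapping[str, str] | None = None,
) -> list[PsmRecord]:
    """Read a PSM export table into :class:`PsmRecord` objects.

    Parameters
    ----------
    path:
        Delimited text file with a header row.
    dialect:
        ``"tsv"`` (default) or ``"csv"``.
    decimal_comma:
        Interpret ``","`` as the decimal separator in numeric cells.
    columns:
        Overrides for :data:`DEFAULT_COLUMNS` (canonical field -> header).

    Raises
    ------
    PsmTableError
        Missing mandatory column, duplicate psm_id, or a row whose mandatory
        fields cannot be parsed (the message carries the 1-based data row
        index).
    """
    path = Path(path)
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    if decimal_comma and dialect == "csv":
        raise PsmTableError("decimal_comma requires the tsv dialect")
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)

    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for fld in MANDATORY_FIELDS:
        if colmap[fld] not in frame.columns:
            raise PsmTableError(f"missing mandatory column: {colmap[fld]!r}")
    has_quant = all(colmap[c] in frame.columns for c in CHANNELS)
    has_ratios = (
        colmap["ratio_medium_light"] in frame.columns
        and colmap["ratio_heavy_light"] in frame.columns
    )
    if not has_quant and not has_ratios:
        raise PsmTableError(
            "need either channel quantity columns "
            f"({', '.join(colmap[c] for c in CHANNELS)}) or ratio columns"
        )

    records: list[PsmRecord] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        cells = dict(zip(frame.columns, row))

        def cell(fld: str) -> str:
            return cells.get(colmap[fld], "")

        try:
            quantities: dict[str, float | None] = {c: None for c in CHANNELS}
            if has_quant:
                for c in CHANNELS:
                    quantities[c] = _parse_optional_positive(cell(c), decimal_comma)
            rml = rhl = None
            if has_ratios:
                rml = _parse_optional_positive(
                    cell("ratio_medium_light"), decimal_comma
                )
                rhl = _parse_optional_positive(
                    cell("ratio_heavy_light"), decimal_comma
                )
            rec = PsmRecord(
                psm_id=cell("psm_id").strip(),
                sequence=cell("sequence").strip().upper(),
                modifications=parse_modifications(cell("modifications")),
                protein_accession=cell("protein_accession").strip(),
                protein_description=cell("protein_description").strip(),
                is_decoy=_parse_bool(cell("is_decoy")),
                rank=int(cell("rank")),
                ion_score=parse_decimal(cell("ion_score"), decimal_comma),
                mass_error_ppm=parse_decimal(cell("mass_error_ppm"), decimal_comma),
                retention_time_min=(
                    parse_decimal(cell("retention_time_min"), decimal_comma)
                    if colmap["retention_time_min"] in frame.columns
                    and cell("retention_time_min").strip()
                    else 0.0
                ),
                channel_quantity=quantities,
                ratio_medium_light=rml,
                ratio_heavy_light=rhl,
                site_probabilities=parse_site_probabilities(
                    cell("site_probabilities"), decimal_comma
                ),
            )
        except (ValueError, KeyError) as exc:
            raise PsmTableError(f"row {i}: {exc}") from exc
        if not rec.psm_id:
            raise PsmTableError(f"row {i}: empty psm_id")
        if rec.psm_id in seen_ids:
            raise PsmTableError(f"row {i}: duplicate psm_id {rec.psm_id!r}")
        seen_ids.add(rec.psm_id)
        records.append(rec)
    return records


def write_psm_table(
    records: Sequence[PsmRecord],
    path: str | Path,
    dialect: str = "tsv",
    columns: Mapping[str, str] | None = None,
) -> None:
    """Write PSM records in the same schema :func:`read_psm_table` consumes."""
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    sep = "\t" if dialect == "tsv" else ","

    def fmt(v: float | None) -> str:
        return "" if v is None else format(v, ".10g")

    rows = []
    for r in records:
        rows.append(
            {
                colmap["psm_id"]: r.psm_id,
                colmap["sequence"]: r.sequence,
                colmap["modifications"]: _format_mods_with_residues(r),
                colmap["protein_accession"]: r.protein_accession,
                colmap["protein_description"]: r.protein_description,
                colmap["is_decoy"]: str(r.is_decoy),
                colmap["rank"]: str(r.rank),
                colmap["ion_score"]: format(r.ion_score, ".10g"),
                colmap["mass_error_ppm"]: format(r.mass_error_ppm, ".10g"),
                colmap["retention_time_min"]: format(r.retention_time_min, ".10g"),
                colmap["light"]: fmt(r.channel_quantity["light"]),
                colmap["medium"]: fmt(r.channel_quantity["medium"]),
                colmap["heavy"]: fmt(r.channel_quantity["heavy"]),
                colmap["ratio_medium_light"]: fmt(r.ratio_medium_light),
                colmap["ratio_heavy_light"]: fmt(r.ratio_heavy_light),
                colmap["site_probabilities"]: format_site_probabilities(
                    r.sequence, r.site_probabilities
                ),
            }
        )
    header = [colmap[f] for f in DEFAULT_COLUMNS]
    frame = pd.DataFrame(rows, columns=header)
    frame.to_csv(path, sep=sep, index=False)


def _format_mods_with_residues(rec: PsmRecord) -> str:
    parts = []
    for m in rec.modifications:
        name = _MOD_NAME_BY_KIND[m.kind]
        if m.position == "N-term":
            parts.append(f"N-Term({name})")
        else:
            parts.append(f"{rec.sequence[m.position - 1]}{m.position}({name})")
    return "; ".join(parts)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, organism_tag: str = "source") -> list[ProteinRecord]:
    """Read a FASTA file; the accession is the first whitespace-delimited
    token of the header.  Sequences are upper-cased.  Duplicate accessions and
    empty files are fatal.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        accession = entry.id
        if accession in seen:
            raise FastaError(f"duplicate accession: {accession}")
        seen.add(accession)
        description = entry.description[len(entry.id):].strip()
        records.append(
            ProteinRecord(
                accession=accession,
                organism_tag=organism_tag,
                sequence=str(entry.seq).upper(),
                description=description,
            )
        )
    if not records:
        raise FastaError(f"no FASTA entries in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.accession
            if rec.description:
                header += f" {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# results table
# ---------------------------------------------------------------------------

RESULTS_COLUMNS = [
    "protein",
    "accession",
    "peptide",
    "site_source",
    "site_human",
    "log2_ns_wt",
    "log2_ls_wt",
    "significant_ns",
    "significant_ls",
    "quadrant",
    "n_psms",
]


def annotate_peptide(sequence: str, localized_positions: Iterable[int]) -> str:
    """Render a peptide with ``(pX)`` marks on localized phosphosites only,
    e.g. ``MEPVV(pY)ADIR``.  Ambiguous peptides are rendered unannotated.
    """
    marked = sorted(set(localized_positions))
    out: list[str] = []
    for i, aa in enumerate(sequence, start=1):
        out.append(f"(p{aa})" if i in marked else aa)
    return "".join(out)


def write_results_table(sites: Sequence, path: str | Path) -> None:
    """Write quantified sites as a TSV mirroring the published table layout.

    Row order is deterministic: descending NS/WT Log2 with missing values
    last, ties broken by accession then peptide sequence.  Ambiguous sites
    carry the literal token ``ambiguous`` in the site columns.
    """
    from .classification import rank_table  # local import: avoid cycle

    ordered = rank_table(list(sites))

    def fmt(v: float | None) -> str:
        return "" if v is None else f"{v:.2f}"

    rows = []
    for s in ordered:
        rows.append(
            {
                "protein": s.protein_name,
                "accession": s.accession_field,
                "peptide": s.annotated_peptide,
                "site_source": s.site_source_label,
                "site_human": s.site_human_label,
                "log2_ns_wt": fmt(s.log2_ns_wt),
                "log2_ls_wt": fmt(s.log2_ls_wt),
                "significant_ns": str(bool(s.significant_ns)),
                "significant_ls": str(bool(s.significant_ls)),
                "quadrant": s.quadrant if s.quadrant is not None else "",
                "n_psms": str(s.n_psms),
            }
        )
    frame = pd.DataFrame(rows, columns=RESULTS_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)
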