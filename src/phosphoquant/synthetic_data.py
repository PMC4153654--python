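"""Synthetic triplex dimethyl phosphoproteomics data.

Two generators live here.  :func:`simulate` draws a randomized dataset with
the statistical structure the analysis assumes — a large excess of
non-phosphopeptides over a minority of phosphosites, three channels mixed at
unequal totals (medium/light 1.38, heavy/light 2.35 by default), lognormal
ratio noise, decoy PSMs with a down-shifted score distribution, a fraction of
ambiguously localized sites, randomly missing channels, and abundant
actin/keratin/vitellogenin-style contaminant proteins.  Every dataset is
accompanied by a :class:`SyntheticTruth` sidecar recording the true Log2
effects, mixing factors, decoy flags and true cross-species site coordinates,
so recovery can be scored exactly.

:func:`make_toy_fixture` writes a small, fully hand-specified 50-PSM dataset
(no randomness) whose expected pipeline output is analytic: every
phosphopeptide quantity is light x mixing x 2^effect exactly, so the
normalized Log2 ratios equal the chosen effects.

Both generators emit the same column schema the PSM reader consumes; there is
no synthetic-only code path through the pipeline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .psm_io import (
    Modification,
    ProteinRecord,
    PsmRecord,
    write_fasta,
    write_psm_table,
)

# K/R excluded (tryptic terminators added separately); C excluded so the
# generated data needs no fixed carbamidomethylation bookkeeping.
_SEGMENT_ALPHABET = "ADEFGHILMNPQSTVWY"

_CONTAMINANT_DESCRIPTIONS = (
    "actin-like contaminant protein",
    "keratin-like contaminant protein",
    "vitellogenin-like contaminant protein",
)


@dataclass
class SimConfig:
    """Parameters of the randomized generator.

    The mixing factors default to the unequal channel totals the analysis is
    designed to remove (medium/light 1.38, heavy/light 2.35).  When
    ``log2_effects`` is None, true site effects are drawn as 80% null and 10%
    up / 10% down with |Log2| in [1.2, 2.5]; an explicit list is cycled over
    the phosphosites instead.
    """

    seed: int = 0
    n_proteins: int = 40
    n_nonphospho_psms: int = 600
    n_phospho_sites: int = 69
    psms_per_site: int = 4
    mixing_medium: float = 1.38
    mixing_heavy: float = 2.35
    log2_effects: list[float] | None = None
    ratio_noise_sigma_log2: float = 0.25
    frac_ambiguous: float = 0.2
    frac_decoy: float = 0.05
    frac_missing_channel: float = 0.1
    contaminant_fraction: float = 0.3
    ortholog_sub_rate: float = 0.03
    ortholog_n_indels: int = 1
    ortholog_indel_max_len: int = 3

    def __post_init__(self) -> None:
        for name in (
            "frac_ambiguous",
            "frac_decoy",
            "frac_missing_channel",
            "contaminant_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_proteins", "n_nonphospho_psms", "n_phospho_sites",
                     "psms_per_site"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mixing_medium <= 0 or self.mixing_heavy <= 0:
            raise ValueError("mixing factors must be positive")
        if self.ratio_noise_sigma_log2 < 0:
            raise ValueError("ratio_noise_sigma_log2 must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside every generated dataset."""

    mixing_medium: float
    mixing_heavy: float
    sites: list[dict] = field(default_factory=list)
    decoy_psm_ids: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        data = json.loads(text)
        return cls(**data)


@dataclass
class ProteomePair:
    """Generated source proteome with derived human 'orthologs'.

    ``position_maps[accession]`` holds, for each 1-based source position, the
    corresponding 1-based human position or None where the residue was
    deleted in the ortholog.
    """

    source: list[ProteinRecord]
    human: list[ProteinRecord]
    pairs: dict[str, str]
    position_maps: dict[str, list[int | None]]


# ---------------------------------------------------------------------------
# proteome generation
# ---------------------------------------------------------------------------


def _random_protein_sequence(rng: np.random.Generator, n_segments: int) -> str:
    parts = ["M"]
    for _ in range(n_segments):
        length = int(rng.integers(5, 15))
        seg = "".join(rng.choice(list(_SEGMENT_ALPHABET), size=length))
        parts.append(seg + str(rng.choice(["K", "R"])))
    return "".join(parts)


def _pick_indel_position(
    rng: np.random.Generator, seq: str, length: int
) -> int:
    """Deletion start (0-based) whose boundaries differ from their context,
    keeping the optimal alignment's gap placement unique."""
    for _ in range(50):
        p = int(rng.integers(1, len(seq) - length - 1))
        block = seq[p : p + length]
        if seq[p - 1] != block[0] and seq[p + length] != block[-1]:
            return p
    return int(rng.integers(1, len(seq) - length - 1))


def _derive_ortholog(
    seq: str, rng: np.random.Generator, cfg: SimConfig
) -> tuple[str, list[int | None]]:
    """Apply seeded point substitutions and indels; return the edited
    sequence and the 1-based source->human position map."""
    n = len(seq)
    substituted = list(seq)
    for i in range(1, n):  # keep the initiator M
        if seq[i] in "KR":
            continue  # preserve tryptic structure
        if rng.random() < cfg.ortholog_sub_rate:
            choices = [a for a in _SEGMENT_ALPHABET if a != seq[i]]
            substituted[i] = str(rng.choice(choices))

    deleted: set[int] = set()
    insert_after: dict[int, str] = {}
    for _ in range(cfg.ortholog_n_indels):
        length = int(rng.integers(1, cfg.ortholog_indel_max_len + 1))
        if rng.random() < 0.5:
            p = _pick_indel_position(rng, seq, length)
            deleted.update(range(p, p + length))
        else:
            p = int(rng.integers(1, n - 1))
            left = substituted[p]
            ins = []
            for _ in range(length):
                choices = [a for a in _SEGMENT_ALPHABET if a != left]
                left = str(rng.choice(choices))
                ins.append(left)
            insert_after[p] = "".join(ins)

    human_chars: list[str] = []
    pos_map: list[int | None] = [None] * n
    for i in range(n):
        if i not in deleted:
            human_chars.append(substituted[i])
            pos_map[i] = len(human_chars)
        if i in insert_after:
            human_chars.extend(insert_after[i])
    return "".join(human_chars), pos_map


def generate_proteome(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> ProteomePair:
    """Random source proteins with controlled tryptic K/R spacing, plus human
    orthologs derived by seeded edits so true site offsets are known.  The
    first three proteins are abundant-contaminant analogs (they receive no
    phosphosites and no ortholog)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    source: list[ProteinRecord] = []
    human: list[ProteinRecord] = []
    pairs: dict[str, str] = {}
    position_maps: dict[str, list[int | None]] = {}

    n_contaminants = min(3, cfg.n_proteins)
    for i in range(cfg.n_proteins):
        is_cont = i < n_contaminants
        acc = f"CONT{i + 1:02d}" if is_cont else f"SRC{i + 1:04d}"
        desc = (
            _CONTAMINANT_DESCRIPTIONS[i % 3]
            if is_cont
            else f"synthetic protein {i + 1}"
        )
        seq = _random_protein_sequence(rng, n_segments=int(rng.integers(15, 30)))
        source.append(
            ProteinRecord(accession=acc, organism_tag="source",
                          sequence=seq, description=desc)
        )
        if is_cont:
            continue
        hum_acc = f"HUM{i + 1:04d}"
        hum_seq, pos_map = _derive_ortholog(seq, rng, cfg)
        human.append(
            ProteinRecord(accession=hum_acc, organism_tag="human",
                          sequence=hum_seq,
                          description=f"human ortholog of {acc}")
        )
        pairs[acc] = hum_acc
        position_maps[acc] = pos_map
    return ProteomePair(source=source, human=human, pairs=pairs,
                        position_maps=position_maps)


# ---------------------------------------------------------------------------
# PSM generation
# ---------------------------------------------------------------------------


def _tryptic_peptides(sequence: str) -> list[tuple[int, str]]:
    """(1-based start, peptide) for fully tryptic fragments (cut after K/R)."""
    peptides = []
    start = 0
    for i, aa in enumerate(sequence):
        if aa in "KR":
            peptides.append((start + 1, sequence[start : i + 1]))
            start = i + 1
    if start < len(sequence):
        peptides.append((start + 1, sequence[start:]))
    return peptides


def _dimethyl_mods(sequence: str) -> list[Modification]:
    mods = [Modification(position="N-term", kind="dimethyl_light")]
    for i, aa in enumerate(sequence, start=1):
        if aa == "K":
            mods.append(Modification(position=i, kind="dimethyl_light"))
    return mods


def _draw_effects(cfg: SimConfig, rng: np.random.Generator) -> list[float]:
    if cfg.log2_effects is not None:
        reps = [cfg.log2_effects[i % len(cfg.log2_effects)]
                for i in range(cfg.n_phospho_sites)]
        return reps
    effects = []
    for _ in range(cfg.n_phospho_sites):
        u = rng.random()
        if u < 0.8:
            effects.append(0.0)
        else:
            mag = float(rng.uniform(1.2, 2.5))
            effects.append(mag if u < 0.9 else -mag)
    return effects


def _channel_quantities(
    cfg: SimConfig, effect: float, rng: np.random.Generator
) -> dict[str, float | None]:
    light = float(np.exp(rng.normal(np.log(1e6), 0.5)))
    sigma = cfg.ratio_noise_sigma_log2
    medium = light * cfg.mixing_medium * 2.0 ** (effect + rng.normal(0, sigma))
    heavy = light * cfg.mixing_heavy * 2.0 ** (effect + rng.normal(0, sigma))
    q: dict[str, float | None] = {
        "light": light, "medium": float(medium), "heavy": float(heavy)
    }
    if rng.random() < cfg.frac_missing_channel:
        q[str(rng.choice(["light", "medium", "heavy"]))] = None
    return q


def _site_probabilities(
    sequence: str,
    site_pos: int,
    ambiguous: bool,
    rng: np.random.Generator,
) -> dict[int, float]:
    candidates = [i for i, aa in enumerate(sequence, start=1) if aa in "STY"]
    others = [p for p in candidates if p != site_pos]
    probs: dict[int, float] = {}
    if ambiguous and others:
        top = float(rng.uniform(40, 74))
        second = float(rng.uniform(0.8, 0.95)) * (100 - top)
        probs[site_pos] = round(top, 1)
        probs[others[0]] = round(second, 1)
        rest = 100 - probs[site_pos] - probs[others[0]]
        for p in others[1:]:
            probs[p] = round(rest / len(others[1:]), 1)
    else:
        top = float(rng.uniform(90, 99.9))
        probs[site_pos] = round(top, 1)
        for p in others:
            probs[p] = round((100 - top) / max(1, len(others)), 1)
    return probs


def generate_psm_table(
    cfg: SimConfig,
    proteome: ProteomePair,
    rng: np.random.Generator | None = None,
) -> tuple[list[PsmRecord], SyntheticTruth]:
    """Draw the PSM table and its ground truth.

    Non-phosphopeptide PSMs carry effect 0 and establish the normalization
    medians; phosphopeptide PSMs multiply in their site's true Log2 effect.
    A ``frac_decoy`` fraction of non-phospho PSMs become reversed-sequence
    decoys with a down-shifted score distribution.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    truth = SyntheticTruth(
        mixing_medium=cfg.mixing_medium, mixing_heavy=cfg.mixing_heavy
    )
    records: list[PsmRecord] = []

    contaminants = [p for p in proteome.source if p.accession.startswith("CONT")]
    regulars = [p for p in proteome.source if not p.accession.startswith("CONT")]

    # --- phosphosites ------------------------------------------------------
    site_pool: list[tuple[ProteinRecord, int, str, list[int]]] = []
    for prot in regulars:
        for start, pep in _tryptic_peptides(prot.sequence):
            if len(pep) < 6 or len(pep) > 30:
                continue
            sty = [i for i, aa in enumerate(pep, start=1) if aa in "STY"]
            if sty:
                site_pool.append((prot, start, pep, sty))
    if len(site_pool) < cfg.n_phospho_sites:
        raise ValueError(
            "proteome too small for the requested number of phosphosites"
        )
    chosen = rng.choice(len(site_pool), size=cfg.n_phospho_sites, replace=False)
    effects = _draw_effects(cfg, rng)

    for site_idx, (pool_idx, effect) in enumerate(zip(chosen, effects)):
        prot, start, pep, sty = site_pool[int(pool_idx)]
        # prefer tyrosines (pTyr-enrichment analog)
        ys = [p for p in sty if pep[p - 1] == "Y"]
        pep_pos = int(rng.choice(ys)) if ys and rng.random() < 0.85 else int(
            rng.choice(sty)
        )
        ambiguous = len(sty) > 1 and rng.random() < cfg.frac_ambiguous
        protein_position = start + pep_pos - 1
        pos_map = proteome.position_maps[prot.accession]
        human_position = pos_map[protein_position - 1]
        truth.sites.append(
            {
                "site_id": f"site{site_idx:04d}",
                "accession": prot.accession,
                "peptide": pep,
                "peptide_position": pep_pos,
                "protein_position": protein_position,
                "residue": pep[pep_pos - 1],
                "true_log2": float(effect),
                "ambiguous": bool(ambiguous),
                "human_accession": proteome.pairs[prot.accession],
                "human_position": human_position,
            }
        )
        for j in range(cfg.psms_per_site):
            mods = _dimethyl_mods(pep) + [
                Modification(position=pep_pos, kind="phospho")
            ]
            records.append(
                PsmRecord(
                    psm_id=f"pho{site_idx:04d}_{j}",
                    sequence=pep,
                    modifications=mods,
                    protein_accession=prot.accession,
                    protein_description=prot.description,
                    is_decoy=False,
                    rank=1 if rng.random() < 0.98 else 2,
                    ion_score=float(max(1.0, rng.normal(45, 10))),
                    mass_error_ppm=float(rng.normal(0, 2.5)),
                    retention_time_min=float(rng.uniform(10, 120)),
                    channel_quantity=_channel_quantities(cfg, effect, rng),
                    site_probabilities=_site_probabilities(
                        pep, pep_pos, ambiguous, rng
                    ),
                )
            )

    # --- non-phosphopeptides ----------------------------------------------
    nonphospho_pool: list[tuple[ProteinRecord, str]] = []
    for prot in regulars + contaminants:
        for _, pep in _tryptic_peptides(prot.sequence):
            if 6 <= len(pep) <= 30:
                nonphospho_pool.append((prot, pep))
    cont_pool = [(p, s) for p, s in nonphospho_pool
                 if p.accession.startswith("CONT")]
    reg_pool = [(p, s) for p, s in nonphospho_pool
                if not p.accession.startswith("CONT")]

    for i in range(cfg.n_nonphospho_psms):
        pool = cont_pool if (cont_pool and rng.random() <
                             cfg.contaminant_fraction) else reg_pool
        prot, pep = pool[int(rng.integers(0, len(pool)))]
        psm_id = f"non{i:05d}"
        is_decoy = rng.random() < cfg.frac_decoy
        sequence = pep
        accession = prot.accession
        description = prot.description
        score = float(max(1.0, rng.normal(45, 10)))
        if is_decoy:
            sequence = pep[::-1]
            accession = f"DECOY_{prot.accession}"
            description = f"decoy of {prot.accession}"
            score = float(max(0.5, rng.normal(12, 6)))
            truth.decoy_psm_ids.append(psm_id)
        records.append(
            PsmRecord(
                psm_id=psm_id,
                sequence=sequence,
                modifications=_dimethyl_mods(sequence),
                protein_accession=accession,
                protein_description=description,
                is_decoy=is_decoy,
                rank=1 if rng.random() < 0.98 else 2,
                ion_score=score,
                mass_error_ppm=float(rng.normal(0, 2.5)),
                retention_time_min=float(rng.uniform(10, 120)),
                channel_quantity=_channel_quantities(cfg, 0.0, rng),
            )
        )
    return records, truth


def simulate(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a full dataset on disk: psms.tsv, source.fasta, human.fasta,
    ortholog_pairs.tsv and truth.json.  Identical configs produce
    byte-identical outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    proteome = generate_proteome(cfg, rng)
    records, truth = generate_psm_table(cfg, proteome, rng)

    paths = {
        "psms": outdir / "psms.tsv",
        "source_fasta": outdir / "source.fasta",
        "human_fasta": outdir / "human.fasta",
        "pairs": outdir / "ortholog_pairs.tsv",
        "truth": outdir / "truth.json",
    }
    write_psm_table(records, paths["psms"])
    write_fasta(proteome.source, paths["source_fasta"])
    write_fasta(proteome.human, paths["human_fasta"])
    with open(paths["pairs"], "w") as fh:
        fh.write("source_accession\thuman_accession\n")
        for src, hum in proteome.pairs.items():
            fh.write(f"{src}\t{hum}\n")
    paths["truth"].write_text(truth.to_json() + "\n")
    return paths


# ---------------------------------------------------------------------------
# hand-specified toy fixture
# ---------------------------------------------------------------------------

_TOY_SOURCE = [
    ("PROTA", "kinase A-like",
     "MLAGELFNKSAMPDYINKDDSAYLQGKNQSEYFDTKTAILR"),
    ("PROTB", "receptor B-like",
     "MVSTDNPEAGKTSPLYQDEKMEGVVYADLRAGLNK"),
    ("PROTC", "kinase C-like", "MGGEYTVVMKLDNGGFYLSKEPLNR"),
    ("PROTD", "kinase D-like", "MAVDSTLKGGEYTVVMKQSVNR"),
    ("ACTL1", "actin-like contaminant protein", "MGLSDEIANKAVFPSIVGR"),
    ("KRTL1", "keratin-like contaminant protein", "MTTPELGFNRSLDLDSIIAK"),
    ("VTGL1", "vitellogenin-like contaminant protein",
     "MEGVNDNEEGFFSARLSPIQNK"),
]

# HUMA: 'LA' (source 2-3) deleted, T37->S substitution: sites shift -2.
# HUMB: 'GGS' inserted after source position 11: sites shift +3.
# HUMC: identical to PROTC.  HUMD: 'A' (source 2) deleted: sites shift -1.
_TOY_HUMAN = [
    ("HUMA", "human ortholog of PROTA",
     "MGELFNKSAMPDYINKDDSAYLQGKNQSEYFDTKSAILR"),
    ("HUMB", "human ortholog of PROTB",
     "MVSTDNPEAGKGGSTSPLYQDEKMEGVVYADLRAGLNK"),
    ("HUMC", "human ortholog of PROTC", "MGGEYTVVMKLDNGGFYLSKEPLNR"),
    ("HUMD", "human ortholog of PROTD", "MVDSTLKGGEYTVVMKQSVNR"),
]

_TOY_PAIRS = [("PROTA", "HUMA"), ("PROTB", "HUMB"),
              ("PROTC", "HUMC"), ("PROTD", "HUMD")]

#: ambiguous peptide -> preferred site position (offline known-site table)
_TOY_KNOWN_SITES = [("TSPLYQDEK", 5)]

# Non-phospho medium quantities: 32 rows at exactly 138 plus the symmetric
# variants below keep the median at 138 (and heavy at 235) exactly.
_TOY_NP_MEDIUM_VARIANTS = [120.0, 125.0, 130.0, 145.0, 150.0]
_TOY_NP_HEAVY_VARIANTS = [200.0, 210.0, 220.0, 250.0, 260.0]

_TOY_NP_PEPTIDES = [
    ("LAGELFNK", "PROTA", "kinase A-like"),
    ("VSTDNPEAGK", "PROTB", "receptor B-like"),
    ("GLSDEIANK", "ACTL1", "actin-like contaminant protein"),
    ("TTPELGFNR", "KRTL1", "keratin-like contaminant protein"),
    ("EGVNDNEEGFFSAR", "VTGL1", "vitellogenin-like contaminant protein"),
    ("AVFPSIVGR", "ACTL1", "actin-like contaminant protein"),
]


def _toy_phospho_row(
    psm_id: str,
    pep: str,
    accession: str,
    description: str,
    site_pos: int,
    probs: dict[int, float],
    effect_ns: float,
    effect_ls: float | None,
    light: float = 1000.0,
) -> PsmRecord:
    medium = light * 1.38 * 2.0 ** effect_ns
    heavy = None if effect_ls is None else light * 2.35 * 2.0 ** effect_ls
    return PsmRecord(
        psm_id=psm_id,
        sequence=pep,
        modifications=_dimethyl_mods(pep)
        + [Modification(position=site_pos, kind="phospho")],
        protein_accession=accession,
        protein_description=description,
        is_decoy=False,
        rank=1,
        ion_score=52.0,
        mass_error_ppm=1.2,
        retention_time_min=42.0,
        channel_quantity={"light": light, "medium": medium, "heavy": heavy},
        site_probabilities=probs,
    )


def make_toy_records() -> list[PsmRecord]:
    """The 50 hand-specified toy PSMs (37 accepted non-phospho, 8 accepted
    phospho, 1 filter-passing decoy, 4 filter-rejected rows)."""
    records: list[PsmRecord] = []
    for i in range(37):
        pep, acc, desc = _TOY_NP_PEPTIDES[i % len(_TOY_NP_PEPTIDES)]
        medium = (_TOY_NP_MEDIUM_VARIANTS[i] if i < 5 else 138.0)
        heavy = (_TOY_NP_HEAVY_VARIANTS[i] if i < 5 else 235.0)
        records.append(
            PsmRecord(
                psm_id=f"NP{i + 1:03d}",
                sequence=pep,
                modifications=_dimethyl_mods(pep),
                protein_accession=acc,
                protein_description=desc,
                rank=1,
                ion_score=48.0,
                mass_error_ppm=-0.8,
                retention_time_min=30.0 + i,
                channel_quantity={"light": 100.0, "medium": medium,
                                  "heavy": heavy},
            )
        )

    # P1 (Fer-analog, 2 PSMs): localized Y, strongly down in both channels
    for j, psm_id in enumerate(["PP01a", "PP01b"]):
        records.append(
            _toy_phospho_row(psm_id, "SAMPDYINK", "PROTA", "kinase A-like",
                             6, {6: 99.0, 1: 1.0}, -1.91, -1.47)
        )
    # P2: localized Y, up in both channels
    records.append(
        _toy_phospho_row("PP02a", "MEGVVYADLR", "PROTB", "receptor B-like",
                         6, {6: 100.0}, 2.95, 1.77)
    )
    # P3: ambiguous localization (all probabilities < 75)
    records.append(
        _toy_phospho_row("PP03a", "TSPLYQDEK", "PROTB", "receptor B-like",
                         5, {1: 15.0, 2: 25.0, 5: 60.0}, -1.18, -0.48)
    )
    # P4: mixed evidence — localized PSM kept, ambiguous PSM dropped
    records.append(
        _toy_phospho_row("PP04a", "DDSAYLQGK", "PROTA", "kinase A-like",
                         5, {3: 2.0, 5: 98.0}, 1.50, 0.40)
    )
    records.append(
        _toy_phospho_row("PP04b", "DDSAYLQGK", "PROTA", "kinase A-like",
                         5, {3: 30.0, 5: 70.0}, 3.00, 3.00)
    )
    # P5: shared peptide (two accessions), significant in LS only
    records.append(
        _toy_phospho_row("PP05a", "GGEYTVVMK", "PROTC;PROTD",
                         "kinase C-like; kinase D-like",
                         4, {4: 97.0, 5: 3.0}, 0.00, 1.92)
    )
    # P6: heavy channel missing — NS ratio only
    records.append(
        _toy_phospho_row("PP06a", "NQSEYFDTK", "PROTA", "kinase A-like",
                         5, {3: 2.0, 5: 96.0, 8: 2.0}, 1.20, None)
    )

    # decoy passing every quality rule (enters the FDR estimate only)
    records.append(
        PsmRecord(
            psm_id="DEC01",
            sequence="KNFLEGAL",  # reversed LAGELFNK
            modifications=_dimethyl_mods("KNFLEGAL"),
            protein_accession="DECOY_PROTA",
            protein_description="decoy of PROTA",
            is_decoy=True,
            rank=1,
            ion_score=45.0,
            mass_error_ppm=0.3,
            retention_time_min=55.0,
            channel_quantity={"light": 100.0, "medium": 140.0, "heavy": 230.0},
        )
    )
    # filter-rejected rows: low score, bad ppm, short peptide, rank 2
    records.append(
        PsmRecord(
            psm_id="REJ01", sequence="LAGELFNK",
            modifications=_dimethyl_mods("LAGELFNK"),
            protein_accession="PROTA", protein_description="kinase A-like",
            rank=1, ion_score=10.0, mass_error_ppm=0.5,
            channel_quantity={"light": 100.0, "medium": 138.0, "heavy": 235.0},
        )
    )
    records.append(
        PsmRecord(
            psm_id="REJ02", sequence="VSTDNPEAGK",
            modifications=_dimethyl_mods("VSTDNPEAGK"),
            protein_accession="PROTB", protein_description="receptor B-like",
            rank=1, ion_score=40.0, mass_error_ppm=15.0,
            channel_quantity={"light": 100.0, "medium": 138.0, "heavy": 235.0},
        )
    )
    records.append(
        PsmRecord(
            psm_id="REJ03", sequence="SAYK",
            modifications=_dimethyl_mods("SAYK")
            + [Modification(position=3, kind="phospho")],
            protein_accession="PROTA", protein_description="kinase A-like",
            rank=1, ion_score=50.0, mass_error_ppm=0.0,
            channel_quantity={"light": 100.0, "medium": 138.0, "heavy": 235.0},
            site_probabilities={3: 99.0, 1: 1.0},
        )
    )
    records.append(
        PsmRecord(
            psm_id="REJ04", sequence="GLSDEIANK",
            modifications=_dimethyl_mods("GLSDEIANK"),
            protein_accession="ACTL1",
            protein_description="actin-like contaminant protein",
            rank=2, ion_score=35.0, mass_error_ppm=0.1,
            channel_quantity={"light": 100.0, "medium": 138.0, "heavy": 235.0},
        )
    )
    assert len(records) == 50
    return records


def make_toy_fixture(outdir: str | Path) -> dict[str, Path]:
    """Write the deterministic toy dataset (PSM table, FASTAs, ortholog pair
    table, known-site table) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "psms": outdir / "toy_psms.tsv",
        "source_fasta": outdir / "toy_source.fasta",
        "human_fasta": outdir / "toy_human.fasta",
        "pairs": outdir / "toy_pairs.tsv",
        "known_sites": outdir / "toy_known_sites.tsv",
    }
    write_psm_table(make_toy_records(), paths["psms"])
    write_fasta(
        [ProteinRecord(a, "source", s, d) for a, d, s in _TOY_SOURCE],
        paths["source_fasta"],
    )
    write_fasta(
        [ProteinRecord(a, "human", s, d) for a, d, s in _TOY_HUMAN],
        paths["human_fasta"],
    )
    with open(paths["pairs"], "w") as fh:
        fh.write("source_accession\thuman_accession\n")
        for src, hum in _TOY_PAIRS:
            fh.write(f"{src}\t{hum}\n")
    with open(paths["known_sites"], "w") as fh:
        fh.write("peptide\tposition\n")
        for pep, pos in _TOY_KNOWN_SITES:
            fh.write(f"{pep}\t{pos}\n")
    return paths
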