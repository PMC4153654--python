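"""End-to-end pipeline: read -> filter -> localize -> quantify -> classify ->
annotate -> write, plus the run summary.

The stages run in a fixed order and the whole pipeline is deterministic:
identical inputs and configuration yield identical output bytes.  Every
fatal error is re-raised with the failing stage's name prefixed so a run log
pinpoints where an input went wrong.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Sequence

from . import annotation as anno
from . import classification, filtering, localization, quantification
from . import psm_io
from .config import PipelineConfig
from .localization import AMBIGUOUS
from .quantification import NormalizationFactors, QuantifiedSite

log = logging.getLogger("phosphoquant")


class StageError(RuntimeError):
    """An error wrapped with the name of the pipeline stage that raised it."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"[{name}] {exc}") from exc
            log.info("stage %-10s done in %.3f s", name, time.perf_counter() - t0)
            return result

        return wrapper

    return deco


def annotate_sites(
    sites: Sequence[QuantifiedSite],
    source_proteins: Sequence[psm_io.ProteinRecord],
    human_proteins: Sequence[psm_io.ProteinRecord],
    pairs: dict[str, str],
    known_sites: dict[str, int] | None = None,
    aligner=None,
) -> list[QuantifiedSite]:
    """Locate each site on its source protein(s) and map it to the paired
    human ortholog by global alignment.

    Shared peptides yield one coordinate per accession, rendered as
    ``"Y19; Y19"``; several phosphosites on one peptide are rendered
    ``"Y55, Y57"`` within each accession.  Ambiguous sites are first looked
    up in the offline known-site table (when provided); sites that stay
    unresolvable carry the literal ``ambiguous`` label and an empty human
    column.  A source site aligned to a gap keeps its row with the human
    column left empty.
    """
    by_src = {p.accession: p for p in source_proteins}
    by_hum = {p.accession: p for p in human_proteins}
    out: list[QuantifiedSite] = []
    for qs in sites:
        accessions = [a.strip() for a in qs.accession_field.split(";") if a.strip()]
        src_parts: list[str] = []
        hum_parts: list[str] = []
        any_located = False
        for acc in accessions:
            prot = by_src.get(acc)
            moiety_src: list[str] = []
            moiety_hum: list[str] = []
            for site in qs.sites:
                a = site
                if known_sites is not None and a.status == AMBIGUOUS:
                    a = anno.apply_known_site_table(a, known_sites)
                if a.status == AMBIGUOUS or prot is None:
                    moiety_src.append(a.label() if prot is not None else AMBIGUOUS)
                    continue
                a = localization.locate_assignment(
                    dataclasses.replace(a, protein_accession=acc), prot
                )
                moiety_src.append(a.label())
                if a.protein_position is None:
                    continue
                any_located = True
                hum_acc = pairs.get(acc)
                human = by_hum.get(hum_acc) if hum_acc else None
                if human is None:
                    continue
                mapping = anno.align_and_map(
                    prot, human, a.protein_position, aligner=aligner
                )
                if mapping.human_position is not None:
                    moiety_hum.append(
                        f"{mapping.human_residue}{mapping.human_position}"
                    )
            src_parts.append(", ".join(moiety_src) if moiety_src else AMBIGUOUS)
            if moiety_hum:
                hum_parts.append(", ".join(moiety_hum))
        if any_located:
            qs.site_source_label = "; ".join(src_parts)
            qs.site_human_label = "; ".join(hum_parts)
        else:
            qs.site_source_label = AMBIGUOUS if qs.is_ambiguous else "; ".join(
                src_parts
            )
            qs.site_human_label = ""
        out.append(qs)
    return out


def run_pipeline(
    psms_path: str | Path,
    proteome_path: str | Path,
    out_path: str | Path,
    human_path: str | Path | None = None,
    pairs_path: str | Path | None = None,
    known_sites_path: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> tuple[list[QuantifiedSite], filtering.FilterReport, dict]:
    """Run every stage and write the results table plus its sidecars.

    Writes ``<out>`` (results TSV), ``<out>.filter_report.tsv`` and
    ``<out>.summary.json``.  Returns (sites, filter report, summary).
    """
    cfg = config or PipelineConfig()
    log.info("resolved config:\n%s", cfg.to_yaml())
    out_path = Path(out_path)

    read = _stage("read")(_read_inputs)
    psms, source_proteins, human_proteins, pairs, known = read(
        psms_path, proteome_path, human_path, pairs_path, known_sites_path, cfg
    )

    accepted, report = _stage("filter")(filtering.apply_filters)(
        psms, cfg.filters
    )
    if report.fdr_exceeded:
        log.warning(
            "estimated FDR %.4f exceeds max_fdr %.3f",
            report.estimated_fdr,
            cfg.filters.max_fdr,
        )

    factors: NormalizationFactors | None
    phospho = [p for p in accepted if p.is_phosphopeptide]
    if phospho:
        factors = _stage("normalize")(quantification.compute_normalization)(
            accepted, cfg.quantification.min_nonphospho
        )
        sites = _stage("quantify")(quantification.aggregate)(
            accepted,
            factors,
            cutoff_pct=cfg.localization.cutoff_pct,
            inclusive=cfg.localization.inclusive,
            method=cfg.quantification.aggregate,
        )
        def _classify_all(all_sites):
            called = [
                quantification.call_significance(s, cfg.quantification.sig_log2)
                for s in all_sites
            ]
            return [classification.classify(s) for s in called]

        sites = _stage("classify")(_classify_all)(sites)
        aligner = anno.make_aligner(
            cfg.annotation.matrix,
            cfg.annotation.gap_open,
            cfg.annotation.gap_extend,
        )
        sites = _stage("annotate")(annotate_sites)(
            sites, source_proteins, human_proteins, pairs, known, aligner
        )
    else:
        factors = None
        sites = []

    _stage("write")(psm_io.write_results_table)(sites, out_path)
    _write_filter_report(report, Path(str(out_path) + ".filter_report.tsv"))
    summary = summarize(sites, report, factors)
    Path(str(out_path) + ".summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    for line in report.to_lines():
        log.info("%s", line)
    return sites, report, summary


def _read_inputs(psms_path, proteome_path, human_path, pairs_path,
                 known_sites_path, cfg: PipelineConfig):
    psms = psm_io.read_psm_table(
        psms_path,
        dialect=cfg.io.dialect,
        decimal_comma=cfg.io.decimal_comma,
        columns=cfg.io.columns or None,
    )
    source_proteins = psm_io.read_fasta(proteome_path, organism_tag="source")
    human_proteins = (
        psm_io.read_fasta(human_path, organism_tag="human")
        if human_path
        else []
    )
    pairs: dict[str, str] = {}
    if pairs_path:
        with open(pairs_path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                cols = line.split("\t")
                if i == 1 and cols[0].lower() == "source_accession":
                    continue
                if len(cols) < 2:
                    raise ValueError(f"ortholog pair table row {i}: expected 2 columns")
                pairs[cols[0]] = cols[1]
    known = (
        anno.read_known_site_table(known_sites_path)
        if known_sites_path
        else None
    )
    return psms, source_proteins, human_proteins, pairs, known


def _write_filter_report(report: filtering.FilterReport, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"n_input\t{report.n_input}\n")
        for rule in filtering.RULES:
            fh.write(f"rejected_{rule}\t{report.counts_per_rule[rule]}\n")
        fh.write(f"n_decoy_passed\t{report.n_decoy_passed}\n")
        fh.write(f"n_accepted\t{report.n_accepted}\n")
        fh.write(f"estimated_fdr\t{report.estimated_fdr:.6f}\n")


def summarize(
    sites: Sequence[QuantifiedSite],
    report: filtering.FilterReport | None = None,
    factors: NormalizationFactors | None = None,
) -> dict:
    """Headline counts of a run: quantified sites, localized pTyr sites,
    significant calls per channel, per-quadrant counts, and the
    normalization factors."""
    quadrants = {label: 0 for label in classification.ALL_LABELS}
    n_localized_ptyr = 0
    n_sig_ns = n_sig_ls = 0
    for s in sites:
        if s.quadrant:
            quadrants[s.quadrant] += 1
        if s.significant_ns:
            n_sig_ns += 1
        if s.significant_ls:
            n_sig_ls += 1
        if s.sites and all(a.is_localized for a in s.sites) and any(
            a.residue == "Y" for a in s.sites
        ):
            n_localized_ptyr += 1
    summary = {
        "n_quantified_sites": len(sites),
        "n_localized_ptyr_sites": n_localized_ptyr,
        "n_ambiguous_sites": sum(1 for s in sites if s.is_ambiguous),
        "n_significant_ns": n_sig_ns,
        "n_significant_ls": n_sig_ls,
        "quadrant_counts": quadrants,
    }
    if report is not None:
        summary["filter"] = {
            "n_input": report.n_input,
            "n_accepted": report.n_accepted,
            "estimated_fdr": report.estimated_fdr,
        }
    if factors is not None:
        summary["normalization"] = {
            "median_medium_over_light": factors.median_medium_over_light,
            "median_heavy_over_light": factors.median_heavy_over_light,
            "n_nonphospho_used": factors.n_nonphospho_used,
        }
    return summary
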