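"""End-to-end discovery pipeline.

Stages, in order: homology screen of toxin queries against the ORFs of each
genome -> flank extraction around each accepted hit -> four-element locus
annotation and classification -> repeat-unit extraction -> pseudoknot
prediction on the repeat unit -> in-silico digestion of the precursor array.
Hit proteins are then clustered by pairwise identity.

Outputs: one GFF3 per genome, a hits TSV, a clusters TSV and a JSON report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

from . import annotate as ann
from . import cleavage as clv
from . import homology as hom
from . import pseudoknot as pk
from .config import PipelineConfig
from .io import Feature, write_gff3

__all__ = ["PipelineError", "run_pipeline"]

logger = logging.getLogger("ta3scan")


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class _Hit:
    genome_id: str
    orf: ann.OrfHit
    protein: str
    query_id: str
    alignment: hom.AlignmentResult
    annotation: ann.TALocusAnnotation | None = None
    flank: ann.FlankRegion | None = None
    extras: dict = field(default_factory=dict)


def _orf_proteins(genome_seq: str, min_len: int) -> list[tuple[ann.OrfHit, str]]:
    out = []
    for orf in ann.find_orf(genome_seq, strand="+", min_len=min_len):
        s, e = orf.interval
        protein = str(Seq(genome_seq[s:e]).translate())
        protein = protein.rstrip("*")
        if "*" not in protein:
            out.append((orf, protein))
    return out


def run_pipeline(
    config: PipelineConfig,
    genomes: dict[str, str],
    queries: dict[str, str],
    outdir,
) -> dict:
    """Run the full discovery pipeline; returns the report dict.

    `genomes` and `queries` map identifiers to sequences (nucleotide and
    protein respectively). Artifacts are written under `outdir`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("thresholds: evalue<%g coverage>%g cluster>=%g repeat %d/%d/%d/%d",
                config.evalue_max, config.coverage_min, config.cluster_threshold,
                config.repeat_match, config.repeat_mismatch, config.repeat_indel,
                config.repeat_min_score)
    params = ann.RepeatFinderParams(
        match=config.repeat_match,
        mismatch=config.repeat_mismatch,
        indel=config.repeat_indel,
        min_score=config.repeat_min_score,
    )
    motif = clv.CleavageMotif(config.motif_pattern, config.motif_cut)

    # --- stage: homology -------------------------------------------------
    hits: list[_Hit] = []
    try:
        for gid, gseq in genomes.items():
            orfs = _orf_proteins(gseq, config.orf_min_codons)
            subjects = [p for _, p in orfs]
            for qid, qseq in queries.items():
                for (orf, protein) in orfs:
                    result = hom.local_align(
                        qseq, protein, gap_open=config.gap_open, gap_extend=config.gap_extend
                    )
                    if result is None:
                        continue
                    result.evalue = hom.estimate_evalue(
                        result, qseq, subjects, n_shuffles=config.n_shuffles, seed=config.seed
                    )
                    if hom.filter_hits([result], config.evalue_max, config.coverage_min):
                        hits.append(_Hit(gid, orf, protein, qid, result))
    except Exception as exc:
        raise PipelineError("homology", str(exc)) from exc
    # deduplicate: one hit per ORF (best evalue across queries), then one hit
    # per genomic region (nested/overlapping ORFs collapse to the longest)
    by_orf: dict[tuple[str, tuple[int, int]], _Hit] = {}
    for h in hits:
        key = (h.genome_id, h.orf.interval)
        if key not in by_orf or h.alignment.evalue < by_orf[key].alignment.evalue:
            by_orf[key] = h
    kept: list[_Hit] = []
    for h in sorted(
        by_orf.values(),
        key=lambda h: (h.genome_id, -h.orf.length, h.alignment.evalue, h.orf.interval),
    ):
        overlaps = any(
            k.genome_id == h.genome_id
            and h.orf.interval[0] < k.orf.interval[1]
            and k.orf.interval[0] < h.orf.interval[1]
            for k in kept
        )
        if not overlaps:
            kept.append(h)
    hits = kept
    logger.info("homology: %d accepted hits", len(hits))

    # --- stage: flanks + annotation + classification ---------------------
    try:
        for h in hits:
            h.flank = ann.extract_flanks(
                genomes[h.genome_id], h.orf.interval, config.flank_up, config.flank_down
            )
            h.annotation = ann.annotate_ta_locus(h.flank.sequence, params=params,
                                                 orf_min_len=config.orf_min_codons)
    except Exception as exc:
        raise PipelineError("annotation", str(exc)) from exc

    # --- stage: repeats -> pseudoknot -> digestion ------------------------
    try:
        for h in hits:
            a = h.annotation
            if a is None or a.repeats is None:
                continue
            unit_rna = a.repeats.consensus.replace("T", "U")
            structure = pk.predict_h_pseudoknot(
                unit_rna,
                scoring={"GC": config.score_gc, "AU": config.score_au, "GU": config.score_gu},
                min_bp=config.pseudoknot_min_bp,
            )
            h.extras["pseudoknot"] = None if structure is None else pk.to_bracket(structure)
            s, e = a.repeats.interval
            precursor = h.flank.sequence[s:e].replace("T", "U")
            fragments = clv.digest(precursor, motif)
            h.extras["n_fragments"] = len(fragments)
    except Exception as exc:
        raise PipelineError("structure", str(exc)) from exc

    # --- stage: clustering ------------------------------------------------
    clustering = None
    if len(hits) >= 2:
        try:
            labelled = {f"{h.genome_id}:{h.orf.interval[0]}-{h.orf.interval[1]}": h.protein for h in hits}
            matrix = hom.identity_matrix(labelled)
            clustering = hom.cluster_by_identity(matrix, config.cluster_threshold)
        except Exception as exc:
            raise PipelineError("clustering", str(exc)) from exc

    # --- outputs ----------------------------------------------------------
    try:
        hits_rows = []
        for h in hits:
            hits_rows.append(
                "\t".join(
                    [
                        h.query_id,
                        f"{h.genome_id}:{h.orf.interval[0]}-{h.orf.interval[1]}",
                        f"{h.alignment.score:g}",
                        f"{h.alignment.identity:.4f}",
                        f"{h.alignment.query_coverage:.4f}",
                        f"{h.alignment.evalue:.3g}",
                    ]
                )
            )
        (outdir / "hits.tsv").write_text(
            "query\tsubject\tscore\tidentity\tcoverage\tevalue\n"
            + "".join(r + "\n" for r in hits_rows)
        )
        if clustering is not None:
            rows = [f"{label}\t{cid}" for label, cid in sorted(clustering.assignments.items())]
            (outdir / "clusters.tsv").write_text("label\tcluster_id\n" + "".join(r + "\n" for r in rows))
        for gid in genomes:
            feats: list[Feature] = []
            pragmas: list[str] = []
            for h in hits:
                if h.genome_id != gid or h.annotation is None:
                    continue
                a = h.annotation
                off = h.flank.genome_start
                pairs = [
                    ("promoter_-35", None if a.promoter is None else a.promoter.minus35),
                    ("promoter_-10", None if a.promoter is None else a.promoter.minus10),
                    ("tandem_repeat_array", None if a.repeats is None else a.repeats.interval),
                    ("terminator", None if a.terminator is None else a.terminator.hairpin),
                    ("CDS", None if a.orf is None else a.orf.interval),
                ]
                for ftype, iv in pairs:
                    if iv is None:
                        continue
                    feats.append(Feature(seqid=gid, type=ftype, start=iv[0] + off, end=iv[1] + off))
                pragmas.append(
                    f"##ta3scan-verdict {gid}:{h.orf.interval[0]}-{h.orf.interval[1]} {a.verdict}"
                )
            write_gff3(feats, outdir / f"{gid}.gff3", pragmas=pragmas)
        report = {
            "n_genomes": len(genomes),
            "n_hits": len(hits),
            "thresholds": config.as_dict(),
            "hits": [
                {
                    "genome": h.genome_id,
                    "orf": list(h.orf.interval),
                    "query": h.query_id,
                    "evalue": h.alignment.evalue,
                    "coverage": h.alignment.query_coverage,
                    "verdict": h.annotation.verdict if h.annotation else None,
                    "failures": h.annotation.failures if h.annotation else None,
                    "repeat_period": h.annotation.repeats.period
                    if h.annotation and h.annotation.repeats
                    else None,
                    "repeat_copies": h.annotation.repeats.copies
                    if h.annotation and h.annotation.repeats
                    else None,
                    "pseudoknot": h.extras.get("pseudoknot"),
                    "n_fragments": h.extras.get("n_fragments"),
                }
                for h in sorted(hits, key=lambda h: (h.genome_id, h.orf.interval))
            ],
            "clusters": None
            if clustering is None
            else {
                "n_clusters": clustering.n_clusters,
                "assignments": dict(sorted(clustering.assignments.items())),
                "n_singletons": sum(
                    1
                    for cid in set(clustering.assignments.values())
                    if len(clustering.members(cid)) == 1
                ),
            },
        }
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("output", str(exc)) from exc
    return report
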