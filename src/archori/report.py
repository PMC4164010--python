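"""Tabular output: predictions (TSV/BED/GFF3), curves, hits and summaries.

All writers convert the internal 0-based half-open coordinates at the
boundary: TSV and GFF3 are 1-based inclusive, BED stays 0-based
half-open.  Intervals wrapping the coordinate origin of a circular
chromosome are written with ``end`` past the genome length, which keeps
start < end and round-trips through :func:`read_reference_intervals`.
"""

from __future__ import annotations

import csv

import pandas as pd

from .errors import InputError
from .genome_io import AnnotatedGenome
from .motif_scan import MotifHit
from .predictor import OriCPrediction
from .zcurve import ZCurveProfile


def predictions_frame(genome: AnnotatedGenome,
                      predictions: list[OriCPrediction]) -> pd.DataFrame:
    rows = []
    for p in predictions:
        flank = p.adjacent_roles[0] if p.adjacent_roles else None
        nearest = min(p.distance_to_extremum.items(), key=lambda kv: abs(kv[1]))
        rows.append({
            "accession": genome.accession,
            "start_1based": p.start + 1,
            "end_1based": p.end,
            "length": p.region.length,
            "rule": p.rule,
            "motif_count": p.motif_count,
            "adjacent_gene": flank[0].identifier if flank else "-",
            "adjacent_role": flank[1] if flank else "-",
            "at_content": round(p.at_content, 4),
            "nearest_extremum_bp": nearest[1],
            "nearest_extremum_curve": nearest[0],
            "n_repeats": len(p.repeats),
        })
    return pd.DataFrame(rows, columns=[
        "accession", "start_1based", "end_1based", "length", "rule",
        "motif_count", "adjacent_gene", "adjacent_role", "at_content",
        "nearest_extremum_bp", "nearest_extremum_curve", "n_repeats"])


def write_predictions_tsv(genome, predictions, path) -> None:
    predictions_frame(genome, predictions).to_csv(path, sep="\t", index=False)


def write_predictions_bed(genome, predictions, path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(predictions):
            fh.write(f"{genome.accession}\t{p.start}\t{p.end}\t"
                     f"oriC_{i + 1}\t{p.motif_count}\t.\n")


def write_predictions_gff3(genome, predictions, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, p in enumerate(predictions):
            oid = f"oriC_{i + 1}"
            fh.write(f"{genome.accession}\tarchori\treplication_origin\t"
                     f"{p.start + 1}\t{p.end}\t.\t.\t.\t"
                     f"ID={oid};rule={p.rule};motif_count={p.motif_count}\n")
            for j, h in enumerate(p.orb_hits):
                w = len(h.matched_sequence)
                fh.write(f"{genome.accession}\tarchori\tsequence_motif\t"
                         f"{h.genome_position + 1}\t{h.genome_position + w}\t"
                         f"{h.score:.2f}\t{h.strand}\t.\t"
                         f"ID={oid}_orb{j + 1};Parent={oid};"
                         f"motif={h.motif_name};pvalue={h.p_value:.3g}\n")


def hits_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "motif": h.motif_name,
        "start": h.genome_position,
        "end": h.genome_position + len(h.matched_sequence),
        "strand": h.strand,
        "score_bits": None if h.score is None else round(h.score, 3),
        "p_value": h.p_value,
        "sequence": h.matched_sequence,
    } for h in hits], columns=["motif", "start", "end", "strand",
                               "score_bits", "p_value", "sequence"])


def write_hits_tsv(hits: list[MotifHit], path) -> None:
    hits_frame(hits).to_csv(path, sep="\t", index=False)


def write_hits_bed(hits: list[MotifHit], accession: str, path) -> None:
    """BED6; score column is bits x 100 capped at 1000."""
    with open(path, "w") as fh:
        for h in hits:
            score = 0 if h.score is None else min(int(round(h.score * 100)), 1000)
            end = h.genome_position + len(h.matched_sequence)
            fh.write(f"{accession}\t{h.genome_position}\t{end}\t"
                     f"{h.motif_name}\t{score}\t{h.strand}\n")


def write_curves_tsv(profile: ZCurveProfile, path, step: int = 1) -> None:
    with open(path, "w") as fh:
        fh.write("position\tx\ty\tz\tat\tgc\n")
        at, gc = profile.at, profile.gc
        for i in range(0, profile.n + 1, step):
            fh.write(f"{i}\t{profile.x[i]}\t{profile.y[i]}\t{profile.z[i]}\t"
                     f"{at[i]:g}\t{gc[i]:g}\n")


def write_repeats_tsv(repeats, path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tpos1\tpos2\tlength\tsequence\tlow_complexity\n")
        for r in repeats:
            fh.write(f"{r.kind}\t{r.pos1}\t{r.pos2}\t{r.length}\t"
                     f"{r.sequence}\t{int(r.low_complexity)}\n")


def summary_text(genome: AnnotatedGenome, predictions,
                 replication_genes) -> str:
    """Plain-text run summary: genome size, GC content, replication-gene
    locations and the predicted origin regions."""
    lines = [
        f"accession          {genome.accession}",
        f"genome size        {genome.length} bp",
        f"GC content         {genome.gc_content * 100:.2f}%",
        f"replication genes  {len(replication_genes)}",
    ]
    for g in replication_genes:
        lines.append(f"  {g.identifier}  {g.start + 1}..{g.end} ({g.strand}) "
                     f"{g.role}: {g.product}")
    lines.append(f"predicted oriCs    {len(predictions)}")
    for i, p in enumerate(predictions):
        lines.append(f"  oriC_{i + 1}  {p.start + 1}..{p.end}  rule={p.rule}  "
                     f"ORB hits={p.motif_count}  AT={p.at_content * 100:.1f}%")
    return "\n".join(lines) + "\n"


def read_reference_intervals(path) -> list[tuple[int, int]]:
    """Reference origin intervals from BED (0-based half-open) or a
    2-column TSV of 1-based inclusive intervals."""
    intervals: list[tuple[int, int]] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith(("#", "track", "browser")):
                continue
            try:
                if len(row) >= 3 and not row[0].isdigit():
                    start, end = int(row[1]), int(row[2])  # BED
                else:
                    start, end = int(row[0]) - 1, int(row[1])  # 1-based TSV
            except (ValueError, IndexError) as exc:
                raise InputError(f"{path}: bad interval row {row!r}") from exc
            if end <= start:
                raise InputError(f"{path}: empty interval {row!r}")
            intervals.append((start, end))
    if not intervals:
        raise InputError(f"{path}: no reference intervals found")
    return intervals
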