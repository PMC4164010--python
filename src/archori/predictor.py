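"""Origin prediction rules and benchmark evaluation.

Two rules fire on intergenic regions of an annotated circular genome:

* **Rule A** (``gene_adjacent_orb``): the region's flanking genes include
  a replication-related role (Orc1/Cdc6, Whip, primase, ...) *and* the
  region contains at least one ORB motif hit at the PSSM p-value cutoff.
* **Rule B** (``multi_motif``): the region contains at least
  ``rule_b_min`` (default 3) ORB hits, regardless of its neighbours —
  the fallback for origins next to unrecognised replication genes.

Every prediction carries its full evidence bundle — motif hits, flanking
roles, AT content, internal repeats and the signed distance to the global
extremum of each disparity curve.  The disparity-extremum proximity is
*evidence only*, never a filter: the decision procedure gates on genes
and ORBs, the curves are context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UsageError
from .gene_roles import REPLICATION_ROLES, annotate_roles
from .genome_io import (AnnotatedGenome, GeneRecord, IntergenicRegion,
                        extract_intergenic)
from .motif_scan import (DEFAULT_P_CUTOFF, MotifHit, MotifModel, PValueTable,
                         scan_all, select_motifs)
from .repeats import RepeatHit, find_repeats
from .zcurve import COMPONENTS, compute_zcurve, find_extrema

RULE_GENE_ADJACENT = "gene_adjacent_orb"
RULE_MULTI_MOTIF = "multi_motif"


@dataclass
class PredictorConfig:
    """Thresholds of the decision procedure (all positive)."""

    p_cutoff: float = DEFAULT_P_CUTOFF
    min_intergenic: int = 50
    rule_b_min: int = 3
    repeat_min_len: int = 8
    include_repeats: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.p_cutoff < 1):
            raise UsageError(f"p_cutoff must be in (0, 1), got {self.p_cutoff}")
        if self.min_intergenic < 0 or self.rule_b_min < 1 or self.repeat_min_len < 4:
            raise UsageError("thresholds must be positive")


@dataclass
class OriCPrediction:
    """A candidate origin region with its evidence bundle."""

    region: IntergenicRegion
    rule: str
    orb_hits: list[MotifHit]
    adjacent_roles: list[tuple[GeneRecord, str]]
    at_content: float
    distance_to_extremum: dict[str, int]
    repeats: list[RepeatHit] = field(default_factory=list)

    @property
    def motif_count(self) -> int:
        return len(self.orb_hits)

    @property
    def start(self) -> int:
        return self.region.start

    @property
    def end(self) -> int:
        return self.region.end


def _signed_circular_distance(pos: int, target: int, n: int) -> int:
    """Signed shortest way from ``target`` to ``pos`` on a circle of size n."""
    d = (pos - target) % n
    return d if d <= n - d else d - n


def _at_content(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("A") + seq.count("T")) / len(seq)


def predict(genome: AnnotatedGenome,
            motifs: list[MotifModel] | None = None,
            config: PredictorConfig | None = None) -> list[OriCPrediction]:
    """Apply both decision rules to every intergenic region.

    ``motifs`` defaults to the built-in set filtered by the genome's
    taxonomy lineage plus the Common motif.  A region satisfying both
    rules is reported once under ``gene_adjacent_orb``.  Predictions are
    sorted by genome position.
    """
    if not genome.genes:
        raise UsageError("prediction requires an annotated genome with genes")
    config = config or PredictorConfig()
    if all(g.role == "none" for g in genome.genes):
        annotate_roles(genome)
    if motifs is None:
        motifs = select_motifs(genome.taxonomy)
    if not motifs:
        raise UsageError("motif set is empty")
    tables = {m.name: PValueTable(m) for m in motifs}

    profile = compute_zcurve(genome.sequence)
    extrema = {c: find_extrema(profile, c, include_local=False)
               for c in COMPONENTS}

    predictions: list[OriCPrediction] = []
    for region in extract_intergenic(genome, config.min_intergenic):
        hits = scan_all(motifs, region, config.p_cutoff, tables=tables)
        flanks = [g for g in (region.left_gene, region.right_gene) if g is not None]
        roles = [(g, g.role) for g in flanks if g.role in REPLICATION_ROLES]
        rule = None
        if roles and len(hits) >= 1:
            rule = RULE_GENE_ADJACENT
        elif len(hits) >= config.rule_b_min:
            rule = RULE_MULTI_MOTIF
        if rule is None:
            continue
        mid = region.midpoint()
        distances = {
            c: _signed_circular_distance(mid, ex["max_position"], genome.length)
            for c, ex in extrema.items()
        }
        reps = (find_repeats(region.sequence, config.repeat_min_len)
                if config.include_repeats else [])
        predictions.append(OriCPrediction(
            region=region,
            rule=rule,
            orb_hits=hits,
            adjacent_roles=roles,
            at_content=_at_content(region.sequence),
            distance_to_extremum=distances,
            repeats=reps,
        ))
    predictions.sort(key=lambda p: p.start)
    return predictions


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvaluationResult:
    """Sensitivity/precision of a prediction set against a reference."""

    true_positives: int
    reference_count: int
    predicted_count: int

    @property
    def sensitivity(self) -> float:
        return self.true_positives / self.reference_count

    @property
    def precision(self) -> float | None:
        if self.predicted_count == 0:
            return None  # undefined: no predictions made
        return self.true_positives / self.predicted_count

    @classmethod
    def from_counts(cls, true_positives: int, reference_count: int,
                    predicted_count: int) -> "EvaluationResult":
        if reference_count <= 0:
            raise UsageError("sensitivity is undefined for an empty reference")
        if not (0 <= true_positives <= min(reference_count, predicted_count)
                if predicted_count else true_positives == 0):
            raise UsageError("true positives exceed reference or prediction count")
        return cls(true_positives, reference_count, predicted_count)


def _overlap_length(a: tuple[int, int], b: tuple[int, int], n: int | None) -> int:
    """Overlap in bp of two half-open intervals, wrap-aware when n given."""
    (s1, e1), (s2, e2) = a, b
    candidates = [(s2, e2)]
    if n:
        candidates += [(s2 + n, e2 + n), (s2 - n, e2 - n)]
    best = 0
    for cs, ce in candidates:
        best = max(best, min(e1, ce) - max(s1, cs))
    return max(best, 0)


def _midpoint_match(pred: tuple[int, int], ref: tuple[int, int], n: int | None) -> bool:
    mid = (pred[0] + pred[1]) // 2
    if n:
        mid %= n
        for shift in (0, n, -n):
            if ref[0] <= mid + shift < ref[1]:
                return True
        return False
    return ref[0] <= mid < ref[1]


def evaluate(predictions, reference, match_rule: str = "overlap",
             genome_length: int | None = None) -> EvaluationResult:
    """Match predictions to reference intervals one-to-one, greedily.

    ``predictions`` is a list of :class:`OriCPrediction` or (start, end)
    pairs; ``reference`` a list of (start, end) pairs on the same 0-based
    half-open coordinate system.  Default ``match_rule='overlap'`` counts
    a reference as recovered when a prediction overlaps it by ≥ 1 bp,
    pairing greedily by decreasing overlap length; ``'midpoint'`` requires
    the prediction midpoint to fall inside the reference interval.
    """
    if not reference:
        raise UsageError("sensitivity is undefined for an empty reference")
    pred_iv = [(p.start, p.end) if isinstance(p, OriCPrediction) else tuple(p)
               for p in predictions]
    ref_iv = [tuple(r) for r in reference]
    pairs = []
    for i, p in enumerate(pred_iv):
        for j, r in enumerate(ref_iv):
            if match_rule == "overlap":
                w = _overlap_length(p, r, genome_length)
                if w > 0:
                    pairs.append((w, i, j))
            elif match_rule == "midpoint":
                if _midpoint_match(p, r, genome_length):
                    pairs.append((1, i, j))
            else:
                raise UsageError(f"unknown match_rule {match_rule!r}")
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_r: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_p or j in used_r:
            continue
        used_p.add(i)
        used_r.add(j)
        tp += 1
    return EvaluationResult(tp, len(ref_iv), len(pred_iv))
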