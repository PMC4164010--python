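"""Classify gene products as replication-related.

Archaeal replication origins sit next to a small set of gene families:
the Orc1/Cdc6 initiator, Whip (winged-helix initiator protein) and DNA
primase, with MCM helicase and replication factors as weaker markers.
Classification is keyword matching on the annotated product string,
case-insensitive substring semantics, with a fixed priority order so a
product mentioning several families gets the strongest role.

The keyword table is configurable (``role<TAB>keyword`` per line) because
no published, exhaustive list of replication-related products exists; the
default covers the families named above plus conservative extensions and
is a sensitivity knob of the whole predictor.
"""

from __future__ import annotations

from .errors import InputError
from .genome_io import AnnotatedGenome, ROLE_NONE

#: priority order: first matching role wins
ROLE_ORDER = ("orc1_cdc6", "whip", "primase", "other_replication")

DEFAULT_ROLE_KEYWORDS: dict[str, tuple[str, ...]] = {
    "orc1_cdc6": ("cdc6", "orc1", "cell division control protein 6", "orc "),
    "whip": ("whip", "winged-helix initiator"),
    "primase": ("primase",),
    "other_replication": ("minichromosome maintenance", "mcm",
                          "replication factor", "replication protein"),
}

REPLICATION_ROLES = frozenset(ROLE_ORDER)


def load_role_table(path) -> dict[str, tuple[str, ...]]:
    """Read a role<TAB>keyword table; later lines append to a role's list."""
    table: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            try:
                role, keyword = line.split("\t", 1)
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: expected role<TAB>keyword") from exc
            role = role.strip()
            if role not in ROLE_ORDER:
                raise InputError(f"{path}:{lineno}: unknown role {role!r}")
            # keep intentional whitespace (e.g. the word-boundary "orc ")
            table.setdefault(role, []).append(keyword.lower())
    if not table:
        raise InputError(f"role table {path} is empty")
    seen: dict[str, str] = {}
    for role, kws in table.items():
        for kw in kws:
            if kw in seen:
                raise InputError(f"keyword {kw!r} appears under both "
                                 f"{seen[kw]!r} and {role!r}")
            seen[kw] = role
    return {r: tuple(kws) for r, kws in table.items()}


def classify_gene(product: str,
                  table: dict[str, tuple[str, ...]] | None = None) -> str:
    """Role of a gene product string; ``'none'`` when no keyword matches."""
    table = table or DEFAULT_ROLE_KEYWORDS
    text = (product or "").lower()
    for role in ROLE_ORDER:
        for keyword in table.get(role, ()):
            if keyword in text:
                return role
    return ROLE_NONE


def annotate_roles(genome: AnnotatedGenome,
                   table: dict[str, tuple[str, ...]] | None = None) -> AnnotatedGenome:
    """Fill ``GeneRecord.role`` for every gene, in place; returns the genome."""
    for gene in genome.genes:
        gene.role = classify_gene(gene.product, table)
    return genome


def replication_genes(genome: AnnotatedGenome):
    """Genes carrying any replication-related role."""
    return [g for g in genome.genes if g.role in REPLICATION_ROLES]
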