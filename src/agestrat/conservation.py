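"""Conservation-class partition of a focal genome.

Each focal-species protein-coding gene is placed in exactly one of three
classes from an orthogroup table and a set of query species:

* ``non_core``   — the gene's orthogroup lacks members in at least one query
  species (default mode), or the gene belongs to no orthogroup at all;
* ``single_core`` — conserved in every query species and present as a
  single copy in the focal species (e.g. a housekeeping enzyme such as
  *HIS1* in *S. cerevisiae*);
* ``multi_core``  — conserved in every query species but duplicated in the
  focal species (e.g. the *GAL1*/*GAL3* paralog pair).

The classes are mutually exclusive and exhaustive over the supplied genes.
``noncore_mode="all"`` switches to the stricter reading where a gene is
non-core only when *every* query species lacks an ortholog.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError
from .io import OrthogroupTable

__all__ = ["ConservationAssignment", "classify_conservation"]

CLASSES = ("single_core", "multi_core", "non_core")


@dataclass(frozen=True)
class ConservationAssignment:
    gene: str
    cls: str  # one of CLASSES
    orthogroup_id: str | None


def classify_conservation(
    ortho: OrthogroupTable,
    focal: str,
    queries: Sequence[str],
    genes: Iterable[str] | None = None,
    noncore_mode: str = "any",
) -> list[ConservationAssignment]:
    """Partition focal genes into single-core / multi-core / non-core.

    Parameters
    ----------
    ortho
        Orthogroup membership across species.
    focal
        The focal species (a column of *ortho*).
    queries
        Non-empty query species against which conservation is judged.
    genes
        Focal genes to classify.  Defaults to every focal gene in *ortho*;
        supplied genes absent from any orthogroup are classified non_core
        (they were measured but have no predicted orthologs).
    noncore_mode
        ``"any"`` (default): non-core iff zero orthologs in >=1 query
        species.  ``"all"``: non-core iff zero orthologs in every query.
    """
    if noncore_mode not in ("any", "all"):
        raise ValidationError(f"unknown noncore_mode {noncore_mode!r}")
    if focal not in ortho.species:
        raise ValidationError(f"focal species {focal!r} not in orthogroup table")
    queries = list(queries)
    if not queries:
        raise ValidationError("at least one query species is required")
    for q in queries:
        if q not in ortho.species:
            raise ValidationError(f"query species {q!r} not in orthogroup table")
        if q == focal:
            raise ValidationError("focal species cannot be its own query")

    if genes is None:
        genes = ortho.genes_of(focal)
    gene_list = list(dict.fromkeys(genes))

    out: list[ConservationAssignment] = []
    for gene in gene_list:
        grp = ortho.group_of(gene)
        if grp is None:
            out.append(ConservationAssignment(gene, "non_core", None))
            continue
        if gene not in grp.members.get(focal, ()):
            raise ValidationError(f"gene {gene!r} is not a {focal!r} member of {grp.og_id!r}")
        absent = [q for q in queries if grp.n_members(q) == 0]
        missing_core = bool(absent) if noncore_mode == "any" else len(absent) == len(queries)
        if missing_core:
            cls = "non_core"
        elif grp.n_members(focal) == 1:
            cls = "single_core"
        else:
            cls = "multi_core"
        out.append(ConservationAssignment(gene, cls, grp.og_id))
    return out
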