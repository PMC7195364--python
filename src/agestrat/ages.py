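"""Evolutionary age stratification of a focal genome.

Genes are first split into three subsets and each subset is dated on the
species ladder:

1. **WGD** — fixed duplicate pairs retained from a whole-genome
   duplication, supplied as an explicit ohnolog list (the package does not
   infer ohnologs from synteny).  These form their own age group.
2. **Single-copy genes** — dated by *origin*: the deepest (oldest) rung
   containing at least one species with an ortholog.  A gene with no
   ortholog outside the focal species is species-specific (rung 1).
3. **Multi-copy non-WGD genes** — dated by *duplication*: scanning rungs
   bottom-up (oldest to youngest), the oldest rung in which some species
   carries the same copy number as the focal species.  Equal copy number in
   an outgroup places the duplication at or before the split with that
   outgroup; no match anywhere means the duplication postdates all sampled
   splits (rung 1).

The default duplication rule takes the *oldest* rung with a copy-number
match.  Because gene loss can make copy numbers fluctuate non-monotonically
across rungs, an alternative ``youngest_contiguous`` rule is provided: it
returns the deepest rung reachable from rung 2 through an unbroken run of
matching rungs, which is more conservative in the presence of losses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError
from .io import Orthogroup, OrthogroupTable, SpeciesLadder

__all__ = [
    "WgdList",
    "AgeAssignment",
    "focal_copy_number",
    "assign_single_copy_age",
    "assign_multicopy_age",
    "stratify_genome",
]

WGD_LABEL = "WGD"
DUP_RULES = ("oldest", "youngest_contiguous")


@dataclass(frozen=True)
class WgdList:
    """Ohnolog pairs retained from a whole-genome duplication."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for a, b in self.pairs:
            for g in (a, b):
                if g in seen:
                    raise ValidationError(f"gene {g!r} appears in two ohnolog pairs")
                seen.add(g)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for pair in self.pairs for g in pair)


@dataclass(frozen=True)
class AgeAssignment:
    gene: str
    age_group: str  # rung label or "WGD"
    basis: str  # origin_single_copy | duplication_timing | wgd | unplaced
    deepest_rung: int
    focal_copy_number: int
    orthogroup_id: str | None = None


def _group_or_none(ortho: OrthogroupTable, gene: str) -> Orthogroup | None:
    return ortho.group_of(gene)


def focal_copy_number(ortho: OrthogroupTable, focal: str, gene: str) -> int:
    """Number of focal-species members in the gene's orthogroup (1 for
    singletons and for genes in no orthogroup)."""
    grp = _group_or_none(ortho, gene)
    if grp is None:
        return 1
    n = grp.n_members(focal)
    if gene not in grp.members.get(focal, ()):
        raise ValidationError(f"gene {gene!r} is not a {focal!r} member of {grp.og_id!r}")
    return max(n, 1)


def _rung_presence(grp: Orthogroup, ladder: SpeciesLadder) -> dict[int, list[int]]:
    """Per-rung list of member counts for non-focal species with members."""
    by_rung: dict[int, list[int]] = {}
    for sp, genes in grp.members.items():
        if sp == ladder.focal_species or not genes:
            continue
        by_rung.setdefault(ladder.rung_of(sp), []).append(len(genes))
    return by_rung


def assign_single_copy_age(ortho: OrthogroupTable, ladder: SpeciesLadder, gene: str) -> int:
    """Deepest rung with >=1 ortholog-bearing species; 1 when none."""
    grp = _group_or_none(ortho, gene)
    if grp is None:
        return 1
    by_rung = _rung_presence(grp, ladder)
    return max(by_rung, default=1)


def assign_multicopy_age(
    ortho: OrthogroupTable,
    ladder: SpeciesLadder,
    gene: str,
    dup_rule: str = "oldest",
) -> int:
    """Date a duplication by copy-number matching across rungs.

    With ``dup_rule="oldest"`` returns the oldest rung where >=1 species
    has exactly the focal copy number; ``youngest_contiguous`` returns the
    deepest rung reachable from rung 2 through consecutive matching rungs.
    Returns 1 when no non-focal species matches the focal copy number.
    """
    if dup_rule not in DUP_RULES:
        raise ValidationError(f"unknown dup_rule {dup_rule!r}")
    grp = _group_or_none(ortho, gene)
    n = focal_copy_number(ortho, ladder.focal_species, gene)
    if n < 2:
        raise ValidationError(f"gene {gene!r} is single-copy; use assign_single_copy_age")
    assert grp is not None
    by_rung = _rung_presence(grp, ladder)
    matching = sorted(r for r, counts in by_rung.items() if n in counts)
    if not matching:
        return 1
    if dup_rule == "oldest":
        return matching[-1]
    # youngest_contiguous: extend from rung 2 while every rung matches
    deepest = 1
    for r in range(2, ladder.n_rungs + 1):
        if r in matching:
            deepest = r
        else:
            break
    return deepest


def stratify_genome(
    ortho: OrthogroupTable,
    ladder: SpeciesLadder,
    wgd: WgdList | None = None,
    measured_genes: Iterable[str] | None = None,
    dup_rule: str = "oldest",
) -> list[AgeAssignment]:
    """Assign every measured focal gene exactly one age group.

    Ohnolog-listed genes go to the "WGD" group; remaining single-copy genes
    are dated by origin and multi-copy genes by duplication timing.  The
    output is restricted to ``measured_genes`` (default: all focal genes in
    the orthogroup table) and ordered as supplied.
    """
    focal = ladder.focal_species
    if measured_genes is None:
        measured = list(dict.fromkeys(ortho.genes_of(focal)))
    else:
        measured = list(dict.fromkeys(measured_genes))
    if not measured:
        raise ValidationError("no measured genes supplied")
    measured_set = set(measured)
    wgd_genes: frozenset[str] = frozenset()
    if wgd is not None:
        unknown = wgd.genes - measured_set - set(ortho.genes_of(focal))
        if unknown:
            raise ValidationError(
                f"ohnolog gene {sorted(unknown)[0]!r} is neither measured nor in the table"
            )
        wgd_genes = wgd.genes

    out: list[AgeAssignment] = []
    for gene in measured:
        grp = ortho.group_of(gene)
        og_id = grp.og_id if grp is not None else None
        n = focal_copy_number(ortho, focal, gene)
        if gene in wgd_genes:
            out.append(AgeAssignment(gene, WGD_LABEL, "wgd", 0, n, og_id))
        elif n == 1:
            rung = assign_single_copy_age(ortho, ladder, gene)
            out.append(
                AgeAssignment(gene, ladder.label_of(rung), "origin_single_copy", rung, n, og_id)
            )
        else:
            rung = assign_multicopy_age(ortho, ladder, gene, dup_rule=dup_rule)
            out.append(
                AgeAssignment(gene, ladder.label_of(rung), "duplication_timing", rung, n, og_id)
            )
    return out
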