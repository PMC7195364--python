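"""Simulation of gene histories on a species ladder, with planted DE effects.

The generator provides ground truth for the sorting and enrichment
machinery.  Each simulated gene family:

* originates at a rung drawn from ``origin_probs`` and is present, at copy
  number 1, in every species from its origin rung down to the focal
  species;
* duplicates at most once (probability ``dup_prob``), at a rung drawn
  uniformly between the origin and the present; from that rung downward
  every species carries copy number 2, and the focal species contributes
  two measurable genes;
* suffers loss independently per non-focal species with probability
  ``loss_rate`` (the focal species never loses its genes, so every truth
  gene stays measurable).  Loss removes the whole gene from that species.

Expression tables plant age-dependent differential expression: a gene is
DE in a condition with probability ``de_prob_by_group`` at its true age
rung; DE genes receive |log2FC| of at least ``lfc_magnitude`` (plus
exponential noise, random sign) and FDR below 0.01, non-DE genes receive
FDR at or above 0.01, so the standard DE filter recovers the planted truth
exactly.

Determinism: all draws come from ``numpy`` generators seeded from
``cfg.seed``; genes are processed in index order and, within a gene,
rungs oldest to youngest.  Loss indicators are drawn from a fixed position
in the stream, so runs that differ only in ``loss_rate`` have *nested*
loss sets — raising the rate can only add losses, which makes recovery
accuracy non-increasing in the rate for a fixed seed.

Probability vectors (``origin_probs``, ``de_prob_by_group``) are indexed
by rung, youngest first: element 0 belongs to rung 1 (the focal species'
own stratum), the last element to the oldest rung.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io import ExpressionTable, Orthogroup, OrthogroupTable, Rung, SpeciesLadder

import pandas as pd

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "make_ladder",
    "simulate_gene_histories",
    "simulate_expression",
]

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV"]

#: Divergence times (Myr) used for the default five-rung ladder; chosen to
#: resemble a budding-yeast ladder spanning the genus split (~20 Mya) out
#: to filamentous fungi (>400 Mya).
_DEFAULT_TIMES_5 = (0.0, 20.0, 120.0, 325.0, 420.0)


def make_ladder(
    n_rungs: int = 5,
    species_per_rung: int = 2,
    focal: str = "FOCAL",
) -> SpeciesLadder:
    """Synthetic species ladder: rung 1 = focal alone, every older rung
    carries ``species_per_rung`` species.  Labels are Roman numerals with
    "I" the oldest rung."""
    if n_rungs < 2:
        raise ValidationError("a ladder needs at least 2 rungs")
    if n_rungs > len(_ROMAN):
        raise ValidationError(f"at most {len(_ROMAN)} rungs supported")
    if species_per_rung < 1:
        raise ValidationError("species_per_rung must be >= 1")
    if n_rungs == 5:
        times = _DEFAULT_TIMES_5
    else:
        times = tuple(100.0 * (r - 1) for r in range(1, n_rungs + 1))
    rungs = [Rung(index=1, label=_ROMAN[n_rungs - 1], species=frozenset({focal}),
                  divergence_myr=times[0])]
    for r in range(2, n_rungs + 1):
        rungs.append(
            Rung(
                index=r,
                label=_ROMAN[n_rungs - r],
                species=frozenset(f"sp_r{r}_{j}" for j in range(species_per_rung)),
                divergence_myr=times[r - 1],
            )
        )
    return SpeciesLadder(focal_species=focal, rungs=tuple(rungs))


@dataclass(frozen=True)
class SimulationConfig:
    ladder: SpeciesLadder
    n_genes: int
    seed: int
    origin_probs: tuple[float, ...] | None = None  # per rung, youngest first
    dup_prob: float = 0.3
    loss_rate: float = 0.0
    de_prob_by_group: tuple[float, ...] | None = None  # per rung, youngest first
    lfc_magnitude: float = 2.0
    n_conditions: int = 3

    def __post_init__(self) -> None:
        R = self.ladder.n_rungs
        if self.n_genes < 0:
            raise ValidationError("n_genes must be non-negative")
        if not 0.0 <= self.dup_prob <= 1.0:
            raise ValidationError("dup_prob must be in [0, 1]")
        if not 0.0 <= self.loss_rate <= 1.0:
            raise ValidationError("loss_rate must be in [0, 1]")
        if self.lfc_magnitude < 1.0:
            raise ValidationError(
                "lfc_magnitude must be >= 1 so planted DE clears the |log2FC| > 1 cut"
            )
        if self.n_conditions < 1:
            raise ValidationError("n_conditions must be >= 1")
        if self.origin_probs is not None:
            p = np.asarray(self.origin_probs, dtype=float)
            if p.size != R:
                raise ValidationError(f"origin_probs must have {R} entries")
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValidationError("origin_probs must be non-negative and sum to 1")
        if self.de_prob_by_group is not None:
            p = np.asarray(self.de_prob_by_group, dtype=float)
            if p.size != R:
                raise ValidationError(f"de_prob_by_group must have {R} entries")
            if (p < 0).any() or (p > 1).any():
                raise ValidationError("de_prob_by_group entries must be in [0, 1]")

    def origin_probs_array(self) -> np.ndarray:
        R = self.ladder.n_rungs
        if self.origin_probs is None:
            return np.full(R, 1.0 / R)
        return np.asarray(self.origin_probs, dtype=float)

    def de_probs_array(self) -> np.ndarray:
        R = self.ladder.n_rungs
        if self.de_prob_by_group is None:
            return np.full(R, 0.1)
        return np.asarray(self.de_prob_by_group, dtype=float)


@dataclass
class SimTruth:
    """Ground truth: per focal gene the origin rung, the duplication rung
    (None for never-duplicated genes), and — once expression has been
    simulated — the planted DE status per condition."""

    genes: tuple[str, ...]
    origin_rung: dict[str, int]
    dup_rung: dict[str, int | None]
    de: dict[str, set[str]] = field(default_factory=dict)  # condition -> DE genes

    def age_rung(self, gene: str) -> int:
        """The rung the sorting method should recover: duplication rung for
        duplicated genes, origin rung otherwise."""
        d = self.dup_rung[gene]
        return d if d is not None else self.origin_rung[gene]


def simulate_gene_histories(cfg: SimulationConfig) -> tuple[OrthogroupTable, SimTruth]:
    """Simulate orthogroup structure for ``cfg.n_genes`` gene families.

    Deterministic given ``cfg.seed``.  Returns the orthogroup table over
    the ladder's species plus the per-gene truth.
    """
    ladder = cfg.ladder
    focal = ladder.focal_species
    R = ladder.n_rungs
    rng = np.random.default_rng([cfg.seed, 0])
    n = cfg.n_genes

    species_order = [focal] + [
        sp for r in range(2, R + 1) for sp in sorted(ladder.rungs[r - 1].species)
    ]
    nonfocal = species_order[1:]
    rung_of = {sp: ladder.rung_of(sp) for sp in nonfocal}

    # Fixed draw order keeps loss sets nested across loss rates (same seed).
    origin = rng.choice(np.arange(1, R + 1), size=max(n, 1), p=cfg.origin_probs_array())
    dup_flag = rng.random(max(n, 1)) < cfg.dup_prob
    dup_u = rng.random(max(n, 1))
    loss_u = rng.random((max(n, 1), len(nonfocal)))

    groups: list[Orthogroup] = []
    genes: list[str] = []
    origin_rung: dict[str, int] = {}
    dup_rung: dict[str, int | None] = {}
    for i in range(n):
        org = int(origin[i])
        dup = None
        if dup_flag[i]:
            dup = 1 + int(dup_u[i] * org)  # uniform on rungs 1..origin
            dup = min(dup, org)
        members: dict[str, tuple[str, ...]] = {}
        base = f"g{i:05d}"
        focal_genes = (base,) if dup is None else (base, base + "d")
        members[focal] = focal_genes
        for j, sp in enumerate(nonfocal):
            r = rung_of[sp]
            if r > org:
                continue
            if loss_u[i, j] < cfg.loss_rate:
                continue
            cn = 2 if (dup is not None and r <= dup) else 1
            members[sp] = tuple(f"{base}_{sp}_{k}" for k in range(cn))
        groups.append(Orthogroup(og_id=f"OG{i:06d}", members=members))
        for g in focal_genes:
            genes.append(g)
            origin_rung[g] = org
            dup_rung[g] = dup
    table = OrthogroupTable(species_order, groups)
    return table, SimTruth(genes=tuple(genes), origin_rung=origin_rung, dup_rung=dup_rung)


def simulate_expression(cfg: SimulationConfig, truth: SimTruth) -> list[ExpressionTable]:
    """Plant age-dependent DE into per-condition expression tables.

    DE genes get |log2FC| = lfc_magnitude + Exp(mean 0.5) with random sign
    and FDR ~ U(0, 0.01); non-DE genes get log2FC ~ N(0, 0.4) and FDR ~
    U(0.01, 1).  Records the planted truth in ``truth.de``.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    de_p = cfg.de_probs_array()
    genes = list(truth.genes)
    p_gene = np.array([de_p[truth.age_rung(g) - 1] for g in genes])
    m = len(genes)
    tables: list[ExpressionTable] = []
    for c in range(cfg.n_conditions):
        cond = f"cond{c + 1}"
        is_de = rng.random(m) < p_gene
        sign = np.where(rng.random(m) < 0.5, -1.0, 1.0)
        mag = cfg.lfc_magnitude + rng.exponential(0.5, size=m)
        lfc = np.where(is_de, sign * mag, rng.normal(0.0, 0.4, size=m))
        fdr = np.where(is_de, rng.uniform(0.0, 0.01, size=m),
                       rng.uniform(0.01, 1.0, size=m))
        df = pd.DataFrame({"gene": genes, "log2fc": lfc, "fdr": fdr})
        tables.append(ExpressionTable(condition=cond, records=df))
        truth.de[cond] = {g for g, d in zip(genes, is_de) if d}
    return tables
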