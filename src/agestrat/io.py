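"""Input/output for orthogroup tables, species ladders and expression data.

All tabular formats are tab-separated with a header row.  Gene and species
identifiers are opaque, case-sensitive strings.  The orthogroup reader
understands the de facto OrthoFinder ``Orthogroups.tsv`` layout (first
column the orthogroup id, one column per species, members joined by
comma+space) as well as a generic long format with columns
``orthogroup_id``, ``species``, ``gene``.

The species ladder is a YAML document describing the ordered taxon rungs of
a simplified phylogenetic tree, youngest first::

    focal: Scer
    rungs:
      - label: V            # rung 1: the focal species alone
        species: [Scer]
      - label: IV
        species: [Seub]
        divergence_myr: 20
      - label: III
        species: [Kmar, Klac]
        divergence_myr: 120
      ...

Rung 1 is the youngest stratum (the focal species itself); higher rung
indices are progressively older ancestors.  ``divergence_myr`` is the
estimated time in million years to the common ancestor with that rung and
must be non-decreasing with rung index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .errors import ValidationError

__all__ = [
    "Rung",
    "SpeciesLadder",
    "Orthogroup",
    "OrthogroupTable",
    "ExpressionTable",
    "CountsMatrix",
    "HomologHit",
    "HomologHitTable",
    "read_orthogroups",
    "read_ladder",
    "read_de_table",
    "read_counts",
    "read_fasta",
    "read_blast_tab",
    "read_wgd_pairs",
    "write_orthogroups",
    "write_ladder",
    "write_assignments",
    "read_assignments",
]


# ---------------------------------------------------------------------------
# Species ladder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rung:
    """One stratum of the species ladder.

    ``index`` is 1-based; rung 1 holds exactly the focal species.  ``label``
    is cosmetic (conventionally Roman numerals, youngest "V" .. oldest "I");
    all logic uses indices.
    """

    index: int
    label: str
    species: frozenset[str]
    divergence_myr: float | None = None


@dataclass(frozen=True)
class SpeciesLadder:
    focal_species: str
    rungs: tuple[Rung, ...]
    notes: str = ""
    _species_to_rung: Mapping[str, int] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.rungs:
            raise ValidationError("species ladder has no rungs")
        if [r.index for r in self.rungs] != list(range(1, len(self.rungs) + 1)):
            raise ValidationError("rung indices must be 1..n in order")
        first = self.rungs[0]
        if first.species != frozenset({self.focal_species}):
            raise ValidationError(
                f"rung 1 must contain exactly the focal species "
                f"{self.focal_species!r}, got {sorted(first.species)}"
            )
        labels = [r.label for r in self.rungs]
        if len(set(labels)) != len(labels):
            raise ValidationError("rung labels must be unique")
        mapping: dict[str, int] = {}
        for rung in self.rungs:
            for sp in rung.species:
                if sp in mapping:
                    raise ValidationError(
                        f"species {sp!r} appears in rungs {mapping[sp]} and {rung.index}"
                    )
                mapping[sp] = rung.index
        prev = None
        for rung in self.rungs:
            if rung.divergence_myr is None:
                continue
            if rung.divergence_myr < 0:
                raise ValidationError(f"rung {rung.index}: negative divergence_myr")
            if prev is not None and rung.divergence_myr < prev:
                raise ValidationError(
                    f"divergence_myr must be non-decreasing with rung index "
                    f"(rung {rung.index}: {rung.divergence_myr} < {prev})"
                )
            prev = rung.divergence_myr
        object.__setattr__(self, "_species_to_rung", mapping)

    @property
    def n_rungs(self) -> int:
        return len(self.rungs)

    def rung_of(self, species: str) -> int:
        """Rung index of ``species``; unmapped species is an error."""
        try:
            return self._species_to_rung[species]
        except KeyError:
            raise ValidationError(f"species {species!r} is not on the ladder") from None

    def label_of(self, rung_index: int) -> str:
        return self.rungs[rung_index - 1].label

    def index_of_label(self, label: str) -> int:
        for rung in self.rungs:
            if rung.label == label:
                return rung.index
        raise ValidationError(f"no rung labelled {label!r}")

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self._species_to_rung)


# ---------------------------------------------------------------------------
# Orthogroup table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Orthogroup:
    og_id: str
    members: Mapping[str, tuple[str, ...]]  # species -> gene ids (may be absent)

    def n_members(self, species: str) -> int:
        return len(self.members.get(species, ()))

    def all_genes(self) -> Iterable[str]:
        for genes in self.members.values():
            yield from genes


class OrthogroupTable:
    """Orthogroup membership across species.

    Enforces that every gene identifier belongs to at most one orthogroup
    and provides O(1) gene -> orthogroup lookup.
    """

    def __init__(self, species: Sequence[str], groups: Sequence[Orthogroup]):
        self.species: tuple[str, ...] = tuple(species)
        self.groups: tuple[Orthogroup, ...] = tuple(groups)
        ids = [g.og_id for g in self.groups]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValidationError(f"duplicate orthogroup id {dup!r}")
        known = set(self.species)
        self._gene_to_group: dict[str, Orthogroup] = {}
        for grp in self.groups:
            total = 0
            for sp, genes in grp.members.items():
                if sp not in known:
                    raise ValidationError(
                        f"orthogroup {grp.og_id!r} names unknown species {sp!r}"
                    )
                total += len(genes)
                for gene in genes:
                    if gene in self._gene_to_group:
                        raise ValidationError(
                            f"gene {gene!r} appears in orthogroups "
                            f"{self._gene_to_group[gene].og_id!r} and {grp.og_id!r}"
                        )
                    self._gene_to_group[gene] = grp
            if total == 0:
                raise ValidationError(f"orthogroup {grp.og_id!r} has no members")

    def group_of(self, gene: str) -> Orthogroup | None:
        return self._gene_to_group.get(gene)

    def genes_of(self, species: str) -> list[str]:
        if species not in self.species:
            raise ValidationError(f"species {species!r} not in orthogroup table")
        out: list[str] = []
        for grp in self.groups:
            out.extend(grp.members.get(species, ()))
        return out

    def __len__(self) -> int:
        return len(self.groups)


# ---------------------------------------------------------------------------
# Expression / counts / homology containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionTable:
    """Per-condition differential-expression results (gene, log2FC, FDR)."""

    condition: str
    records: pd.DataFrame  # columns: gene, log2fc, fdr

    def __post_init__(self) -> None:
        df = self.records
        missing = {"gene", "log2fc", "fdr"} - set(df.columns)
        if missing:
            raise ValidationError(f"expression table missing columns {sorted(missing)}")
        if df["gene"].duplicated().any():
            dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
            raise ValidationError(
                f"gene {dup!r} appears twice in condition {self.condition!r}"
            )
        bad = df[(df["fdr"] < 0) | (df["fdr"] > 1) | df["fdr"].isna()]
        if len(bad):
            raise ValidationError(
                f"FDR outside [0, 1] for gene {bad['gene'].iloc[0]!r} "
                f"in condition {self.condition!r}"
            )
        if df["log2fc"].isna().any():
            gene = df.loc[df["log2fc"].isna(), "gene"].iloc[0]
            raise ValidationError(f"non-numeric log2FC for gene {gene!r}")


@dataclass(frozen=True)
class CountsMatrix:
    """Raw counts with gene lengths; samples carry condition/replicate labels.

    ``counts`` is genes x samples; sample column names follow
    ``<condition>:<replicate>``.
    """

    counts: pd.DataFrame
    lengths: pd.Series  # bp per gene, index aligned with counts
    sample_condition: Mapping[str, str]
    sample_replicate: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            raise ValidationError("counts and lengths index mismatch")
        if (self.lengths <= 0).any():
            gene = self.lengths[self.lengths <= 0].index[0]
            raise ValidationError(f"gene {gene!r} has non-positive length")
        if (self.counts < 0).any().any():
            raise ValidationError("negative counts present")

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.sample_condition[s] == condition]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.counts.columns:
            c = self.sample_condition[s]
            if c not in seen:
                seen.append(c)
        return seen


@dataclass(frozen=True)
class HomologHit:
    query: str
    subject: str
    pct_identity: float
    bitscore: float
    aln_len: int


@dataclass(frozen=True)
class HomologHitTable:
    hits: tuple[HomologHit, ...]

    def __post_init__(self) -> None:
        for h in self.hits:
            if not 0.0 <= h.pct_identity <= 100.0:
                raise ValidationError(
                    f"hit {h.query!r}->{h.subject!r}: pct_identity {h.pct_identity} "
                    "outside [0, 100]"
                )
            if h.aln_len <= 0:
                raise ValidationError(
                    f"hit {h.query!r}->{h.subject!r}: non-positive alignment length"
                )

    def for_query(self, query: str) -> list[HomologHit]:
        return [h for h in self.hits if h.query == query]

    @property
    def queries(self) -> list[str]:
        seen: list[str] = []
        for h in self.hits:
            if h.query not in seen:
                seen.append(h.query)
        return seen


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_orthogroups(path: str | Path, dialect: str = "orthofinder_tsv") -> OrthogroupTable:
    """Read an orthogroup membership table.

    ``orthofinder_tsv``: wide layout, first column the orthogroup id, one
    column per species, cell = comma(+space)-separated gene ids, empty cell
    = no members in that species.  ``generic_tsv``: long layout with columns
    ``orthogroup_id``, ``species``, ``gene``.
    """
    path = Path(path)
    if dialect == "orthofinder_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if df.shape[1] < 2:
            raise ValidationError(f"{path}: need an id column plus species columns")
        species = list(df.columns[1:])
        groups = []
        for _, row in df.iterrows():
            members = {}
            for sp in species:
                cell = row[sp].strip()
                if cell:
                    members[sp] = tuple(g.strip() for g in cell.split(",") if g.strip())
            groups.append(Orthogroup(og_id=row.iloc[0], members=members))
        return OrthogroupTable(species, groups)
    if dialect == "generic_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"orthogroup_id", "species", "gene"}
        if missing := required - set(df.columns):
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        species = list(dict.fromkeys(df["species"]))
        groups = []
        for og_id, sub in df.groupby("orthogroup_id", sort=False):
            members = {
                sp: tuple(g["gene"]) for sp, g in sub.groupby("species", sort=False)
            }
            groups.append(Orthogroup(og_id=og_id, members=members))
        return OrthogroupTable(species, groups)
    raise ValidationError(f"unknown orthogroup dialect {dialect!r}")


def read_ladder(path: str | Path) -> SpeciesLadder:
    """Read a species-ladder YAML config (see module docstring for layout)."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "focal" not in doc or "rungs" not in doc:
        raise ValidationError(f"{path}: ladder config needs 'focal' and 'rungs' keys")
    rungs = []
    for i, entry in enumerate(doc["rungs"], start=1):
        if "species" not in entry:
            raise ValidationError(f"{path}: rung {i} missing 'species'")
        div = entry.get("divergence_myr")
        rungs.append(
            Rung(
                index=i,
                label=str(entry.get("label", str(i))),
                species=frozenset(str(s) for s in entry["species"]),
                divergence_myr=None if div is None else float(div),
            )
        )
    return SpeciesLadder(
        focal_species=str(doc["focal"]),
        rungs=tuple(rungs),
        notes=str(doc.get("notes", "")),
    )


def read_de_table(path: str | Path, condition: str) -> ExpressionTable:
    """Read a DE TSV with columns gene, log2fc, fdr (header required)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df.columns = [c.lower() for c in df.columns]
    rename = {"log2fold": "log2fc", "logfc": "log2fc", "log2foldchange": "log2fc",
              "padj": "fdr", "qvalue": "fdr"}
    df = df.rename(columns=rename)
    if missing := {"gene", "log2fc", "fdr"} - set(df.columns):
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    for col in ("log2fc", "fdr"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return ExpressionTable(condition=condition, records=df[["gene", "log2fc", "fdr"]])


def read_counts(path: str | Path) -> CountsMatrix:
    """Read a counts TSV: columns gene, length, then one column per sample.

    Sample column headers are ``<condition>:<replicate>``, e.g. ``ref:1``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    df.columns = [str(c) for c in df.columns]
    low = [c.lower() for c in df.columns[:2]]
    if low != ["gene", "length"]:
        raise ValidationError(f"{path}: first two columns must be gene, length")
    df = df.set_index(df.columns[0])
    lengths = pd.to_numeric(df.iloc[:, 0], errors="raise").astype(int)
    counts = df.iloc[:, 1:].apply(pd.to_numeric, errors="raise")
    cond, rep = {}, {}
    for col in counts.columns:
        if ":" not in col:
            raise ValidationError(
                f"{path}: sample column {col!r} must be '<condition>:<replicate>'"
            )
        c, r = col.split(":", 1)
        cond[col], rep[col] = c, r
    return CountsMatrix(counts=counts, lengths=lengths,
                        sample_condition=cond, sample_replicate=rep)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (protein) FASTA into an id -> sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValidationError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


#: Columns of the standard BLAST tabular output (-outfmt 6).
BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_blast_tab(path: str | Path) -> HomologHitTable:
    """Read BLAST tabular (outfmt-6-style, 12 columns, no header)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise ValidationError(f"{path}: expected >=12 outfmt-6 columns, got {df.shape[1]}")
    df = df.iloc[:, :12]
    df.columns = BLAST6_COLUMNS
    hits = tuple(
        HomologHit(
            query=str(r.qseqid),
            subject=str(r.sseqid),
            pct_identity=float(r.pident),
            bitscore=float(r.bitscore),
            aln_len=int(r.length),
        )
        for r in df.itertuples()
    )
    return HomologHitTable(hits=hits)


def read_wgd_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read an ohnolog pair list: TSV with two gene-id columns, header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: ohnolog list needs two gene columns")
    return [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]


def write_orthogroups(ortho: OrthogroupTable, path: str | Path) -> None:
    """Write an OrthogroupTable in the OrthoFinder wide TSV layout."""
    rows = []
    for grp in ortho.groups:
        row = {"Orthogroup": grp.og_id}
        for sp in ortho.species:
            row[sp] = ", ".join(grp.members.get(sp, ()))
        rows.append(row)
    pd.DataFrame(rows, columns=["Orthogroup", *ortho.species]).to_csv(
        path, sep="\t", index=False
    )


def write_ladder(ladder: SpeciesLadder, path: str | Path) -> None:
    """Write a SpeciesLadder as the YAML config read_ladder understands."""
    doc = {
        "focal": ladder.focal_species,
        "rungs": [
            {
                "label": r.label,
                "species": sorted(r.species),
                **({} if r.divergence_myr is None else {"divergence_myr": r.divergence_myr}),
            }
            for r in ladder.rungs
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Assignment TSV round-trip
# ---------------------------------------------------------------------------

ASSIGNMENT_COLUMNS = ["gene", "conservation_class", "age_group", "basis", "orthogroup_id"]


def write_assignments(assignments, path: str | Path) -> None:
    """Write per-gene assignment records as a TSV.

    Accepts any iterable of objects (or mappings) exposing the fields in
    ``ASSIGNMENT_COLUMNS``; missing fields are written as empty cells.
    """
    rows = []
    for a in assignments:
        get = a.get if isinstance(a, dict) else lambda k, _a=a: getattr(_a, k, None)
        rows.append({c: ("" if get(c) is None else get(c)) for c in ASSIGNMENT_COLUMNS})
    pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if missing := set(ASSIGNMENT_COLUMNS) - set(df.columns):
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return df[ASSIGNMENT_COLUMNS]
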