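"""Readers and writers for the on-disk formats the pipeline touches.

Every other module consumes and produces the types defined here. Coordinates
are 1-based inclusive throughout (GFF convention); interval arithmetic in the
rest of the package assumes this. KEGG Orthology (KO) tokens are opaque
strings — no database lookups are ever performed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import AlignIO, SearchIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import dendropy

PHENOTYPE_LABELS = frozenset(
    {
        "sporulating",
        "sporulating_inferred",
        "nonsporulating",
        "nonsporulating_inferred",
        "unknown",
    }
)

#: Normalisation map for the phenotype spellings seen in curated compendia.
_PHENOTYPE_ALIASES = {
    "sporulating": "sporulating",
    "spore-forming": "sporulating",
    "sporulating-inferred": "sporulating_inferred",
    "sporulating_inferred": "sporulating_inferred",
    "nonsporulating": "nonsporulating",
    "non-sporulating": "nonsporulating",
    "nonsporulating-inferred": "nonsporulating_inferred",
    "nonsporulating_inferred": "nonsporulating_inferred",
    "unknown": "unknown",
}


class ParseError(ValueError):
    """Malformed input file; message names the offending line where known."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene in one species (1-based inclusive coordinates)."""

    species_id: str
    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    ko: Optional[str] = None
    product: str = ""
    aa_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand {self.strand!r} not in +/-")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainHit:
    """A profile match on a protein (alignment coordinates, 1-based aa)."""

    gene_id: str
    profile: str
    ali_start: int
    ali_end: int
    evalue: float

    def __post_init__(self) -> None:
        if self.ali_start > self.ali_end:
            raise ValueError(
                f"{self.gene_id}/{self.profile}: ali_start > ali_end "
                f"({self.ali_start} > {self.ali_end})"
            )
        if self.evalue < 0:
            raise ValueError(f"{self.gene_id}/{self.profile}: negative E-value")

    @property
    def span(self) -> int:
        return self.ali_end - self.ali_start + 1


@dataclass(frozen=True)
class PhenotypeLabel:
    species_id: str
    label: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.label not in PHENOTYPE_LABELS:
            raise ValueError(f"{self.species_id}: unknown phenotype {self.label!r}")


@dataclass(frozen=True)
class Taxonomy:
    """class/family/genus lineage of one species ('unknown' sentinel allowed)."""

    species_id: str
    class_: str
    family: str
    genus: str


_GENE_COLUMNS = [
    "species_id",
    "gene_id",
    "contig_id",
    "start",
    "end",
    "strand",
    "ko",
    "product",
]


def read_gene_table(path, fasta_path=None) -> list[GeneRecord]:
    """Read a TSV gene table, optionally attaching protein sequences.

    The TSV must carry the header columns ``species_id gene_id contig_id start
    end strand ko product`` (``ko`` may be empty). A companion FASTA keyed by
    gene_id supplies ``aa_seq``. Records come back sorted by
    (species, contig, start).
    """
    seqs: dict[str, str] = {}
    if fasta_path is not None:
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}

    records: list[GeneRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _GENE_COLUMNS if c not in header]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        idx = {c: header.index(c) for c in _GENE_COLUMNS}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < len(header):
                parts += [""] * (len(header) - len(parts))
            try:
                start = int(parts[idx["start"]])
                end = int(parts[idx["end"]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates: {exc}") from exc
            ko = parts[idx["ko"]] or None
            try:
                rec = GeneRecord(
                    species_id=parts[idx["species_id"]],
                    gene_id=parts[idx["gene_id"]],
                    contig_id=parts[idx["contig_id"]],
                    start=start,
                    end=end,
                    strand=parts[idx["strand"]],
                    ko=ko,
                    product=parts[idx["product"]],
                    aa_seq=seqs.get(parts[idx["gene_id"]]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            key = (rec.species_id, rec.gene_id)
            if key in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene_id {rec.gene_id}")
            seen.add(key)
            records.append(rec)
    records.sort(key=lambda r: (r.species_id, r.contig_id, r.start, r.gene_id))
    return records


def write_gene_table(records: Sequence[GeneRecord], path, fasta_path=None) -> None:
    """Write the TSV counterpart of :func:`read_gene_table` (lossless)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for r in sorted(records, key=lambda r: (r.species_id, r.contig_id, r.start, r.gene_id)):
            fh.write(
                "\t".join(
                    [
                        r.species_id,
                        r.gene_id,
                        r.contig_id,
                        str(r.start),
                        str(r.end),
                        r.strand,
                        r.ko or "",
                        r.product,
                    ]
                )
                + "\n"
            )
    if fasta_path is not None:
        with_seq = [r for r in records if r.aa_seq]
        SeqIO.write(
            (SeqRecord(Seq(r.aa_seq), id=r.gene_id, description="") for r in with_seq),
            str(fasta_path),
            "fasta",
        )


def read_domain_table(path) -> list[DomainHit]:
    """Parse an HMMER3 per-domain table (``hmmscan --domtblout`` output).

    One :class:`DomainHit` per domain row; alignment coordinates (``ali_from``
    / ``ali_to``) become the hit span and the independent-domain E-value
    (i-Evalue) becomes ``evalue``. The query name is the protein, the hit name
    the profile.
    """
    hits: list[DomainHit] = []
    try:
        for qresult in SearchIO.parse(str(path), "hmmscan3-domtab"):
            for hit in qresult.hits:
                for hsp in hit.hsps:
                    if hsp.evalue < 0:
                        raise ParseError(
                            f"{path}: negative E-value for {qresult.id}/{hit.id}"
                        )
                    hits.append(
                        DomainHit(
                            gene_id=qresult.id,
                            profile=hit.id,
                            # SearchIO coordinates are 0-based half-open
                            ali_start=hsp.query_start + 1,
                            ali_end=hsp.query_end,
                            evalue=float(hsp.evalue),
                        )
                    )
    except ParseError:
        raise
    except Exception as exc:  # truncated rows etc.
        raise ParseError(f"{path}: malformed domain table: {exc}") from exc
    return hits


_DOMTAB_HEADER = (
    "#                                                                            "
    "--- full sequence --- -------------- this domain -------------   hmm coord   "
    "ali coord   env coord\n"
    "# target name        accession   tlen query name           accession   qlen   "
    "E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  "
    "from    to  from    to  acc description of target\n"
    "#------------------- ---------- ----- -------------------- ---------- ----- "
    "--------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- "
    "----- ----- ----- ----- ---- ---------------------\n"
)


def write_domain_table(hits: Sequence[DomainHit], path, qlen: Mapping[str, int] | None = None) -> None:
    """Emit hits in HMMER3 domtblout layout (readable by :func:`read_domain_table`)."""
    qlen = qlen or {}
    by_gene: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    with open(path, "w") as fh:
        fh.write(_DOMTAB_HEADER)
        for gene, gene_hits in by_gene.items():
            n = len(gene_hits)
            glen = qlen.get(gene, max(h.ali_end for h in gene_hits) + 10)
            for i, h in enumerate(gene_hits, start=1):
                tlen = h.span + 4
                fh.write(
                    f"{h.profile:<20} -          {tlen:5d} {gene:<20} -          "
                    f"{glen:5d} {h.evalue:9.2g} {50.0:6.1f} {0.0:5.1f} "
                    f"{i:3d} {n:3d} {h.evalue:9.2g} {h.evalue:9.2g} {48.0:6.1f} {0.0:5.1f} "
                    f"{1:5d} {tlen:5d} {h.ali_start:5d} {h.ali_end:5d} "
                    f"{max(1, h.ali_start - 2):5d} {h.ali_end + 2:5d} 0.95 -\n"
                )
        fh.write("#\n")


# ---------------------------------------------------------------------------
# Phenotype / phyletic matrix tables


DEFAULT_COLUMN_MAP = {
    "species": "species_id",
    "class": "class",
    "family": "family",
    "genus": "genus",
    "phenotype": "phenotype",
    "source": "source",
}

#: Alternate spellings tried when the mapped column is absent.
_COLUMN_FALLBACKS = {
    "species": ("species_id", "species", "Species", "organism"),
    "phenotype": ("phenotype", "Phenotype", "sporulation_phenotype"),
    "class": ("class", "Class"),
    "family": ("family", "Family"),
    "genus": ("genus", "Genus"),
    "source": ("source", "Source", "reference"),
}


def read_phenotype_matrix(
    path,
    column_map: Mapping[str, str] | None = None,
    sheet: int | str = 0,
):
    """Read a species x protein presence/absence table with metadata columns.

    Accepts a TSV, or a single-sheet rectangular XLSX (curated compendia are
    commonly distributed as spreadsheets). ``column_map`` maps the canonical
    roles (species/class/family/genus/phenotype/source) to the column names
    used in the file; every remaining column is taken as a binary protein
    column. Returns ``(matrix_df, phenotype_labels, taxonomies)`` where
    ``matrix_df`` is indexed by species with strictly {0,1} integer entries.
    Non-binary cells are rejected, never coerced.
    """
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        df = pd.read_csv(path, sep="\t")

    for role, candidates in _COLUMN_FALLBACKS.items():
        if colmap[role] not in df.columns:
            for cand in candidates:
                if cand in df.columns:
                    colmap[role] = cand
                    break

    sp_col = colmap["species"]
    if sp_col not in df.columns:
        raise ParseError(f"{path}: species column {sp_col!r} not found")
    meta_cols = {role: colmap[role] for role in colmap if colmap[role] in df.columns}
    protein_cols = [c for c in df.columns if c not in set(meta_cols.values())]

    matrix = df.set_index(sp_col)[protein_cols]
    for col in protein_cols:
        for species, val in matrix[col].items():
            if val not in (0, 1, "0", "1"):
                raise ParseError(
                    f"{path}: non-binary cell at species {species!r}, column {col!r}: {val!r}"
                )
    matrix = matrix.astype(int)
    matrix.index.name = "species_id"

    labels: list[PhenotypeLabel] = []
    taxa: list[Taxonomy] = []
    pheno_col = meta_cols.get("phenotype")
    src_col = meta_cols.get("source")
    for _, row in df.iterrows():
        sp = row[sp_col]
        if pheno_col is not None:
            raw = str(row[pheno_col]).strip().lower()
            norm = _PHENOTYPE_ALIASES.get(raw)
            if norm is None:
                raise ParseError(f"{path}: unknown phenotype {row[pheno_col]!r} for {sp}")
            labels.append(
                PhenotypeLabel(sp, norm, str(row[src_col]) if src_col else "")
            )
        taxa.append(
            Taxonomy(
                species_id=sp,
                class_=str(row[meta_cols["class"]]) if "class" in meta_cols else "unknown",
                family=str(row[meta_cols["family"]]) if "family" in meta_cols else "unknown",
                genus=str(row[meta_cols["genus"]]) if "genus" in meta_cols else "unknown",
            )
        )
    return matrix, labels, taxa


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# Alignments and trees


def write_stockholm(alignment: Iterable[tuple[str, str]] | MultipleSeqAlignment, path) -> None:
    """Write an alignment (pairs of (id, seq) or a Biopython MSA) as Stockholm."""
    if not isinstance(alignment, MultipleSeqAlignment):
        alignment = MultipleSeqAlignment(
            SeqRecord(Seq(seq), id=name, description="") for name, seq in alignment
        )
    AlignIO.write(alignment, str(path), "stockholm")


def read_stockholm(path) -> list[tuple[str, str]]:
    aln = AlignIO.read(str(path), "stockholm")
    return [(rec.id, str(rec.seq)) for rec in aln]


def read_newick(path_or_string) -> dendropy.Tree:
    """Read a Newick tree from a path or a literal string."""
    s = str(path_or_string)
    if s.lstrip().startswith("(") or s.rstrip().endswith(";"):
        data, kind = s, "string"
    else:
        data, kind = s, "path"
    try:
        tree = dendropy.Tree.get(
            **{kind: data}, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:
        raise ParseError(f"bad Newick input: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
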