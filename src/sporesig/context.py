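"""Genomic-context filtering of architecture calls into probable orthologs.

An architecture match alone does not separate orthologs from paralogs. The
second gate is the conserved gene neighborhood: for each target protein the
KEGG-Orthology labels (KOs) of the three genes upstream and three downstream
of every architecture-bearing homolog are tallied across genomes, and KOs
seen at least eight times become representative contextual KOs (RCKOs). A
candidate becomes a probable ortholog (PO) when

1. it carries an accepted architecture,
2. at least one neighbor gene carries a selected RCKO, and
3. its own KO, when present, is recorded but never required.

Candidates whose entire neighborhood lacks KO labels (context undefined) are
dismissed rather than rejected on evidence. Accepted POs populate the binary
species x protein phyletic matrix; the Spo0A column, a stage-0 sporulation
signature predicted elsewhere, is imported verbatim when provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .architectures import ArchitectureCall
from .io_formats import GeneRecord, Taxonomy


@dataclass
class Neighborhood:
    """Up to three genes either side of a focal gene on the same contig.

    "Upstream"/"downstream" follow genomic coordinate order irrespective of
    the focal strand (a strand-relative mode is available in
    :func:`extract_neighborhood`); operonic neighbors are co-oriented so the
    two conventions coincide where it matters.
    """

    focal_gene: str
    upstream: list[GeneRecord] = field(default_factory=list)  # nearest first
    downstream: list[GeneRecord] = field(default_factory=list)  # nearest first

    @property
    def genes(self) -> list[GeneRecord]:
        return list(self.upstream) + list(self.downstream)


@dataclass
class RCKOTable:
    target_protein: str
    ko_counts: dict[str, int]
    min_count: int = 8

    @property
    def selected(self) -> set[str]:
        return {k for k, n in self.ko_counts.items() if n >= self.min_count}


@dataclass
class POCall:
    species_id: str
    gene_id: str
    target_protein: str
    architecture: str
    rckos_matched: set[str]
    focal_ko_matched: bool
    context_defined: bool
    accepted: bool


class PhyleticMatrix:
    """Binary species x protein matrix with taxonomy and phenotype joined.

    ``df`` holds {0,1} ints (rows = species, columns = proteins); ``taxonomy``
    maps species_id -> Taxonomy; ``phenotype`` maps species_id -> 5-way label.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        taxonomy: Mapping[str, Taxonomy] | None = None,
        phenotype: Mapping[str, str] | None = None,
    ):
        bad = df.map(lambda v: v not in (0, 1))
        if bad.any().any():
            cell = next(zip(*bad.values.nonzero()))
            raise ValueError(
                f"non-binary cell at row {df.index[cell[0]]!r}, "
                f"column {df.columns[cell[1]]!r}"
            )
        self.df = df.astype(int)
        self.taxonomy = dict(taxonomy or {})
        self.phenotype = dict(phenotype or {})

    @property
    def species_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def protein_names(self) -> list[str]:
        return list(self.df.columns)

    def genus_of(self, species_id: str) -> str:
        tax = self.taxonomy.get(species_id)
        return tax.genus if tax else "unknown"

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "genus", [self.genus_of(s) for s in out.index])
        out.insert(0, "family", [getattr(self.taxonomy.get(s), "family", "unknown") for s in out.index])
        out.insert(0, "class", [getattr(self.taxonomy.get(s), "class_", "unknown") for s in out.index])
        out["phenotype"] = [self.phenotype.get(s, "unknown") for s in out.index]
        out.to_csv(path, sep="\t")


def extract_neighborhood(
    genes: Sequence[GeneRecord],
    focal: str,
    k: int = 3,
    strand_relative: bool = False,
) -> Neighborhood:
    """The k genes before and after the focal gene on its contig.

    Fewer are returned at contig edges. With ``strand_relative=True`` the
    up/down labels are swapped for minus-strand focal genes.
    """
    focal_recs = [g for g in genes if g.gene_id == focal]
    if not focal_recs:
        raise KeyError(f"focal gene {focal!r} not found")
    focal_rec = focal_recs[0]
    contig = sorted(
        (g for g in genes if g.species_id == focal_rec.species_id
         and g.contig_id == focal_rec.contig_id),
        key=lambda g: (g.start, g.gene_id),
    )
    i = next(idx for idx, g in enumerate(contig) if g.gene_id == focal)
    before = contig[max(0, i - k): i][::-1]  # nearest first
    after = contig[i + 1: i + 1 + k]
    if strand_relative and focal_rec.strand == "-":
        before, after = after, before
    return Neighborhood(focal_gene=focal, upstream=before, downstream=after)


def tally_contextual_kos(
    neighborhoods: Iterable[Neighborhood],
    target_protein: str = "",
    min_count: int = 8,
) -> RCKOTable:
    """Tally neighbor KOs across genomes; KOs seen >= min_count are RCKOs.

    Counts are per gene occurrence, pooled across all species (not per-species
    presence). The >= 8 default is the published cutoff.
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    counts: dict[str, int] = {}
    for nbhd in neighborhoods:
        for gene in nbhd.genes:
            if gene.ko:
                counts[gene.ko] = counts.get(gene.ko, 0) + 1
    return RCKOTable(target_protein=target_protein, ko_counts=counts, min_count=min_count)


def call_po(
    candidate: ArchitectureCall,
    nbhd: Neighborhood,
    rckos: RCKOTable,
    expected_ko: Optional[str] = None,
    species_id: str = "",
    focal_ko: Optional[str] = None,
) -> POCall:
    """Apply the three PO rules to one architecture-accepted candidate.

    Accepted iff >= 1 neighbor carries a selected RCKO AND the context is
    defined (some neighbor carries any KO). The focal gene's own KO match is
    recorded but never required. Rejections are data, not errors.
    """
    neighbor_kos = {g.ko for g in nbhd.genes if g.ko}
    context_defined = bool(neighbor_kos)
    matched = neighbor_kos & rckos.selected
    accepted = bool(candidate.accepted and matched and context_defined)
    return POCall(
        species_id=species_id,
        gene_id=candidate.gene_id,
        target_protein=candidate.target_protein,
        architecture=candidate.architecture,
        rckos_matched=matched,
        focal_ko_matched=(expected_ko is not None and focal_ko == expected_ko),
        context_defined=context_defined,
        accepted=accepted,
    )


def build_phyletic_matrix(
    calls: Iterable[POCall],
    species: Sequence[str],
    proteins: Sequence[str],
    spo0a: Optional[Mapping[str, int]] = None,
    taxonomy: Mapping[str, Taxonomy] | None = None,
    phenotype: Mapping[str, str] | None = None,
) -> PhyleticMatrix:
    """Binary matrix with a 1 wherever >= 1 accepted PO exists for the cell.

    Multiple paralogous accepted calls never raise a cell above 1. The Spo0A
    column, when provided, is copied verbatim from the import — it is never
    computed here.
    """
    df = pd.DataFrame(0, index=list(species), columns=list(proteins), dtype=int)
    for call in calls:
        if not call.accepted:
            continue
        if call.species_id not in df.index:
            raise KeyError(f"species {call.species_id!r} not in matrix axes")
        if call.target_protein not in df.columns:
            raise KeyError(f"protein {call.target_protein!r} not in matrix axes")
        df.loc[call.species_id, call.target_protein] = 1
    if spo0a is not None:
        df["Spo0A"] = [int(spo0a.get(s, 0)) for s in df.index]
    return PhyleticMatrix(df, taxonomy=taxonomy, phenotype=phenotype)
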