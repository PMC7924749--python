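"""End-to-end driver: domain hits -> architecture calls -> POs -> matrix.

Thin orchestration over the stage modules; every step is also usable on its
own. The flow mirrors the published procedure: E-filter and overlap-resolve
the per-protein domain hits, match the architecture registry, pool the
3-gene neighborhoods of all architecture-bearing candidates per target to
select RCKOs (>= 8 occurrences), apply the PO rules, and collapse accepted
calls into the binary phyletic matrix with taxonomy, phenotype and the
imported Spo0A column joined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from . import architectures as arch_mod
from . import context as ctx_mod
from .architectures import Architecture, ArchitectureCall
from .context import Neighborhood, PhyleticMatrix, POCall, RCKOTable
from .io_formats import DomainHit, GeneRecord, Taxonomy


@dataclass
class PipelineResult:
    candidates: list[tuple[str, ArchitectureCall]]  # (species_id, call)
    rcko_tables: dict[str, RCKOTable]
    po_calls: list[POCall]
    matrix: PhyleticMatrix


def scan_architectures(
    genes: Sequence[GeneRecord],
    hits: Sequence[DomainHit],
    registry: Sequence[Architecture],
    e_max: float = 0.001,
) -> list[tuple[str, ArchitectureCall]]:
    """Accepted architecture calls as (species_id, call), deterministic order."""
    species_of = {g.gene_id: g.species_id for g in genes}
    seq_of = {g.gene_id: g.aa_seq for g in genes}
    by_gene: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    out: list[tuple[str, ArchitectureCall]] = []
    for gene_id in sorted(by_gene):
        if gene_id not in species_of:
            continue
        gene_hits = arch_mod.resolve_overlaps(
            arch_mod.filter_hits(by_gene[gene_id], e_max=e_max)
        )
        for call in arch_mod.detect_architecture(
            gene_hits, registry, aa_seq=seq_of.get(gene_id)
        ):
            if call.accepted:
                out.append((species_of[gene_id], call))
    return out


def predict_pos(
    genes: Sequence[GeneRecord],
    hits: Sequence[DomainHit],
    registry: Sequence[Architecture],
    e_max: float = 0.001,
    window_k: int = 3,
    rcko_min: int = 8,
) -> tuple[list[POCall], dict[str, RCKOTable]]:
    """Architecture scan plus genomic-context filtering, all targets at once."""
    candidates = scan_architectures(genes, hits, registry, e_max=e_max)
    genes_by_species: dict[str, list[GeneRecord]] = {}
    for g in genes:
        genes_by_species.setdefault(g.species_id, []).append(g)
    ko_of = {g.gene_id: g.ko for g in genes}

    nbhd_cache: dict[str, Neighborhood] = {}

    def neighborhood(species_id: str, gene_id: str) -> Neighborhood:
        if gene_id not in nbhd_cache:
            nbhd_cache[gene_id] = ctx_mod.extract_neighborhood(
                genes_by_species[species_id], gene_id, k=window_k
            )
        return nbhd_cache[gene_id]

    by_target: dict[str, list[tuple[str, ArchitectureCall]]] = {}
    for species_id, call in candidates:
        by_target.setdefault(call.target_protein, []).append((species_id, call))

    rcko_tables: dict[str, RCKOTable] = {}
    po_calls: list[POCall] = []
    for target in sorted(by_target):
        cands = by_target[target]
        nbhds = [neighborhood(sp, call.gene_id) for sp, call in cands]
        rcko_tables[target] = ctx_mod.tally_contextual_kos(
            nbhds, target_protein=target, min_count=rcko_min
        )
        for (species_id, call), nbhd in zip(cands, nbhds):
            po_calls.append(
                ctx_mod.call_po(
                    call,
                    nbhd,
                    rcko_tables[target],
                    species_id=species_id,
                    focal_ko=ko_of.get(call.gene_id),
                )
            )
    return po_calls, rcko_tables


def run_pipeline(
    genes: Sequence[GeneRecord],
    hits: Sequence[DomainHit],
    registry: Sequence[Architecture],
    species: Optional[Sequence[str]] = None,
    spo0a: Optional[Mapping[str, int]] = None,
    taxonomy: Mapping[str, Taxonomy] | None = None,
    phenotype: Mapping[str, str] | None = None,
    e_max: float = 0.001,
    window_k: int = 3,
    rcko_min: int = 8,
) -> PipelineResult:
    if species is None:
        species = sorted({g.species_id for g in genes})
    po_calls, rcko_tables = predict_pos(
        genes, hits, registry, e_max=e_max, window_k=window_k, rcko_min=rcko_min
    )
    matrix = ctx_mod.build_phyletic_matrix(
        po_calls,
        species=species,
        proteins=arch_mod.target_proteins(registry),
        spo0a=spo0a,
        taxonomy=taxonomy,
        phenotype=phenotype,
    )
    candidates = scan_architectures(genes, hits, registry, e_max=e_max)
    return PipelineResult(
        candidates=candidates,
        rcko_tables=rcko_tables,
        po_calls=po_calls,
        matrix=matrix,
    )
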