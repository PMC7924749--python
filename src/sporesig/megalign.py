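"""Species selection, reciprocal-best-hit orthology, and the mega-alignment.

The species tree is built from organisms with a nonredundant phyletic profile
within their family, using single-copy ortholog groups found by the
bidirectional best hit (BDBH) criterion: mutual best hits with E < 1e-4 whose
aligned region covers >= 50% of the shorter protein. Groups present in >= 90%
of the organisms are aligned per group (by a pluggable aligner), missing
species are padded with all-dash rows, columns with < 90% informative
(non-gap) positions are removed, and the filtered blocks are concatenated
into the mega-alignment handed to an external tree builder. A neighbor-
joining fallback over profile or alignment distances exists for test-scale
work only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .context import PhyleticMatrix
from .io_formats import Taxonomy


@dataclass(frozen=True)
class PairHit:
    """One directed pairwise similarity hit from the scoring backend."""

    query_species: str
    query_gene: str
    subject_species: str
    subject_gene: str
    evalue: float
    aln_len: int  # length of the aligned (similar) region


@dataclass
class OrthologGroup:
    group_id: str
    members: dict[str, str]  # species_id -> gene_id (at most one per species)


@dataclass
class MegaAlignment:
    species_ids: list[str]
    sequences: dict[str, str]  # equal-length aligned rows
    partitions: dict[str, tuple[int, int]]  # group_id -> [start, end) columns

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sp in self.species_ids:
                fh.write(f">{sp}\n{self.sequences[sp]}\n")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f" {len(self.species_ids)} {self.length}\n")
            for sp in self.species_ids:
                fh.write(f"{sp}  {self.sequences[sp]}\n")

    def write_partitions(self, path) -> None:
        with open(path, "w") as fh:
            for gid, (a, b) in sorted(self.partitions.items(), key=lambda kv: kv[1]):
                fh.write(f"AA, {gid} = {a + 1}-{b}\n")


def select_representatives(
    matrix: PhyleticMatrix, taxonomy: Mapping[str, Taxonomy] | None = None
) -> list[str]:
    """One species per distinct phyletic profile within each family.

    Tie-break: the lexicographically smallest species_id of each profile
    class. Output size equals the sum over families of distinct profile
    counts.
    """
    tax = taxonomy or matrix.taxonomy
    chosen: list[str] = []
    by_family: dict[str, list[str]] = {}
    for sp in matrix.species_ids:
        fam = tax[sp].family if sp in tax else "unknown"
        by_family.setdefault(fam, []).append(sp)
    for fam in sorted(by_family):
        seen: dict[tuple, str] = {}
        for sp in sorted(by_family[fam]):
            profile = tuple(matrix.df.loc[sp])
            seen.setdefault(profile, sp)
        chosen.extend(sorted(seen.values()))
    return chosen


def bdbh_orthologs(
    score_table: Sequence[PairHit],
    lengths: Mapping[str, int],
    e_max: float = 1e-4,
    cov_min: float = 0.5,
) -> list[OrthologGroup]:
    """Ortholog groups by bidirectional best hits plus single linkage.

    A pair (a, b) is orthologous iff a is b's best hit and b is a's best hit
    in their respective species, E-value strictly below ``e_max``, and the
    aligned region covers >= ``cov_min`` of the shorter protein. Groups are
    single-linkage components of the pair graph with a one-gene-per-species
    cap; conflicts keep the gene with the best mean pair E-value.
    """
    for hit in score_table:
        if hit.query_gene not in lengths or hit.subject_gene not in lengths:
            raise KeyError(f"missing protein length for {hit.query_gene}/{hit.subject_gene}")

    # best hit per (query gene, subject species); ties to lexicographic gene
    best: dict[tuple[str, str], PairHit] = {}
    for h in score_table:
        key = (h.query_gene, h.subject_species)
        cur = best.get(key)
        if cur is None or (h.evalue, h.subject_gene) < (cur.evalue, cur.subject_gene):
            best[key] = h

    pairs: dict[frozenset[str], float] = {}
    for (qgene, ssp), h in best.items():
        back = best.get((h.subject_gene, h.query_species))
        if back is None or back.subject_gene != qgene:
            continue
        min_len = min(lengths[qgene], lengths[h.subject_gene])
        cov_ok = (
            h.aln_len >= cov_min * min_len and back.aln_len >= cov_min * min_len
        )
        e_ok = h.evalue < e_max and back.evalue < e_max
        if cov_ok and e_ok:
            pairs[frozenset((qgene, h.subject_gene))] = max(h.evalue, back.evalue)

    species_of = {h.query_gene: h.query_species for h in score_table}
    species_of.update({h.subject_gene: h.subject_species for h in score_table})

    # single-linkage components
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for pair in pairs:
        a, b = sorted(pair)
        parent[find(a)] = find(b)

    comps: dict[str, list[str]] = {}
    for gene in parent:
        comps.setdefault(find(gene), []).append(gene)

    # per-gene mean evalue over its incident accepted pairs
    incident: dict[str, list[float]] = {}
    for pair, ev in pairs.items():
        for gene in pair:
            incident.setdefault(gene, []).append(ev)

    groups: list[OrthologGroup] = []
    for idx, comp in enumerate(sorted(comps.values(), key=lambda c: sorted(c)[0])):
        members: dict[str, str] = {}
        for gene in sorted(comp, key=lambda g: (np.mean(incident[g]), g)):
            sp = species_of[gene]
            members.setdefault(sp, gene)  # best mean evalue wins the slot
        if len(members) >= 2:
            groups.append(OrthologGroup(group_id=f"OG{idx:05d}", members=members))
    return groups


def core_groups(
    groups: Sequence[OrthologGroup], species: Sequence[str], min_frac: float = 0.90
) -> list[OrthologGroup]:
    """Groups present in at least ceil(min_frac x |species|) of the organisms."""
    need = math.ceil(min_frac * len(species))
    return [g for g in groups if len(g.members) >= need]


def assemble_megaalignment(
    per_group_alignments: Mapping[str, Mapping[str, str]],
    species: Sequence[str],
    col_frac: float = 0.90,
) -> MegaAlignment:
    """Dash-pad, filter uninformative columns, concatenate.

    Each value of ``per_group_alignments`` maps species -> aligned sequence
    (all the same length within a group). Missing species get all-dash rows
    of that length. Columns are kept iff the fraction of non-gap residues is
    >= ``col_frac``; partition intervals are recorded after filtering.
    """
    species = list(species)
    pieces: dict[str, list[str]] = {sp: [] for sp in species}
    partitions: dict[str, tuple[int, int]] = {}
    offset = 0
    for gid in sorted(per_group_alignments):
        aln = per_group_alignments[gid]
        if len(set(aln)) != len(aln):
            raise ValueError(f"{gid}: duplicated species in group alignment")
        lengths = {len(s) for s in aln.values()}
        if len(lengths) != 1:
            raise ValueError(f"{gid}: ragged group alignment")
        width = lengths.pop()
        block = np.array(
            [list(aln.get(sp, "-" * width)) for sp in species], dtype="U1"
        )
        informative = (block != "-").mean(axis=0) >= col_frac
        filtered = block[:, informative]
        for i, sp in enumerate(species):
            pieces[sp].append("".join(filtered[i]))
        new_offset = offset + filtered.shape[1]
        partitions[gid] = (offset, new_offset)
        offset = new_offset
    return MegaAlignment(
        species_ids=species,
        sequences={sp: "".join(parts) for sp, parts in pieces.items()},
        partitions=partitions,
    )


def nj_tree(distance: pd.DataFrame | np.ndarray, taxa: Sequence[str] | None = None) -> str:
    """Neighbor-joining Newick string (test-scale fallback, not an ML tree).

    The distance matrix must be symmetric with zero diagonal and no negative
    entries; ties break deterministically by taxon order.
    """
    if isinstance(distance, pd.DataFrame):
        taxa = list(distance.index)
        mat = distance.values.astype(float)
    else:
        mat = np.asarray(distance, dtype=float)
        taxa = list(taxa or [f"t{i}" for i in range(mat.shape[0])])
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be square and symmetric")
    if (mat < 0).any():
        raise ValueError("negative distances are not allowed")
    if len(taxa) == 2:
        d = mat[0, 1] / 2.0
        return f"({taxa[0]}:{d:g},{taxa[1]}:{d:g});"
    tree = _skbio_nj(DistanceMatrix(mat, ids=taxa))
    return str(tree).strip()


def simple_pair_hits(
    proteomes: Mapping[str, Mapping[str, str]],
) -> tuple[list[PairHit], dict[str, int]]:
    """A built-in pairwise scoring backend for tests and examples.

    Globally aligns every cross-species protein pair with a BLOSUM-free
    match/mismatch scheme and converts the score to a pseudo E-value
    ``2^-score`` (monotone in similarity; not a database E-value). Real
    pipelines plug in an external aligner's tabular output instead.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    lengths = {
        gene: len(seq) for genes in proteomes.values() for gene, seq in genes.items()
    }
    hits: list[PairHit] = []
    species = sorted(proteomes)
    for qs in species:
        for ss in species:
            if qs == ss:
                continue
            for qg, qseq in sorted(proteomes[qs].items()):
                for sg, sseq in sorted(proteomes[ss].items()):
                    aln = aligner.align(qseq, sseq)[0]
                    score = aln.score
                    aligned_cols = sum(qe - qs_ for (qs_, qe) in aln.aligned[0])
                    evalue = 2.0 ** (-float(score)) if score > 0 else 10.0
                    hits.append(
                        PairHit(qs, qg, ss, sg, evalue=evalue, aln_len=aligned_cols)
                    )
    return hits, lengths
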