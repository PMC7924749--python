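"""Rescue unannotated spoIIIA-operon genes from intergenic DNA.

Two planted SpoIIIAH genes are deleted from the annotation but their coding
sequence stays in the contig. The rescue stage finds intergenic gaps >= 200
nt, translates all six frames, rescans at the relaxed E <= 0.01, and accepts
a candidate only with a matching architecture and a contextual KO (here the
acetyl-CoA-carboxylase-like K01961 downstream) in the flanking genes.
"""

import sporesig as s
from sporesig.pipeline import predict_pos
from sporesig.rescue import find_intergenic_gaps, rescue_scan

bundle = s.generate_pangenome(s.SynthConfig(rng_seed=1, hidden_gene_count=2))
print("hidden genes:", [(h["species_id"], h["target"], h["strand"])
                        for h in bundle.truth.hidden_genes])

sub = [g for g in bundle.genes
       if (g.species_id, g.contig_id) in bundle.contig_seqs]
regions = find_intergenic_gaps(sub, bundle.contig_lengths, min_gap=200)
print(f"intergenic regions >= 200 nt on the affected contigs: {len(regions)}")

_, rckos = predict_pos(bundle.genes, bundle.hits, s.default_registry())
rescued = rescue_scan(regions, s.MockProfileBackend(), s.default_registry(),
                      bundle.contig_seqs, genes=sub, rckos=rckos)
for r in rescued:
    if r.accepted:
        print(f"rescued {r.architecture_call.target_protein} in "
              f"{r.region.species_id} at {r.region.start}-{r.region.end} "
              f"frame {r.frame:+d}, context {sorted(r.context_support)}")
# Every hidden gene is recovered and nothing else is accepted:
# precision = recall = 1 on noise-free input.
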