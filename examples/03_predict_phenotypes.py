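"""Predict sporulation phenotypes for inferred/unknown species.

A species whose profile contains every protein of its genus signature is
called consistent with sporulation; a species missing a signature protein
is predicted nonsporulating; genera without a significant signature give no
call.
"""

from collections import Counter

import sporesig as s
from sporesig.pipeline import run_pipeline
from sporesig.signatures import predict_phenotype

bundle = s.generate_pangenome(s.SynthConfig(rng_seed=1))
result = run_pipeline(
    bundle.genes, bundle.hits, s.default_registry(),
    spo0a=bundle.truth.spo0a, taxonomy=bundle.truth.taxonomy,
    phenotype=bundle.truth.phenotypes,
)
matrix = result.matrix
by_genus = {r.genus: r for r in s.call_signatures(matrix)}

verdicts = {}
for sp in matrix.species_ids:
    if matrix.phenotype.get(sp) not in ("sporulating_inferred", "unknown"):
        continue
    sig = by_genus[matrix.genus_of(sp)]
    verdicts[sp] = predict_phenotype(matrix.df.loc[sp].to_dict(), sig)

print(f"tested {len(verdicts)} species with inferred/unknown phenotype:")
for verdict, count in sorted(Counter(verdicts.values()).items()):
    print(f"  {verdict}: {count}")
deviants = [sp for sp, v in verdicts.items() if v == "deviates_nonsporulating"]
print(f"\npredicted nonsporulating: {deviants}")
print(f"planted deviants:         {sorted(bundle.truth.deviant_species)}")
# The one species planted with a broken signature is the one flagged.
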