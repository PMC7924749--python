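"""Shared fixtures: one synthetic pan-genome bundle reused across the suite."""

from __future__ import annotations

import dendropy
import pytest

import sporesig as s
from sporesig.pipeline import run_pipeline


BUNDLE_SEED = 11


@pytest.fixture(scope="session")
def bundle():
    cfg = s.SynthConfig(rng_seed=BUNDLE_SEED, hidden_gene_count=2)
    return s.generate_pangenome(cfg)


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    return run_pipeline(
        bundle.genes,
        bundle.hits,
        s.default_registry(),
        spo0a=bundle.truth.spo0a,
        taxonomy=bundle.truth.taxonomy,
        phenotype=bundle.truth.phenotypes,
    )


def balanced_newick(n_tips: int, bl: float = 0.3) -> str:
    names = [f"t{i}" for i in range(n_tips)]

    def build(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return f"{names[lo]}:{bl}"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):{bl}"

    return build(0, n_tips) + ";"


@pytest.fixture(scope="session")
def tree32():
    return dendropy.Tree.get(data=balanced_newick(32), schema="newick")


@pytest.fixture(scope="session")
def rate_recovery(tree32):
    """Simulate 500 characters at known rates and refit once for the session."""
    true_g, true_l = 0.5, 1.5
    matrix, events = s.simulate_profiles(tree32, true_g, true_l, 500, seed=7)
    model = s.fit_gainloss(tree32, matrix)
    return {"true": (true_g, true_l), "model": model, "matrix": matrix, "events": events}
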