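"""Shared fixtures: one desk-scale synthetic study reused across test modules."""

import numpy as np
import pytest

import extremosig as es


@pytest.fixture(scope="session")
def study():
    """Default-config synthetic dataset (120 genomes) with k=6 and k=3 signatures."""
    cfg = es.GeneratorConfig(seed=0)
    contigsets, meta, truth = es.generate_dataset(cfg)
    sig6 = es.signatures_from_contigsets(contigsets, k=6, seed=0)
    sig3 = es.signatures_from_contigsets(contigsets, k=3, seed=0)
    return {
        "config": cfg,
        "contigsets": contigsets,
        "meta": meta,
        "truth": truth,
        "sig6": sig6,
        "sig3": sig3,
        "domain": np.array([m.domain for m in meta]),
        "env": np.array([m.temp_category for m in meta]),
        "genus": np.array([m.genus for m in meta]),
    }


def random_dna(rng, length, with_n=False):
    alphabet = "ACGTN" if with_n else "ACGT"
    p = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(list(alphabet), size=length, p=p))
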