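"""Shared fixtures: synthetic benchmark runs reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from fxlink import xl_consensus as xc
from fxlink import xl_search as xs
from fxlink.synthetic import gen_proteome, gen_xl_spectra

BENCHMARK_SEED = 1


def _true_residue_pairs(truth: dict) -> set:
    return {
        tuple(sorted([
            (l["protein_a"], l["site_a_protein"]),
            (l["protein_b"], l["site_b_protein"]),
        ]))
        for l in truth["links"]
    }


def _run_benchmark(coverage: float) -> dict:
    """Default seeded benchmark: 30 proteins, 40 planted links, 3 replicates."""
    proteome, localisation = gen_proteome(30, 300, seed=BENCHMARK_SEED)
    spectra_by_rep, truth = gen_xl_spectra(
        proteome, n_links=40, coverage=coverage, noise_peaks=5, seed=BENCHMARK_SEED
    )
    params = xs.SearchParams()
    db = xs.build_search_database(proteome, n_top=len(proteome))
    index = xs.PeptideIndex(db, params)
    hits_by_rep = {
        rep: xs.search_spectra(spectra, index, params)
        for rep, spectra in spectra_by_rep.items()
    }
    links = xc.build_consensus(hits_by_rep, condition=truth["condition"])
    accepted = [l for l in links if xc.accept(l)]
    found = {
        tuple(sorted([(l.protein_a, int(l.site_a)), (l.protein_b, int(l.site_b))]))
        for l in accepted
    }
    true_pairs = _true_residue_pairs(truth)
    return {
        "proteome": proteome,
        "localisation": localisation,
        "truth": truth,
        "index": index,
        "params": params,
        "hits_by_rep": hits_by_rep,
        "links": links,
        "accepted": accepted,
        "recovery": len(true_pairs & found) / len(true_pairs),
        "true_pairs": true_pairs,
        "found_pairs": found,
    }


@pytest.fixture(scope="session")
def xl_benchmark() -> dict:
    """Planted-link benchmark at the default 85% fragment coverage."""
    return _run_benchmark(coverage=0.85)


@pytest.fixture(scope="session")
def xl_benchmark_low_coverage() -> dict:
    """Same benchmark degraded to 30% fragment coverage."""
    return _run_benchmark(coverage=0.30)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
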