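"""Shared simulation fixtures.

The heavier simulated datasets are session-scoped so the property tests and
the acceptance suite reuse one realization instead of regenerating it.
"""

from __future__ import annotations

import numpy as np
import pytest

from ptmd import enrichment as en
from ptmd import footprints as fp
from ptmd import synthetic as syn
from ptmd.config import SimulationConfig
from ptmd.genetics import SENSE_CODONS

RECOVERY_DEPTH = 200_000


def distinct_codon_weights(seed: int = 7) -> dict[str, float]:
    """An all-distinct recruitment-weight vector spanning ~0.5x-4x."""
    rng = np.random.default_rng(seed)
    return {c: float(w) for c, w in zip(SENSE_CODONS, np.exp2(rng.uniform(-1, 2, len(SENSE_CODONS))))}


@pytest.fixture(scope="session")
def concentrated_sim():
    """Few transcripts / one read length: deep per-species coverage, so the
    significance-thresholded enrichment statistic has power at desk scale."""
    cfg = SimulationConfig(
        seed=1, n_transcripts=25, cds_length_range=(90, 130), read_length_probs={29: 1.0}
    )
    tx = syn.generate_transcriptome(cfg)
    inp = syn.simulate_footprints(tx, cfg, "input")
    ip = syn.simulate_footprints(tx, cfg, "ip")
    ia = fp.annotate_footprints(inp, tx)
    pa = fp.annotate_footprints(ip, tx)
    results = en.test_footprint_enrichment(ip, inp, alpha=0.01)
    return {"config": cfg, "tx": tx, "input": inp, "ip": ip,
            "input_annot": ia, "ip_annot": pa, "results": results}


@pytest.fixture(scope="session")
def broad_sim():
    """Many-transcript simulation with the default 4-length read mixture,
    plus IP libraries under distinct and flat recruitment weights."""
    cfg = SimulationConfig(seed=1, n_transcripts=120, cds_length_range=(120, 200))
    tx = syn.generate_transcriptome(cfg)
    inp = syn.simulate_footprints(tx, cfg, "input")
    ia = fp.annotate_footprints(inp, tx)

    wdist = distinct_codon_weights()
    cfg_dist = cfg.replace(recruitment_weights=wdist)
    pa_dist = fp.annotate_footprints(syn.simulate_footprints(tx, cfg_dist, "ip"), tx)

    cfg_flat = cfg.replace(recruitment_weights={c: 1.0 for c in SENSE_CODONS})
    pa_flat = fp.annotate_footprints(syn.simulate_footprints(tx, cfg_flat, "ip"), tx)

    return {"config": cfg, "tx": tx, "input": inp, "input_annot": ia,
            "distinct_weights": wdist, "ip_annot_distinct": pa_dist,
            "ip_annot_flat": pa_flat}


@pytest.fixture(scope="session")
def coupling_sim():
    """Flat recruitment, spread dwell times, IP acceptance coupled to the
    A-site dwell only when the P-site codon is CGG/CGA/AGG."""
    rng = np.random.default_rng(11)
    dwells = {c: float(np.exp2(rng.normal(0.0, 0.5))) for c in SENSE_CODONS}
    cfg = SimulationConfig(
        seed=5,
        n_transcripts=120,
        cds_length_range=(120, 200),
        recruitment_weights={c: 1.0 for c in SENSE_CODONS},
        dwell_times=dwells,
        ip_dwell_coupling=frozenset({"CGG", "CGA", "AGG"}),
        ip_dwell_exponent=1.0,
    )
    tx = syn.generate_transcriptome(cfg)
    inp = syn.simulate_footprints(tx, cfg, "input")
    ip = syn.simulate_footprints(tx, cfg, "ip")
    ip_uncoupled = syn.simulate_footprints(tx, cfg.replace(ip_dwell_coupling=None), "ip")
    # an independent input realization for dwell-time estimation, so the
    # dwell table's sampling noise is not shared with the enrichment ratios
    # (mirrors taking dwell times from an independent dataset)
    inp_b = syn.simulate_footprints(tx, cfg.replace(seed=105), "input")
    return {"config": cfg, "tx": tx, "dwells": dwells,
            "input_annot": fp.annotate_footprints(inp, tx),
            "input_annot_b": fp.annotate_footprints(inp_b, tx),
            "ip_annot": fp.annotate_footprints(ip, tx),
            "ip_annot_uncoupled": fp.annotate_footprints(ip_uncoupled, tx)}
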