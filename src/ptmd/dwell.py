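"""A-site dwell-time estimation and P-site-conditioned correlation.

The relative decoding speed of each codon is approximated by its A-site
dwell time: the count-weighted share of input footprints with the codon in
the A-site, divided by the codon's expected share given the codon
composition of the positions ribosomes could have occupied
(coverage-weighted per transcript, so transcript abundance cancels).

The conditional analysis partitions footprints by P-site codon class
*before* recomputing A-site enrichment on each partition, then correlates
the partition-specific log2 A-site enrichment with log2 dwell time — the
comparison that shows dwell time matters for CNOT3 association mainly when
a CGG/CGA/AGG arginine codon occupies the P-site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection

import numpy as np
import pandas as pd
from scipy import stats

from ptmd.footprints import Transcriptome
from ptmd.genetics import SENSE_CODONS

ARG_PSITE_CODONS = frozenset({"CGG", "CGA", "AGG"})


def estimate_dwell_times(
    annotated_input: pd.DataFrame, transcriptome: Transcriptome
) -> pd.DataFrame:
    """Ratio estimator of per-codon A-site dwell time from the input library.

    occupancy: each codon's share of count-weighted A-site observations.
    expected: each codon's share of eligible A-site positions (internal
    codons, start/stop and the two outermost codons excluded), with each
    transcript's positions weighted by that transcript's footprint total so
    that doubling a transcript's abundance leaves the estimate unchanged.
    dwell = occupancy / expected; codons never eligible are undefined.
    """
    ok = annotated_input[
        (annotated_input["status"] == "ok")
        & annotated_input["a_codon"].isin(SENSE_CODONS)
    ]
    occ = ok.groupby("a_codon")["count"].sum().reindex(SENSE_CODONS, fill_value=0).astype(float)
    occupancy = occ / occ.sum()

    per_tx_counts = ok.groupby("transcript_id")["count"].sum()
    expected = pd.Series(0.0, index=list(SENSE_CODONS))
    for tid, c_t in per_tx_counts.items():
        tx = transcriptome[tid]
        cods = tx.codons()
        eligible = [c for c in cods[3 : tx.n_codons - 2] if c in SENSE_CODONS]
        if not eligible:
            continue
        share = pd.Series(eligible).value_counts() / len(eligible)
        expected = expected.add(c_t * share, fill_value=0.0)
    expected = expected.reindex(SENSE_CODONS, fill_value=0.0)
    expected = expected / expected.sum()

    with np.errstate(divide="ignore", invalid="ignore"):
        dwell = np.where(expected > 0, occupancy / expected, np.nan)
    return pd.DataFrame(
        {
            "codon": list(SENSE_CODONS),
            "occupancy": occupancy.to_numpy(),
            "expected": expected.to_numpy(),
            "dwell": dwell,
        }
    )


def load_dwell_table(path) -> pd.DataFrame:
    """Read an external per-codon dwell table (columns: codon, dwell)."""
    df = pd.read_csv(path, sep="\t")
    if not {"codon", "dwell"}.issubset(df.columns):
        raise ValueError("dwell table must have columns codon, dwell")
    return df


@dataclass
class ConditionalCorrelation:
    r: float
    p_value: float
    n: int
    partition: str
    site_table: pd.DataFrame


def _partition(annotated: pd.DataFrame, p_site_codons, complement: bool) -> pd.DataFrame:
    mask = annotated["p_codon"].isin(set(p_site_codons))
    if complement:
        mask = ~mask & annotated["p_codon"].notna()
    return annotated[mask]


def conditional_enrichment_dwell_correlation(
    ip_annotated: pd.DataFrame,
    input_annotated: pd.DataFrame,
    dwell_table: pd.DataFrame,
    p_site_codons: Collection[str] | None = None,
    complement: bool = False,
    selection: str = "ip",
    alpha: float = 0.01,
) -> ConditionalCorrelation:
    """Pearson correlation of A-site enrichment with dwell time in a P-site
    codon partition.

    Footprints are restricted to those whose P-site codon is in
    ``p_site_codons`` (or its complement) before the A-site enrichment table
    is recomputed on the partition.  ``selection='ip'`` (default) uses the
    direct all-IP-footprint ratio, which stays defined in partitions too
    sparse for per-species significance calling; ``selection='enriched'``
    reruns the Fisher/FDR test within the partition first.
    Both enrichment ratio and dwell are log2-transformed.
    """
    from ptmd.enrichment import site_codon_enrichment, test_footprint_enrichment
    from ptmd.footprints import FootprintSet

    if p_site_codons is None:
        ip_part, input_part = ip_annotated, input_annotated
        label = "all"
    else:
        ip_part = _partition(ip_annotated, p_site_codons, complement)
        input_part = _partition(input_annotated, p_site_codons, complement)
        label = ("complement-of-" if complement else "") + "/".join(sorted(p_site_codons))

    results = None
    if selection == "enriched":
        cols = ["transcript_id", "five_prime_pos", "length", "count"]
        results = test_footprint_enrichment(
            FootprintSet("ip", ip_part[cols]),
            FootprintSet("input", input_part[cols]),
            alpha=alpha,
        )
    table = site_codon_enrichment(
        ip_part, input_part, site="A", results=results, selection=selection
    )

    merged = table.set_index("codon")[["ratio"]].join(
        dwell_table.set_index("codon")["dwell"], how="inner"
    )
    merged = merged[(merged["ratio"] > 0) & (merged["dwell"] > 0)].dropna()
    if len(merged) < 3:
        raise ValueError(
            f"partition {label!r} has only {len(merged)} codons with defined values"
        )
    r, p = stats.pearsonr(np.log2(merged["ratio"]), np.log2(merged["dwell"]))
    return ConditionalCorrelation(float(r), float(p), int(len(merged)), label, table)


def dwell_correlation_null_band(
    site_table: pd.DataFrame,
    dwell_table: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
    quantiles: tuple[float, float] = (0.025, 0.975),
) -> tuple[float, float]:
    """Permutation 95% band for the dwell correlation under codon-label shuffling."""
    merged = site_table.set_index("codon")[["ratio"]].join(
        dwell_table.set_index("codon")["dwell"], how="inner"
    )
    merged = merged[(merged["ratio"] > 0) & (merged["dwell"] > 0)].dropna()
    x = np.log2(merged["ratio"].to_numpy())
    y = np.log2(merged["dwell"].to_numpy())
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    rs = np.empty(n_permutations)
    for i in range(n_permutations):
        rs[i] = (xc * rng.permutation(yc)).sum() / denom
    lo, hi = np.quantile(rs, quantiles)
    return float(lo), float(hi)
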