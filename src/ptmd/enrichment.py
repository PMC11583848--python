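"""IP-enrichment testing and site-level codon / amino-acid enrichment.

The core statistic mirrors the selective-profiling analysis: footprint
species significantly enriched in the IP library over the input library
(two-sided Fisher's exact test, Benjamini–Hochberg FDR < 0.01, IP-direction
enforced) are identified first; the percentage of enriched footprints
bearing each codon at the E-, P- or A-site, divided by the percentage of
input footprints bearing it, is the per-codon enrichment ratio.

Fisher p-values are computed with exact integer hypergeometric numerators
(arbitrary-precision combinatorics), so ties in the two-sided tail are
resolved exactly rather than to floating-point tolerance.

Besides the significance-thresholded ratio, a direct ratio over *all* IP
footprints (``selection='ip'``) is provided: at modest sequencing depth the
thresholded estimator censors weakly enriched codons toward zero, so rank
comparisons against a continuous per-codon quantity use the direct ratio.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_right
from itertools import accumulate
from math import comb
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ptmd.footprints import FootprintSet, Transcriptome
from ptmd.genetics import SENSE_CODONS, translate_codon

logger = logging.getLogger(__name__)

_KEY = ["transcript_id", "five_prime_pos", "length"]


# ---------------------------------------------------------------------------
# Fisher's exact test (two-sided), vectorised over footprint species
# ---------------------------------------------------------------------------

def fisher_exact_pvalues(
    ip_counts: np.ndarray, input_counts: np.ndarray, ip_total: int, input_total: int
) -> np.ndarray:
    """Two-sided Fisher p for tables [[a, ip_total-a], [b, input_total-b]].

    For each species the conditional distribution of a given the species
    total n = a + b is hypergeometric with support of size <= n + 1, so the
    probabilities are computed as exact integers C(ip_total, k) *
    C(input_total, n-k) and the two-sided tail (all k with probability <=
    that of the observed table) is summed by integer comparison — no
    floating-point tie tolerance.
    """
    a = np.asarray(ip_counts, dtype=np.int64)
    b = np.asarray(input_counts, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("count arrays must have equal length")
    if np.any(a < 0) or np.any(b < 0) or np.any(a > ip_total) or np.any(b > input_total):
        raise ValueError("counts must be within [0, library total]")
    n = a + b
    p = np.ones(a.shape, dtype=float)
    for nv in np.unique(n):
        idx = np.nonzero(n == nv)[0]
        k_lo = max(0, int(nv) - input_total)
        k_hi = min(int(nv), ip_total)
        # integer numerators of the hypergeometric pmf over the support
        nums: list[int] = []
        c = comb(ip_total, k_lo) * comb(input_total, int(nv) - k_lo)
        for k in range(k_lo, k_hi + 1):
            nums.append(c)
            if k < k_hi:
                c = c * (ip_total - k) * (int(nv) - k) // ((k + 1) * (input_total - int(nv) + k + 1))
        denom = sum(nums)
        order = sorted(range(len(nums)), key=nums.__getitem__)
        sorted_nums = [nums[i] for i in order]
        prefix = list(accumulate(sorted_nums))
        for i in idx:
            num_obs = nums[int(a[i]) - k_lo]
            rank = bisect_right(sorted_nums, num_obs)
            p[i] = prefix[rank - 1] / denom
    return np.minimum(p, 1.0)


def test_footprint_enrichment(
    ip: FootprintSet, input_set: FootprintSet, alpha: float = 0.01
) -> pd.DataFrame:
    """Per-species IP-vs-input enrichment test.

    The tested universe is the union of footprint keys from both libraries
    (absent keys count 0).  Returns one row per species with the Fisher p,
    the BH-adjusted q and the ``enriched`` flag (q < alpha and proportions in
    the IP direction).
    """
    ip_total, input_total = ip.total, input_set.total
    if ip_total == 0 or input_total == 0:
        raise ValueError("both libraries must contain footprints")
    merged = pd.merge(
        ip.data.rename(columns={"count": "ip_count"}),
        input_set.data.rename(columns={"count": "input_count"}),
        on=_KEY,
        how="outer",
    ).fillna({"ip_count": 0, "input_count": 0})
    merged["ip_count"] = merged["ip_count"].astype(np.int64)
    merged["input_count"] = merged["input_count"].astype(np.int64)
    merged["ip_total"] = ip_total
    merged["input_total"] = input_total
    merged["p_value"] = fisher_exact_pvalues(
        merged["ip_count"].to_numpy(), merged["input_count"].to_numpy(), ip_total, input_total
    )
    merged["q_value"] = multipletests(merged["p_value"].to_numpy(), method="fdr_bh")[1]
    toward_ip = merged["ip_count"] / ip_total > merged["input_count"] / input_total
    merged["enriched"] = (merged["q_value"] < alpha) & toward_ip
    return merged


# ---------------------------------------------------------------------------
# site-level enrichment tables
# ---------------------------------------------------------------------------

def _numerator_annotations(
    ip_annotated: pd.DataFrame,
    results: pd.DataFrame | None,
    selection: str,
) -> pd.DataFrame:
    if selection == "enriched":
        if results is None:
            raise ValueError("selection='enriched' requires the enrichment test results")
        keys = results.loc[results["enriched"], _KEY]
        return ip_annotated.merge(keys, on=_KEY, how="inner")
    if selection == "ip":
        return ip_annotated
    raise ValueError("selection must be 'enriched' or 'ip'")


def site_codon_enrichment(
    ip_annotated: pd.DataFrame,
    input_annotated: pd.DataFrame,
    site: str,
    results: pd.DataFrame | None = None,
    selection: str = "enriched",
    min_input_count: int = 50,
) -> pd.DataFrame:
    """Per-codon enrichment ratio at one ribosomal site.

    ``pct_enriched`` is the count-weighted percentage of numerator footprints
    (the significantly enriched set, or all IP footprints for
    ``selection='ip'``) bearing each sense codon at the site; ``pct_input``
    the same over input footprints; ``ratio`` their quotient.  Percentages
    are normalized over sense codons observed in the input, so
    sum(ratio * pct_input) == 100.  Codons unobserved in the input are
    reported with an undefined (NaN) ratio; stop-codon tallies are kept in
    ``DataFrame.attrs['stop_counts']``.
    """
    from ptmd.footprints import site_codon_counts

    numer_annot = _numerator_annotations(ip_annotated, results, selection)
    numer = site_codon_counts(numer_annot, site)
    input_counts = site_codon_counts(input_annotated, site)

    stop_counts = {
        "numerator": int(numer.drop(index=list(SENSE_CODONS), errors="ignore").sum()),
        "input": int(input_counts.drop(index=list(SENSE_CODONS), errors="ignore").sum()),
    }
    numer = numer.reindex(SENSE_CODONS, fill_value=0).astype(float)
    inp = input_counts.reindex(SENSE_CODONS, fill_value=0).astype(float)

    observed = inp > 0
    if numer[observed].sum() == 0:
        warnings.warn(f"empty numerator footprint set at site {site}; ratios undefined")
    pct_num = pd.Series(np.nan, index=numer.index)
    pct_inp = pd.Series(np.nan, index=inp.index)
    if numer[observed].sum() > 0:
        pct_num[observed] = 100.0 * numer[observed] / numer[observed].sum()
    pct_inp[observed] = 100.0 * inp[observed] / inp[observed].sum()
    ratio = pct_num / pct_inp

    table = pd.DataFrame(
        {
            "codon": list(SENSE_CODONS),
            "amino_acid": [translate_codon(c) for c in SENSE_CODONS],
            "pct_enriched": pct_num.to_numpy(),
            "pct_input": pct_inp.to_numpy(),
            "ratio": ratio.to_numpy(),
            "n_enriched": numer.to_numpy(int),
            "n_input": inp.to_numpy(int),
        }
    )
    table["low_support"] = table["n_input"] < min_input_count
    table.attrs["site"] = site.upper()
    table.attrs["selection"] = selection
    table.attrs["stop_counts"] = stop_counts
    return table


def _aa_triples(annotated: pd.DataFrame) -> pd.DataFrame:
    ok = annotated[
        (annotated["status"] == "ok")
        & annotated["e_codon"].notna()
        & annotated["a_codon"].notna()
    ].copy()
    for col in ("e_codon", "p_codon", "a_codon"):
        ok[col.replace("codon", "aa")] = ok[col].map(translate_codon)
    ok = ok[(ok[["e_aa", "p_aa", "a_aa"]] != "*").all(axis=1)]
    ok["tripeptide"] = ok["e_aa"] + ok["p_aa"] + ok["a_aa"]
    return ok


def tripeptide_enrichment(
    ip_annotated: pd.DataFrame,
    input_annotated: pd.DataFrame,
    results: pd.DataFrame | None = None,
    selection: str = "enriched",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Amino-acid enrichment: (E, P, A) tripeptides and per-site residues.

    Applies the same percentage-ratio statistic to the amino acids encoded at
    the three sites.  Returns ``(tripeptide_table, logo_matrix)`` where the
    logo matrix is amino acid x site enrichment ratios, ready for sequence-
    logo rendering.  Triples touching a stop codon are excluded.
    """
    numer = _aa_triples(_numerator_annotations(ip_annotated, results, selection))
    inp = _aa_triples(input_annotated)

    def pct(df: pd.DataFrame, col: str) -> pd.Series:
        tallies = df.groupby(col)["count"].sum().astype(float)
        return 100.0 * tallies / tallies.sum()

    tri_inp = pct(inp, "tripeptide")
    tri_num = pct(numer, "tripeptide").reindex(tri_inp.index, fill_value=0.0)
    tri = (
        pd.DataFrame({"tripeptide": tri_inp.index, "pct_enriched": tri_num.to_numpy(),
                      "pct_input": tri_inp.to_numpy()})
        .assign(ratio=lambda d: d["pct_enriched"] / d["pct_input"])
        .sort_values("ratio", ascending=False, ignore_index=True)
    )
    tri["p_site_aa"] = tri["tripeptide"].str[1]

    logo = {}
    for site, col in zip("EPA", ("e_aa", "p_aa", "a_aa")):
        site_inp = pct(inp, col)
        site_num = pct(numer, col).reindex(site_inp.index, fill_value=0.0)
        logo[site] = site_num / site_inp
    logo_matrix = pd.DataFrame(logo).rename_axis("amino_acid")
    return tri, logo_matrix


# ---------------------------------------------------------------------------
# weighted codon score and metric correlation
# ---------------------------------------------------------------------------

def weighted_codon_score(
    transcriptome: Transcriptome, weights: Mapping[str, float]
) -> pd.DataFrame:
    """Per-transcript weighted codon score.

    Sum of the weights of the ORF's sense codons divided by the number of
    ORF sense codons (stop codons excluded from both; unknown/ambiguous
    codons contribute zero weight but stay in the denominator).
    """
    rows = []
    unknown_seen = 0
    for tx in transcriptome:
        total = weighted = 0.0
        n_weighted = 0
        n_codons = 0
        for codon in tx.codons():
            if codon in SENSE_CODONS:
                n_codons += 1
                w = weights.get(codon, 0.0)
                if w:
                    weighted += w
                    n_weighted += 1
            elif translate_codon(codon) == "X":
                n_codons += 1
                unknown_seen += 1
        rows.append(
            {
                "transcript_id": tx.id,
                "score": weighted / n_codons if n_codons else 0.0,
                "n_codons": n_codons,
                "n_weighted": n_weighted,
            }
        )
    if unknown_seen:
        logger.warning("%d ambiguous codons contributed zero weight", unknown_seen)
    return pd.DataFrame(rows)


def weights_from_site_table(
    site_table: pd.DataFrame, codons: tuple[str, ...] = ("CGG", "CGA", "AGG")
) -> dict[str, float]:
    """Extract enrichment-ratio weights for a codon set from a P-site table."""
    sub = site_table.set_index("codon").loc[list(codons), "ratio"]
    if sub.isna().any():
        raise ValueError(f"undefined enrichment ratio for {list(sub.index[sub.isna()])}")
    return sub.to_dict()


def correlate_codon_metric(
    site_table: pd.DataFrame,
    metric: Mapping[str, float],
    method: str = "pearson",
    log2_ratio: bool = True,
) -> tuple[float, float, int]:
    """Correlate per-codon site enrichment with an external codon metric.

    The metric is any codon-keyed quantity (tAI, codon stability coefficient,
    dwell time, ...).  Ratios are log2-transformed by default; codons with an
    undefined or non-positive ratio, or without a metric value, are dropped.
    Returns (r, p, n).
    """
    metric_s = pd.Series(dict(metric), dtype=float)
    df = site_table.set_index("codon")[["ratio"]].join(metric_s.rename("metric"), how="inner")
    df = df.dropna()
    if log2_ratio:
        df = df[df["ratio"] > 0]
        x = np.log2(df["ratio"].to_numpy())
    else:
        x = df["ratio"].to_numpy()
    y = df["metric"].to_numpy()
    if len(df) < 3:
        raise ValueError(f"only {len(df)} codons with both values defined; need >= 3")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p), int(len(df))
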