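"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the structure of a selective ribosome profiling
experiment: a transcriptome of AUG...stop ORFs, paired input/IP footprint
libraries in which the IP accepts footprints in proportion to a P-site codon
recruitment weight (the mechanism under study: the P-site tRNA recruits
CNOT3), ribosome positions occupied in proportion to the A-site codon's
relative dwell time, labeled-fraction decay time courses over
0/1/2/4/8/12 h in control and perturbed conditions, and cloverleaf tRNA
records with prescribed D-arm features.

Everything is deterministic given the config seed; independent seed streams
are derived per generator so adding one stage never perturbs another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ptmd.config import ConfigurationError, SimulationConfig
from ptmd.footprints import (
    FootprintSet,
    P_SITE_OFFSETS,
    Transcriptome,
    TranscriptRecord,
)
from ptmd.genetics import SENSE_CODONS, STOP_CODONS, revcomp_rna

_NUCS = np.array(list("ACGT"))

# fixed salts so each generator draws from an independent stream
_SALT_TRANSCRIPTOME = 11
_SALT_FOOTPRINTS = 29
_SALT_DECAY = 47
_SALT_BASE_HALFLIFE = 99


def _rng(config: SimulationConfig, *salts: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed)] + [int(s) for s in salts])


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

def generate_transcriptome(config: SimulationConfig) -> Transcriptome:
    """Random transcriptome: 5'UTR + (AUG ... stop) ORF + 3'UTR per transcript.

    Internal codons are drawn from ``config.codon_frequency``; the first codon
    is always ATG and the last a stop codon.  UTR lengths are drawn from the
    configured ranges (the 5'UTR is kept >= 13 nt so any P-site offset fits).
    """
    rng = _rng(config, _SALT_TRANSCRIPTOME)
    codons = np.array(SENSE_CODONS)
    probs = np.array([config.codon_frequency[c] for c in SENSE_CODONS])
    probs = probs / probs.sum()
    stops = np.array(STOP_CODONS)
    lo, hi = config.cds_length_range
    width = len(str(config.n_transcripts))
    records = []
    for i in range(config.n_transcripts):
        n = int(rng.integers(lo, hi + 1))
        u5 = int(rng.integers(config.utr5_range[0], config.utr5_range[1] + 1))
        u3 = int(rng.integers(config.utr3_range[0], config.utr3_range[1] + 1))
        internal = rng.choice(codons, size=n - 2, p=probs)
        orf = "ATG" + "".join(internal) + str(rng.choice(stops))
        utr5 = "".join(rng.choice(_NUCS, size=u5))
        utr3 = "".join(rng.choice(_NUCS, size=u3))
        records.append(
            TranscriptRecord(
                id=f"tx{i:0{width}d}",
                sequence=utr5 + orf + utr3,
                cds_start=u5,
                cds_end=u5 + 3 * n,
            )
        )
    return Transcriptome(records)


# ---------------------------------------------------------------------------
# footprints
# ---------------------------------------------------------------------------

def _eligible_positions(transcriptome: Transcriptome) -> pd.DataFrame:
    """All ribosome placements with the P-site at an internal codon.

    The first and last two codons of each ORF are excluded as P-site
    positions, so the E, P and A sites of every placement are sense codons
    away from initiation/termination.
    """
    rows = []
    for tx in transcriptome:
        n = tx.n_codons
        cod = tx.codons()
        for i in range(2, n - 2):
            rows.append((tx.id, i, tx.cds_start + 3 * i, cod[i], cod[i + 1]))
    df = pd.DataFrame(rows, columns=["transcript_id", "p_index", "p_start", "p_codon", "a_codon"])
    if df.empty:
        raise ConfigurationError("no eligible ribosome positions; ORFs too short")
    return df


def simulate_footprints(
    transcriptome: Transcriptome,
    config: SimulationConfig,
    library: str,
) -> FootprintSet:
    """Simulate one footprint library ('input' or 'ip').

    Generative model: a ribosome position (P-site at internal codon i) is
    drawn with probability proportional to abundance (uniform per transcript)
    times the A-site codon's dwell time; for the IP library the acceptance
    probability is further multiplied by the P-site codon's recruitment
    weight (rejection sampling, renormalized to the requested depth), and
    optionally by dwell^exponent when the P-site codon is in the configured
    coupling set.  The read length is drawn from ``read_length_probs`` and
    the 5' end set so the P-site codon begins at the canonical offset.
    """
    if library not in {"input", "ip"}:
        raise ValueError("library must be 'input' or 'ip'")
    depth = config.depth_input if library == "input" else config.depth_ip
    if depth == 0:
        warnings.warn(f"requested depth 0 for {library} library; returning empty set")
        return FootprintSet(library=library, data=pd.DataFrame(columns=["transcript_id", "five_prime_pos", "length", "count"]))

    rng = _rng(config, _SALT_FOOTPRINTS, 0 if library == "input" else 1)
    pos = _eligible_positions(transcriptome)

    dwell = pos["a_codon"].map(config.dwell_times).to_numpy(float)
    weight = dwell.copy()
    if library == "ip":
        weight = weight * pos["p_codon"].map(config.recruitment_weights).to_numpy(float)
        if config.ip_dwell_coupling:
            coupled = pos["p_codon"].isin(config.ip_dwell_coupling).to_numpy()
            weight = weight * np.where(coupled, dwell**config.ip_dwell_exponent, 1.0)
    probs = weight / weight.sum()
    counts = rng.multinomial(depth, probs)

    lengths = sorted(config.read_length_probs)
    lprobs = np.array([config.read_length_probs[L] for L in lengths])
    by_length = rng.multinomial(counts, lprobs)  # (positions, lengths)

    frames = []
    for j, L in enumerate(lengths):
        c = by_length[:, j]
        nz = c > 0
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": pos.loc[nz, "transcript_id"].to_numpy(),
                    "five_prime_pos": pos.loc[nz, "p_start"].to_numpy() - P_SITE_OFFSETS[L],
                    "length": L,
                    "count": c[nz],
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)

    truth = (
        pd.Series(counts, index=pos["p_codon"].to_numpy()).groupby(level=0).sum().astype(int)
    )
    return FootprintSet(library=library, data=data, psite_truth=truth.to_dict())


# ---------------------------------------------------------------------------
# decay time courses
# ---------------------------------------------------------------------------

@dataclass
class DecayMeasurements:
    """Labeled-fraction time courses plus (for synthetic data) the truth."""

    data: pd.DataFrame  # transcript_id, condition, timepoint_h, labeled_fraction, replicate
    true_half_life: pd.Series | None = None  # hours, indexed by transcript_id

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def true_weighted_scores(transcriptome: Transcriptome, config: SimulationConfig) -> pd.Series:
    """Ground-truth weighted codon score per transcript.

    Sum of the non-neutral recruitment weights over ORF sense codons, divided
    by the number of ORF sense codons (the same statistic the enrichment
    module estimates from data).
    """
    weights = {c: w for c, w in config.recruitment_weights.items() if w != 1.0}
    scores = {}
    for tx in transcriptome:
        cods = [c for c in tx.codons() if c in SENSE_CODONS]
        scores[tx.id] = sum(weights.get(c, 0.0) for c in cods) / len(cods)
    return pd.Series(scores, name="score")


def _assign_half_lives(
    transcriptome: Transcriptome, config: SimulationConfig, condition: str
) -> pd.Series:
    model = config.halflife_model
    rng = _rng(config, _SALT_DECAY, _SALT_BASE_HALFLIFE)
    ids = transcriptome.ids
    base = model.base_median_h * np.exp2(rng.normal(0.0, model.base_log2_sd, size=len(ids)))
    t_half = pd.Series(base, index=ids)
    if condition == "perturbed" and model.stabilization_factor != 1.0:
        scores = true_weighted_scores(transcriptome, config)
        top_n = model.stabilized_top_n
        if top_n is None:
            top_n = max(len(ids) // 10, 1)
        stabilized = scores.sort_values(ascending=False, kind="stable").index[:top_n]
        t_half.loc[stabilized] *= model.stabilization_factor
    elif condition not in {"control", "perturbed"}:
        raise ValueError("condition must be 'control' or 'perturbed'")
    return t_half


def labeled_fraction(t_half: float, t: np.ndarray) -> np.ndarray:
    """Noise-free labeled fraction y(t) = exp(-ln2 * t / t_half); 1.0 if stable."""
    if t_half <= 0:
        raise ConfigurationError("half-life must be positive")
    if np.isinf(t_half):
        return np.ones_like(np.asarray(t, dtype=float))
    return np.exp(-np.log(2.0) / t_half * np.asarray(t, dtype=float))


def simulate_decay(
    transcriptome: Transcriptome,
    config: SimulationConfig,
    condition: str,
) -> DecayMeasurements:
    """Simulate a labeled-fraction decay time course for one condition.

    Both conditions share the same baseline half-lives (drawn from one seed
    stream); the perturbed condition multiplies the half-life of the top
    weighted-score transcripts by the configured stabilization factor,
    emulating stabilization of high-score mRNAs when CNOT3 is lost.
    """
    t_half = _assign_half_lives(transcriptome, config, condition)
    timepoints = np.asarray(config.decay_timepoints, dtype=float)
    noise = config.noise_model
    cond_salt = 0 if condition == "control" else 1
    rng = _rng(config, _SALT_DECAY, cond_salt)
    rows = []
    for tid, th in t_half.items():
        y = labeled_fraction(th, timepoints)
        for rep in range(1, config.n_decay_replicates + 1):
            if noise.kind == "binomial":
                obs = rng.binomial(noise.reads, np.clip(y, 0.0, 1.0)) / noise.reads
            elif noise.kind == "gaussian":
                obs = np.clip(y + rng.normal(0.0, noise.sd, size=y.shape), 0.0, 1.0)
            else:
                obs = y
            for t, v in zip(timepoints, obs):
                rows.append((tid, condition, t, v, rep))
    data = pd.DataFrame(
        rows, columns=["transcript_id", "condition", "timepoint_h", "labeled_fraction", "replicate"]
    )
    return DecayMeasurements(data=data, true_half_life=t_half)


# ---------------------------------------------------------------------------
# tRNA records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TRNASpec:
    """Requested D-arm features for one synthetic tRNA."""

    pos13: str
    pos22: str
    pos46: str
    alpha_len: int
    anticodon: str  # RNA alphabet, 5'->3'
    id: str | None = None


_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def build_trna(spec: TRNASpec):
    """Realize a :class:`TRNASpec` as a cloverleaf sequence + dot-bracket.

    The scaffold is a canonical type-I tRNA body; the D-loop is constructed as
    ``alpha_len`` adenosines followed by the conserved GG motif and a short
    beta element, so the requested alpha length is exactly what a structure
    parser recovers.  Returns a parsed :class:`ptmd.trna.TRNARecord`.
    """
    from ptmd.trna import parse_trna_structure

    if spec.alpha_len < 1:
        raise ValueError("alpha element length must be >= 1 (the GG motif needs a preceding nt)")
    for base, name in [(spec.pos13, "pos13"), (spec.pos22, "pos22"), (spec.pos46, "pos46")]:
        if base not in "ACGU":
            raise ValueError(f"{name} must be one of A/C/G/U, got {base!r}")
    if len(spec.anticodon) != 3 or set(spec.anticodon) - set("ACGU"):
        raise ValueError("anticodon must be a trinucleotide over A/C/G/U")

    acc5, link = "GCGGAUU", "UA"
    d5 = "GCU"  # Sprinzl 10-12; pos13 follows
    dloop = "A" * spec.alpha_len + "GG" + "CA"
    d3 = "AGC"  # pairs 12-10
    ac5 = "CCGGA"
    acloop = "CU" + spec.anticodon + "AA"
    ac3 = revcomp_rna(ac5)
    var = "AG" + spec.pos46 + "UC"
    t5 = "GAGGC"
    tloop = "UUCGAAU"
    t3 = revcomp_rna(t5)
    acc3 = revcomp_rna(acc5)
    tail = "ACCA"  # discriminator + CCA end

    seq = (
        acc5 + link + d5 + spec.pos13 + dloop + spec.pos22 + d3 + "A"
        + ac5 + acloop + ac3 + var + t5 + tloop + t3 + acc3 + tail
    )
    struct = (
        "(" * 7 + ".." + "(((" + "." + "." * len(dloop) + "." + ")))" + "."
        + "(((((" + "." * 7 + ")))))" + "." * 5
        + "(((((" + "." * 7 + ")))))" + ")" * 7 + "...."
    )
    assert len(seq) == len(struct)
    trna_id = spec.id or f"tRNA-{spec.anticodon}-{spec.pos13}{spec.pos22}{spec.pos46}-a{spec.alpha_len}"
    return parse_trna_structure(trna_id, seq, struct)


def generate_trna_set(specs: Iterable[TRNASpec | tuple]):
    """Build tRNA records from feature tuples (round-trips through parsing)."""
    records = []
    for s in specs:
        if not isinstance(s, TRNASpec):
            s = TRNASpec(*s)
        records.append(build_trna(s))
    return records


_BLOCKED_AAS = set("NKIYMFT")


def default_trna_panel(decoded_codons: Sequence[str] = SENSE_CODONS):
    """A complete decoding panel mirroring the study's tRNA feature landscape.

    One tRNA per sense codon (anticodon = reverse complement), with the
    CNOT3-recruiting U13:A22:A46 / short-alpha D-arm on tRNAs decoding
    CGG/CGA/AGG, the extended alpha element (steric block) on tRNAs decoding
    N/K/I/Y/M/F/T codons, and the common C13:G22:G46 / short-alpha
    configuration elsewhere.
    """
    from ptmd.genetics import CODON_TO_AA, dna_to_rna

    specs = []
    for codon in decoded_codons:
        anticodon = revcomp_rna(dna_to_rna(codon))
        aa = CODON_TO_AA[codon]
        if codon in {"CGG", "CGA", "AGG"}:
            spec = TRNASpec("U", "A", "A", 1, anticodon, id=f"tRNA-{aa}-{anticodon}")
        elif aa in _BLOCKED_AAS:
            spec = TRNASpec("C", "G", "G", 2, anticodon, id=f"tRNA-{aa}-{anticodon}")
        else:
            spec = TRNASpec("C", "G", "G", 1, anticodon, id=f"tRNA-{aa}-{anticodon}")
        specs.append(spec)
    return generate_trna_set(specs)
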