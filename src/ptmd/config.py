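"""Configuration for the synthetic-data generators.

The defaults describe the generative model the downstream analyses assume: a
transcriptome of AUG...stop ORFs with codons drawn from a codon-frequency
table, two footprint libraries (total ribosome "input" and an IP of
CNOT3-bound ribosomes) in which the IP accepts footprints in proportion to a
per-codon P-site recruitment weight, ribosome positions occupied in
proportion to the A-site codon's relative dwell time, and labeled-fraction
decay time courses measured at 0, 1, 2, 4, 8 and 12 h in two genetic
conditions (control vs. CNOT3-perturbed, in which high-score transcripts are
stabilized).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

from ptmd.genetics import SENSE_CODONS

#: read lengths retained for analysis, chosen for their triplet periodicity
ANALYSIS_READ_LENGTHS: tuple[int, ...] = (29, 30, 32, 35)

#: default P-site recruitment multipliers: the three CNOT3-associated arginine
#: codons are enriched (CGG > CGA > AGG), everything else is neutral
DEFAULT_RECRUITMENT_WEIGHTS: dict[str, float] = {"CGG": 4.0, "CGA": 3.0, "AGG": 2.0}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class HalfLifeModel:
    """Links a transcript's weighted codon score to its true half-life.

    Baseline half-lives are log-normal around ``base_median_h`` (spread
    ``base_log2_sd`` in log2 units).  In the perturbed condition the
    ``stabilized_top_n`` transcripts with the highest true weighted score have
    their half-life multiplied by ``stabilization_factor``; everything else is
    unchanged.  ``stabilized_top_n=None`` stabilizes the top 10% of
    transcripts.
    """

    base_median_h: float = 4.0
    base_log2_sd: float = 0.5
    stabilization_factor: float = 2.0
    stabilized_top_n: int | None = None

    def validate(self) -> None:
        if self.base_median_h <= 0:
            raise ConfigurationError("base half-life must be positive")
        if self.stabilization_factor <= 0:
            raise ConfigurationError("stabilization factor must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise for labeled fractions.

    ``binomial`` resamples each labeled fraction as Binomial(reads, y)/reads,
    matching the count-based origin of conversion fractions; ``gaussian`` adds
    N(0, sd); ``none`` returns the noise-free curve.
    """

    kind: str = "binomial"
    reads: int = 1000
    sd: float = 0.02

    def validate(self) -> None:
        if self.kind not in {"binomial", "gaussian", "none"}:
            raise ConfigurationError(f"unknown noise model {self.kind!r}")
        if self.kind == "binomial" and self.reads < 1:
            raise ConfigurationError("binomial noise requires reads >= 1")
        if self.kind == "gaussian" and self.sd < 0:
            raise ConfigurationError("gaussian sd must be >= 0")


def _uniform_codon_frequency() -> dict[str, float]:
    p = 1.0 / len(SENSE_CODONS)
    return {c: p for c in SENSE_CODONS}


def _full_weights(partial: Mapping[str, float] | None, default: float = 1.0) -> dict[str, float]:
    w = {c: default for c in SENSE_CODONS}
    if partial:
        for codon, value in partial.items():
            if codon not in w:
                raise ConfigurationError(f"{codon!r} is not a sense codon")
            w[codon] = float(value)
    return w


@dataclass
class SimulationConfig:
    seed: int = 0
    n_transcripts: int = 200
    cds_length_range: tuple[int, int] = (120, 240)
    codon_frequency: dict[str, float] = field(default_factory=_uniform_codon_frequency)
    recruitment_weights: dict[str, float] = field(
        default_factory=lambda: _full_weights(DEFAULT_RECRUITMENT_WEIGHTS)
    )
    dwell_times: dict[str, float] = field(default_factory=lambda: _full_weights(None))
    read_length_probs: dict[int, float] = field(
        default_factory=lambda: {29: 0.4, 30: 0.3, 32: 0.2, 35: 0.1}
    )
    depth_input: int = 200_000
    depth_ip: int = 200_000
    decay_timepoints: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0, 12.0)
    halflife_model: HalfLifeModel = field(default_factory=HalfLifeModel)
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    utr5_range: tuple[int, int] = (15, 30)
    utr3_range: tuple[int, int] = (25, 40)
    # Optional coupling of IP acceptance to A-site dwell, restricted to
    # footprints whose P-site codon is in the coupling set (None = no coupling).
    ip_dwell_coupling: frozenset[str] | None = None
    ip_dwell_exponent: float = 1.0
    n_decay_replicates: int = 1

    def __post_init__(self) -> None:
        self.recruitment_weights = _full_weights(self.recruitment_weights)
        self.dwell_times = _full_weights(self.dwell_times)
        if self.ip_dwell_coupling is not None:
            self.ip_dwell_coupling = frozenset(self.ip_dwell_coupling)
        self.validate()

    def validate(self) -> None:
        missing = set(SENSE_CODONS) - set(self.codon_frequency)
        if missing:
            raise ConfigurationError(
                f"codon_frequency missing {len(missing)} sense codons, e.g. {sorted(missing)[:3]}"
            )
        total = sum(self.codon_frequency[c] for c in SENSE_CODONS)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"codon frequencies sum to {total!r}, not 1")
        if abs(sum(self.read_length_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("read length probabilities must sum to 1")
        unsupported = set(self.read_length_probs) - set(ANALYSIS_READ_LENGTHS)
        if unsupported:
            raise ConfigurationError(
                f"read lengths {sorted(unsupported)} have no P-site offset rule"
            )
        if any(w <= 0 for w in self.recruitment_weights.values()):
            raise ConfigurationError("recruitment weights must be > 0")
        if any(d <= 0 for d in self.dwell_times.values()):
            raise ConfigurationError("dwell times must be > 0")
        if self.cds_length_range[0] < 5:
            raise ConfigurationError("minimum CDS length is 5 codons (E/P/A sites need room)")
        if self.cds_length_range[0] > self.cds_length_range[1]:
            raise ConfigurationError("cds_length_range must be (min, max) with min <= max")
        if self.utr5_range[0] < 13:
            raise ConfigurationError("5'UTR must be >= 13 nt so every offset fits")
        if self.utr3_range[0] < 24:
            raise ConfigurationError("3'UTR must be >= 24 nt so every offset fits")
        if self.n_transcripts < 1:
            raise ConfigurationError("need at least one transcript")
        self.halflife_model.validate()
        self.noise_model.validate()

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)
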