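"""tRNA D-arm feature extraction and PTMD classification.

The ribosome-bound CCR4-NOT subunit CNOT3 probes the P-site tRNA from the
vacant E-site.  Two D-arm features decide the outcome: a U13:A22:A46 base
triple (Sprinzl numbering) hydrogen-bonds to CNOT3 and stabilizes it
(promoting accelerated decay), while an extra nucleotide in the D-loop alpha
element — the segment immediately preceding the universally conserved GG
motif — sterically blocks CNOT3.  Each tRNA is therefore classified as
``promoting``, ``neutral`` or ``blocking``; codons inherit the class of
their decoding tRNA(s) and transcripts the density of each codon class.

De novo cloverleaf folding is deliberately not implemented: records carry
explicit Sprinzl-style coordinates, or a dot-bracket secondary structure
from which the arms are delimited by paired-region order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ptmd.genetics import CODON_TO_AA, SENSE_CODONS, revcomp_rna, rna_to_dna

logger = logging.getLogger(__name__)

PROMOTING_TRIPLET = ("U", "A", "A")

#: Crick wobble at anticodon position 34: anticodon 5' base -> readable
#: third codon bases (DNA alphabet), in addition to nothing but these.
DEFAULT_WOBBLE: dict[str, str] = {"G": "CT", "C": "G", "U": "AG", "A": "T"}

_CLASS_PRIORITY = {"blocking": 0, "promoting": 1, "neutral": 2}


def _reduce_base(base: str) -> str:
    """Reduce a (possibly modified) base symbol to its parent base, RNA alphabet."""
    b = base.strip().upper()
    b = {"T": "U", "M7G": "G", "M1A": "A", "D": "U", "PSI": "U"}.get(b, b)
    if b not in "ACGU":
        raise ValueError(f"cannot reduce base {base!r} to A/C/G/U")
    return b


@dataclass
class TRNARecord:
    """A tRNA with the D-arm coordinates needed for PTMD classification."""

    id: str
    sequence: str  # RNA alphabet, 5'->3'
    anticodon: str
    pos13: str
    pos22: str
    pos46: str | None
    alpha_len: int
    structure: str | None = None
    parse_ok: bool = True
    flags: list[str] = field(default_factory=list)

    @property
    def triplet(self) -> tuple[str, str, str] | None:
        if self.pos46 is None:
            return None
        return (self.pos13, self.pos22, self.pos46)


# ---------------------------------------------------------------------------
# structure parsing
# ---------------------------------------------------------------------------

def _helix_runs(structure: str) -> tuple[dict[int, int], list[tuple[int, int]]]:
    """Base-pair map and 5'-strand runs [(start, end) inclusive] of each helix."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
        elif ch != ".":
            raise ValueError(f"unexpected character {ch!r} in dot-bracket string")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    starts = sorted(i for i in pairs if pairs[i] > i)
    runs: list[tuple[int, int]] = []
    for i in starts:
        if runs and i == runs[-1][1] + 1 and pairs[i] == pairs[runs[-1][1]] - 1:
            runs[-1] = (runs[-1][0], i)
        else:
            runs.append((i, i))
    return pairs, runs


def parse_trna_structure(trna_id: str, sequence: str, structure: str) -> TRNARecord:
    """Delimit the cloverleaf arms of a dot-bracket annotation.

    The acceptor stem is the outermost helix; the D-, anticodon- and T-stems
    follow in 5' order (extra helices, e.g. a type-II variable arm, are
    flagged).  Position 13 is the fourth nucleotide of the D-stem region
    (paired or not, so trans-Hoogsteen 13:22 pairs are handled), position 22
    the nucleotide across from it, and position 46 the third nucleotide of
    the variable region.  The alpha element is everything in the D-loop
    before its first GG; a missing GG is a parse failure, a second GG only a
    warning.
    """
    seq = _normalize_rna(sequence)
    if len(seq) != len(structure):
        raise ValueError("sequence and structure must have equal length")
    flags: list[str] = []
    try:
        pairs, runs = _helix_runs(structure)
        if len(runs) < 4:
            raise ValueError(f"expected >= 4 helices (found {len(runs)})")
        acceptor, d_run, ac_run = runs[0], runs[1], runs[2]
        t_run = max(runs[3:], key=lambda r: pairs[r[0]])
        if len(runs) > 4:
            flags.append("extra_helix")

        d_start = d_run[0]
        idx13 = d_start + 3
        idx22 = pairs[d_start + 2] - 1
        dloop = seq[idx13 + 1 : idx22]
        gg = dloop.find("GG")
        if gg < 0:
            raise ValueError("no GG motif in D-loop")
        if dloop.find("GG", gg + 2) >= 0:
            flags.append("multiple_dloop_gg")
            logger.warning("%s: multiple GG dinucleotides in D-loop; using the first", trna_id)
        alpha_len = gg

        ac_loop_start = ac_run[1] + 1
        ac_loop_end = pairs[ac_run[1]]  # first index of the 3' strand
        loop = seq[ac_loop_start:ac_loop_end]
        if len(loop) < 5:
            raise ValueError("anticodon loop too short")
        anticodon = loop[2:5]

        var_start = pairs[ac_run[0]] + 1
        var_end = t_run[0]
        var = seq[var_start:var_end]
        if len(var) > 7:
            flags.append("type_ii_variable_arm")
        pos46 = var[2] if len(var) >= 3 else None

        pos13, pos22 = seq[idx13], seq[idx22]
        if (pos13, pos22) == ("G", "A"):
            flags.append("g13a22_trans_hoogsteen")
        return TRNARecord(
            id=trna_id,
            sequence=seq,
            anticodon=anticodon,
            pos13=pos13,
            pos22=pos22,
            pos46=pos46,
            alpha_len=alpha_len,
            structure=structure,
            parse_ok=True,
            flags=flags,
        )
    except ValueError as err:
        logger.warning("%s: structure parse failed (%s)", trna_id, err)
        return TRNARecord(
            id=trna_id,
            sequence=seq,
            anticodon="",
            pos13="",
            pos22="",
            pos46=None,
            alpha_len=0,
            structure=structure,
            parse_ok=False,
            flags=["parse_failed"],
        )


def _normalize_rna(sequence: str) -> str:
    return sequence.strip().upper().replace("T", "U")


def parse_trna(
    trna_id: str,
    sequence: str,
    *,
    structure: str | None = None,
    anticodon: str | None = None,
    pos13: str | None = None,
    pos22: str | None = None,
    pos46: str | None = None,
    alpha_len: int | None = None,
) -> TRNARecord:
    """Build a :class:`TRNARecord` from explicit coordinates or a structure."""
    if structure is not None:
        return parse_trna_structure(trna_id, sequence, structure)
    if None in (anticodon, pos13, pos22, pos46, alpha_len):
        raise ValueError("without a structure, anticodon/pos13/pos22/pos46/alpha_len are required")
    if alpha_len < 1:
        raise ValueError("alpha element length must be >= 1")
    return TRNARecord(
        id=trna_id,
        sequence=_normalize_rna(sequence),
        anticodon=_normalize_rna(anticodon),
        pos13=_reduce_base(pos13),
        pos22=_reduce_base(pos22),
        pos46=_reduce_base(pos46),
        alpha_len=int(alpha_len),
    )


def load_trna_table(path: str | Path) -> list[TRNARecord]:
    """Read a tRNA TSV (id, sequence, anticodon, pos13, pos22, pos46, alpha_len)."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            parse_trna(
                row.id,
                row.sequence,
                anticodon=row.anticodon,
                pos13=row.pos13,
                pos22=row.pos22,
                pos46=row.pos46,
                alpha_len=int(row.alpha_len),
            )
        )
    return records


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TRNAClassification:
    trna_id: str
    ptmd_class: str  # promoting | neutral | blocking | unclassified
    has_u13a22a46: bool
    has_alpha_insertion: bool
    flags: tuple[str, ...] = ()


def classify_ptmd(record: TRNARecord) -> TRNAClassification:
    """Three-outcome classification of a tRNA's effect on CNOT3 recruitment.

    The steric block of an extended alpha element takes precedence over the
    stabilizing triplet: blocking if alpha_len >= 2, else promoting if the
    13:22:46 triplet is U:A:A, else neutral.  Unparsed records are left
    unclassified.
    """
    if not record.parse_ok:
        return TRNAClassification(record.id, "unclassified", False, False, tuple(record.flags))
    has_triplet = record.triplet == PROMOTING_TRIPLET
    has_insertion = record.alpha_len >= 2
    if has_insertion:
        cls = "blocking"
    elif has_triplet:
        cls = "promoting"
    else:
        cls = "neutral"
    return TRNAClassification(record.id, cls, has_triplet, has_insertion, tuple(record.flags))


def classify_trna_set(records: Iterable[TRNARecord]) -> pd.DataFrame:
    rows = [classify_ptmd(r) for r in records]
    return pd.DataFrame(
        {
            "trna_id": [r.trna_id for r in rows],
            "ptmd_class": [r.ptmd_class for r in rows],
            "has_u13a22a46": [r.has_u13a22a46 for r in rows],
            "has_alpha_insertion": [r.has_alpha_insertion for r in rows],
            "flags": [";".join(r.flags) for r in rows],
        }
    )


def decoded_codons(anticodon: str, wobble: Mapping[str, str] = DEFAULT_WOBBLE) -> list[str]:
    """Sense codons (DNA alphabet) read by an anticodon under Crick wobble."""
    ac = _normalize_rna(anticodon)
    if len(ac) != 3:
        raise ValueError("anticodon must be a trinucleotide")
    stem = rna_to_dna(revcomp_rna(ac))[:2]  # codon positions 1-2, Watson-Crick
    thirds = wobble.get(ac[0], rna_to_dna(revcomp_rna(ac[0])))
    return [stem + third for third in thirds if (stem + third) in CODON_TO_AA]


def classify_codons(
    records: Sequence[TRNARecord],
    wobble: Mapping[str, str] = DEFAULT_WOBBLE,
) -> pd.DataFrame:
    """Propagate tRNA classes to the 61 sense codons through the decoding table.

    Codons decoded by tRNAs of different classes are flagged ambiguous and
    resolved by priority blocking > promoting > neutral.  A sense codon with
    no decoding tRNA in the set is a hard error (never silent).
    """
    per_codon: dict[str, list[tuple[str, str]]] = {c: [] for c in SENSE_CODONS}
    for rec in records:
        cls = classify_ptmd(rec)
        if cls.ptmd_class == "unclassified":
            continue
        for codon in decoded_codons(rec.anticodon, wobble):
            per_codon[codon].append((cls.ptmd_class, rec.id))
    undecoded = [c for c, lst in per_codon.items() if not lst]
    if undecoded:
        raise ValueError(f"sense codons with no decoding tRNA: {undecoded}")
    rows = []
    for codon, lst in per_codon.items():
        classes = {c for c, _ in lst}
        ambiguous = len(classes) > 1
        resolved = min(classes, key=_CLASS_PRIORITY.__getitem__)
        if ambiguous:
            logger.info("codon %s decoded by tRNAs of classes %s; resolved to %s",
                        codon, sorted(classes), resolved)
        rows.append(
            {
                "codon": codon,
                "amino_acid": CODON_TO_AA[codon],
                "ptmd_class": resolved,
                "ambiguous": ambiguous,
                "decoded_by": ";".join(sorted(tid for _, tid in lst)),
            }
        )
    return pd.DataFrame(rows).sort_values("codon", ignore_index=True)


def transcript_ptmd_profile(transcriptome, codon_classes: pd.DataFrame) -> pd.DataFrame:
    """Per-transcript density of promoting/neutral/blocking codons.

    Densities are fractions of all ORF codons; stop codons and codons without
    a class stay in the denominator but never in a numerator, so the three
    densities sum to <= 1.
    """
    class_of = dict(zip(codon_classes["codon"], codon_classes["ptmd_class"]))
    rows = []
    for tx in transcriptome:
        cods = tx.codons()
        n = len(cods)
        tallies = {"promoting": 0, "neutral": 0, "blocking": 0}
        for c in cods:
            cls = class_of.get(c)
            if cls in tallies:
                tallies[cls] += 1
        rows.append(
            {
                "transcript_id": tx.id,
                "n_codons": n,
                **{f"n_{k}": v for k, v in tallies.items()},
                **{f"density_{k}": v / n for k, v in tallies.items()},
            }
        )
    return pd.DataFrame(rows)
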