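"""Per-gene content and clustering of Elongator-targeted codons.

Eleven A-ending codons are decoded by tRNAs whose wobble uridine (U34)
carries an Elongator-dependent modification.  For each coding sequence six
parameters summarise how loaded the message is with these codons:

``F_T``
    frequency of target codons among all codons,
``F_S``
    frequency of target codons among codons encoding the same eleven
    amino-acid families (controls for amino-acid usage),
``F_2``, ``F_3``, ``F_4``
    fraction of codons lying inside runs of >= 2, 3 or 4 consecutive
    target codons,
``D``
    mean spacing, in codons, between consecutive target codons.

A high codon load corresponds to high F parameters and a low D.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .io import CodingSequence

log = logging.getLogger(__name__)

__all__ = [
    "TARGET_CODONS",
    "CODON_MODIFICATION",
    "GENETIC_CODE",
    "STOP_CODONS",
    "TARGET_AMINO_ACIDS",
    "PARAMETERS",
    "CodonProfile",
    "tokenize_cds",
    "compute_codon_profile",
    "compute_profiles_batch",
]

# wobble-uridine modification class of the decoding tRNA, per target codon
CODON_MODIFICATION: dict[str, str] = {
    "TTA": "ncm5U34",   # Leu
    "GTA": "ncm5U34",   # Val
    "TCA": "ncm5U34",   # Ser
    "ACA": "ncm5U34",   # Thr
    "GCA": "ncm5U34",   # Ala
    "CCA": "ncm5U34",   # Pro
    "GGA": "mcm5U34",   # Gly
    "AGA": "mcm5U34",   # Arg
    "CAA": "mcm5s2U34",  # Gln
    "GAA": "mcm5s2U34",  # Glu
    "AAA": "mcm5s2U34",  # Lys
}

TARGET_CODONS: frozenset[str] = frozenset(CODON_MODIFICATION)

STOP_CODONS: frozenset[str] = frozenset({"TAA", "TAG", "TGA"})

# standard nuclear genetic code, 61 sense codons
GENETIC_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}

# the eleven amino-acid families the target codons belong to
TARGET_AMINO_ACIDS: frozenset[str] = frozenset(
    GENETIC_CODE[c] for c in TARGET_CODONS
)

PARAMETERS = ("F_T", "F_S", "F_2", "F_3", "F_4", "D")

PROFILE_COLUMNS = ["gene_id", "n_codons", "n_target", *PARAMETERS]


@dataclass(frozen=True)
class CodonProfile:
    gene_id: str
    n_codons: int
    n_target: int
    f_t: float
    f_s: float | None
    f_2: float
    f_3: float
    f_4: float
    d: float | None

    def as_row(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "n_codons": self.n_codons,
            "n_target": self.n_target,
            "F_T": self.f_t,
            "F_S": math.nan if self.f_s is None else self.f_s,
            "F_2": self.f_2,
            "F_3": self.f_3,
            "F_4": self.f_4,
            "D": math.nan if self.d is None else self.d,
        }


def tokenize_cds(seq: CodingSequence) -> list[str]:
    """Split an in-frame CDS into codons, dropping a terminal stop if present.

    Internal stop codons are retained in the list (a warning is logged);
    downstream they are treated like ambiguous codons.  Raises ``ValueError``
    if the sequence length is not a multiple of 3.
    """
    s = seq.sequence
    if len(s) % 3 != 0:
        raise ValueError(
            f"gene {seq.gene_id!r}: length {len(s)} is not a multiple of 3"
        )
    codons = [s[i:i + 3] for i in range(0, len(s), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if any(c in STOP_CODONS for c in codons):
        log.warning("gene %s: internal stop codon(s) retained", seq.gene_id)
    return codons


def _is_unambiguous(codon: str) -> bool:
    return all(b in "ACGT" for b in codon)


def compute_codon_profile(codons: list[str], gene_id: str = "") -> CodonProfile:
    """Compute the six codon parameters for one tokenized CDS.

    Ambiguous codons (any non-ACGT base) and internal stops count toward
    ``n_codons`` but are never targets and are excluded from the synonymous
    denominator of ``F_S``.
    """
    if not codons:
        raise ValueError(f"gene {gene_id!r}: empty codon list")
    n = len(codons)
    is_target = [
        _is_unambiguous(c) and c in TARGET_CODONS for c in codons
    ]
    n_target = sum(is_target)
    f_t = n_target / n

    n_family = sum(
        1
        for c in codons
        if _is_unambiguous(c)
        and c in GENETIC_CODE
        and GENETIC_CODE[c] in TARGET_AMINO_ACIDS
    )
    f_s = n_target / n_family if n_family > 0 else None

    # maximal runs of consecutive target codons
    run_codons = {2: 0, 3: 0, 4: 0}
    run = 0
    for flag in [*is_target, False]:
        if flag:
            run += 1
        else:
            for k in run_codons:
                if run >= k:
                    run_codons[k] += run
            run = 0
    f_2, f_3, f_4 = (run_codons[k] / n for k in (2, 3, 4))

    positions = [i + 1 for i, flag in enumerate(is_target) if flag]
    if n_target >= 2:
        gaps = [b - a for a, b in zip(positions, positions[1:])]
        d = sum(gaps) / len(gaps)
    else:
        d = None

    return CodonProfile(gene_id, n, n_target, f_t, f_s, f_2, f_3, f_4, d)


def compute_profiles_batch(
    cds,
    min_codons: int = 10,
) -> pd.DataFrame:
    """Profile a collection of coding sequences.

    Returns a DataFrame with one row per analyzable gene, in input order,
    with columns ``gene_id, n_codons, n_target, F_T, F_S, F_2, F_3, F_4, D``
    (missing F_S / D encoded as NaN).  Genes failing tokenization or shorter
    than ``min_codons`` codons are skipped with a logged reason.
    """
    rows = []
    for record in cds:
        try:
            codons = tokenize_cds(record)
        except ValueError as exc:
            log.warning("skipping %s: %s", record.gene_id, exc)
            continue
        if len(codons) < min_codons:
            log.warning(
                "skipping %s: %d codons < min_codons=%d",
                record.gene_id, len(codons), min_codons,
            )
            continue
        rows.append(compute_codon_profile(codons, record.gene_id).as_row())
    if not rows:
        raise ValueError("no analyzable sequences")
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)
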