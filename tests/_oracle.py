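"""Brute-force reference for the six codon parameters.

Deliberately naive: explicit nested scans over the codon list, with the
genetic code taken from Biopython rather than the package, so agreement
with ``compute_codon_profile`` is an independent check.
"""

from Bio.Data import CodonTable

TARGETS = {
    "TTA", "GTA", "TCA", "ACA", "GCA", "CCA",
    "GGA", "AGA", "CAA", "GAA", "AAA",
}

_FORWARD = CodonTable.unambiguous_dna_by_id[1].forward_table
_TARGET_AA = {_FORWARD[c] for c in TARGETS}


def _clean(codon):
    return all(ch in "ACGT" for ch in codon)


def oracle_profile(codons):
    """Return (n_codons, n_target, f_t, f_s, f_2, f_3, f_4, d); None = missing."""
    n = len(codons)
    is_t = [_clean(c) and c in TARGETS for c in codons]
    n_target = sum(is_t)
    f_t = n_target / n

    n_family = 0
    for c in codons:
        if _clean(c) and c in _FORWARD and _FORWARD[c] in _TARGET_AA:
            n_family += 1
    f_s = n_target / n_family if n_family else None

    def in_run_ge(k):
        count = 0
        for i in range(n):
            if not is_t[i]:
                continue
            lo = i
            while lo > 0 and is_t[lo - 1]:
                lo -= 1
            hi = i
            while hi < n - 1 and is_t[hi + 1]:
                hi += 1
            if hi - lo + 1 >= k:
                count += 1
        return count

    f_2, f_3, f_4 = (in_run_ge(k) / n for k in (2, 3, 4))

    positions = [i + 1 for i in range(n) if is_t[i]]
    if len(positions) >= 2:
        total = 0
        for a, b in zip(positions, positions[1:]):
            total += b - a
        d = total / (len(positions) - 1)
    else:
        d = None
    return n, n_target, f_t, f_s, f_2, f_3, f_4, d
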