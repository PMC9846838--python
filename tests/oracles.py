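"""Independent brute-force reference implementations used only by tests.

These re-derive the primer-matching and beta-partition semantics from first
principles (naive per-window scans, plain python sets) so the vectorised
package code can be checked against a slow but obviously-correct oracle.
"""

from __future__ import annotations

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

COMP = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def window_mismatches(seq: str, primer: str, start: int, cap: int) -> int:
    """Mismatches of primer vs seq[start:], early exit above cap."""
    mm = 0
    for i, p in enumerate(primer):
        if not (IUPAC[p] & IUPAC[seq[start + i]]):
            mm += 1
            if mm > cap:
                return cap + 1
    return mm


def scan(seq: str, primer: str, cap: int) -> dict[int, int]:
    """Naive full scan: start -> mismatch count for every window within cap."""
    out = {}
    for i in range(len(seq) - len(primer) + 1):
        m = window_mismatches(seq, primer, i, cap)
        if m <= cap:
            out[i] = m
    return out


def brute_force_pcr(
    seq: str, fwd: str, rev: str, cap: int, ins_min: int, ins_max: int
) -> set[tuple]:
    """All amplicons as (fwd_start, rev_start, strand, fmm, rmm, insert) tuples,
    normalised to + strand coordinates."""
    L = len(seq)
    results: set[tuple] = set()

    def one_strand(s: str, strand: str) -> None:
        f_sites = scan(s, fwd, cap)
        r_sites = scan(s, rc(rev), cap)
        for fs, fmm in f_sites.items():
            f_end = fs + len(fwd)
            for rs, rmm in r_sites.items():
                if rs < f_end:
                    continue
                insert = s[f_end:rs]
                if not (ins_min <= len(insert) <= ins_max):
                    continue
                if strand == "+":
                    results.add((fs, rs, "+", fmm, rmm, insert))
                else:
                    results.add(
                        (L - f_end, L - (rs + len(rev)), "-", fmm, rmm, insert)
                    )

    one_strand(seq, "+")
    one_strand(rc(seq), "-")
    return results


def beta_partition(set_a: set, set_b: set) -> tuple[float, float, float]:
    """(turnover, nestedness, total) from plain set algebra."""
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    m = min(b, c)
    sim = m / (a + m) if (a + m) else 0.0
    sor = (b + c) / (2 * a + b + c) if (a + b + c) else 0.0
    return sim, sor - sim, sor
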