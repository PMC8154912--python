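"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (dict lookups, explicit triple loops)
and independent of the package's vectorized code paths.  The genetic code
comes from Biopython's codon table, not from the package.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

_T = CodonTable.unambiguous_dna_by_id[1]
ORACLE_CODE = dict(_T.forward_table)
for _stop in _T.stop_codons:
    ORACLE_CODE[_stop] = "*"
ALL_CODONS_ORACLE = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
assert len(ORACLE_CODE) == 64


def naive_substitution_class(a: str, b: str) -> str:
    purines = {"A", "G"}
    if (a in purines) == (b in purines):
        return "transition"
    return "transversion"


def naive_q(ci: str, cj: str, kappa: float, mu: float) -> float:
    """Kernel entry from first principles: enumerate differing sites."""
    if ci == cj:
        return 1.0 - mu
    diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
    if len(diffs) != 1:
        return 0.0
    a, b = diffs[0]
    if naive_substitution_class(a, b) == "transition":
        return mu * (kappa / (1 + kappa)) / 3.0
    return mu * (1 / (1 + kappa)) / 6.0


def naive_distortion(
    p: dict[str, float],
    kappa: float,
    mu: float,
    scale: dict[str, float],
    stop_policy: str = "exclude",
    form: str = "squared",
) -> float:
    """Triple-loop expected distortion over all 64 x 64 codon pairs."""
    max_d = 0.0
    if stop_policy == "max_penalty":
        for x in scale.values():
            for y in scale.values():
                d = (x - y) ** 2 if form == "squared" else abs(x - y)
                max_d = max(max_d, d)
    total = 0.0
    for ci in ALL_CODONS_ORACLE:
        aa_i = ORACLE_CODE[ci]
        if aa_i == "*":
            continue
        pi = p.get(ci, 0.0)
        if pi == 0.0:
            continue
        for cj in ALL_CODONS_ORACLE:
            q = naive_q(ci, cj, kappa, mu)
            if q == 0.0:
                continue
            aa_j = ORACLE_CODE[cj]
            if aa_j == "*":
                d = max_d if stop_policy == "max_penalty" else 0.0
            elif aa_i == aa_j:
                d = 0.0
            else:
                vi, vj = scale[aa_i], scale[aa_j]
                d = (vi - vj) ** 2 if form == "squared" else abs(vi - vj)
            total += pi * q * d
    return total


def random_sense_profile(rng: np.random.Generator) -> dict[str, float]:
    """Random frequency dict over the 61 sense codons."""
    sense = sorted(c for c in ALL_CODONS_ORACLE if ORACLE_CODE[c] != "*")
    freqs = rng.dirichlet(np.ones(len(sense)))
    return dict(zip(sense, freqs))
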