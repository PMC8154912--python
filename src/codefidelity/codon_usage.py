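"""Codon usage and GC-content extraction from coding sequences.

Each CDS record is read in frame from its first position.  Records whose
length is not a multiple of 3 are skipped entirely; individual codons
containing ambiguous (non-ACGT) symbols are skipped.  U is mapped to T on
read so mRNA input works transparently.  Usage frequencies P(c_i) are
defined over the 61 sense codons, with stop-codon counts kept for
diagnostics but excluded from the normalization (stop codons carry no
amino-acid property value, so they cannot enter the distortion sum).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

from .code_tables import ALL_CODONS, GeneticCode, standard_code

__all__ = [
    "CodonUsageProfile",
    "count_codons",
    "usage_from_counts",
    "gc_content",
    "profile_from_fasta",
    "read_cds_fasta",
]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class CodonUsageProfile:
    """Per-taxon codon counts, sense-codon frequencies and GC-content."""

    taxon_id: str
    counts: Mapping[str, int]
    p: Mapping[str, float]
    gc: float
    n_sequences_used: int = 0
    n_sequences_skipped: int = 0

    def freq_vector(self, code: GeneticCode | None = None) -> np.ndarray:
        """Frequencies as a vector over the code's sense codons (sorted)."""
        sense = (code or standard_code()).sense_codons
        return np.array([self.p.get(c, 0.0) for c in sense], dtype=float)


def _clean_seq(seq: str) -> str:
    return str(seq).upper().replace("U", "T")


def count_codons(records: Iterable[str]) -> tuple[Counter, int, int]:
    """Count in-frame codons over a set of CDS strings.

    Returns ``(counts, n_used, n_skipped)`` where skipped records are those
    whose length is not divisible by 3.  Codons with non-ACGT symbols are
    dropped individually and do not fail the record.
    """
    records = list(records)
    if not records:
        raise ValueError("empty CDS record set")
    counts: Counter = Counter()
    n_used = n_skipped = 0
    for rec in records:
        seq = _clean_seq(rec)
        if len(seq) % 3 != 0:
            n_skipped += 1
            continue
        n_used += 1
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if set(codon) <= _ACGT:
                counts[codon] += 1
    return counts, n_used, n_skipped


def gc_content(records: Iterable[str]) -> float:
    """(G + C) / (A + C + G + T) over all bases; ambiguous symbols ignored."""
    gc = total = 0
    for rec in records:
        seq = _clean_seq(rec)
        for b in seq:
            if b in _ACGT:
                total += 1
                if b in "GC":
                    gc += 1
    if total == 0:
        raise ValueError("no unambiguous ACGT bases in input")
    return gc / total


def usage_from_counts(
    counts: Mapping[str, int],
    code: GeneticCode | None = None,
    taxon_id: str = "",
    gc: float = float("nan"),
    n_sequences_used: int = 0,
    n_sequences_skipped: int = 0,
) -> CodonUsageProfile:
    """Normalize sense-codon counts to frequencies summing to one."""
    code = code or standard_code()
    full = {c: int(counts.get(c, 0)) for c in ALL_CODONS}
    sense_total = sum(full[c] for c in code.sense_codons)
    if sense_total <= 0:
        raise ValueError("no sense-codon counts; cannot form a usage profile")
    p = {c: full[c] / sense_total for c in code.sense_codons}
    return CodonUsageProfile(
        taxon_id=taxon_id,
        counts=full,
        p=p,
        gc=float(gc),
        n_sequences_used=n_sequences_used,
        n_sequences_skipped=n_sequences_skipped,
    )


def read_cds_fasta(path: str | Path) -> list[str]:
    """Read a (multi-)FASTA of CDS into plain sequence strings."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


def profile_from_fasta(
    path: str | Path,
    taxon_id: str | None = None,
    code: GeneticCode | None = None,
) -> CodonUsageProfile:
    """Full extraction for one taxon: counts, frequencies and GC-content."""
    path = Path(path)
    seqs = read_cds_fasta(path)
    counts, n_used, n_skipped = count_codons(seqs)
    retained = [s for s in seqs if len(_clean_seq(s)) % 3 == 0]
    gc = gc_content(retained)
    return usage_from_counts(
        counts,
        code=code,
        taxon_id=taxon_id if taxon_id is not None else path.stem,
        gc=gc,
        n_sequences_used=n_used,
        n_sequences_skipped=n_skipped,
    )
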