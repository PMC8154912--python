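"""Two-parameter background mutation model over codons.

A single mutation event is a single-nucleotide substitution; conditional on
an event hitting a codon, it is a transition with probability kappa/(1+kappa)
and a transversion with probability 1/(1+kappa) (Kimura two-parameter form,
with kappa the ti/tv rate ratio).  Given the class, the event is uniform over
the codon's 3 transition neighbors or 6 transversion neighbors.  The per-copy
mutation rate mu sets the diagonal: a codon is reproduced unchanged with
probability 1 - mu.  Codon pairs differing at more than one site have
probability zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .code_tables import ALL_CODONS, single_nt_neighbors

__all__ = ["MutationKernel", "build_kernel", "transition_mass_fraction"]

_CODON_INDEX = {c: i for i, c in enumerate(ALL_CODONS)}

# class masks are kappa/mu independent: build once
_TI_MASK = np.zeros((64, 64), dtype=bool)
_TV_MASK = np.zeros((64, 64), dtype=bool)
for _c in ALL_CODONS:
    for _nb, _cls in single_nt_neighbors(_c):
        if _cls == "transition":
            _TI_MASK[_CODON_INDEX[_c], _CODON_INDEX[_nb]] = True
        else:
            _TV_MASK[_CODON_INDEX[_c], _CODON_INDEX[_nb]] = True


@dataclass(frozen=True)
class MutationKernel:
    """64x64 row-stochastic conditional kernel P(Y = c_j | X = c_i)."""

    kappa: float
    mu: float
    codons: tuple[str, ...]
    q: np.ndarray = field(repr=False)

    def prob(self, c_from: str, c_to: str) -> float:
        return float(self.q[_CODON_INDEX[c_from], _CODON_INDEX[c_to]])

    def to_tsv(self, path: str | Path) -> None:
        """Write the kernel as a labeled 64x64 TSV matrix."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write("codon\t" + "\t".join(self.codons) + "\n")
            for i, c in enumerate(self.codons):
                fh.write(c + "\t" + "\t".join(f"{x:.17g}" for x in self.q[i]) + "\n")


def build_kernel(kappa: float = 2.5, mu: float = 1.0) -> MutationKernel:
    """Build the codon mutation kernel for given kappa (> 0) and mu in (0, 1].

    Off-diagonal single-site entries are
    ``mu * [kappa/(1+kappa) * 1/3]`` for transitions and
    ``mu * [1/(1+kappa) * 1/6]`` for transversions; the diagonal is 1 - mu.
    """
    if not np.isfinite(kappa) or kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    if not np.isfinite(mu) or not 0 < mu <= 1:
        raise ValueError(f"mu must be in (0, 1], got {mu}")
    p_ti = kappa / (1.0 + kappa)
    p_tv = 1.0 / (1.0 + kappa)
    q = np.zeros((64, 64), dtype=float)
    q[_TI_MASK] = mu * p_ti / 3.0
    q[_TV_MASK] = mu * p_tv / 6.0
    np.fill_diagonal(q, 1.0 - mu)
    return MutationKernel(kappa=float(kappa), mu=float(mu), codons=ALL_CODONS, q=q)


def transition_mass_fraction(kernel: MutationKernel) -> float:
    """Share of off-diagonal mutation mass in the transition class.

    Identical for every codon row and equal to kappa/(1+kappa) analytically;
    computed here from the kernel entries as a self-check.
    """
    ti = kernel.q[_TI_MASK].reshape(64, 3).sum(axis=1)
    tv = kernel.q[_TV_MASK].reshape(64, 6).sum(axis=1)
    frac = ti / (ti + tv)
    return float(frac.mean())
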