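"""Expected distortion of the genetic code under background mutation.

The distortion statistic is

    D = sum_{i,j} P(c_i) * P(Y = c_j | X = c_i) * d(aa_i, aa_j)

summed over sense-codon pairs: the codon-usage-weighted expected
physicochemical cost per translated symbol of one round of background
mutation.  P(c_i) is the taxon's sense-codon usage, the conditional kernel
comes from the two-parameter mutation model, and d is a distortion matrix
built from one amino-acid property scale.  Mutations into stop codons have
no defined property cost; by default they are excluded from the sum
(``stop_policy="exclude"``), with an optional worst-case nonsense penalty
(``stop_policy="max_penalty"``) that charges the maximum cost in the matrix.

D is linear in the usage vector, so the whole panel is a single matrix
product; :class:`CodonDistortion` exposes it as a scikit-learn transformer
mapping an (n_taxa, 61) frequency matrix to an (n_taxa, n_scales) panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .code_tables import (
    SCALE_NAMES,
    DistortionMatrix,
    GeneticCode,
    PropertyScale,
    build_distortion_matrix,
    builtin_scales,
    standard_code,
)
from .codon_usage import CodonUsageProfile
from .mutation_kernel import MutationKernel, build_kernel

__all__ = [
    "SHORT_NAMES",
    "DistortionPanel",
    "CodonDistortion",
    "expected_distortion",
    "distortion_panel",
    "panel_table",
    "kappa_sweep",
]

# conventional short labels for the four response measures
SHORT_NAMES = {
    "hydropathy": "D_hyd",
    "polar_requirement": "D_pol",
    "molecular_volume": "D_vol",
    "isoelectric_point": "D_pI",
}

StopPolicy = Literal["exclude", "max_penalty"]


def _codon_cost_vector(
    kernel: MutationKernel,
    dmat: DistortionMatrix,
    code: GeneticCode,
    stop_policy: StopPolicy,
) -> np.ndarray:
    """Per-sense-codon expected cost: cost[i] = sum_j q(c_i, c_j) d(aa_i, aa_j)."""
    sense = code.sense_codons
    aa_index = {aa: k for k, aa in enumerate(dmat.amino_acids)}
    codon_idx = {c: k for k, c in enumerate(kernel.codons)}
    if stop_policy not in ("exclude", "max_penalty"):
        raise ValueError(f"unknown stop policy: {stop_policy!r}")
    nonsense = dmat.max_cost if stop_policy == "max_penalty" else 0.0
    cost = np.zeros(len(sense))
    for i, ci in enumerate(sense):
        row = kernel.q[codon_idx[ci]]
        aa_i = code.translate(ci)
        total = 0.0
        for cj in kernel.codons:
            qij = row[codon_idx[cj]]
            if qij == 0.0:
                continue
            aa_j = code.translate(cj)
            if code.is_stop(cj):
                total += qij * nonsense
            else:
                total += qij * dmat.d[aa_index[aa_i], aa_index[aa_j]]
        cost[i] = total
    return cost


@dataclass(frozen=True)
class DistortionPanel:
    """The four distortion measures for one taxon at fixed kernel parameters."""

    taxon_id: str
    kappa: float
    mu: float
    stop_policy: str
    values: dict[str, float]  # scale name -> D

    def __getattr__(self, name: str):
        # allow panel.D_hyd style access via the conventional short names
        for scale, short in SHORT_NAMES.items():
            if name == short and scale in self.values:
                return self.values[scale]
        raise AttributeError(name)


class CodonDistortion(TransformerMixin, BaseEstimator):
    """Transform sense-codon usage frequencies into distortion measures.

    Parameters
    ----------
    kappa : float, default 2.5
        Transition/transversion rate ratio of the background mutation model.
    mu : float, default 1.0
        Per-copy mutation rate.  D is proportional to mu off the diagonal,
        so for between-taxon comparison mu is a pure scale factor and the
        default of 1 reports distortion per mutation event.
    scales : sequence of PropertyScale, optional
        Property scales to score; defaults to the four built-ins
        (polar requirement, hydropathy, molecular volume, isoelectric point).
    stop_policy : {"exclude", "max_penalty"}, default "exclude"
        How mutations into stop codons are charged.
    d_form : {"squared", "absolute"}, default "squared"
        Functional form of the pairwise amino-acid cost.
    code : GeneticCode, optional
        Defaults to the standard genetic code.

    Attributes
    ----------
    kernel_ : MutationKernel
    distortion_matrices_ : list of DistortionMatrix
    cost_matrix_ : ndarray of shape (61, n_scales)
        Per-codon expected costs; ``transform(X) == X @ cost_matrix_``.
    feature_names_in_order_ : tuple of str
        Sense codons, lexicographic, defining the expected column order of X.
    """

    def __init__(
        self,
        kappa: float = 2.5,
        mu: float = 1.0,
        scales: Sequence[PropertyScale] | None = None,
        stop_policy: StopPolicy = "exclude",
        d_form: Literal["squared", "absolute"] = "squared",
        code: GeneticCode | None = None,
    ):
        self.kappa = kappa
        self.mu = mu
        self.scales = scales
        self.stop_policy = stop_policy
        self.d_form = d_form
        self.code = code

    def fit(self, X=None, y=None) -> "CodonDistortion":
        code = self.code if self.code is not None else standard_code()
        scales = list(self.scales) if self.scales is not None else builtin_scales()
        self.code_ = code
        self.kernel_ = build_kernel(self.kappa, self.mu)
        self.distortion_matrices_ = [
            build_distortion_matrix(s, code, form=self.d_form) for s in scales
        ]
        self.scale_names_ = tuple(s.name for s in scales)
        self.feature_names_in_order_ = code.sense_codons
        self.cost_matrix_ = np.column_stack(
            [
                _codon_cost_vector(self.kernel_, dm, code, self.stop_policy)
                for dm in self.distortion_matrices_
            ]
        )
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "cost_matrix_")
        if isinstance(X, pd.DataFrame):
            X = X.reindex(columns=list(self.feature_names_in_order_)).to_numpy()
        X = check_array(X, dtype=float)
        if X.shape[1] != len(self.feature_names_in_order_):
            raise ValueError(
                f"expected {len(self.feature_names_in_order_)} sense-codon "
                f"frequency columns, got {X.shape[1]}"
            )
        if np.any(X < -1e-12) or not np.allclose(X.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("rows of X must be frequency vectors summing to 1")
        return X @ self.cost_matrix_

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "scale_names_")
        return np.array([SHORT_NAMES.get(n, f"D_{n}") for n in self.scale_names_])


def expected_distortion(
    profile: CodonUsageProfile,
    kernel: MutationKernel | None = None,
    dmat: DistortionMatrix | None = None,
    code: GeneticCode | None = None,
    stop_policy: StopPolicy = "exclude",
) -> float:
    """Expected distortion D for one taxon on one property scale."""
    code = code or standard_code()
    kernel = kernel or build_kernel()
    if dmat is None:
        raise ValueError("a DistortionMatrix is required")
    missing = set(code.amino_acids()) - set(dmat.amino_acids)
    if missing:
        raise ValueError(
            f"distortion matrix (scale {dmat.scale_name!r}) does not cover "
            f"the code's amino acids: {sorted(missing)}"
        )
    cost = _codon_cost_vector(kernel, dmat, code, stop_policy)
    return float(profile.freq_vector(code) @ cost)


def distortion_panel(
    profile: CodonUsageProfile,
    kernel: MutationKernel | None = None,
    scales: Sequence[PropertyScale] | None = None,
    code: GeneticCode | None = None,
    stop_policy: StopPolicy = "exclude",
    d_form: Literal["squared", "absolute"] = "squared",
) -> DistortionPanel:
    """All four distortion measures for one taxon."""
    kernel = kernel or build_kernel()
    est = CodonDistortion(
        kappa=kernel.kappa,
        mu=kernel.mu,
        scales=scales,
        stop_policy=stop_policy,
        d_form=d_form,
        code=code,
    ).fit()
    values = est.transform(profile.freq_vector(est.code_)[None, :])[0]
    return DistortionPanel(
        taxon_id=profile.taxon_id,
        kappa=kernel.kappa,
        mu=kernel.mu,
        stop_policy=stop_policy,
        values=dict(zip(est.scale_names_, map(float, values))),
    )


def panel_table(
    profiles: Iterable[CodonUsageProfile],
    kappa: float = 2.5,
    mu: float = 1.0,
    scales: Sequence[PropertyScale] | None = None,
    code: GeneticCode | None = None,
    stop_policy: StopPolicy = "exclude",
    d_form: Literal["squared", "absolute"] = "squared",
) -> pd.DataFrame:
    """Distortion panel for many taxa as a tidy DataFrame.

    Columns: taxon_id, kappa, mu, stop_policy, D_<scale> for each scale, gc.
    """
    profiles = list(profiles)
    est = CodonDistortion(
        kappa=kappa, mu=mu, scales=scales, stop_policy=stop_policy,
        d_form=d_form, code=code,
    ).fit()
    X = np.vstack([p.freq_vector(est.code_) for p in profiles])
    D = est.transform(X)
    out = pd.DataFrame(D, columns=est.get_feature_names_out())
    out.insert(0, "taxon_id", [p.taxon_id for p in profiles])
    out.insert(1, "kappa", kappa)
    out.insert(2, "mu", mu)
    out.insert(3, "stop_policy", stop_policy)
    out["gc"] = [p.gc for p in profiles]
    return out


def kappa_sweep(
    profile: CodonUsageProfile,
    kappa_values: Sequence[float],
    scales: Sequence[PropertyScale] | None = None,
    code: GeneticCode | None = None,
    mu: float = 1.0,
    stop_policy: StopPolicy = "exclude",
) -> pd.DataFrame:
    """Distortion panel across a grid of ti/tv ratios, mu held fixed.

    Returns a long-format frame (taxon_id, kappa, scale, D) ordered by kappa.
    """
    kappa_values = list(kappa_values)
    if not kappa_values:
        raise ValueError("empty kappa grid")
    rows = []
    for k in sorted(kappa_values):
        panel = distortion_panel(
            profile, build_kernel(k, mu), scales=scales, code=code,
            stop_policy=stop_policy,
        )
        for scale, val in panel.values.items():
            rows.append({"taxon_id": profile.taxon_id, "kappa": k,
                         "scale": scale, "D": val})
    return pd.DataFrame(rows)
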