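"""Synthetic comparative datasets: tree, environments, and codon usage.

The generator produces complete inputs for the pipeline without any
external data: a pure-birth (Yule) clade tree, environmental optima and
GC-content evolving by Brownian motion along it, and per-taxon codon usage
vectors whose composition responds to GC and environment through planted,
controllable effect sizes.

The usage model is deliberately simple.  A base codon distribution is the
product of independent per-position nucleotide probabilities with
P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2, so GC-content is a genuine
causal driver of composition.  Environmental deviations from the baseline
[GC = 0.5, T = 30 C, NaCl = 2.5 w/V%, pH = 7] then tilt the distribution
log-linearly along per-scale "local distortion" axes: the standardized
vector of each sense codon's expected mutational cost on one property
scale.  A positive temperature effect size therefore shifts usage toward
codons whose mutational neighborhoods are costly on the targeted scales,
which raises the corresponding distortion responses - the planted signal
the comparative analysis is supposed to recover.  Sampling noise is
compound-multinomial (Dirichlet-multinomial), mimicking gene-to-gene
heterogeneity in real proteomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .code_tables import STOP_CODONS, standard_code
from .codon_usage import CodonUsageProfile, usage_from_counts
from .distortion import CodonDistortion, panel_table
from .pgls import ComparativeDataset

__all__ = [
    "TRAIT_BASELINE",
    "TRAIT_RATES",
    "TRAIT_BOUNDS",
    "DEFAULT_EFFECT_SIZES",
    "SyntheticScenario",
    "simulate_tree",
    "simulate_traits",
    "synthesize_usage",
    "simulate_scenario",
    "simulate_comparative_dataset",
    "write_scenario",
]

logger = logging.getLogger(__name__)

# Reference point the planted effects are measured from.
TRAIT_BASELINE: dict[str, float] = {
    "gc": 0.5,
    "temperature": 30.0,  # degrees C
    "nacl": 2.5,          # w/V %
    "ph": 7.0,
}

# Brownian rates (squared trait units per unit branch length).  On a Yule
# tree with birth rate 1 and ~64 tips (depth ~ 3.5) these give tip spreads
# of roughly +/- 15 C, +/- 2 w/V%, +/- 0.8 pH and +/- 0.08 GC around the
# baseline - the mesophile-to-extremophile ranges the analysis is aimed at.
TRAIT_RATES: dict[str, float] = {
    "gc": 0.002,
    "temperature": 64.0,
    "nacl": 1.0,
    "ph": 0.16,
}

# Hard biological bounds applied after simulation (clamping is logged).
TRAIT_BOUNDS: dict[str, tuple[float, float]] = {
    "gc": (0.25, 0.75),
    "temperature": (0.0, 110.0),
    "nacl": (0.0, 30.0),
    "ph": (4.0, 10.0),
}

# Planted log-linear effects: predictor -> {property scale: coefficient per
# unit predictor deviation on the standardized local-distortion axis}.
# Signs follow the comparative findings the pipeline should recover:
# temperature degrades hydropathic/volumetric/isoelectric fidelity, NaCl
# degrades polar/isoelectric fidelity, pH (weakly) polar fidelity, and GC
# additionally tilts hydropathic fidelity beyond its compositional role.
DEFAULT_EFFECT_SIZES: dict[str, dict[str, float]] = {
    "temperature": {
        "hydropathy": 0.002,
        "molecular_volume": 0.002,
        "isoelectric_point": 0.002,
    },
    "nacl": {
        "polar_requirement": 0.02,
        "isoelectric_point": 0.02,
    },
    "ph": {
        "polar_requirement": 0.04,
    },
    "gc": {
        "hydropathy": 0.4,
    },
}


@dataclass(frozen=True)
class SyntheticScenario:
    """Everything needed to generate one synthetic comparative study."""

    n_tips: int = 64
    seed: int = 0
    birth_rate: float = 1.0
    trait_baseline: Mapping[str, float] = field(
        default_factory=lambda: dict(TRAIT_BASELINE))
    trait_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(TRAIT_RATES))
    effect_sizes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECT_SIZES.items()})
    noise_concentration: float = 5000.0
    genes_per_taxon: int = 200
    gene_length_codons: int = 300

    def __post_init__(self) -> None:
        if self.n_tips < 4:
            raise ValueError(f"n_tips must be >= 4, got {self.n_tips}")
        if self.birth_rate <= 0 or self.noise_concentration <= 0:
            raise ValueError("birth_rate and noise_concentration must be positive")
        if self.gene_length_codons < 2 or self.genes_per_taxon < 1:
            raise ValueError("need gene_length_codons >= 2 and genes_per_taxon >= 1")
        if any(r < 0 for r in self.trait_rates.values()):
            raise ValueError("Brownian rates must be non-negative")

    def with_(self, **kwargs) -> "SyntheticScenario":
        return replace(self, **kwargs)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n_tips`` labeled tips.

    Lineages split at rate ``birth_rate`` each; after the last split the
    process runs for one more exponential waiting time so every pendant
    edge has positive length.  Deterministic per seed.
    """
    if n_tips < 4:
        raise ValueError(f"n_tips must be >= 4, got {n_tips}")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    active = [root.new_child(edge_length=0.0), root.new_child(edge_length=0.0)]
    k = 2
    while k < n_tips:
        dt = rng.exponential(1.0 / (k * birth_rate))
        for node in active:
            node.edge.length += dt
        idx = rng.integers(len(active))
        parent = active.pop(int(idx))
        active.append(parent.new_child(edge_length=0.0))
        active.append(parent.new_child(edge_length=0.0))
        k += 1
    dt = rng.exponential(1.0 / (n_tips * birth_rate))
    for node in active:
        node.edge.length += dt
    ns = dendropy.TaxonNamespace()
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = ns.new_taxon(f"t{i:03d}")
    tree.taxon_namespace = ns
    return tree


def simulate_traits(
    tree: dendropy.Tree,
    baseline: Mapping[str, float] | None = None,
    rates: Mapping[str, float] | None = None,
    seed: int = 0,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Brownian-motion traits along the tree, one column per trait.

    Each trait starts at its baseline at the root and accrues independent
    Normal(0, rate * branch_length) increments down every edge.  Values are
    clamped to biological bounds afterwards; clamping is logged.
    """
    baseline = dict(baseline or TRAIT_BASELINE)
    rates = dict(rates or TRAIT_RATES)
    bounds = dict(bounds or TRAIT_BOUNDS)
    if any(r < 0 for r in rates.values()):
        raise ValueError("Brownian rates must be non-negative")
    traits = sorted(baseline)
    rngs = dict(zip(traits, _substreams(seed, len(traits))))

    values: dict[int, dict[str, float]] = {id(tree.seed_node): dict(baseline)}
    rows = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length or 0.0
        parent = values[id(node.parent_node)]
        here = {
            tr: parent[tr] + rngs[tr].normal(0.0, np.sqrt(rates.get(tr, 0.0) * bl))
            for tr in traits
        }
        values[id(node)] = here
        if node.is_leaf():
            rows[node.taxon.label] = dict(here)

    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "taxon_id"
    n_clamped = 0
    for tr, (lo, hi) in bounds.items():
        if tr in df.columns:
            out = (df[tr] < lo) | (df[tr] > hi)
            n_clamped += int(out.sum())
            df[tr] = df[tr].clip(lo, hi)
    if n_clamped:
        logger.warning("clamped %d simulated trait values to biological bounds",
                       n_clamped)
    return df[sorted(df.columns)]


def _distortion_axes() -> tuple[np.ndarray, tuple[str, ...]]:
    """Standardized per-sense-codon local distortion axes, one per scale."""
    est = CodonDistortion(kappa=2.5, mu=1.0).fit()
    cost = est.cost_matrix_  # (61, 4)
    z = (cost - cost.mean(axis=0)) / cost.std(axis=0)
    return z, est.scale_names_


_AXES_CACHE: tuple[np.ndarray, tuple[str, ...]] | None = None


def _axes() -> tuple[np.ndarray, tuple[str, ...]]:
    global _AXES_CACHE
    if _AXES_CACHE is None:
        _AXES_CACHE = _distortion_axes()
    return _AXES_CACHE


def expected_usage(
    gc: float,
    temperature: float = 30.0,
    nacl: float = 2.5,
    ph: float = 7.0,
    effect_sizes: Mapping[str, Mapping[str, float]] | None = None,
    baseline: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Noise-free sense-codon distribution for given GC and environment."""
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be strictly inside (0, 1), got {gc}")
    effect_sizes = effect_sizes if effect_sizes is not None else DEFAULT_EFFECT_SIZES
    baseline = dict(baseline or TRAIT_BASELINE)
    code = standard_code()
    sense = code.sense_codons
    p_base_nt = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    base = np.array([np.prod([p_base_nt[b] for b in c]) for c in sense])
    z, scale_names = _axes()
    env = {"gc": gc, "temperature": temperature, "nacl": nacl, "ph": ph}
    tilt = np.zeros(len(sense))
    for pred, per_scale in effect_sizes.items():
        dev = env[pred] - baseline[pred]
        for scale, coef in per_scale.items():
            tilt += coef * dev * z[:, scale_names.index(scale)]
    w = base * np.exp(tilt)
    return w / w.sum()


def synthesize_usage(
    gc: float,
    temperature: float = 30.0,
    nacl: float = 2.5,
    ph: float = 7.0,
    effect_sizes: Mapping[str, Mapping[str, float]] | None = None,
    noise_concentration: float = 5000.0,
    seed: int | np.random.Generator = 0,
    n_codons: int = 60000,
    taxon_id: str = "synthetic",
) -> CodonUsageProfile:
    """Sample one taxon's codon usage profile.

    Counts are Dirichlet-multinomial around the expected usage: the taxon's
    true frequencies are drawn from Dirichlet(concentration * expected), and
    ``n_codons`` codons are then drawn multinomially.  GC-content is
    computed from the sampled codon counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise_concentration <= 0 or n_codons < 1:
        raise ValueError("noise_concentration and n_codons must be positive")
    w = expected_usage(gc, temperature, nacl, ph, effect_sizes)
    p_true = rng.dirichlet(noise_concentration * w)
    counts_vec = rng.multinomial(n_codons, p_true)
    code = standard_code()
    counts = dict(zip(code.sense_codons, (int(x) for x in counts_vec)))
    gc_counts = sum(n * sum(b in "GC" for b in c) for c, n in counts.items())
    realized_gc = gc_counts / (3 * n_codons)
    return usage_from_counts(counts, code=code, taxon_id=taxon_id, gc=realized_gc)


def simulate_scenario(
    scenario: SyntheticScenario,
) -> tuple[dendropy.Tree, pd.DataFrame, list[CodonUsageProfile]]:
    """Generate tree, tip traits, and per-taxon usage profiles."""
    ss = np.random.SeedSequence(scenario.seed).spawn(3)
    tree_seed, trait_seed, usage_ss = ss[0], ss[1], ss[2]
    tree = simulate_tree(
        scenario.n_tips, scenario.birth_rate,
        seed=int(tree_seed.generate_state(1)[0] % (2**31)))
    traits = simulate_traits(
        tree, scenario.trait_baseline, scenario.trait_rates,
        seed=int(trait_seed.generate_state(1)[0] % (2**31)))
    n_codons = scenario.genes_per_taxon * scenario.gene_length_codons
    profiles = []
    for taxon, child in zip(traits.index, usage_ss.spawn(len(traits))):
        row = traits.loc[taxon]
        profiles.append(synthesize_usage(
            gc=float(row["gc"]),
            temperature=float(row["temperature"]),
            nacl=float(row["nacl"]),
            ph=float(row["ph"]),
            effect_sizes=scenario.effect_sizes,
            noise_concentration=scenario.noise_concentration,
            seed=np.random.default_rng(child),
            n_codons=n_codons,
            taxon_id=taxon,
        ))
    return tree, traits, profiles


def simulate_comparative_dataset(
    scenario: SyntheticScenario, kappa: float = 2.5, mu: float = 1.0,
) -> ComparativeDataset:
    """End-to-end synthetic dataset: distortion panel joined with environment.

    The ``gc`` predictor is the realized GC of the sampled codons (as the
    extraction stage would measure), not the latent Brownian trait.
    """
    tree, traits, profiles = simulate_scenario(scenario)
    panel = panel_table(profiles, kappa=kappa, mu=mu).set_index("taxon_id")
    merged = panel[["D_pol", "D_hyd", "D_vol", "D_pI", "gc"]].join(
        traits[["temperature", "nacl", "ph"]])
    return ComparativeDataset(tree=tree, traits=merged)


def write_scenario(scenario: SyntheticScenario, outdir: str | Path) -> dict[str, Path]:
    """Materialize a scenario on disk as Newick + FASTA + TSV.

    Writes ``tree.nwk``, ``traits.tsv`` (taxon_id, temperature, nacl, ph),
    ``manifest.tsv`` (taxon_id, fasta path) and one CDS FASTA per taxon
    under ``cds/``.  Genes are sampled codon-by-codon from the taxon's
    usage profile with one stop codon appended, so re-extracting usage from
    the FASTA recovers the profile up to multinomial sampling error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "cds").mkdir(exist_ok=True)
    tree, traits, profiles = simulate_scenario(scenario)
    fasta_rng = np.random.default_rng(np.random.SeedSequence(scenario.seed).spawn(4)[3])

    tree_path = outdir / "tree.nwk"
    tree_path.write_text(tree.as_string(schema="newick", suppress_rooting=True))

    traits_path = outdir / "traits.tsv"
    traits[["temperature", "nacl", "ph"]].to_csv(traits_path, sep="\t")

    code = standard_code()
    sense = np.array(code.sense_codons)
    stops = np.array(STOP_CODONS)
    manifest_rows = []
    for prof in profiles:
        p = prof.freq_vector(code)
        path = outdir / "cds" / f"{prof.taxon_id}.fasta"
        with path.open("w") as fh:
            for g in range(scenario.genes_per_taxon):
                codons = fasta_rng.choice(sense, size=scenario.gene_length_codons, p=p)
                stop = fasta_rng.choice(stops)
                fh.write(f">{prof.taxon_id}_gene{g + 1}\n")
                fh.write("".join(codons) + stop + "\n")
        manifest_rows.append((prof.taxon_id, str(path)))
    manifest_path = outdir / "manifest.tsv"
    with manifest_path.open("w") as fh:
        fh.write("taxon_id\tfasta\n")
        for taxon, path in manifest_rows:
            fh.write(f"{taxon}\t{path}\n")
    return {"tree": tree_path, "traits": traits_path, "manifest": manifest_path}
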