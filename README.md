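# codefidelity

Mutational robustness of the standard genetic code, weighted by codon usage,
analysed in a phylogenetic comparative framework.

## The problem

The genetic code is often called "one in a million" for how well its layout
buffers point mutations: most single-nucleotide changes either preserve the
amino acid or substitute a physicochemically similar one.  That buffering,
however, depends on which codons an organism actually uses.  Thermophiles,
halophiles and GC-rich genomes have characteristic codon compositions, so the
*expected* cost of a random mutation differs between organisms even though
they share the same code.  This package quantifies that cost per taxon and
asks, with phylogenetically corrected regression, whether extreme
environments (high optimal growth temperature, high salinity, extreme pH) and
GC-content push codon usage toward regions of the code where mutations are
more damaging.

It is aimed at molecular-evolution researchers who have per-taxon coding
sequences (CDS FASTA), a dated/rooted phylogeny (Newick), and environmental
optima, and want a reproducible distortion-and-PGLS pipeline — plus a
synthetic-data generator to validate every stage without external downloads.

## The statistic

For a taxon with sense-codon usage P(c_i), the expected distortion on one
amino-acid property scale is

    D = Σ_{i,j} P(c_i) · P(Y = c_j | X = c_i) · d(aa_i, aa_j)

where the mutation kernel P(Y = c_j | X = c_i) is a Kimura-style
two-parameter model over codons — single-nucleotide events only, transition
probability κ/(1+κ) and transversion probability 1/(1+κ) conditional on an
event (κ is the ti/tv rate ratio; at the default κ = 2.5 roughly 71 % of
mutations are transitions), diagonal 1 − μ — and d(aa_i, aa_j) is the squared
difference of a property value, zero for synonymous pairs.  Four scales give
four measures: polar requirement (D_pol), hydropathy (D_hyd), molecular
volume (D_vol) and isoelectric point (D_pI).

Each D is then regressed on GC-content, temperature, NaCl and pH with
phylogenetic generalized least squares (PGLS) under a Brownian-motion
covariance V (V_ij = shared root-to-tip branch length of tips i and j):
β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y, with per-coefficient t tests, standardized (Z-scored)
partial coefficients, a generalized R² against the GLS intercept-only null,
and the model F statistic with (4, n−5) degrees of freedom.

## Worked example

A fully synthetic 64-taxon study with the default planted effects
(temperature degrades hydropathic/volumetric/isoelectric fidelity, NaCl
degrades polar/isoelectric fidelity, GC raises hydropathic distortion):

```python
from codefidelity import (SyntheticScenario, simulate_comparative_dataset,
                          run_full_analysis, model_summary_table,
                          results_long_table)

ds = simulate_comparative_dataset(SyntheticScenario(n_tips=64, seed=42))
results = run_full_analysis(ds)
print(model_summary_table(results).round(3).to_string(index=False))
```

```
response    r2      f  df1  df2  p_model  n
   D_hyd 0.573 19.780    4   59      0.0 64
   D_pol 0.703 34.970    4   59      0.0 64
   D_vol 0.501 14.828    4   59      0.0 64
    D_pI 0.700 34.368    4   59      0.0 64
```

All four distortion responses yield significant models with the F₄,₅₉ shape
of a 64-taxon design.  Per-term output for the hydropathy response:

```python
t = results_long_table(results)
print(t[t.response == "D_hyd"].round(4).to_string(index=False))
```

```
response        term    beta     se       t      p  beta_std
   D_hyd   intercept  6.3634 0.2869 22.1784 0.0000       NaN
   D_hyd          gc  1.7989 0.2406  7.4776 0.0000    0.6996
   D_hyd temperature  0.0079 0.0015  5.2886 0.0000    0.8385
   D_hyd        nacl  0.0169 0.0118  1.4226 0.1601    0.2176
   D_hyd          ph -0.0131 0.0328 -0.4005 0.6902   -0.0735
```

GC-content and temperature show the planted significant positive effects on
hydropathic distortion (hotter environments and GC-richer coding regions →
codon usages whose mutations damage hydrophobic patterning more), while NaCl
and pH — which were not planted on this response — stay non-significant.

The same pipeline runs from files via the CLI:

```bash
codefidelity simulate --n-tips 64 --seed 42 --out scenario/
codefidelity distortion --manifest scenario/manifest.tsv --out dist/
# join dist/panel.tsv with scenario/traits.tsv on taxon_id, then:
codefidelity pgls --tree scenario/tree.nwk --traits merged.tsv --out pgls/
codefidelity sweep --manifest scenario/manifest.tsv --kappa-grid 2.5,5,7.5,10 --out sweep/
```

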