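"""Multiple-testing adjustment across a published gene-set screen.

Applies Benjamini-Hochberg step-up FDR adjustment to the bundled combined
p-values of a 20-gene-set bipolar-disorder exome screen and prints the
sets reaching nominal significance.
"""

from bomp import bh_adjust
from bomp.datasets import BIPOLAR_GENE_SET_PVALUES

names = list(BIPOLAR_GENE_SET_PVALUES)
pvals = [v[0] for v in BIPOLAR_GENE_SET_PVALUES.values()]
fdr = bh_adjust(pvals)

print(f"{'gene set':55s} {'p':>8s} {'FDR':>8s}")
for name, p, q in sorted(zip(names, pvals, fdr), key=lambda t: t[1]):
    flag = " *" if p < 0.05 else ""
    print(f"{name:55s} {p:8.4f} {q:8.4f}{flag}")

n_nominal = sum(p < 0.05 for p in pvals)
print(f"\n{n_nominal} of {len(pvals)} sets are nominally significant (p < 0.05, "
      "starred); after BH adjustment the\nseven smallest share an FDR of "
      f"{fdr[0]:.4f} - borderline at a 0.10 false-discovery level.")
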