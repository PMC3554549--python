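"""Bundled example data.

``BIPOLAR_GENE_SET_PVALUES`` holds the published per-gene-set permutation
p-values (combined, burden-only and position-only) of a whole-exome
bipolar-disorder case-control screen (191 cases, 107 controls) over twenty
synaptic-gene-enriched MSigDB gene sets. It is used in examples and tests
as a realistic input for multiple-testing adjustment across functional
groups.
"""

from __future__ import annotations

__all__ = ["BIPOLAR_GENE_SET_PVALUES", "bipolar_pvalues"]

#: gene set name -> (combined p, burden p, position p)
BIPOLAR_GENE_SET_PVALUES: dict[str, tuple[float, float, float]] = {
    "MAPK SIGNALING PATHWAY (KEGG)": (0.0065, 1.0000, 0.0043),
    "AXON GUIDANCE (Reactome)": (0.0162, 0.5847, 0.0137),
    "NEUROLOGICAL SYSTEM PROCESS (GO)": (0.0274, 0.2787, 0.0273),
    "METABOLISM OF PROTEINS (Reactome)": (0.0299, 0.3437, 0.0272),
    "NEUROACTIVE LIGAND RECEPTOR INTERACTION (KEGG)": (0.0309, 0.8490, 0.0259),
    "HUNTINGTONS DISEASE (KEGG)": (0.0312, 0.5408, 0.0266),
    "CALCIUM SIGNALING PATHWAY (KEGG)": (0.0332, 0.4796, 0.0303),
    "POST TRANSLATIONAL PROTEIN MODIFICATION (GO)": (0.0635, 0.4031, 0.0620),
    "NERVOUS SYSTEM DEVELOPMENT (GO)": (0.0744, 0.8912, 0.0674),
    "SIGNALLING BY NGF (Reactome)": (0.1290, 0.8393, 0.1139),
    "GNRH SIGNALING PATHWAY (KEGG)": (0.1313, 0.7485, 0.1109),
    "OXIDATIVE PHOSPHORYLATION (KEGG)": (0.1390, 0.4222, 0.1263),
    "ALZHEIMERS DISEASE (KEGG)": (0.2164, 0.7012, 0.1904),
    "INTRACELLULAR SIGNALING CASCADE (GO)": (0.2267, 0.7489, 0.2174),
    "NEUROTROPHIN SIGNALING PATHWAY (KEGG)": (0.2363, 0.7995, 0.2031),
    "CHEMOKINE SIGNALING PATHWAY (KEGG)": (0.2667, 0.6638, 0.2464),
    "WNT SIGNALING PATHWAY (KEGG)": (0.2781, 0.7009, 0.2519),
    "REGULATION OF GENE EXPRESSION IN BETA CELLS (Reactome)": (0.3401, 0.0877, 0.4571),
    "MITOCHONDRION (GO)": (0.4315, 0.9727, 0.4047),
    "PARKINSONS DISEASE (KEGG)": (0.7893, 0.3087, 0.8111),
}


def bipolar_pvalues() -> list[float]:
    """The twenty combined p-values, in published order."""
    return [v[0] for v in BIPOLAR_GENE_SET_PVALUES.values()]
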