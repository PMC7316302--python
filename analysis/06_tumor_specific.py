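"""Identify tumor-specific superenhancers and the gene set they drive.

Acquired: present (log2(RPKM+1) >= 6) in >= 4 tumor cell lines and >= 1
primary tumor, absent from all normals. Enlarged: same tumor presence but
present in normals with >= 2x mean tumor/normal signal. Emits the calls,
the associated gene list, and a comparison against the planted truth.
"""

import pandas as pd

from common import load_truth, require_study, results_dir
from selandscape import pipeline
from selandscape.io import read_matrix
from selandscape.tumor import tumor_specific_genes

study_dir = require_study()
expression = read_matrix(study_dir / "expression.tsv")
genes = pd.read_csv(study_dir / "genes.tsv", sep="\t")
result = pipeline.run_pipeline(study_dir, expression=expression, genes=genes)

out = results_dir()
result.tumor_calls.to_csv(out / "06_tumor_specific_se.tsv", sep="\t")
passing = result.associations[result.associations["r"] >= 0.6]
gene_list = tumor_specific_genes(result.tumor_calls, passing)
pd.Series(gene_list, name="gene").to_csv(out / "06_tumor_specific_genes.tsv",
                                         sep="\t", index=False)

truth = load_truth()
planted = {
    (e["chrom"], e["start"], e["end"]) for e in truth["elements"]
    if e["class"] == "tumor_specific_SE"
}
called = {
    (result.element_scores.intervals[e].chrom,
     result.element_scores.intervals[e].start,
     result.element_scores.intervals[e].end)
    for e in result.tumor_calls.index
}
tp = len(called & planted)
precision = tp / len(called) if called else float("nan")
recall = tp / len(planted) if planted else float("nan")

print(result.tumor_calls[["mode", "n_tumor_lines_present", "n_primaries_present",
                          "n_normals_present", "fold"]])
print(f"precision vs planted truth: {precision:.2f}; recall: {recall:.2f}")
print(f"screen gene set ({len(gene_list)}): {gene_list}")
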