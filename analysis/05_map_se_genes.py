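"""Associate consensus superenhancers with putative target genes.

For each SE, Pearson correlation of log2 SE size vs log2 gene RPKM across
the tumor cell lines, over all genes within 10 Mb; genes at r >= 0.6 are
associated and every SE keeps its two best-correlated genes regardless.
Reports the distance distribution and checks recovery of the planted pairs.
"""

import pandas as pd

from common import load_truth, require_study, results_dir
from selandscape import pipeline
from selandscape.genemap import distance_report
from selandscape.io import read_matrix

study_dir = require_study()
expression = read_matrix(study_dir / "expression.tsv")
genes = pd.read_csv(study_dir / "genes.tsv", sep="\t")
result = pipeline.run_pipeline(study_dir, expression=expression, genes=genes)

out = results_dir()
result.associations.to_csv(out / "05_se_gene_associations.tsv", sep="\t", index=False)

report = distance_report(result.associations)
passing = result.associations[result.associations["r"] >= 0.6]
truth = load_truth()
planted_genes = {g for _, g, _ in truth["associations"]}
recovered = planted_genes & set(passing["gene"])

print(f"{len(result.associations)} associations for {result.associations['element'].nunique()} SEs "
      f"({len(passing)} at r >= 0.6, rest mandatory best-two)")
print(f"distance quantiles (bp): {report['quantiles']}")
print(f"planted association genes recovered at threshold: "
      f"{len(recovered)}/{len(planted_genes)}")
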