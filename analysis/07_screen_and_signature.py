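"""Score the CRISPR dropout screen and build dependency-correlated SE
signatures.

Guide LFCs (CPM, pseudocount 0.5) -> gene LFC (mean of the 3 most-depleted
guides) -> control-anchored normalization (essentials at -1, NTCs at 0) ->
hits at <= -0.5. Cell lines are classified dependent at CERES <= -0.5 and
the SEs most positively/negatively correlated with dependency form the
signature, with a naive and a permutation-calibrated separation p-value.
"""

import numpy as np
import pandas as pd

from common import load_truth, require_study, results_dir
from selandscape.io import read_matrix
from selandscape.screen import (
    classify_dependent,
    dependency_signature,
    permutation_separation_p,
    score_screen,
)

study_dir = require_study()
truth = load_truth()
roles = pd.read_csv(study_dir / "screen" / "roles.tsv", sep="\t", index_col=0)["role"]
out = results_dir()

screen_tables = []
for line in truth["screen_lines"] + [truth["screen_normal_line"]]:
    counts = pd.read_csv(study_dir / "screen" / f"{line}.counts.tsv", sep="\t")
    res = score_screen(counts, roles)
    res.insert(0, "cell_line", line)
    screen_tables.append(res)
screen_result = pd.concat(screen_tables)
screen_result.to_csv(out / "07_screen_results.tsv", sep="\t")

hits = screen_result[screen_result.is_hit & (screen_result.role == "target")]
dep_genes = set(truth["dependencies"])
print("target-gene hits per line:")
print(hits.groupby("cell_line").apply(lambda d: sorted(d.index), include_groups=False))
print(f"planted dependency genes: {sorted(dep_genes)}")

# dependency signature from CERES-like scores for one dependency gene
ceres = read_matrix(study_dir / "ceres.tsv")
gene = sorted(dep_genes)[0]
labels = classify_dependent(ceres.loc[gene])
sizes = read_matrix(out / "03_se_sizes.tsv")[labels.index.tolist()]
log_scores = np.log2(sizes + 1.0)
sig = dependency_signature(log_scores, labels, signature_size=600)
perm_p = permutation_separation_p(log_scores, labels, signature_size=600,
                                  n_permutations=499, seed=0)
sig.positive.rename("r").to_csv(out / "07_signature_positive.tsv", sep="\t",
                                index_label="element")
sig.negative.rename("r").to_csv(out / "07_signature_negative.tsv", sep="\t",
                                index_label="element")
print(f"{gene}: {int(labels.sum())} dependent lines {sorted(labels[labels].index)}")
print(f"signature size {sig.signature_size} (capped by map size); "
      f"separation p = {sig.separation_p:.4g}, permutation-calibrated p = {perm_p:.4g}")
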