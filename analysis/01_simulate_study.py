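"""Generate the synthetic H3K27Ac study with planted ground truth.

Writes per-sample peak BEDs and ChIP/input coverage, the sample sheet,
gene annotation, an expression matrix, screen count tables and CERES-like
dependency scores under scratch/synthetic_study, plus a summary table under
results/. The landscape plants 31 samples (16 clustered cell lines, 2
outlier lines, 8 clustered primaries, 1 outlier primary, 4 normals) and 72
superenhancers across shared / cluster-specific / tumor-specific /
normal-only classes on an 8 x 2.5 Mb genome.
"""

import pandas as pd

from common import RESULTS, SEED, STUDY_DIR, results_dir
from selandscape import synth

landscape = synth.simulate_landscape(seed=SEED)
files = synth.write_study(landscape, STUDY_DIR)

classes = pd.Series([e.klass for e in landscape.elements]).value_counts()
summary = classes.rename("n_elements").to_frame()
summary.to_csv(results_dir() / "01_landscape_summary.tsv", sep="\t", index_label="class")

print(f"study written to {STUDY_DIR}")
print(f"{len(landscape.samples)} samples "
      f"({len(landscape.cell_lines)} cell lines, {len(landscape.primaries)} primaries, "
      f"{len(landscape.normals)} normals)")
print(summary)
print(f"planted associations: {len(landscape.associations)}; "
      f"planted dependencies: {sorted(landscape.dependencies)}")
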