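"""Consensus maps, 20 kb bins, input-subtracted RPKM scoring and presence.

Consolidates per-sample SE calls (>= 5 kb overlap) and raw peaks
(>= 10 bp overlap, TSS-overlapping enhancers removed), bins SEs at 20 kb,
scores every sample against the SE map, and calls per-sample SE presence at
log2(RPKM+1) >= 6. Writes the consensus BEDs and the score/presence/size
matrices.
"""

import pandas as pd

from common import require_study, results_dir
from selandscape import pipeline
from selandscape.io import write_bed, write_matrix

study = pipeline.load_study(require_study())
tables = pipeline.call_sample_enhancers(study)
se_elements, enh_elements, bins = pipeline.build_consensus_maps(study, tables)
scored = pipeline.score_consensus(study, se_elements, bins)

out = results_dir()
write_bed(
    out / "03_consensus_se.bed",
    [e.interval for e in se_elements],
    scores=[len(e.samples) for e in se_elements],
)
write_bed(
    out / "03_consensus_enhancers.bed",
    [e.interval for e in enh_elements],
    scores=[len(e.samples) for e in enh_elements],
)
write_matrix(out / "03_se_scores.tsv", scored["element_scores"].values, "element")
write_matrix(out / "03_se_presence.tsv", scored["presence"].astype(int), "element")
write_matrix(out / "03_se_sizes.tsv", scored["sizes"], "element")

presence = scored["presence"]
print(f"consensus map: {len(se_elements)} SEs ({len(bins)} bins), "
      f"{len(enh_elements)} enhancers")
print(f"SE presence calls per sample: min {int(presence.sum().min())}, "
      f"max {int(presence.sum().max())}")
print(f"SEs present in every sample: {int(presence.all(axis=1).sum())}; "
      f"in exactly one: {int((presence.sum(axis=1) == 1).sum())}")
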