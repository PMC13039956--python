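"""Score one variant: REF/ALT contact maps compared under 4 augmentations.

A deletion that removes a TAD boundary motif merges the two blocks it
separated, changing predicted contacts across the whole window; an
equal-length deletion in featureless sequence barely moves the map.
MSE and CORR (1 - Pearson r) quantify that contrast; each variant is
scored under four input augmentations (none, +/-1 bp shift, reverse
complement) and aggregated by the median.
"""

import numpy as np

from svfold import StructuralVariant, ToyPredictor, ToyPredictorParams, \
    score_variant
from svfold.synthetic import _scrub_motifs

params = ToyPredictorParams()
rng = np.random.default_rng(1)
seq = list(rng.choice(list("ACGT"), size=2_400_000))
_scrub_motifs(seq, params)
seq[1_200_000 : 1_200_012] = params.boundary_motif  # one TAD boundary
genome = {"chr1": "".join(seq)}

predictor = ToyPredictor(params)
driver = StructuralVariant(id="boundary_del", chrom="chr1",
                           start=1_199_500, end=1_200_600, svtype="DEL")
passenger = StructuralVariant(id="passenger_del", chrom="chr1",
                              start=900_000, end=901_100, svtype="DEL")

for sv in (driver, passenger):
    res = score_variant(sv, genome, predictor)
    print(f"{sv.id}: MSE(median)={res.mse_median:.5f}  "
          f"CORR(median)={res.corr_median:.5f}")
    print("  per augmentation:",
          {a: round(c.mse, 5) for a, c in res.per_augmentation.items()})

# The boundary-deleting variant scores orders of magnitude above the
# passenger: that separation is what the cohort cutoff exploits.
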