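"""Agreement metrics from a published-style 3-class confusion table.

Takes a 3-class confusion matrix (predicted stage by row, technician stage
by column) of an 8207-epoch evaluation, collapses it to the binary wake and
N3 tables, and prints sensitivity, accuracy and Cohen's kappa for each, plus
the 3-class global accuracy — the standard report format for automatic-
versus-technician staging comparisons.
"""

import numpy as np

from sleepwvd import ConfusionMatrixK, cohen_kappa, global_accuracy, \
    sensitivity_accuracy

counts = np.array([[1971, 30, 487],
                   [36, 1263, 421],
                   [100, 119, 3780]])
multi = ConfusionMatrixK(counts)
print(f"epochs scored: {multi.total}")

for stage in ("WAKE", "N3"):
    m = multi.collapse(stage)
    sens, acc = sensitivity_accuracy(m)
    print(f"{stage:>4}: A={m.A} B={m.B} C={m.C} D={m.D}  "
          f"sensitivity {100 * sens:.2f} %  accuracy {100 * acc:.2f} %  "
          f"kappa {cohen_kappa(m):.2f}")

acc, rates = global_accuracy(multi)
print(f"global accuracy {100 * acc:.2f} %  per-class TP rates: "
      + ", ".join(f"{c} {100 * r:.2f} %" for c, r in rates.items()))
# kappa near 0.8 indicates substantial-to-excellent chance-corrected
# agreement between the automatic scorer and the technician.
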