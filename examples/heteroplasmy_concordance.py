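"""Validate mtDNA heteroplasmy quantification against known-level controls.

Simulates the control experiment: 13 samples with known heteroplasmy between
6% and 42%, sequenced to depth 1000 (binomial read sampling), quantified as
alt/(ref+alt), and compared with the known levels using Lin's concordance
correlation coefficient. Calls under the 16% caller floor are flagged for
manual review instead of being dropped.
"""

import numpy as np

from macpen.mito import heteroplasmy_fraction, lin_ccc
from macpen.simulate import MtdnaControl, simulate_mtdna_counts

levels = np.linspace(0.06, 0.42, 13)
controls = [MtdnaControl(f"CTRL{i:02d}", float(h), depth=1000)
            for i, h in enumerate(levels)]
counts = simulate_mtdna_counts(controls, np.random.default_rng(3))

measured = []
for row in counts.itertuples(index=False):
    call = heteroplasmy_fraction(row.ref_count, row.alt_count,
                                 sample=row.sample, position=row.position)
    measured.append(call.fraction)
    flag = "" if call.caller_detected else "  <- below caller floor, manual review"
    print(f"{call.sample}: true {row.true_heteroplasmy:.2f}  "
          f"measured {call.fraction:.3f}{flag}")

res = lin_ccc(levels, measured)
print(f"\nLin's concordance rho_c = {res.rho_c:.4f} "
      f"(95% CI {res.ci_low:.4f}-{res.ci_high:.4f}, n = {res.n})")
# rho_c close to 1 means the panel recovers heteroplasmy levels essentially
# without bias or scale distortion at this depth; the 6% control is still
# quantifiable even though a germline caller would not have reported it.
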