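"""ΔΔCt relative quantification of a denervation marker.

Builds a synthetic Ct table in which Scn5a (a denervation marker) is
planted 8-fold higher in G93A muscle than in wild type, then recovers the
fold change with the ΔΔCt method: dCt = Ct(target) - Ct(Gapdh) per sample,
ΔΔCt normalized to the mean WT dCt, RQ = 2^(-ΔΔCt).
"""

from eomsc.qpcr import ddct_rq, dose_response_summary
from eomsc.synth import CtSimSpec, gen_ct_table

ct = gen_ct_table(CtSimSpec(true_rq={"WT": {}, "G93A": {"Scn5a": 8.0}}, seed=2))
rq = ddct_rq(ct, target_gene="Scn5a", ref_gene="Gapdh", ref_group="WT")
print(rq.to_string(index=False))
print("G93A mean RQ:", rq.loc[rq["group"] == "G93A", "rq"].mean())
print("RQ is fold change relative to the WT group mean; the planted 8-fold "
      "induction is recovered exactly at zero noise.\n")

# dose-response: planted peak at 0.5 mM
import pandas as pd

doses = pd.DataFrame({
    "dose": [0.0] * 3 + [0.5] * 3 + [1.0] * 3,
    "rq": [1.0, 1.1, 0.9, 3.0, 3.2, 2.8, 1.5, 1.4, 1.6],
})
means, argmax = dose_response_summary(doses)
print(means.to_string(index=False))
print(f"expression peaks at {argmax[0]} mM")
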