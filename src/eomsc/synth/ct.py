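"""Synthetic qPCR Ct tables with known relative quantities.

Ct values are constructed backwards from planted per-group relative
quantities (RQ): each sample's reference-gene Ct is drawn around a base
cycle number, and the target-gene Ct adds the group's planted
dCt = base_dct - log2(RQ).  At zero replicate noise the ΔΔCt method
recovers the planted RQ exactly (the reference group's planted RQ is 1 by
definition).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = ["CtSimSpec", "gen_ct_table"]


@dataclass
class CtSimSpec:
    """Specification of one synthetic Ct table.

    ``true_rq`` maps group -> {target gene -> planted RQ relative to
    ``ref_group``}; the reference group itself is implicitly at RQ 1 and
    must appear in ``true_rq`` (with RQ 1 or omitted genes defaulting to 1).
    """

    target_genes: list[str] = dc_field(default_factory=lambda: ["Scn5a"])
    ref_gene: str = "Gapdh"
    ref_group: str = "WT"
    true_rq: dict[str, dict[str, float]] = dc_field(default_factory=dict)
    n_replicates: int = 3
    n_technical: int = 2
    noise_sd: float = 0.0
    base_ct_ref: float = 18.0
    base_dct: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ref_gene:
            raise ValueError("a reference gene is required")
        if self.ref_group not in self.true_rq:
            self.true_rq = {self.ref_group: {}, **self.true_rq}
        for group, rqs in self.true_rq.items():
            for gene, rq in rqs.items():
                if rq <= 0:
                    raise ValueError(f"planted RQ must be > 0 ({group}/{gene}: {rq})")
        ref_rqs = self.true_rq[self.ref_group]
        if any(not np.isclose(v, 1.0) for v in ref_rqs.values()):
            raise ValueError("the reference group's planted RQ must be 1")


def gen_ct_table(spec: CtSimSpec) -> pd.DataFrame:
    """Build a tidy Ct table (columns sample, group, gene, ct) from a spec."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group, rqs in spec.true_rq.items():
        for r in range(spec.n_replicates):
            sample = f"{group}_{r + 1}"
            ref_ct = spec.base_ct_ref + rng.normal(0.0, 1.0) * (0.5 if spec.noise_sd else 0.0)
            for gene in [spec.ref_gene, *spec.target_genes]:
                if gene == spec.ref_gene:
                    level = ref_ct
                else:
                    rq = rqs.get(gene, 1.0)
                    level = ref_ct + spec.base_dct - np.log2(rq)
                for _ in range(spec.n_technical):
                    rows.append(
                        {
                            "sample": sample,
                            "group": group,
                            "gene": gene,
                            "ct": level + rng.normal(0.0, spec.noise_sd),
                        }
                    )
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])
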