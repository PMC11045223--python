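"""Negative-binomial count-matrix simulator with planted signature structure.

Samples live on a muscle-origin x genotype x medium x treatment design
(origins HL / Dia / EOM, genotypes WT / G93A, media G / D, treatment none /
NaBu3).  Planted effects are attached to signature roles; each role maps to
the subset of samples in which its genes are shifted:

============== =======================================
role           expressed higher in samples with
============== =======================================
activation     medium == "G"
differentiation medium == "D"
quiescence     origin == "EOM"
eom_up         origin == "EOM"
nabu_up        treatment == "NaBu3"
============== =======================================

Counts are drawn NB(mean = library-scaled baseline x 2^(effect x indicator),
variance = mu + dispersion * mu^2); dispersion 0 degenerates to Poisson.
The truth table lists every planted gene with its role and signed log2
effect, so downstream DEG and signature recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = ["PlantedEffect", "CountsSimSpec", "gen_counts", "default_design", "ROLE_PREDICATES"]

ROLE_PREDICATES = {
    "activation": lambda s: s["medium"] == "G",
    "differentiation": lambda s: s["medium"] == "D",
    "quiescence": lambda s: s["origin"] == "EOM",
    "eom_up": lambda s: s["origin"] == "EOM",
    "nabu_up": lambda s: s["treatment"] == "NaBu3",
}

#: Planted DE genes must clear the downstream calling threshold.
MIN_PLANTED_LOG2FC = 0.4

ORIGINS = ("HL", "Dia", "EOM")
GENOTYPES = ("WT", "G93A")
MEDIA = ("G", "D")
TREATMENTS = ("none", "NaBu3")


@dataclass
class PlantedEffect:
    """One planted signature: a role, member gene indices, log2 effects."""

    role: str
    genes: list[int]
    log2fc: float | list[float] = 1.0

    def __post_init__(self) -> None:
        if self.role not in ROLE_PREDICATES:
            raise ValueError(f"unknown role {self.role!r}; known: {sorted(ROLE_PREDICATES)}")
        effects = np.atleast_1d(np.asarray(self.log2fc, dtype=float))
        if effects.size not in (1, len(self.genes)):
            raise ValueError("log2fc must be scalar or one value per gene")
        if np.any(np.abs(effects) < MIN_PLANTED_LOG2FC):
            raise ValueError(
                f"planted |log2fc| must be >= {MIN_PLANTED_LOG2FC} so planted genes stay "
                "recoverable at the calling threshold"
            )

    def effects(self) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(self.log2fc, dtype=float))
        return np.full(len(self.genes), arr[0]) if arr.size == 1 else arr


@dataclass
class CountsSimSpec:
    """Specification of one simulated count matrix."""

    n_genes: int = 2000
    design: pd.DataFrame | None = None
    planted: list[PlantedEffect] = dc_field(default_factory=list)
    dispersion: float = 0.05
    library_size: float = 2e6
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design is None:
            self.design = default_design()
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        seen: set[int] = set()
        for eff in self.planted:
            overlap = seen & set(eff.genes)
            if overlap:
                raise ValueError(f"planted sets must be disjoint; genes {sorted(overlap)} reused")
            if max(eff.genes, default=-1) >= self.n_genes:
                raise ValueError("planted gene index out of range")
            seen |= set(eff.genes)


def default_design(n_per_group: int = 3) -> pd.DataFrame:
    """Origin x genotype x medium design, untreated, n replicates per cell."""
    rows = []
    for origin in ORIGINS:
        for genotype in GENOTYPES:
            for medium in MEDIA:
                for r in range(n_per_group):
                    rows.append(
                        {
                            "sample": f"{genotype}_{origin}_{medium}_{r + 1}",
                            "origin": origin,
                            "genotype": genotype,
                            "medium": medium,
                            "treatment": "none",
                        }
                    )
    return pd.DataFrame(rows).set_index("sample")


def gen_counts(spec: CountsSimSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate (counts, sample metadata, truth table) from a spec.

    Counts are a genes x samples integer DataFrame (gene symbols ``g0000``…);
    the truth table has one row per planted gene with columns
    ``gene, role, log2fc, affected_when``.
    """
    rng = np.random.default_rng(spec.seed)
    meta = spec.design.copy()
    n_samples = len(meta)
    genes = [f"g{i:04d}" for i in range(spec.n_genes)]

    baseline = 2.0 ** rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, spec.n_genes)
    log2_effect = np.zeros((spec.n_genes, n_samples))
    truth_rows = []
    for eff in spec.planted:
        pred = ROLE_PREDICATES[eff.role]
        affected = np.array([bool(pred(row)) for _, row in meta.iterrows()])
        for g, e in zip(eff.genes, eff.effects()):
            log2_effect[g, affected] = e
            truth_rows.append(
                {
                    "gene": genes[g],
                    "role": eff.role,
                    "log2fc": e,
                    "affected_when": eff.role,
                }
            )

    mu = baseline[:, None] * 2.0 ** log2_effect
    # scale each sample to the requested expected library size
    mu = mu * (spec.library_size / mu.sum(axis=0, keepdims=True))
    if spec.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        n_nb = 1.0 / spec.dispersion
        counts = rng.negative_binomial(n_nb, n_nb / (n_nb + mu))
    counts_df = pd.DataFrame(counts, index=genes, columns=meta.index)
    truth = pd.DataFrame(truth_rows, columns=["gene", "role", "log2fc", "affected_when"])
    return counts_df, meta, truth
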