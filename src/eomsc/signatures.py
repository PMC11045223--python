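"""Homeostasis signature sets and shared-DEG (Venn) analysis.

Satellite-cell homeostasis is profiled with three signature gene sets —
quiescence, activation and differentiation.  The activation and
differentiation sets are derived from growth-medium vs differentiation-medium
contrasts (genes significantly higher in growth medium in both genotypes form
the activation signature; the mirror image forms the differentiation
signature).  The quiescence set is a published list of genes upregulated in
quiescent satellite cells, extended by 18 curated markers bundled here.

The shared-DEG analysis intersects several DEG lists that all compare a
focal group (e.g. EOM-derived satellite cells) against other origins; genes
in the intersection are then profiled by direction and by signature
membership.  Intersection is by gene identity first, direction second:
mixed-direction genes stay in the intersection, unclassified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .deg import DEGTable, call_degs

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureSet",
    "SharedDEGSet",
    "QUIESCENCE_EXTENSION_GENES",
    "QUIESCENCE_SUBGROUPS",
    "derive_activation_signature",
    "derive_differentiation_signature",
    "load_quiescence_signature",
    "shared_degs",
    "signature_direction_profile",
    "eom_signature",
    "export_gene_lists",
    "read_gene_list",
]

#: The 18 curated quiescence markers bundled with the package (added to the
#: published quiescence list when one is supplied).
QUIESCENCE_EXTENSION_GENES = (
    "Notch1", "Notch2", "Hes1", "Hey1", "Rbpj", "Dtx4", "Jag1", "Sox8", "Sdc3",
    "Itga7", "Itgb1", "Met", "Vcam1", "Ncam1", "Cdh2", "Cdh15", "Cxcr4", "Cav1",
)

#: Quiescence-signature subgroups used for profile annotation.
QUIESCENCE_SUBGROUPS = {
    "sc_marker": ("Pax7", "Cd34", "Cxcr4", "Vcam1", "Sdc3", "Sdc4", "Cdh15", "Met", "Cav1"),
    "notch": ("Notch1", "Notch2", "Notch3", "Jag1", "Heyl", "Dtx4", "Msc"),
    "pluripotency": ("Klf4", "Igf1", "Bmp2", "Bmp4", "Fzd4", "Fgfr4", "Pik3r1", "Lifr"),
}


def _normalize(symbols) -> list[str]:
    """Case-insensitive de-duplication preserving first-seen casing and order."""
    seen: dict[str, str] = {}
    for s in symbols:
        key = str(s).strip().lower()
        if key and key not in seen:
            seen[key] = str(s).strip()
    return list(seen.values())


@dataclass
class SignatureSet:
    """A named gene-symbol set with provenance."""

    name: str
    genes: list[str]
    provenance: str = "derived"

    def __post_init__(self) -> None:
        self.genes = _normalize(self.genes)

    def keys(self) -> set[str]:
        return {g.lower() for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return str(symbol).lower() in self.keys()


@dataclass
class SharedDEGSet:
    """Genes shared by every DEG table of a focal-group Venn intersection.

    ``up`` / ``down`` are the direction-consistent subsets (higher / lower in
    the focal group in every contrast); genes with mixed signs remain only in
    ``genes``.
    """

    focal_group: str
    contrasts: list[str]
    genes: list[str]
    up: list[str]
    down: list[str]
    log2fc: pd.DataFrame = field(repr=False)  # genes x contrasts


def _sig_genes(table: DEGTable, sign: int, lfc_min: float, adj_max: float) -> set[str]:
    hits = call_degs(table, lfc_min=lfc_min, adj_max=adj_max)
    if sign > 0:
        hits = hits[hits["log2fc"] > 0]
    else:
        hits = hits[hits["log2fc"] < 0]
    return {g.lower() for g in hits["gene"]}


def _derive_medium_signature(
    deg_wt: DEGTable,
    deg_g93a: DEGTable,
    sign: int,
    name: str,
    lfc_min: float,
    adj_max: float,
) -> SignatureSet:
    if (deg_wt.group_a, deg_wt.group_b) != (deg_g93a.group_a, deg_g93a.group_b):
        raise ValueError(
            f"mismatched contrasts: {deg_wt.contrast!r} vs {deg_g93a.contrast!r}"
        )
    keys = _sig_genes(deg_wt, sign, lfc_min, adj_max) & _sig_genes(deg_g93a, sign, lfc_min, adj_max)
    # restore casing from the WT table
    casing = {g.lower(): g for g in deg_wt.table["gene"]}
    return SignatureSet(name=name, genes=sorted(casing.get(k, k) for k in keys), provenance="derived")


def derive_activation_signature(
    deg_wt: DEGTable,
    deg_g93a: DEGTable,
    lfc_min: float = 0.4,
    adj_max: float = 0.001,
) -> SignatureSet:
    """Genes significantly higher in growth medium in both genotypes.

    Both inputs must contrast growth vs differentiation medium (growth as
    group A) within one genotype; the activation signature is the
    intersection of their up-in-growth DEG calls at the stated thresholds.
    """
    return _derive_medium_signature(deg_wt, deg_g93a, +1, "activation", lfc_min, adj_max)


def derive_differentiation_signature(
    deg_wt: DEGTable,
    deg_g93a: DEGTable,
    lfc_min: float = 0.4,
    adj_max: float = 0.001,
) -> SignatureSet:
    """Mirror of the activation derivation: higher in differentiation medium."""
    return _derive_medium_signature(deg_wt, deg_g93a, -1, "differentiation", lfc_min, adj_max)


def load_quiescence_signature(curated_path: str | Path | None = None) -> SignatureSet:
    """Quiescence signature: optional published list plus 18 built-in markers.

    ``curated_path`` points to a user-supplied one-symbol-per-line file (the
    published list of genes upregulated in quiescent vs activated satellite
    cells); it is never bundled.  Without it only the 18 built-in markers are
    returned, with a warning.
    """
    genes = list(QUIESCENCE_EXTENSION_GENES)
    provenance = "built-in"
    if curated_path is None:
        logger.warning(
            "no curated quiescence list supplied; using the %d built-in markers only",
            len(QUIESCENCE_EXTENSION_GENES),
        )
    else:
        curated = read_gene_list(curated_path)
        before = len(curated) + len(genes)
        genes = curated + genes
        provenance = f"curated file + built-in ({curated_path})"
        dedup = len(_normalize(genes))
        if dedup < before:
            logger.info("quiescence union dropped %d duplicate symbols", before - dedup)
    return SignatureSet(name="quiescence", genes=genes, provenance=provenance)


def shared_degs(
    tables: list[DEGTable],
    focal_group: str,
    lfc_min: float = 0.4,
    adj_max: float = 0.001,
) -> SharedDEGSet:
    """Intersect >= 2 DEG lists that all compare ``focal_group`` to others.

    Every table must carry the focal group as group A.  A gene enters the
    shared set when it passes the thresholds in every table; it is
    "up-in-focal" when its log2fc is positive in every table, "down-in-focal"
    when negative in every table, otherwise unclassified.
    """
    if len(tables) < 2:
        raise ValueError("shared_degs needs at least two DEG tables")
    for t in tables:
        if t.group_a != focal_group:
            raise ValueError(
                f"table {t.contrast!r} does not have focal group {focal_group!r} as group A"
            )
    per_table = []
    for t in tables:
        hits = call_degs(t, lfc_min=lfc_min, adj_max=adj_max)
        per_table.append({g.lower(): lfc for g, lfc in zip(hits["gene"], hits["log2fc"])})
    shared_keys = set(per_table[0])
    for d in per_table[1:]:
        shared_keys &= set(d)
    casing = {g.lower(): g for t in tables for g in t.table["gene"]}
    genes = sorted(casing[k] for k in shared_keys)
    lfc = pd.DataFrame(
        {t.contrast: [d[g.lower()] for g in genes] for t, d in zip(tables, per_table)},
        index=genes,
    )
    up = [g for g in genes if all(d[g.lower()] > 0 for d in per_table)]
    down = [g for g in genes if all(d[g.lower()] < 0 for d in per_table)]
    return SharedDEGSet(
        focal_group=focal_group,
        contrasts=[t.contrast for t in tables],
        genes=genes,
        up=up,
        down=down,
        log2fc=lfc,
    )


def signature_direction_profile(
    shared: SharedDEGSet,
    signatures: list[SignatureSet],
    reference_contrast: str | None = None,
) -> pd.DataFrame:
    """Partition each signature's shared genes by direction, with log2FC.

    Returns a tidy frame (``gene, signature, subgroup, log2fc, direction``);
    log2fc comes from ``reference_contrast`` (default: the first contrast of
    the shared set).  Quiescence subgroup tags (SC markers / Notch /
    pluripotency) are applied from the built-in lists; other genes get "".
    Mixed-direction genes are reported with direction "mixed".
    """
    ref = reference_contrast or shared.contrasts[0]
    if ref not in shared.log2fc.columns:
        raise ValueError(f"unknown reference contrast {ref!r}; have {shared.contrasts}")
    subgroup_of = {
        g.lower(): tag for tag, genes in QUIESCENCE_SUBGROUPS.items() for g in genes
    }
    up = {g.lower() for g in shared.up}
    down = {g.lower() for g in shared.down}
    rows = []
    for sig in signatures:
        keys = sig.keys()
        for gene in shared.genes:
            k = gene.lower()
            if k not in keys:
                continue
            direction = "up" if k in up else "down" if k in down else "mixed"
            rows.append(
                {
                    "gene": gene,
                    "signature": sig.name,
                    "subgroup": subgroup_of.get(k, ""),
                    "log2fc": shared.log2fc.loc[gene, ref],
                    "direction": direction,
                }
            )
    return pd.DataFrame(rows, columns=["gene", "signature", "subgroup", "log2fc", "direction"])


def eom_signature(up_growth, up_diff, name: str = "eom") -> SignatureSet:
    """Genes higher in the focal origin under both media: set intersection.

    Inputs are gene collections (e.g. the ``up`` lists of two shared-DEG
    runs, one per culture medium).
    """
    a = _normalize(up_growth)
    b_keys = {g.lower() for g in _normalize(up_diff)}
    return SignatureSet(
        name=name, genes=sorted(g for g in a if g.lower() in b_keys), provenance="derived"
    )


def export_gene_lists(sets: list[SignatureSet], directory: str | Path) -> list[Path]:
    """Write each set as a one-symbol-per-line UTF-8 file (sorted, stable)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in sets:
        p = directory / f"{s.name}.txt"
        p.write_text("".join(f"{g}\n" for g in sorted(s.genes)), encoding="utf-8")
        paths.append(p)
    return paths


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list (blank lines ignored)."""
    text = Path(path).read_text(encoding="utf-8")
    return _normalize(line for line in text.splitlines() if line.strip())
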