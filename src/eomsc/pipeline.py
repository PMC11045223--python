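"""End-to-end orchestration: simulate -> quantify -> deg -> signatures -> qpcr -> stats.

``run_pipeline`` executes the requested stages in order on synthetic inputs
(or, for the quantification stages, on stacks already on disk), writes every
output table as CSV under the configured output directory, and finishes with
a manifest JSON recording the package version, the seed, every parameter and
threshold used, and a SHA-256 hash of every file written — so a rerun with
the same config and seed is byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, culture, deg, nmj, qpcr, signatures, stats
from .synth import (
    CountsSimSpec,
    CtSimSpec,
    CultureSceneSpec,
    NMJSceneSpec,
    PlantedEffect,
    gen_counts,
    gen_ct_table,
    gen_culture_image,
    gen_nmj_stack,
    write_scene,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_config", "DEFAULT_CONFIG"]

STAGES = ("simulate", "quantify", "deg", "signatures", "qpcr", "stats")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "eomsc_out",
    "stages": list(STAGES),
    "simulate": {
        "n_scenes": 2,
        "scene": {"n_nmjs": 3, "noise_sd": 0.0},
        "culture": {
            "n_myotubes": 3,
            "patch_specs": [[30.0, True, True], [30.0, False, True], [8.0, True, True]],
        },
        "counts": {"n_genes": 600, "n_planted_per_role": 25, "dispersion": 0.05},
        "ct": {"true_rq": {"WT": {}, "G93A": {"Scn5a": 8.0}}},
    },
    "quantify": {
        "disc_diameter_um": 75.0,
        "min_nmj_area_um2": 20.0,
        "min_patch_area_um2": 10.0,
    },
    "deg": {"lfc_min": 0.4, "adj_max": 0.05},
    "signatures": {"lfc_min": 0.4, "adj_max": 0.05},
    "qpcr": {"target": "Scn5a", "ref_gene": "Gapdh", "ref_group": "WT"},
    "stats": {"n_top_genes": 500},
}


def load_config(path: str | Path) -> dict:
    """Read a YAML config, filling unset keys from the defaults."""
    user = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _planted_effects(n_genes: int, per_role: int) -> list[PlantedEffect]:
    roles = ["activation", "differentiation", "eom_up", "nabu_up"]
    effects, start = [], 0
    for role in roles:
        sign = 1.0
        effects.append(PlantedEffect(role=role, genes=list(range(start, start + per_role)), log2fc=sign))
        start += per_role
    if start > n_genes:
        raise ValueError("not enough genes for the requested planted sets")
    return effects


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the configured stages and return the manifest dict."""
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in config.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value

    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = list(cfg["stages"])
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")

    outputs: dict[str, list[str]] = {}
    state: dict = {}

    def register(stage: str, path: Path) -> None:
        outputs.setdefault(stage, []).append(str(path))

    for stage in STAGES:
        if stage not in stages:
            continue
        if stage == "simulate":
            sim = cfg["simulate"]
            state["scenes"] = []
            for i in range(int(sim["n_scenes"])):
                spec = NMJSceneSpec(seed=seed + i, **sim["scene"])
                stack, truth = gen_nmj_stack(spec)
                stem = outdir / f"scene_{i:02d}"
                write_scene(stack, truth, stem)
                register(stage, stem.with_suffix(".tif"))
                register(stage, stem.with_suffix(".truth.json"))
                state["scenes"].append((stack, truth))
            cspec = CultureSceneSpec(seed=seed + 101, **sim["culture"])
            state["culture_scene"] = gen_culture_image(cspec)
            counts_cfg = dict(sim["counts"])
            per_role = int(counts_cfg.pop("n_planted_per_role"))
            spec = CountsSimSpec(
                seed=seed + 202,
                planted=_planted_effects(int(counts_cfg.get("n_genes", 600)), per_role),
                **counts_cfg,
            )
            counts_df, meta, truth_tbl = gen_counts(spec)
            deg.write_counts_tsv(counts_df, outdir / "counts.tsv")
            meta.to_csv(outdir / "samples.csv")
            truth_tbl.to_csv(outdir / "planted_truth.csv", index=False)
            for name in ("counts.tsv", "samples.csv", "planted_truth.csv"):
                register(stage, outdir / name)
            state["counts"] = (counts_df, meta, truth_tbl)
            ct_tbl = gen_ct_table(CtSimSpec(seed=seed + 303, **sim["ct"]))
            ct_tbl.to_csv(outdir / "ct.csv", index=False)
            register(stage, outdir / "ct.csv")
            state["ct"] = ct_tbl
        elif stage == "quantify":
            if "scenes" not in state:
                raise RuntimeError("quantify requested but no simulated scenes; run simulate first")
            q = cfg["quantify"]
            logger.info("quantify thresholds: %s", q)
            records = []
            for i, (stack, _) in enumerate(state["scenes"]):
                records += nmj.quantify_nmj_stack(
                    stack,
                    min_area_um2=q["min_nmj_area_um2"],
                    disc_diameter_um=q["disc_diameter_um"],
                    group=f"scene_{i:02d}",
                )
            frame = nmj.records_to_frame(records)
            frame.to_csv(outdir / "nmj_records.csv", index=False)
            register(stage, outdir / "nmj_records.csv")
            _, cond = nmj.summarize_innervation(records)
            cond.to_csv(outdir / "innervation_summary.csv", index=False)
            register(stage, outdir / "innervation_summary.csv")
            cstack, _ = state["culture_scene"]
            _, ratios = culture.classify_nuclei(cstack, mhc_channel="MHC")
            fi = culture.fusion_index(cstack)
            field = culture.build_coculture_field(cstack)
            try:
                ir = culture.innervation_ratio(field, q["min_patch_area_um2"])
            except ValueError:
                ir = float("nan")
            pd.DataFrame(
                [{**ratios, "fusion_index": fi, "innervation_ratio": ir}]
            ).to_csv(outdir / "culture_metrics.csv", index=False)
            register(stage, outdir / "culture_metrics.csv")
        elif stage == "deg":
            if "counts" not in state:
                raise RuntimeError("deg requested but no counts; run simulate first")
            counts_df, meta, _ = state["counts"]
            d = cfg["deg"]
            meta = meta.copy()
            meta["group"] = meta["origin"] + "_" + meta["medium"]
            tables = {}
            for contrast in (("EOM_G", "HL_G"), ("EOM_G", "Dia_G"), ("EOM_D", "HL_D"), ("EOM_D", "Dia_D")):
                t = deg.nb_wald_test(counts_df, meta, contrast)
                t.to_csv(outdir / f"deg_{contrast[0]}_vs_{contrast[1]}.csv")
                register(stage, outdir / f"deg_{contrast[0]}_vs_{contrast[1]}.csv")
                tables[contrast] = t
            state["deg_tables"] = tables
            logger.info("deg thresholds: |log2FC| >= %s, adj <= %s", d["lfc_min"], d["adj_max"])
        elif stage == "signatures":
            if "deg_tables" not in state:
                raise RuntimeError("signatures requested but no DEG tables; run deg first")
            s = cfg["signatures"]
            tables = state["deg_tables"]
            growth = [tables[("EOM_G", "HL_G")], tables[("EOM_G", "Dia_G")]]
            diffm = [tables[("EOM_D", "HL_D")], tables[("EOM_D", "Dia_D")]]
            shared_g = signatures.shared_degs(growth, "EOM_G", s["lfc_min"], s["adj_max"])
            shared_d = signatures.shared_degs(diffm, "EOM_D", s["lfc_min"], s["adj_max"])
            eom = signatures.eom_signature(shared_g.up, shared_d.up)
            quiescence = signatures.load_quiescence_signature()
            paths = signatures.export_gene_lists([eom, quiescence], outdir / "gene_lists")
            for p in paths:
                register(stage, p)
            profile = signatures.signature_direction_profile(shared_d, [quiescence])
            profile.to_csv(outdir / "quiescence_profile.csv", index=False)
            register(stage, outdir / "quiescence_profile.csv")
            state["eom_signature"] = eom
        elif stage == "qpcr":
            if "ct" not in state:
                raise RuntimeError("qpcr requested but no Ct table; run simulate first")
            qc = cfg["qpcr"]
            rq = qpcr.ddct_rq(state["ct"], qc["target"], qc["ref_gene"], qc["ref_group"])
            rq.to_csv(outdir / "rq.csv", index=False)
            register(stage, outdir / "rq.csv")
        elif stage == "stats":
            if "counts" not in state:
                raise RuntimeError("stats requested but no counts; run simulate first")
            counts_df, meta, _ = state["counts"]
            rng = np.random.default_rng(seed + 404)
            lengths = pd.Series(rng.integers(500, 5000, len(counts_df)), index=counts_df.index)
            tpm = deg.tpm(counts_df, lengths)
            overview = stats.transcriptome_overview(tpm, n_top_genes=cfg["stats"]["n_top_genes"])
            overview.coordinates.to_csv(outdir / "pca.csv")
            register(stage, outdir / "pca.csv")
            pd.Series(overview.dendrogram_order).to_csv(
                outdir / "dendrogram_order.csv", index=False, header=["sample"]
            )
            register(stage, outdir / "dendrogram_order.csv")

    manifest = {
        "package": "eomsc",
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "parameters": {k: cfg[k] for k in cfg if k not in ("outdir",)},
        "outputs": {
            stage: {Path(p).name: _sha256(Path(p)) for p in paths}
            for stage, paths in outputs.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
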