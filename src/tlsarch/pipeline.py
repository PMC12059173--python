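"""Pipeline configuration and end-to-end runner.

A config (YAML/JSON or dict) either points at existing input files or asks
the synthetic generator to produce them, then runs the requested stages in
dependency order (qc -> enrichment / density / scoring; repertoire, spatial
and proximity independent), writing delimited outputs plus a run manifest
(config hash, input checksums, per-stage row counts and timings). All
randomness flows from the config seed; reruns with identical config and
inputs produce identical output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from tlsarch import cooccurrence, density, enrichment, io, proximity, qc
from tlsarch import repertoire as rep
from tlsarch import scoring, synthetic
from tlsarch.gene_sets import bundled_gene_sets

logger = logging.getLogger(__name__)

_SECTION_KEYS = {
    "seed": None,
    "output_dir": None,
    "inputs": {"cell_table", "counts", "airr", "spots", "points"},
    "simulate": {
        "samples_per_status", "cells_per_sample", "clusters", "base_proportions",
        "planted_log2_or", "cluster_lineages", "status_shift", "signature",
        "expression_effect", "n_genes", "sharing_prob", "ambiguous_frac",
        "multichain_frac", "n_spots", "colocalized_pairs", "n_cores",
        "core_status",
    },
    "qc": {"min_genes", "max_genes", "max_pct_mito", "max_umi", "max_doublet",
           "min_cells"},
    "enrichment": {"per_sample", "compartment", "max_neglog10"},
    "density": {"n_grid", "group_field", "normalized"},
    "scoring": {"top_fraction", "gene_sets"},
    "repertoire": {"threshold", "cluster_field"},
    "cooccurrence": {"compositional"},
    "proximity": {"pairs", "pooled"},
    "stages": None,
}

ALL_STAGES = ("qc", "enrichment", "density", "scoring", "repertoire",
              "cooccurrence", "proximity")


def load_config(path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    """Reject unknown keys at the top level and within each section."""
    unknown = set(cfg) - set(_SECTION_KEYS)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for section, allowed in _SECTION_KEYS.items():
        if allowed is None or section not in cfg:
            continue
        extra = set(cfg[section]) - allowed
        if extra:
            raise ValueError(f"unknown key(s) in config section {section!r}: {sorted(extra)}")
    if "output_dir" not in cfg:
        raise ValueError("config must set output_dir")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulate_inputs(cfg: dict, outdir: Path) -> dict:
    """Generate all pipeline inputs from the config seed; returns paths."""
    sim = dict(cfg.get("simulate", {}))
    seed = int(cfg.get("seed", 0))
    indir = outdir / "inputs"
    indir.mkdir(parents=True, exist_ok=True)

    clusters = tuple(sim.get("clusters", ("Tstem", "Tex", "Bgc", "Myeloid")))
    base = tuple(sim.get("base_proportions", (0.25,) * len(clusters)))
    planted = {
        tuple(k.split("|")) if isinstance(k, str) else tuple(k): v
        for k, v in sim.get(
            "planted_log2_or", {("Tstem", "mTLS"): 1.5, ("Tex", "mTLS"): -1.0}
        ).items()
    }
    lineages = sim.get("cluster_lineages", {"Bgc": "B"})
    comp = synthetic.CompositionSpec(
        samples_per_status=sim.get("samples_per_status", 4),
        cells_per_sample=sim.get("cells_per_sample", 2000),
        clusters=clusters, base_proportions=base,
        planted_log2_or=planted, cluster_lineages=lineages,
        seed=synthetic.child_seed(seed, "composition"),
    )
    cells = synthetic.simulate_composition(comp)
    cells = synthetic.simulate_embedding(
        cells, seed=synthetic.child_seed(seed, "embedding"),
        status_shift=sim.get("status_shift", {"mTLS": (1.0, 0.0)}),
    )
    cells["signature_positive"] = cells["tls_status"] == "mTLS"
    io.write_cell_table(cells, indir / "cells.csv")

    sig = bundled_gene_sets()[sim.get("signature", "chemokine_12")]
    matrix = synthetic.simulate_expression(
        cells, sig, effect=sim.get("expression_effect", 3.0),
        seed=synthetic.child_seed(seed, "expression"),
        n_genes=sim.get("n_genes", 500),
    )
    io.write_counts(matrix, indir / "counts")

    rspec = synthetic.RepertoireSpec(
        sharing_prob={
            tuple(k.split("|")) if isinstance(k, str) else tuple(k): v
            for k, v in sim.get("sharing_prob", {("Tstem", "Tex"): 0.3}).items()
        },
        ambiguous_frac=sim.get("ambiguous_frac", 0.02),
        multichain_frac=sim.get("multichain_frac", 0.01),
        seed=synthetic.child_seed(seed, "repertoire"),
    )
    chains, truth = synthetic.simulate_repertoire(cells, rspec)
    io.write_airr(chains, indir / "chains.airr.tsv")
    io.write_table(truth, indir / "chains_truth.csv")

    sspec = synthetic.SpotSpec(
        n_spots=sim.get("n_spots", 300),
        colocalized_pairs={
            tuple(k.split("|")) if isinstance(k, str) else tuple(k): v
            for k, v in sim.get("colocalized_pairs", {("B", "CD4T"): 1.0}).items()
        },
        seed=synthetic.child_seed(seed, "spots"),
    )
    spots, _ = synthetic.simulate_spots(sspec)
    io.write_spots(spots, indir / "spots.csv")

    pspec = synthetic.PointSpec(
        n_cores=sim.get("n_cores", 6),
        core_status=tuple(
            sim.get("core_status", ("nTLS", "nTLS", "imTLS", "imTLS", "mTLS", "mTLS"))
        ),
        seed=synthetic.child_seed(seed, "points"),
    )
    points = synthetic.simulate_points(pspec)
    io.write_points(points, indir / "points.csv")

    io.write_ground_truth(
        {"planted_log2_or": planted, "sharing_prob": rspec.sharing_prob,
         "colocalized_pairs": sspec.colocalized_pairs, "seed": seed},
        indir / "ground_truth.json",
    )
    return {"cell_table": indir / "cells.csv", "counts": indir / "counts",
            "airr": indir / "chains.airr.tsv", "spots": indir / "spots.csv",
            "points": indir / "points.csv"}


def run_pipeline(cfg: dict) -> dict:
    """Execute the configured stages; returns the run manifest."""
    cfg = validate_config(cfg)
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages", list(ALL_STAGES))

    if "inputs" in cfg:
        paths = {k: Path(v) for k, v in cfg["inputs"].items()}
    else:
        paths = _simulate_inputs(cfg, outdir)

    manifest: dict = {
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "input_checksums": {
            k: _sha256(p) for k, p in paths.items() if p.is_file()
        },
        "package_version": __import__("tlsarch").__version__,
        "stages": {},
        "output_checksums": {},
    }

    cells = io.read_cell_table(paths["cell_table"]) if "cell_table" in paths else None
    matrix = io.read_counts(paths["counts"]) if "counts" in paths else None

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            rows = fn()
        except Exception as e:
            raise RuntimeError(f"[stage:{name}] {e}") from e
        manifest["stages"][name] = {
            "rows": rows, "seconds": round(time.perf_counter() - t0, 3)
        }
        logger.info("stage %s: %s rows in %.2fs", name, rows,
                    manifest["stages"][name]["seconds"])

    if "qc" in stages and matrix is not None:
        def _qc():
            nonlocal matrix
            opts = dict(cfg.get("qc", {}))
            min_cells = opts.pop("min_cells", 3)
            doublet = None
            if cells is not None and "doublet_score" in cells.columns:
                doublet = cells.set_index("cell_id")["doublet_score"]
            matrix, qc_table, report = qc.qc_pipeline(
                matrix, doublet_scores=doublet, min_cells=min_cells, **opts
            )
            io.write_table(qc_table.rename_axis("cell_id"), outdir / "qc.csv", index=True)
            (outdir / "qc_report.json").write_text(json.dumps(report.__dict__, indent=1))
            return matrix.n_cells
        _stage("qc", _qc)

    if "enrichment" in stages and cells is not None:
        def _enrich():
            opts = cfg.get("enrichment", {})
            grid = enrichment.enrichment_grid(
                cells, compartment=opts.get("compartment"),
                per_sample=opts.get("per_sample", False),
                max_neglog10=opts.get("max_neglog10", 10.0),
            )
            io.write_table(grid, outdir / "enrichment.csv")
            return len(grid)
        _stage("enrichment", _enrich)

    if "density" in stages and cells is not None:
        def _density():
            opts = cfg.get("density", {})
            out = density.status_density_contrasts(
                cells, n_grid=opts.get("n_grid", 60),
                group_field=opts.get("group_field"),
                normalized=opts.get("normalized", True),
            )
            io.write_table(out, outdir / "density.csv")
            return len(out)
        _stage("density", _density)

    if "scoring" in stages and matrix is not None:
        def _score():
            opts = cfg.get("scoring", {})
            sets = bundled_gene_sets()
            names = opts.get("gene_sets") or list(sets)
            cols = {}
            for name in names:
                try:
                    sv = scoring.aucell_score(
                        matrix, sets[name], top_fraction=opts.get("top_fraction", 0.05)
                    )
                except ValueError:
                    continue  # set absent from the simulated gene universe
                cols[name] = sv.scores
            out = pd.DataFrame(cols).rename_axis("cell_id")
            io.write_table(out, outdir / "scores.csv", index=True)
            return len(out)
        _stage("scoring", _score)

    if "repertoire" in stages and "airr" in paths:
        def _repertoire():
            opts = cfg.get("repertoire", {})
            chains = io.read_airr(paths["airr"])
            classes = rep.classify_cells(chains)
            tcr = rep.define_tcr_clonotypes(chains, classes)
            thr = opts.get("threshold", "auto")
            if thr == "auto":
                thr = rep.estimate_bcr_threshold(chains, classes)
            bcr = rep.define_bcr_clonotypes(chains, float(thr), classes)
            combined = rep.ClonotypeAssignment(
                pd.concat([tcr.cell_to_clonotype, bcr.cell_to_clonotype]), classes
            )
            assign = combined.cell_to_clonotype.rename("clonotype_id").rename_axis("cell_id")
            io.write_table(
                pd.concat([assign, classes.rename_axis("cell_id")], axis=1),
                outdir / "clonotypes.csv", index=True,
            )
            if cells is not None:
                cfield = opts.get("cluster_field", "subcluster")
                div = rep.diversity_by_group(combined, cells, cfield)
                io.write_table(div, outdir / "diversity.csv")
                share = rep.sharing_matrix(combined, cells, cfield)
                io.write_table(share.rename_axis("cluster"), outdir / "sharing.csv",
                               index=True)
            return int(combined.cell_to_clonotype.notna().sum())
        _stage("repertoire", _repertoire)

    if "cooccurrence" in stages and "spots" in paths:
        def _cooccur():
            spots = io.read_spots(paths["spots"])
            M = cooccurrence.cooccurrence_matrix(
                spots, compositional=cfg.get("cooccurrence", {}).get("compositional", False)
            )
            io.write_table(M.rename_axis("cell_type"), outdir / "cooccurrence.csv",
                           index=True)
            io.write_table(cooccurrence.cooccurrence_long(M),
                           outdir / "cooccurrence_long.csv")
            return M.size
        _stage("cooccurrence", _cooccur)

    if "proximity" in stages and "points" in paths:
        def _proximity():
            points = io.read_points(paths["points"])
            opts = cfg.get("proximity", {})
            phenos = sorted(points["phenotype"].unique())
            pairs = opts.get("pairs") or [
                (a, b) for a in phenos for b in phenos if a != b
            ]
            pairs = [tuple(p) for p in pairs]
            summary = proximity.proximity_summary(
                points, pairs, pooled=opts.get("pooled", False)
            )
            io.write_table(summary, outdir / "proximity.csv")
            io.write_table(proximity.status_medians(summary),
                           outdir / "proximity_status_medians.csv")
            return len(summary)
        _stage("proximity", _proximity)

    for f in sorted(outdir.glob("*.csv")) + sorted(outdir.glob("*.json")):
        manifest["output_checksums"][f.name] = _sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
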