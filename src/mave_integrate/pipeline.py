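"""End-to-end orchestration: simulate -> score -> composite -> classify ->
nullmodel -> enrich -> cluster.

A single YAML config (one block per stage) and a single global seed drive
the whole run.  Each stage derives a child seed by stable hashing of the
stage name, so inserting or removing a stage does not perturb the
randomness of the others.  The run emits a manifest listing every output
file with its SHA-256 checksum; a rerun with the same config and seed
reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import (
    abundance_scoring,
    composite_filter,
    integrate_classify,
    io_variants,
    mutational_null,
    synthetic_data,
    tolerance_clustering,
)
from .io_variants import ScoreTable, write_table

log = logging.getLogger("mave_integrate")

BUNDLED_CDS = Path(__file__).parent / "data" / "pten_cds_synthetic.fa"

STAGES = (
    "simulate",
    "score",
    "composite",
    "classify",
    "nullmodel",
    "enrich",
    "cluster",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage child seed (< 2^31) from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def demo_config(outdir: str | Path, seed: int = 1) -> dict:
    """A self-contained synthetic run at desk scale (< 2 min)."""
    return {
        "seed": seed,
        "outdir": str(outdir),
        "log_level": "INFO",
        "simulate": {
            "n_variants": 500,
            "n_replicates": 8,
            "reads_per_bin": 50_000,
            "fluorescence_noise_sd": 0.10,
            "dropout_rate": 0.20,
            "catalog_n_observations": 2000,
            "catalog_fold_enrichments": {
                "wt_like": 1.0,
                "loss_abundance_only": 1.0,
                "loss_activity_only": 1.0,
                "loss_both": 3.0,
            },
        },
        "scoring": {"min_reads_per_variant": 5},
        "filter": {"n_boot": 100, "pass_fraction": 0.95},
        "classify": {},
        "nullmodel": {"cds": str(BUNDLED_CDS)},
        "enrich": {"mode": "per_observation"},
        "cluster": {"min_missense": 17},
    }


def run_pipeline(config: dict) -> dict:
    """Run all stages; returns the manifest (also written as JSON).

    Any stage failure aborts with the stage name and cause.
    """
    outdir = Path(config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    logging.basicConfig(
        level=getattr(logging, str(config.get("log_level", "INFO")).upper(), 20),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    outputs: list[Path] = []
    state: dict = {}
    for stage in STAGES:
        runner = globals()[f"_stage_{stage}"]
        log.info("stage %s (seed %d)", stage, stage_seed(seed, stage))
        try:
            outputs.extend(runner(config, state, outdir, stage_seed(seed, stage)))
        except Exception as e:  # noqa: BLE001 - annotate stage and re-raise
            raise PipelineError(f"stage {stage!r} failed: {e}") from e
    manifest = {
        "seed": seed,
        "outputs": {p.name: _sha256(p) for p in sorted(set(outputs))},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _sim_config(config: dict) -> synthetic_data.SortSimConfig:
    block = dict(config.get("simulate", {}))
    block.pop("catalog_n_observations", None)
    block.pop("catalog_fold_enrichments", None)
    block.pop("cds", None)
    return synthetic_data.SortSimConfig(**block)


def _stage_simulate(config, state, outdir: Path, seed: int) -> list[Path]:
    block = config.get("simulate", {})
    sim = _sim_config(config)
    cds_path = block.get("cds", str(BUNDLED_CDS))
    cds = io_variants.read_cds_fasta(cds_path)
    library = synthetic_data.generate_library(sim, seed=seed, cds=cds)
    out = []
    counts = []
    for r in range(sim.n_replicates):
        bct = synthetic_data.simulate_sort_replicate(library, sim, r, seed=seed)
        p = outdir / f"counts_{bct.replicate}.tsv"
        bct.to_tsv(p)
        out.append(p)
        counts.append(bct)
    truth_p = outdir / "truth.tsv"
    write_table(library.truth, truth_p)
    activity = synthetic_data.generate_activity_scores(
        library, seed=seed, noise_sd_log10=sim.activity_noise_sd_log10
    )
    act_p = outdir / "activity.tsv"
    io_variants.write_score_table(activity, act_p)

    spectrum = mutational_null.null_spectrum(cds)
    class_map = dict(zip(library.truth["variant"], library.truth["true_class"]))
    truth_like = {
        t: class_map[t] for t in spectrum.df["variant"] if t in class_map
    }
    folds = block.get(
        "catalog_fold_enrichments",
        {c: 1.0 for c in mutational_null.CLASSES} | {"loss_both": 3.0},
    )
    catalog = synthetic_data.generate_cancer_catalog(
        spectrum,
        truth_like,
        folds,
        int(block.get("catalog_n_observations", 2000)),
        seed=seed,
        category="simulated_cancer",
    )
    cat_p = outdir / "catalog.tsv"
    io_variants.write_cancer_catalog(catalog, cat_p)
    state.update(
        library=library, counts=counts, cds=cds, spectrum=spectrum, catalog=catalog
    )
    return out + [truth_p, act_p, cat_p]


def _stage_score(config, state, outdir: Path, seed: int) -> list[Path]:
    cfg = abundance_scoring.ScoringConfig(**config.get("scoring", {}))
    if "counts" not in state:
        raise PipelineError("missing input: bin count tables (run simulate)")
    scores = abundance_scoring.score_replicates(state["counts"], cfg)
    p = outdir / "scores.tsv"
    io_variants.write_score_table(scores, p)
    state["scores"] = scores
    return [p]


def _stage_composite(config, state, outdir: Path, seed: int) -> list[Path]:
    block = dict(config.get("filter", {}))
    block.setdefault("seed", seed)
    fcfg = composite_filter.FilterConfig(**block)
    selection = composite_filter.select_replicate_filter(state["scores"], fcfg)
    composite = composite_filter.aggregate_composite(
        state["scores"], selection.k_star
    )
    composite = composite_filter.classify_abundance_confidence(composite)
    rep_p = outdir / "filter_report.tsv"
    write_table(selection.report(), rep_p)
    comp_p = outdir / "composite.tsv"
    write_table(composite.reset_index(), comp_p)
    log.info("selected replicate filter k* = %d", selection.k_star)
    state["composite"] = composite
    state["k_star"] = selection.k_star
    return [rep_p, comp_p]


def _stage_classify(config, state, outdir: Path, seed: int) -> list[Path]:
    act_path = config.get("classify", {}).get("activity")
    if act_path:
        activity = io_variants.read_score_table(act_path)
    elif (outdir / "activity.tsv").exists():
        activity = io_variants.read_score_table(outdir / "activity.tsv")
    else:
        raise PipelineError("missing input: activity score table")
    classes = integrate_classify.classify_variants(state["composite"], activity)
    p = outdir / "classes.tsv"
    write_table(classes.reset_index(), p)
    state["classes"] = classes
    return [p]


def _stage_nullmodel(config, state, outdir: Path, seed: int) -> list[Path]:
    cds = state.get("cds")
    if cds is None:
        cds = io_variants.read_cds_fasta(
            config.get("nullmodel", {}).get("cds", str(BUNDLED_CDS))
        )
    classes = state["classes"]
    classified = classes[classes["joint_class"] != "unclassified"]
    class_map = dict(zip(classified.index, classified["joint_class"]))
    spectrum = mutational_null.null_spectrum(
        cds, class_map=class_map, min_class_coverage=0.0
    )
    events = mutational_null.enumerate_snvs(cds)
    ev_p = outdir / "snv_events.tsv"
    write_table(
        pd.DataFrame(
            {
                "nt_position": [e.nt_position for e in events],
                "ref_nt": [e.ref_nt for e in events],
                "alt_nt": [e.alt_nt for e in events],
                "codon_index": [e.codon_index for e in events],
                "ref_codon": [e.ref_codon for e in events],
                "alt_codon": [e.alt_codon for e in events],
                "protein_variant": [str(e.protein_variant) for e in events],
                "consequence": [e.consequence for e in events],
            }
        ),
        ev_p,
    )
    spec_p = outdir / "null_spectrum.tsv"
    write_table(spectrum.df, spec_p)
    frac_p = outdir / "class_fractions.tsv"
    write_table(
        spectrum.expected_class_fractions().rename("expected_fraction").reset_index(),
        frac_p,
    )
    state["null_spectrum_classified"] = spectrum
    state["class_map"] = class_map
    return [ev_p, spec_p, frac_p]


def _stage_enrich(config, state, outdir: Path, seed: int) -> list[Path]:
    cat_path = config.get("enrich", {}).get("catalog")
    catalog = (
        io_variants.read_cancer_catalog(cat_path) if cat_path else state.get("catalog")
    )
    if catalog is None:
        raise PipelineError("missing input: variant catalog")
    mode = config.get("enrich", {}).get("mode", "per_observation")
    baseline = state["null_spectrum_classified"].expected_class_fractions()
    enr = integrate_classify.category_enrichment(
        catalog, state["class_map"], baseline, mode=mode
    )
    p = outdir / "enrichment.tsv"
    write_table(enr, p)
    dn = integrate_classify.split_dominant_negative_candidates(
        state["classes"], catalog
    )
    dn_p = outdir / "dominant_negative_split.json"
    dn_p.write_text(json.dumps(dn, indent=2) + "\n")
    return [p, dn_p]


def _stage_cluster(config, state, outdir: Path, seed: int) -> list[Path]:
    block = config.get("cluster", {})
    min_missense = int(block.get("min_missense", 17))
    profiles = tolerance_clustering.tolerance_profiles(state["composite"])
    keep = tolerance_clustering.select_high_coverage_positions(
        profiles, min_missense=min_missense
    )
    prof_p = outdir / "profiles.tsv"
    write_table(profiles.reset_index(), prof_p)
    groups = tolerance_clustering.tolerance_groups(
        profiles, min_scored=min_missense
    )
    grp_p = outdir / "groups.tsv"
    write_table(groups, grp_p)
    out = [prof_p, grp_p]
    if len(keep) >= 2:
        result = tolerance_clustering.cluster_positions(
            profiles.loc[keep], linkage_method=block.get("linkage", "average")
        )
        nwk_p = outdir / "dendrogram.nwk"
        nwk_p.write_text(result.newick + "\n")
        out.append(nwk_p)
    else:
        log.warning("fewer than 2 high-coverage positions; clustering skipped")
    return out
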