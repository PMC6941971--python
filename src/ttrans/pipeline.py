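"""End-to-end orchestration: signatures -> match scores -> target enrichment.

A run is driven by a plain key/value config (YAML).  In ``synthetic`` mode the
cohorts, compendium and link table are generated with planted ground truth;
in ``files`` mode they are read from the paths the config names.  All
intermediate artifacts are written as deterministic TSVs together with a
manifest (config, seed, software version, output checksums): re-running from
the same config and seed reproduces every output byte for byte.

The single global seed fans out to per-stage seeds through a declared scheme
(BLAKE2 hash of "<seed>:<stage>", reduced mod 2^31), so each stage is also
independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .compendium import filter_cell_lines, z_transform
from .datamodel import (
    EnrichmentTable,
    MatchScoreTable,
    PerturbationCompendium,
    SignatureSet,
    TargetLinkTable,
    ValidationError,
)
from .enrichment import (
    DEFAULT_MIN_GROUP_SIZE,
    DEFAULT_Q_THRESHOLD,
    DEFAULT_SCORE_THRESHOLD,
    enrich_all,
    mst_of_targets,
)
from .io import write_signatures, write_tables
from .matching import fit_calibration, score_all
from .signatures import (
    ConsistencyReport,
    signature_consistency,
    signatures_from_cohort,
)
from .synthetic import simulate_cohorts, simulate_compendium

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "mode": "synthetic",
    "seed": 0,
    "k": 2,
    "n_cohorts": 3,
    "n_patients": 200,
    "p_disease": 16,
    "p_genes": 978,
    "n_drugs": 300,
    "n_cell_lines": 3,
    "n_targets": 20,
    "drugs_per_target": 10,
    "effect_size": 5.0,
    "noise_sd": 1.0,
    "coverage": 1.0,
    "consistency_threshold": 0.4,
    "min_drugs_per_line": 3,
    "stitch_threshold": DEFAULT_SCORE_THRESHOLD,
    "min_drugs_per_target": DEFAULT_MIN_GROUP_SIZE,
    "q_threshold": DEFAULT_Q_THRESHOLD,
    "fdr": "bh",
    "directions": "both",
}


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed: BLAKE2b("<seed>:<stage>") mod 2^31."""
    digest = hashlib.blake2b(f"{seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)


@dataclass
class PipelineResult:
    signatures: list[SignatureSet]
    consistency: ConsistencyReport
    scores: MatchScoreTable
    enrichment: EnrichmentTable
    mst: pd.DataFrame | None
    manifest: dict
    out_dir: Path | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(cohorts, comp: PerturbationCompendium,
                    links: TargetLinkTable) -> list[str]:
    """Pre-compute structural checks; returns a list of issues (report mode)."""
    issues: list[str] = []
    gene_sets = {tuple(c.gene_ids) for c in cohorts}
    if len(gene_sets) > 1:
        issues.append("cohorts disagree on landmark gene ids")
    for c in cohorts:
        try:
            c.validate()
        except ValidationError as exc:
            issues.append(f"cohort {c.cohort_id}: {exc}")
    try:
        comp.validate()
    except ValidationError as exc:
        issues.append(f"compendium: {exc}")
    try:
        links.validate()
    except ValidationError as exc:
        issues.append(f"link table: {exc}")
    if cohorts:
        overlap = len(set(cohorts[0].gene_ids) & set(comp.gene_ids))
        frac = overlap / max(len(comp.gene_ids), 1)
        if frac < 0.5:
            issues.append(
                f"cohort/compendium gene overlap only {overlap} genes "
                f"({frac:.0%})"
            )
    linked = {str(c) for c in links.records["chemical"]} & set(comp.drugs)
    if not linked:
        issues.append("no compendium drug appears in the link table")
    return issues


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    return cfg


def run_pipeline(config: dict, out_dir: str | Path | None = None
                 ) -> PipelineResult:
    """Run the full pipeline as configured; write artifacts when out_dir set."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    seed = int(cfg["seed"])

    if cfg["mode"] == "synthetic":
        cohorts, truth = simulate_cohorts(
            n_cohorts=int(cfg["n_cohorts"]), n_patients=int(cfg["n_patients"]),
            p_disease=int(cfg["p_disease"]), p_genes=int(cfg["p_genes"]),
            k=int(cfg["k"]), noise_sd=float(cfg["noise_sd"]),
            seed=stage_seed(seed, "cohorts"),
        )
        comp_raw, links, _ = simulate_compendium(
            n_drugs=int(cfg["n_drugs"]), n_cell_lines=int(cfg["n_cell_lines"]),
            n_targets=int(cfg["n_targets"]),
            drugs_per_target=int(cfg["drugs_per_target"]),
            effect_size=float(cfg["effect_size"]),
            noise_sd=float(cfg["noise_sd"]), B_true=truth.B_true,
            coverage=float(cfg["coverage"]),
            seed=stage_seed(seed, "compendium"),
            p_genes=int(cfg["p_genes"]),
        )
    elif cfg["mode"] == "files":
        from .io import read_cohort, read_matrix, read_target_links

        for field in ("cohorts", "compendium", "links", "landmark_genes"):
            if field not in cfg:
                raise ValidationError(f"config missing required field {field!r}")
        landmark = [
            line.strip()
            for line in Path(cfg["landmark_genes"]).read_text().splitlines()
            if line.strip()
        ]
        cohorts = [
            read_cohort(entry["factors"], entry["expression"], landmark,
                        cohort_id=entry.get("id"))
            for entry in cfg["cohorts"]
        ]
        from .compendium import from_pooled

        profiles = {
            name: read_matrix(path)
            for name, path in dict(cfg["compendium"]).items()
        }
        comp_raw = from_pooled(profiles, zscored=False)
        links = read_target_links(cfg["links"])
    else:
        raise ValidationError(f"unknown mode {cfg['mode']!r}")

    issues = validate_inputs(cohorts, comp_raw, links)
    for issue in issues:
        logger.warning("validate_inputs: %s", issue)

    comp = filter_cell_lines(comp_raw,
                             min_drugs=int(cfg["min_drugs_per_line"]))
    comp = z_transform(comp)

    sets: list[SignatureSet] = []
    for cohort in cohorts:
        _, sig = signatures_from_cohort(cohort, k=int(cfg["k"]))
        sets.append(sig)
    consistency = signature_consistency(
        sets, threshold=float(cfg["consistency_threshold"])
    )
    passing = consistency.passing_features()
    if not passing:
        raise ValidationError("stage signatures: no feature passed consistency")

    calib = fit_calibration(comp, links,
                            link_threshold=int(cfg["stitch_threshold"]))
    directions = {"both": ("-", "+"), "suppress": ("-",),
                  "enhance": ("+",)}[str(cfg["directions"])]
    scores = score_all(comp, sets, calib, features=passing,
                       directions=directions, flips=consistency.flips,
                       allowed_features=passing)
    enr = enrich_all(scores, links, alpha_q=float(cfg["q_threshold"]),
                     score_threshold=int(cfg["stitch_threshold"]),
                     min_group_size=int(cfg["min_drugs_per_target"]),
                     fdr_method=str(cfg["fdr"]))

    significant = enr.table.loc[enr.table["significant"], "target"]
    mst = None
    sig_targets = sorted(set(significant))
    if len(sig_targets) >= 2 and "protein_links" in cfg:
        from .io import read_protein_links

        mst = mst_of_targets(sig_targets, read_protein_links(cfg["protein_links"]))

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": {k: cfg[k] for k in sorted(cfg)},
        "stage_seeds": {s: stage_seed(seed, s) for s in ("cohorts", "compendium")},
        "validation_issues": issues,
    }

    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        write_signatures(sets, out_path / "signatures.tsv")
        objects: dict[str, object] = {
            "consistency": consistency.table,
            "consistency_pairs": consistency.pairwise,
            "match_scores": scores,
            "enrichment": enr,
            "links": links,
        }
        if mst is not None:
            objects["mst_edges"] = mst
        write_tables(objects, out_path)
        files = sorted(p for p in out_path.iterdir()
                       if p.suffix == ".tsv")
        manifest["outputs"] = {p.name: _sha256(p) for p in files}
        with open(out_path / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return PipelineResult(signatures=sets, consistency=consistency,
                          scores=scores, enrichment=enr, mst=mst,
                          manifest=manifest, out_dir=out_path)
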