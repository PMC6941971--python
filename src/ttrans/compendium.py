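"""Build the z-scored drug-profile compendium from replicate-level data.

Replicate profiles (log2 expression with drug/dose/time/plate/vehicle
metadata) are turned into one fold-change profile per (drug, cell line):
each plate's mean vehicle (DMSO) profile is subtracted from its treated
profiles, then the dose/time replicate groups of a drug are pooled by a
precision-weighted mean.  Per cell line, each gene is finally standardized
to mean 0 / sd 1 across drugs (population sd), and thinly covered cell
lines are dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import PerturbationCompendium, ValidationError

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ["profile_id", "drug", "cell_line", "dose", "time", "plate",
                    "is_vehicle"]


def pool_replicates(profiles: pd.DataFrame, metadata: pd.DataFrame
                    ) -> PerturbationCompendium:
    """Pool replicate profiles into per-(drug, cell line) fold changes.

    ``profiles`` is genes x profile_ids (log2 scale); ``metadata`` has one row
    per profile with columns drug, cell_line, dose, time, plate, is_vehicle.
    Per plate the mean vehicle profile is subtracted.  Per (drug, cell line),
    replicates are grouped by (dose, time); each group contributes its mean
    profile with weight n/s² (s² = mean per-gene sample variance within the
    group); groups with fewer than 3 replicates fall back to weight n
    (unweighted at the replicate level).  Pooling is invariant to replicate
    ordering and plate relabeling.
    """
    meta = metadata.set_index("profile_id") if "profile_id" in metadata.columns \
        else metadata
    missing = [p for p in profiles.columns if p not in meta.index]
    if missing:
        raise ValidationError(f"profiles without metadata: {missing[:5]}")
    meta = meta.loc[list(profiles.columns)]

    # plate-wise vehicle centring
    centred = profiles.astype(float).copy()
    for plate, sub in meta.groupby("plate", sort=True):
        vehicles = sub.index[sub["is_vehicle"].astype(bool)]
        if len(vehicles) == 0:
            raise ValidationError(f"plate {plate!r} has no vehicle profile")
        vehicle_mean = profiles[vehicles].to_numpy(dtype=float).mean(axis=1)
        centred[sub.index] = (
            profiles[sub.index].to_numpy(dtype=float) - vehicle_mean[:, None]
        )

    treated = meta[~meta["is_vehicle"].astype(bool)]
    G: dict[tuple[str, str], np.ndarray] = {}
    counts: dict[tuple[str, str], int] = {}
    drugs, lines = [], []
    for (drug, line), sub in treated.groupby(["drug", "cell_line"], sort=True):
        group_means, group_weights = [], []
        for (_, _), grp in sub.groupby(["dose", "time"], sort=True):
            mat = centred[grp.index].to_numpy(dtype=float)  # genes x reps
            n_rep = mat.shape[1]
            mean = mat.mean(axis=1)
            if n_rep >= 3:
                s2 = float(mat.var(axis=1, ddof=1).mean())
                weight = n_rep / s2 if s2 > 0 else float(n_rep)
            else:
                weight = float(n_rep)
            group_means.append(mean)
            group_weights.append(weight)
        w = np.asarray(group_weights)
        pooled = np.average(np.column_stack(group_means), axis=1, weights=w)
        key = (str(drug), str(line))
        G[key] = pooled
        counts[key] = int(len(sub))
        if str(drug) not in drugs:
            drugs.append(str(drug))
        if str(line) not in lines:
            lines.append(str(line))

    comp = PerturbationCompendium(
        drugs=sorted(drugs),
        cell_lines=sorted(lines),
        gene_ids=[str(g) for g in profiles.index],
        G=G,
        zscored=False,
        replicate_counts=counts,
    )
    return comp


def from_pooled(profiles_by_line: dict[str, pd.DataFrame],
                zscored: bool = False) -> PerturbationCompendium:
    """Wrap externally pooled per-line (genes x drugs) frames unchanged."""
    gene_ids: list[str] | None = None
    G: dict[tuple[str, str], np.ndarray] = {}
    drugs: list[str] = []
    for line, frame in profiles_by_line.items():
        ids = [str(g) for g in frame.index]
        if gene_ids is None:
            gene_ids = ids
        elif ids != gene_ids:
            raise ValidationError(f"cell line {line}: gene ids differ")
        for drug in frame.columns:
            G[(str(drug), str(line))] = frame[drug].to_numpy(dtype=float)
            if str(drug) not in drugs:
                drugs.append(str(drug))
    return PerturbationCompendium(
        drugs=sorted(drugs),
        cell_lines=sorted(profiles_by_line),
        gene_ids=gene_ids or [],
        G=G,
        zscored=zscored,
    )


def z_transform(comp: PerturbationCompendium,
                min_drugs: int = 3) -> PerturbationCompendium:
    """Standardize each gene to mean 0 / sd 1 across drugs within a cell line.

    Population (ddof=0) sd, for bit-reproducibility.  Genes constant within a
    cell line are set to 0 and logged.  Idempotent on already-standardized
    data up to floating error.
    """
    G: dict[tuple[str, str], np.ndarray] = {}
    for line in comp.cell_lines:
        drugs, mat = comp.matrix(line)
        if len(drugs) < min_drugs:
            raise ValidationError(
                f"cell line {line} has {len(drugs)} < {min_drugs} drugs; "
                "cannot standardize"
            )
        mean = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=0)
        flat = sd == 0
        if flat.any():
            logger.warning(
                "z_transform: %d constant genes in cell line %s set to 0",
                int(flat.sum()), line,
            )
        sd_safe = np.where(flat, 1.0, sd)
        zmat = (mat - mean) / sd_safe
        zmat[:, flat] = 0.0
        for i, drug in enumerate(drugs):
            G[(drug, line)] = zmat[i]
    out = PerturbationCompendium(
        drugs=list(comp.drugs),
        cell_lines=list(comp.cell_lines),
        gene_ids=list(comp.gene_ids),
        G=G,
        zscored=True,
        replicate_counts=dict(comp.replicate_counts),
    )
    out.validate(min_drugs=min_drugs)
    return out


def filter_cell_lines(comp: PerturbationCompendium,
                      min_drugs: int = 1000) -> PerturbationCompendium:
    """Drop cell lines carrying fewer than ``min_drugs`` unique drugs."""
    counts = comp.drug_counts()
    kept = [s for s in comp.cell_lines if counts[s] >= min_drugs]
    removed = [s for s in comp.cell_lines if s not in kept]
    if removed:
        logger.info(
            "filter_cell_lines: removed %d cell lines below %d drugs: %s",
            len(removed), min_drugs, removed,
        )
    if not kept:
        raise ValidationError(
            f"all cell lines below min_drugs={min_drugs} (counts {counts})"
        )
    G = {(r, s): g for (r, s), g in comp.G.items() if s in kept}
    drugs = sorted({r for (r, _) in G})
    return PerturbationCompendium(
        drugs=drugs,
        cell_lines=kept,
        gene_ids=list(comp.gene_ids),
        G=G,
        zscored=comp.zscored,
        replicate_counts={k: v for k, v in comp.replicate_counts.items()
                          if k[1] in kept},
    )
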