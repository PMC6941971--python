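"""Core domain types shared by every pipeline stage.

The pipeline revolves around a handful of typed containers: per-cohort
disease/expression matrices, low-rank feature decompositions, landmark-gene
signatures, a z-scored drug-perturbation compendium, chemical->protein link
tables, and the tabular outputs (match scores, target enrichments).  All
containers are thin dataclasses over numpy arrays / pandas frames with a
``validate()`` method enforcing the structural invariants the downstream
algebra relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CohortData",
    "FeatureDecomposition",
    "SignatureSet",
    "PerturbationCompendium",
    "TargetLinkTable",
    "SurvivalTable",
    "MatchScoreTable",
    "EnrichmentTable",
    "ValidationError",
]


class ValidationError(ValueError):
    """An object violates one of its structural invariants."""


@dataclass
class CohortData:
    """One cohort: disease-factor matrix Y and landmark expression matrix Z.

    Y is ``p_disease x n`` (binary aberrations coded 0/1, continuous scores on
    input scale, NaN allowed for missing factor values).  Z is
    ``p_genes x n`` log-scale expression restricted to the landmark gene set,
    row-centred.  Columns of Y and Z refer to the same patients in the same
    order.
    """

    cohort_id: str
    patients: list[str]
    factors: list[str]
    Y: np.ndarray
    gene_ids: list[str]
    Z: np.ndarray

    def validate(self, atol: float = 1e-8) -> None:
        n = len(self.patients)
        if self.Y.shape != (len(self.factors), n):
            raise ValidationError(
                f"cohort {self.cohort_id}: Y shape {self.Y.shape} != "
                f"({len(self.factors)}, {n})"
            )
        if self.Z.shape != (len(self.gene_ids), n):
            raise ValidationError(
                f"cohort {self.cohort_id}: Z shape {self.Z.shape} != "
                f"({len(self.gene_ids)}, {n})"
            )
        if not np.all(np.isfinite(self.Z)):
            raise ValidationError(f"cohort {self.cohort_id}: Z has non-finite entries")
        row_means = self.Z.mean(axis=1)
        if self.Z.shape[1] and np.abs(row_means).max(initial=0.0) > atol:
            raise ValidationError(
                f"cohort {self.cohort_id}: Z rows not centred "
                f"(max |mean| = {np.abs(row_means).max():.3g})"
            )
        for j, fac in enumerate(self.factors):
            row = self.Y[j]
            finite = row[np.isfinite(row)]
            if finite.size and np.ptp(finite) == 0:
                raise ValidationError(
                    f"cohort {self.cohort_id}: factor {fac!r} is constant"
                )


@dataclass
class FeatureDecomposition:
    """Rank-k summary Y ~ H F of a disease-factor matrix."""

    H: np.ndarray  # p_disease x k loadings
    F: np.ndarray  # k x n per-patient latent features
    k: int
    explained_fraction: np.ndarray  # per-feature share of ||Y||^2
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.feature_names:
            self.feature_names = [f"feature_{j + 1}" for j in range(self.k)]

    def validate(self, unit_norm: bool = True, atol: float = 1e-8) -> None:
        if self.H.shape[1] != self.k or self.F.shape[0] != self.k:
            raise ValidationError("H/F inner dimensions disagree with k")
        if self.k > min(self.H.shape[0], self.F.shape[1]):
            raise ValidationError("k exceeds min(p_disease, n)")
        if unit_norm:
            norms = np.linalg.norm(self.F, axis=1)
            if np.abs(norms - 1.0).max(initial=0.0) > atol:
                raise ValidationError("rows of F are not unit L2 norm")


@dataclass
class SignatureSet:
    """Per-cohort landmark-gene signature matrix B (genes x features)."""

    cohort_id: str
    gene_ids: list[str]
    feature_names: list[str]
    B: np.ndarray

    def validate(self) -> None:
        if self.B.shape != (len(self.gene_ids), len(self.feature_names)):
            raise ValidationError(
                f"signatures {self.cohort_id}: B shape {self.B.shape} != "
                f"({len(self.gene_ids)}, {len(self.feature_names)})"
            )
        if not np.all(np.isfinite(self.B)):
            raise ValidationError(f"signatures {self.cohort_id}: non-finite entries")

    def vector(self, feature: str) -> np.ndarray:
        return self.B[:, self.feature_names.index(feature)]


@dataclass
class PerturbationCompendium:
    """Drug x cell-line expression profiles g_{r,s} over the landmark genes.

    ``G[(drug, cell_line)]`` is a length-``p_genes`` profile; coverage may be
    sparse (a drug need not be present in every cell line).  ``zscored`` marks
    whether each gene has been standardized to mean 0 / sd 1 across drugs
    within each cell line.
    """

    drugs: list[str]
    cell_lines: list[str]
    gene_ids: list[str]
    G: dict[tuple[str, str], np.ndarray]
    zscored: bool = False
    replicate_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def profiles_in(self, cell_line: str) -> dict[str, np.ndarray]:
        return {
            r: g for (r, s), g in self.G.items() if s == cell_line
        }

    def cell_lines_of(self, drug: str) -> list[str]:
        return [s for s in self.cell_lines if (drug, s) in self.G]

    def drug_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in self.cell_lines}
        for (_, s) in self.G:
            counts[s] += 1
        return counts

    def matrix(self, cell_line: str) -> tuple[list[str], np.ndarray]:
        """Dense (drugs x genes) matrix of the profiles present in one line."""
        profs = self.profiles_in(cell_line)
        drugs = [r for r in self.drugs if r in profs]
        if not drugs:
            return [], np.empty((0, len(self.gene_ids)))
        return drugs, np.vstack([profs[r] for r in drugs])

    def validate(self, atol: float = 1e-6, min_drugs: int = 3) -> None:
        p = len(self.gene_ids)
        for key, g in self.G.items():
            if g.shape != (p,):
                raise ValidationError(f"profile {key} has length {g.shape}, want {p}")
        if self.zscored:
            for s in self.cell_lines:
                _, mat = self.matrix(s)
                if mat.shape[0] < min_drugs:
                    raise ValidationError(
                        f"cell line {s} carries {mat.shape[0]} < {min_drugs} profiles"
                    )
                mean = mat.mean(axis=0)
                sd = mat.std(axis=0)
                live = sd > atol  # constant genes are zeroed, not standardized
                if np.abs(mean).max(initial=0.0) > atol:
                    raise ValidationError(f"cell line {s}: genes not centred")
                if live.any() and np.abs(sd[live] - 1.0).max() > atol:
                    raise ValidationError(f"cell line {s}: gene sd != 1")


@dataclass
class TargetLinkTable:
    """Chemical -> protein links with integer confidence scores in [0, 1000]."""

    records: pd.DataFrame  # columns: chemical, protein, combined_score

    def __post_init__(self) -> None:
        self._by_protein: dict[str, dict[str, int]] | None = None

    def validate(self) -> None:
        needed = {"chemical", "protein", "combined_score"}
        if not needed.issubset(self.records.columns):
            raise ValidationError(f"link table missing columns {needed}")
        scores = self.records["combined_score"]
        if len(scores) and (scores.min() < 0 or scores.max() > 1000):
            raise ValidationError("combined_score outside [0, 1000]")
        if self.records.duplicated(["chemical", "protein"]).any():
            raise ValidationError("duplicate (chemical, protein) pairs")

    @property
    def by_protein(self) -> dict[str, dict[str, int]]:
        if self._by_protein is None:
            idx: dict[str, dict[str, int]] = {}
            for chem, prot, score in self.records[
                ["chemical", "protein", "combined_score"]
            ].itertuples(index=False):
                idx.setdefault(prot, {})[chem] = int(score)
            self._by_protein = idx
        return self._by_protein

    @property
    def proteins(self) -> list[str]:
        return sorted(self.by_protein)

    def chemicals_above(self, protein: str, min_score: int) -> set[str]:
        """Chemicals linked to ``protein`` with score strictly above ``min_score``."""
        return {
            c for c, sc in self.by_protein.get(protein, {}).items() if sc > min_score
        }


@dataclass
class SurvivalTable:
    """Right-censored survival data: time >= 0, event in {0, 1}."""

    table: pd.DataFrame  # index: patient id; columns: time, event, covariates...

    def validate(self) -> None:
        if not {"time", "event"}.issubset(self.table.columns):
            raise ValidationError("survival table needs 'time' and 'event' columns")
        if (self.table["time"] < 0).any():
            raise ValidationError("negative survival times")
        if not self.table["event"].isin([0, 1]).all():
            raise ValidationError("event indicator must be 0/1")

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("time", "event")]


#: canonical direction labels: "-" scores against -B (suppressors),
#: "+" against +B (enhancers)
DIRECTIONS = ("-", "+")


@dataclass
class MatchScoreTable:
    """One row per (drug, feature, direction): S in [0,1] plus diagnostics."""

    table: pd.DataFrame
    # columns: drug, feature, direction, score, sigma_bar, n_cell_lines

    def validate(self) -> None:
        t = self.table
        needed = {"drug", "feature", "direction", "score", "sigma_bar", "n_cell_lines"}
        if not needed.issubset(t.columns):
            raise ValidationError(f"match score table missing columns {needed}")
        if len(t):
            if t["score"].min() < 0 or t["score"].max() > 1:
                raise ValidationError("match scores outside [0, 1]")
            if not t["direction"].isin(DIRECTIONS).all():
                raise ValidationError("direction labels must be '-' or '+'")

    def scores(self, feature: str, direction: str) -> pd.Series:
        t = self.table
        sub = t[(t["feature"] == feature) & (t["direction"] == direction)]
        return sub.set_index("drug")["score"]


@dataclass
class EnrichmentTable:
    """Per (target, feature, direction): one-sided KS D, p, FDR q, group sizes."""

    table: pd.DataFrame
    # columns: target, feature, direction, D, p, q, n_plus, n_minus, significant

    COLUMNS = ("target", "feature", "direction", "D", "p", "q", "n_plus", "n_minus",
               "significant")

    def validate(self) -> None:
        t = self.table
        if not set(self.COLUMNS).issubset(t.columns):
            raise ValidationError("enrichment table missing columns")
        if len(t):
            for col, lo, hi in (("D", 0, 1), ("p", 0, 1), ("q", 0, 1)):
                if t[col].min() < lo or t[col].max() > hi:
                    raise ValidationError(f"{col} outside [{lo}, {hi}]")


def as_mapping(obj: Mapping | None) -> dict:
    return dict(obj) if obj else {}
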