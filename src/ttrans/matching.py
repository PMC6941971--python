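"""Match drug perturbation profiles against risk signatures.

The match score of a drug r against a k=1 signature B, in direction d in
{-, +}, is

    S(r) = sigma_bar(r) * (1/N_r) * sum_s w_s * prod_i sigma(g_{r,s}, d*B(i))

where the sum runs over the cell lines s carrying the drug, the product runs
over cohorts i, w_s are nonnegative cell-line weights normalized to mean 1
over those lines, and N_r = sum_s w_s.  Direction "-" scores against -B
(drugs predicted to suppress the signature), "+" against +B (enhancers).

sigma is a calibrated, clipped cosine: raw cosine similarity divided by the
expected same-target cosine rho_same (estimated from drug pairs that share a
high-confidence protein link), clipped to [0, 1] — 0 means no match, 1 a
match at the level expected of two drugs with the same target.  sigma_bar is
the drug's cross-cell-line response consistency, the analogously calibrated
mean cosine between the drug's profiles in different cell lines; drugs seen
in a single line get the neutral value 0.5.

Significance is calibrated by permutation: the signature's gene labels are
shuffled (the same shuffle across cohorts, preserving the drug-drug
correlation structure of the compendium) and all drugs rescored.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    DIRECTIONS,
    MatchScoreTable,
    PerturbationCompendium,
    SignatureSet,
    TargetLinkTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: smallest admissible calibration scale; guards against a (near-)zero or
#: negative reference cosine when the calibration set carries no signal
RHO_FLOOR = 0.05
NEUTRAL_CONSISTENCY = 0.5
MIN_SAME_TARGET_PAIRS = 30


def _unit_rows(mat: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValidationError("zero-norm profile encountered")
    return mat / norms


def cosine(g: np.ndarray, h: np.ndarray) -> float:
    ng, nh = np.linalg.norm(g), np.linalg.norm(h)
    if ng == 0 or nh == 0:
        raise ValidationError("zero-norm vector in cosine similarity")
    return float(g @ h / (ng * nh))


@dataclass
class SimilarityCalibration:
    """Reference cosine scales estimated from the compendium itself.

    ``rho_same[s]`` is the mean cosine among profile pairs in cell line s
    whose drugs share a protein link above ``link_threshold`` (the level of
    similarity expected for two drugs with the same target).  Lines with
    fewer than ``min_pairs`` such pairs fall back to the pooled global
    estimate.  ``rho_cons`` is the compendium-wide mean same-drug,
    cross-cell-line cosine used to calibrate sigma_bar.  Both are floored at
    ``RHO_FLOOR``.
    """

    rho_same: dict[str, float]
    rho_cons: float
    n_pairs: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.rho_cons <= 0 or any(v <= 0 for v in self.rho_same.values()):
            raise ValidationError("calibration scales must be positive")


def fit_calibration(comp: PerturbationCompendium, links: TargetLinkTable,
                    link_threshold: int = 900,
                    min_pairs: int = MIN_SAME_TARGET_PAIRS,
                    max_pairs_per_line: int = 20000) -> SimilarityCalibration:
    """Estimate rho_same per cell line and the global rho_cons."""
    same_target_pairs: set[tuple[str, str]] = set()
    drug_set = set(comp.drugs)
    for protein in links.by_protein:
        linked = sorted(links.chemicals_above(protein, link_threshold) & drug_set)
        for a, b in itertools.combinations(linked, 2):
            same_target_pairs.add((a, b))

    per_line: dict[str, float] = {}
    n_pairs: dict[str, int] = {}
    all_cosines: list[float] = []
    for line in comp.cell_lines:
        drugs, mat = comp.matrix(line)
        index = {d: i for i, d in enumerate(drugs)}
        unit = _unit_rows(mat)
        cos = []
        for a, b in itertools.islice(
            (p for p in sorted(same_target_pairs)
             if p[0] in index and p[1] in index),
            max_pairs_per_line,
        ):
            cos.append(float(unit[index[a]] @ unit[index[b]]))
        n_pairs[line] = len(cos)
        all_cosines.extend(cos)
        if len(cos) >= min_pairs:
            per_line[line] = max(float(np.mean(cos)), RHO_FLOOR)

    if all_cosines:
        pooled = max(float(np.mean(all_cosines)), RHO_FLOOR)
    else:
        pooled = RHO_FLOOR
        logger.warning(
            "fit_calibration: no same-target pairs in the compendium; "
            "rho_same floored at %.2f", RHO_FLOOR,
        )
    for line in comp.cell_lines:
        if line not in per_line:
            if n_pairs.get(line, 0) < min_pairs:
                logger.info(
                    "fit_calibration: cell line %s has %d < %d same-target "
                    "pairs; using pooled estimate %.4f",
                    line, n_pairs.get(line, 0), min_pairs, pooled,
                )
            per_line[line] = pooled

    # cross-line consistency scale: mean same-drug cosine across line pairs
    cons: list[float] = []
    for drug in comp.drugs:
        lines = comp.cell_lines_of(drug)
        for sa, sb in itertools.combinations(lines, 2):
            cons.append(cosine(comp.G[(drug, sa)], comp.G[(drug, sb)]))
    rho_cons = max(float(np.mean(cons)), RHO_FLOOR) if cons else RHO_FLOOR
    calib = SimilarityCalibration(rho_same=per_line, rho_cons=rho_cons,
                                  n_pairs=n_pairs)
    calib.validate()
    return calib


def similarity(g: np.ndarray, h: np.ndarray, rho_same: float) -> float:
    """Calibrated clipped cosine: clip(cos(g, h) / rho_same, 0, 1).

    Monotone non-decreasing in g'h; sigma(g, h) = sigma(-g, -h); equals 1
    when g matches h at (or beyond) the same-target reference level, 0 at or
    below orthogonality.
    """
    if rho_same <= 0:
        raise ValidationError("rho_same must be positive")
    return float(np.clip(cosine(g, h) / rho_same, 0.0, 1.0))


def drug_consistency(drug: str, comp: PerturbationCompendium,
                     rho_cons: float) -> tuple[float, bool]:
    """Cross-cell-line response consistency sigma_bar(r) in [0, 1].

    Mean over unordered cell-line pairs of the calibrated clipped cosine
    between the drug's profiles.  Drugs present in fewer than 2 lines get the
    neutral value 0.5 (flagged via the returned bool).
    """
    lines = comp.cell_lines_of(drug)
    if len(lines) < 2:
        return NEUTRAL_CONSISTENCY, True
    vals = [
        float(np.clip(cosine(comp.G[(drug, sa)], comp.G[(drug, sb)]) / rho_cons,
                      0.0, 1.0))
        for sa, sb in itertools.combinations(lines, 2)
    ]
    return float(np.mean(vals)), False


def _signature_matrix(signatures: list[SignatureSet], feature: str,
                      flips: dict[tuple[str, str], bool] | None = None
                      ) -> np.ndarray:
    """Stack one feature's (possibly sign-aligned) vectors: cohorts x genes."""
    rows = []
    for s in signatures:
        v = s.vector(feature)
        if flips and flips.get((s.cohort_id, feature), False):
            v = -v
        rows.append(v)
    return np.vstack(rows)


def _normalize_weights(weights: dict[str, float] | None,
                       lines: list[str]) -> np.ndarray:
    if weights is None:
        return np.ones(len(lines))
    w = np.asarray([float(weights.get(s, 0.0)) for s in lines])
    if (w < 0).any():
        raise ValidationError("cell-line weights must be nonnegative")
    if w.sum() == 0:
        raise ValidationError("all cell-line weights are zero for this drug")
    return w / w.mean()


def match_score(drug: str, comp: PerturbationCompendium,
                signatures: list[SignatureSet], feature: str, direction: str,
                calib: SimilarityCalibration,
                weights: dict[str, float] | None = None,
                flips: dict[tuple[str, str], bool] | None = None,
                sigma_bar: float | None = None) -> float:
    """Match score S(r) for one drug, feature and direction."""
    if direction not in DIRECTIONS:
        raise ValidationError(f"direction must be one of {DIRECTIONS}")
    sign = -1.0 if direction == "-" else 1.0
    B = _signature_matrix(signatures, feature, flips) * sign  # cohorts x genes
    lines = comp.cell_lines_of(drug)
    if not lines:
        raise ValidationError(f"drug {drug!r} absent from compendium")
    if sigma_bar is None:
        sigma_bar, _ = drug_consistency(drug, comp, calib.rho_cons)
    w = _normalize_weights(weights, lines)
    terms = np.empty(len(lines))
    for idx, line in enumerate(lines):
        g = comp.G[(drug, line)]
        prod = 1.0
        for i in range(B.shape[0]):
            prod *= similarity(g, B[i], calib.rho_same[line])
        terms[idx] = prod
    return float(sigma_bar * np.sum(w * terms) / np.sum(w))


def _score_all_matrix(comp: PerturbationCompendium,
                      sig_matrix: np.ndarray,
                      calib: SimilarityCalibration,
                      sigma_bars: np.ndarray,
                      weights: dict[str, float] | None = None
                      ) -> np.ndarray:
    """Vectorized S(r) for every drug against a fixed cohorts x genes block.

    ``sig_matrix`` already carries the direction sign.  Returns one score per
    compendium drug (order of ``comp.drugs``).
    """
    h_unit = _unit_rows(sig_matrix)  # cohorts x genes
    drug_index = {d: i for i, d in enumerate(comp.drugs)}
    num = np.zeros(len(comp.drugs))
    den = np.zeros(len(comp.drugs))
    for line in comp.cell_lines:
        drugs, mat = comp.matrix(line)
        if not drugs:
            continue
        unit = _unit_rows(mat)  # drugs_in_line x genes
        cos = unit @ h_unit.T  # x cohorts
        sig = np.clip(cos / calib.rho_same[line], 0.0, 1.0)
        prod = sig.prod(axis=1)
        w_line = 1.0 if weights is None else float(weights.get(line, 0.0))
        rows = np.fromiter((drug_index[d] for d in drugs), dtype=int,
                           count=len(drugs))
        num[rows] += w_line * prod
        den[rows] += w_line
    covered = den > 0
    scores = np.zeros(len(comp.drugs))
    scores[covered] = sigma_bars[covered] * num[covered] / den[covered]
    return scores


def compute_sigma_bars(comp: PerturbationCompendium,
                       calib: SimilarityCalibration) -> np.ndarray:
    out = np.empty(len(comp.drugs))
    for i, drug in enumerate(comp.drugs):
        out[i], _ = drug_consistency(drug, comp, calib.rho_cons)
    return out


def score_all(comp: PerturbationCompendium, signatures: list[SignatureSet],
              calib: SimilarityCalibration,
              features: list[str] | None = None,
              directions: tuple[str, ...] = DIRECTIONS,
              weights: dict[str, float] | None = None,
              flips: dict[tuple[str, str], bool] | None = None,
              allowed_features: list[str] | None = None,
              force: bool = False) -> MatchScoreTable:
    """Score every (drug, feature, direction) triple.

    ``allowed_features`` (e.g. the consistency-passing set) restricts scoring;
    requesting a feature outside it raises unless ``force``.
    """
    if not comp.zscored:
        logger.warning("score_all: compendium profiles are not z-scored")
    if features is None:
        features = list(signatures[0].feature_names)
    if allowed_features is not None and not force:
        bad = [f for f in features if f not in allowed_features]
        if bad:
            raise ValidationError(
                f"features failed the consistency filter: {bad}; "
                "pass force=True to score them anyway"
            )
    sigma_bars = compute_sigma_bars(comp, calib)
    n_lines = np.asarray([len(comp.cell_lines_of(d)) for d in comp.drugs])
    rows = []
    for feature in features:
        base = _signature_matrix(signatures, feature, flips)
        for direction in directions:
            sign = -1.0 if direction == "-" else 1.0
            scores = _score_all_matrix(comp, base * sign, calib, sigma_bars,
                                       weights)
            for i, drug in enumerate(comp.drugs):
                rows.append((drug, feature, direction, scores[i],
                             sigma_bars[i], int(n_lines[i])))
    table = MatchScoreTable(
        table=pd.DataFrame(
            rows,
            columns=["drug", "feature", "direction", "score", "sigma_bar",
                     "n_cell_lines"],
        )
    )
    table.validate()
    return table


@dataclass
class PermutationNull:
    """Gene-label permutation null for one (feature, direction)."""

    null_scores: np.ndarray  # n_perm x n_drugs
    observed: np.ndarray  # n_drugs
    p_values: pd.Series  # per drug, add-one empirical
    n_perm: int

    def null_ecdf(self) -> tuple[np.ndarray, np.ndarray]:
        flat = np.sort(self.null_scores.ravel())
        return flat, np.arange(1, flat.size + 1) / flat.size


def permutation_null(comp: PerturbationCompendium,
                     signatures: list[SignatureSet], feature: str,
                     direction: str, n_perm: int, seed: int,
                     calib: SimilarityCalibration,
                     weights: dict[str, float] | None = None,
                     flips: dict[tuple[str, str], bool] | None = None,
                     randomized: bool = False) -> PermutationNull:
    """Null distribution of S(r) under gene-label permutation.

    Each iteration draws one fresh permutation of the signature's gene labels
    and applies it identically across cohorts, then rescores every drug.
    Empirical p per drug uses the add-one rule (1 + #{null >= S}) / (1 + n_perm).

    The match score is clipped, so its null distribution has an atom at 0 and
    the deterministic rule is conservative there (ties push p toward 1).
    ``randomized=True`` switches to the tie-randomized p
    ``(#{null > S} + U (1 + #{null = S})) / (1 + n_perm)`` with U ~ U(0,1)
    drawn from the same seeded generator — exactly uniform under the null and
    the right choice when calibrating the permutation control itself.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    sign = -1.0 if direction == "-" else 1.0
    base = _signature_matrix(signatures, feature, flips) * sign
    sigma_bars = compute_sigma_bars(comp, calib)
    observed = _score_all_matrix(comp, base, calib, sigma_bars, weights)
    rng = np.random.default_rng(seed)
    p_genes = base.shape[1]
    null = np.empty((n_perm, len(comp.drugs)))
    for j in range(n_perm):
        perm = rng.permutation(p_genes)
        null[j] = _score_all_matrix(comp, base[:, perm], calib, sigma_bars,
                                    weights)
    if randomized:
        greater = (null > observed[None, :]).sum(axis=0)
        ties = (null == observed[None, :]).sum(axis=0)
        u = rng.uniform(size=len(comp.drugs))
        p = (greater + u * (1.0 + ties)) / (1.0 + n_perm)
    else:
        exceed = (null >= observed[None, :]).sum(axis=0)
        p = (1.0 + exceed) / (1.0 + n_perm)
    return PermutationNull(
        null_scores=null,
        observed=observed,
        p_values=pd.Series(p, index=list(comp.drugs), name="p"),
        n_perm=n_perm,
    )
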