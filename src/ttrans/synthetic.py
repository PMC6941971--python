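"""Synthetic cohorts, compendia, link tables and survival data with planted truth.

The generators emulate the linear-Gaussian structure the estimation stages
assume, so every pipeline stage can be exercised end to end without any
external download:

* cohorts: Y = H F + e_Y and Z = B F + e_Z with a shared H_true / B_true
  across cohorts and independent latent features F and noise per cohort;
* compendium: causal drugs respond along a planted signature
  (g = direction * effect_size * B_true[:, feature] + noise), inert drugs are
  pure noise; the link table wires causal drugs to their causal target at
  score 950 and decoy targets to random inert drugs;
* survival: exponential event times with rate exp(x beta) and independent
  uniform censoring;
* protrusions: per-image Poisson counts of exponentially distributed lengths
  for the morphology stage.

Every generator is a pure function of its arguments and seed; regeneration
with the same seed is bit-identical.  Defaults mirror the study conditions of
the analysis the package implements: 978 landmark genes, 16 disease factors,
noise sd 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    CohortData,
    PerturbationCompendium,
    SurvivalTable,
    TargetLinkTable,
    ValidationError,
)

DEFAULT_P_GENES = 978
DEFAULT_P_DISEASE = 16
CAUSAL_LINK_SCORE = 950


@dataclass
class GroundTruth:
    """Planted parameters recorded alongside every generated dataset."""

    seed: int
    B_true: np.ndarray | None = None
    H_true: np.ndarray | None = None
    F_true: dict[str, np.ndarray] = field(default_factory=dict)
    causal_targets: dict[str, tuple[str, str, float]] = field(default_factory=dict)
    # feature -> (target id, direction, effect size)
    drug_targets: dict[str, str] = field(default_factory=dict)
    causal_drugs: dict[str, list[str]] = field(default_factory=dict)
    # target -> drugs carrying the planted response

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "causal_target", "feature": feat, "target": tgt,
             "direction": direction, "effect_size": eff}
            for feat, (tgt, direction, eff) in self.causal_targets.items()
        ]
        rows += [
            {"kind": "drug_target", "feature": "", "target": tgt,
             "direction": "", "effect_size": np.nan, "drug": drug}
            for drug, tgt in sorted(self.drug_targets.items())
        ]
        return pd.DataFrame(rows)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_cohorts(
    n_cohorts: int = 3,
    n_patients: int = 200,
    p_disease: int = DEFAULT_P_DISEASE,
    p_genes: int = DEFAULT_P_GENES,
    k: int = 2,
    signal_scale: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    heavy_tails: bool = False,
) -> tuple[list[CohortData], GroundTruth]:
    """Simulate cohorts sharing H_true and B_true with independent F and noise.

    The loading matrix H_true is block-structured the way clustered risk data
    look: each latent risk axis loads positively on its own disjoint set of
    clinical factors (one dominant anchor factor per axis, strength 4; the
    supporting factors uniform in [0.8, 2]), and earlier axes are supported
    by more factors.  Disjoint positive blocks make the axes orthogonal and
    their order and sign identifiable from data, so fitted and planted
    features can be compared one-to-one.  Disease factors and expression are
    continuous Gaussian; ``heavy_tails`` swaps the noise for t(df=3) scaled
    to unit variance, for robustness checks.
    """
    if not 1 <= k <= min(p_disease, n_patients):
        raise ValidationError(f"k={k} outside [1, {min(p_disease, n_patients)}]")
    rng = _rng(seed)

    def noise(shape):
        if heavy_tails:
            return rng.standard_t(3, size=shape) / np.sqrt(3.0)
        return rng.standard_normal(shape)

    # block sizes proportional to k, k-1, ..., 1 (each at least 1 factor)
    weights = np.arange(k, 0, -1, dtype=float)
    sizes = np.maximum(1, np.floor(p_disease * weights / weights.sum())).astype(int)
    while sizes.sum() > p_disease:
        sizes[np.argmax(sizes)] -= 1
    sizes[0] += p_disease - sizes.sum()
    H_true = np.zeros((p_disease, k))
    start = 0
    for j, size in enumerate(sizes):
        block = rng.uniform(0.8, 2.0, size=size)
        block[0] = 4.0  # anchor factor dominates its axis
        H_true[start:start + size, j] = block
        start += size
    B_true = signal_scale * rng.standard_normal((p_genes, k))
    gene_ids = [f"g{i + 1}" for i in range(p_genes)]
    factors = [f"factor_{j + 1}" for j in range(p_disease)]

    cohorts: list[CohortData] = []
    truth = GroundTruth(seed=seed, B_true=B_true, H_true=H_true)
    for c in range(n_cohorts):
        cid = f"cohort_{c + 1}"
        # latent features: zero-mean, exactly uncorrelated rows of norm sqrt(n)
        F = rng.standard_normal((k, n_patients))
        F = F - F.mean(axis=1, keepdims=True)
        Q, R = np.linalg.qr(F.T)
        Q = Q * np.sign(np.diag(R))
        F = Q.T * np.sqrt(n_patients)
        Y = H_true @ F + noise_sd * noise((p_disease, n_patients))
        Z = B_true @ F + noise_sd * noise((p_genes, n_patients))
        Z = Z - Z.mean(axis=1, keepdims=True)
        cohort = CohortData(
            cohort_id=cid,
            patients=[f"{cid}_p{i + 1}" for i in range(n_patients)],
            factors=factors,
            Y=Y,
            gene_ids=gene_ids,
            Z=Z,
        )
        cohort.validate()
        cohorts.append(cohort)
        truth.F_true[cid] = F
    return cohorts, truth


def simulate_compendium(
    n_drugs: int = 300,
    n_cell_lines: int = 3,
    n_targets: int = 20,
    drugs_per_target: int = 10,
    effect_size: float = 5.0,
    noise_sd: float = 1.0,
    B_true: np.ndarray | None = None,
    causal: dict[str, tuple[int, str]] | None = None,
    coverage: float = 1.0,
    seed: int = 0,
    p_genes: int = DEFAULT_P_GENES,
) -> tuple[PerturbationCompendium, TargetLinkTable, GroundTruth]:
    """Simulate a drug-perturbation compendium with one or more causal targets.

    ``causal`` maps a ground-truth label (conventionally the feature name,
    but any unique key works when planting several targets on one feature)
    -> (column of B_true, direction "-"/"+"); default plants one suppressor
    target on feature_1.  The drugs of a causal
    target respond as ``direction * effect_size * unit(B_true[:, col]) * sqrt(p)
    + noise`` in every cell line where they are present (profiles are NOT yet
    z-scored; run ``compendium.z_transform`` downstream).  Decoy targets are
    linked to disjoint random sets of inert drugs at the same score, so the
    link table carries no information beyond the planted response.
    ``coverage`` < 1 drops each (drug, cell line) entry i.i.d. Bernoulli to
    exercise the sparse-coverage averaging rule.
    """
    if effect_size < 0:
        raise ValidationError("effect_size must be >= 0; direction encodes sign")
    if drugs_per_target * n_targets > n_drugs:
        raise ValidationError("not enough drugs for the requested targets")
    rng = _rng(seed)
    if B_true is None:
        B_true = rng.standard_normal((p_genes, 2))
    p = B_true.shape[0]
    if causal is None:
        causal = {"feature_1": (0, "-")}

    drugs = [f"drug_{i + 1:04d}" for i in range(n_drugs)]
    lines = [f"line_{s + 1}" for s in range(n_cell_lines)]
    targets = [f"T{j + 1:03d}" for j in range(n_targets)]

    # assign disjoint drug groups to targets; causal targets come first
    perm = rng.permutation(n_drugs)
    truth = GroundTruth(seed=seed, B_true=B_true)
    assignments: dict[str, list[str]] = {}
    cursor = 0
    causal_targets = targets[: len(causal)]
    for (feature, (col, direction)), tgt in zip(causal.items(), causal_targets):
        group = [drugs[i] for i in perm[cursor: cursor + drugs_per_target]]
        cursor += drugs_per_target
        assignments[tgt] = group
        truth.causal_targets[feature] = (tgt, direction, effect_size)
        truth.causal_drugs[tgt] = group
    for tgt in targets[len(causal):]:
        group = [drugs[i] for i in perm[cursor: cursor + drugs_per_target]]
        cursor += drugs_per_target
        assignments[tgt] = group

    causal_profile: dict[str, np.ndarray] = {}
    for feature, (col, direction) in causal.items():
        b = B_true[:, col]
        unit = b / np.linalg.norm(b)
        sign = -1.0 if direction == "-" else 1.0
        # scaled to sqrt(p) so per-gene signal amplitude ~ effect_size
        template = sign * effect_size * unit * np.sqrt(p)
        for drug in truth.causal_drugs[truth.causal_targets[feature][0]]:
            causal_profile[drug] = template

    G: dict[tuple[str, str], np.ndarray] = {}
    for drug in drugs:
        present = [
            s for s in lines
            if coverage >= 1.0 or rng.random() < coverage
        ]
        if not present:  # every drug appears somewhere
            present = [lines[int(rng.integers(len(lines)))]]
        for s in present:
            base = causal_profile.get(drug, 0.0)
            G[(drug, s)] = base + noise_sd * rng.standard_normal(p)

    records = []
    for tgt, group in assignments.items():
        for drug in group:
            records.append((drug, tgt, CAUSAL_LINK_SCORE))
            truth.drug_targets[drug] = tgt
    links = TargetLinkTable(
        records=pd.DataFrame(records,
                             columns=["chemical", "protein", "combined_score"])
    )
    links.validate()
    comp = PerturbationCompendium(
        drugs=drugs,
        cell_lines=lines,
        gene_ids=[f"g{i + 1}" for i in range(p)],
        G=G,
        zscored=False,
    )
    return comp, links, truth


def simulate_survival(n: int = 200, beta: float | np.ndarray = 0.0,
                      censoring_rate: float = 0.2, seed: int = 0
                      ) -> SurvivalTable:
    """Exponential survival with linear predictor x beta and random censoring.

    Event times ~ Exp(rate = exp(x beta)); independent exponential censoring
    with its rate set so the expected censored fraction is ``censoring_rate``
    (for an average-hazard patient); rate 0 disables censoring entirely.
    """
    if not 0 <= censoring_rate < 1:
        raise ValidationError("censoring_rate must be in [0, 1)")
    rng = _rng(seed)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = rng.standard_normal((n, beta.size))
    lp = X @ beta
    hazard = np.exp(lp)
    times = rng.exponential(1.0 / hazard)
    if censoring_rate > 0:
        # competing Exp(c): P(censored) = c / (c + hazard)
        c = censoring_rate / (1.0 - censoring_rate) * float(hazard.mean())
        cens = rng.exponential(1.0 / c, size=n)
        event = (times <= cens).astype(int)
        obs = np.minimum(times, cens)
    else:
        event = np.ones(n, dtype=int)
        obs = times
    df = pd.DataFrame(
        {"time": obs, "event": event,
         **{f"x{j}": X[:, j] for j in range(beta.size)}},
        index=[f"p{i + 1}" for i in range(n)],
    )
    table = SurvivalTable(table=df)
    table.validate()
    return table


def simulate_protrusions(A_true: float = 50.0, k_true: float = 0.002,
                         n_images: int = 10, interface_length: float = 1000.0,
                         seed: int = 0) -> pd.DataFrame:
    """Per-image protrusion lengths: Poisson(A_true) counts, Exp(k_true) lengths.

    Returns a long frame (image_id, protrusion_length, N_bp); the expected
    count per image is A_true and the mean length 1/k_true.
    """
    if k_true <= 0:
        raise ValidationError("k_true must be positive")
    rng = _rng(seed)
    rows = []
    for i in range(n_images):
        count = int(rng.poisson(A_true))
        lengths = rng.exponential(1.0 / k_true, size=count)
        for length in lengths:
            rows.append((f"img_{i + 1}", float(length), interface_length))
    return pd.DataFrame(rows,
                        columns=["image_id", "protrusion_length", "N_bp"])
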