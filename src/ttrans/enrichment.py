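"""Target deconvolution from match scores.

For every protein target, compendium drugs are split into R+ (linked to the
target with a chemical-protein confidence score strictly above 900/1000) and
R- (everything else).  A one-sided two-sample Kolmogorov-Smirnov test asks
whether the R+ score distribution is shifted toward higher match scores:

    D = sup_x [ ecdf_minus(x) - ecdf_plus(x) ]

with an exact permutation p-value (enumeration over all splits) for small
samples and the asymptotic one-sided bound exp(-2 D^2 mn/(m+n)) otherwise.
Targets with fewer than 4 linked compendium drugs are skipped.  q-values are
Benjamini-Hochberg within each (feature, direction) family by default, with
a Storey pi0 option and a pooled-family flag.  Significant targets can be
summarized as a minimum spanning forest over a protein-protein link graph,
and direction calls evaluated against observed signature modulation by ROC.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    EnrichmentTable,
    MatchScoreTable,
    TargetLinkTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_SCORE_THRESHOLD = 900  # strict >, the stringent link level
DEFAULT_MIN_GROUP_SIZE = 4
DEFAULT_Q_THRESHOLD = 1e-4
EXACT_KS_MAX_N = 16


def split_by_target(target: str, links: TargetLinkTable, drugs: list[str],
                    score_threshold: int = DEFAULT_SCORE_THRESHOLD,
                    min_group_size: int = DEFAULT_MIN_GROUP_SIZE
                    ) -> tuple[set[str], set[str]] | None:
    """Split compendium drugs into (R+, R-) for one protein target.

    R+ holds the drugs linked to ``target`` with score strictly above
    ``score_threshold``; R- all remaining compendium drugs (including those
    with sub-threshold links).  Returns None, with the reason logged, when the
    target is absent from the link table or |R+| < ``min_group_size``.
    """
    drug_set = set(drugs)
    if target not in links.by_protein:
        logger.info("split_by_target: %s absent from link table, skipped", target)
        return None
    r_plus = links.chemicals_above(target, score_threshold) & drug_set
    if len(r_plus) < min_group_size:
        logger.info(
            "split_by_target: %s has %d < %d linked compendium drugs, skipped",
            target, len(r_plus), min_group_size,
        )
        return None
    return r_plus, drug_set - r_plus


def _ks_statistic(plus: np.ndarray, minus: np.ndarray) -> float:
    """One-sided D = sup_x [ecdf_minus(x) - ecdf_plus(x)] over the pooled grid."""
    grid = np.concatenate([plus, minus])
    ecdf_plus = np.searchsorted(np.sort(plus), grid, side="right") / plus.size
    ecdf_minus = np.searchsorted(np.sort(minus), grid, side="right") / minus.size
    return float(np.max(ecdf_minus - ecdf_plus))


def _exact_p(plus: np.ndarray, minus: np.ndarray, d_obs: float) -> float:
    """Exact permutation p: fraction of splits with D >= observed.

    Enumerates all C(m+n, m) assignments of the pooled sample (tie-safe) and
    recomputes the one-sided statistic for each; vectorized over splits.
    """
    pooled = np.concatenate([plus, minus])
    n = pooled.size
    m = plus.size
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), m)),
        dtype=np.intp,
    ).reshape(-1, m)
    is_plus = np.zeros((combos.shape[0], n), dtype=bool)
    np.put_along_axis(is_plus, combos, True, axis=1)
    order = np.argsort(pooled, kind="stable")
    sorted_vals = pooled[order]
    plus_sorted = is_plus[:, order]
    # ecdf difference at each pooled point, evaluated left-to-right
    cum_plus = np.cumsum(plus_sorted, axis=1) / m
    cum_minus = np.cumsum(~plus_sorted, axis=1) / (n - m)
    diff = cum_minus - cum_plus
    # at tied values the ecdf step completes only at the last tied position
    last_of_run = np.r_[sorted_vals[1:] != sorted_vals[:-1], True]
    d_all = diff[:, last_of_run].max(axis=1)
    return float(np.mean(d_all >= d_obs - 1e-12))


def ks_one_sided(sample_plus, sample_minus,
                 exact_max_n: int = EXACT_KS_MAX_N) -> tuple[float, float]:
    """One-sided two-sample KS test for R+ shifted toward higher scores.

    Returns (D, p).  Exact enumeration when the pooled size is at most
    ``exact_max_n``; otherwise the asymptotic one-sided tail bound
    exp(-2 D^2 mn/(m+n)), capped at 1.
    """
    plus = np.asarray(sample_plus, dtype=float)
    minus = np.asarray(sample_minus, dtype=float)
    if plus.size == 0 or minus.size == 0:
        raise ValidationError("both KS samples must be non-empty")
    d = _ks_statistic(plus, minus)
    n_tot = plus.size + minus.size
    if n_tot <= exact_max_n:
        p = _exact_p(plus, minus, d)
    else:
        en = plus.size * minus.size / n_tot
        p = min(1.0, math.exp(-2.0 * d * d * en))
    return d, p


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def storey_qvalues(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with fixed-lambda pi0 estimate (mafdr-like).

    pi0_hat = min(1, #{p > lambda} / ((1 - lambda) m)); q = pi0_hat * BH q.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    pi0 = min(1.0, float((p > lam).sum()) / ((1.0 - lam) * p.size))
    pi0 = max(pi0, 1.0 / p.size)  # never exactly 0
    return np.minimum(pi0 * bh_qvalues(p), 1.0)


def enrich_all(scores: MatchScoreTable, links: TargetLinkTable,
               alpha_q: float = DEFAULT_Q_THRESHOLD,
               score_threshold: int = DEFAULT_SCORE_THRESHOLD,
               min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
               fdr_method: str = "bh",
               pool_families: bool = False) -> EnrichmentTable:
    """KS-test every eligible target in every (feature, direction) family.

    FDR correction is applied within each (feature, direction) family
    (``pool_families=True`` corrects across all rows jointly).  Rows are
    sorted by q ascending then D descending; ``significant`` flags q < alpha_q.
    """
    if fdr_method not in ("bh", "storey"):
        raise ValidationError("fdr_method must be 'bh' or 'storey'")
    qfun = bh_qvalues if fdr_method == "bh" else storey_qvalues
    t = scores.table
    rows = []
    for (feature, direction), sub in t.groupby(["feature", "direction"],
                                               sort=True):
        s = sub.set_index("drug")["score"]
        drugs = list(s.index)
        for target in links.proteins:
            split = split_by_target(target, links, drugs, score_threshold,
                                    min_group_size)
            if split is None:
                continue
            r_plus, r_minus = split
            if not r_minus:
                logger.info("enrich_all: %s links every drug, skipped", target)
                continue
            d, p = ks_one_sided(s.loc[sorted(r_plus)].to_numpy(),
                                s.loc[sorted(r_minus)].to_numpy())
            rows.append({"target": target, "feature": feature,
                         "direction": direction, "D": d, "p": p,
                         "n_plus": len(r_plus), "n_minus": len(r_minus)})
    if not rows:
        logger.warning("enrich_all: no eligible targets")
        empty = pd.DataFrame(columns=list(EnrichmentTable.COLUMNS))
        return EnrichmentTable(table=empty)
    df = pd.DataFrame(rows)
    if pool_families:
        df["q"] = qfun(df["p"].to_numpy())
    else:
        df["q"] = np.nan
        for _, idx in df.groupby(["feature", "direction"], sort=False).groups.items():
            df.loc[idx, "q"] = qfun(df.loc[idx, "p"].to_numpy())
    df["significant"] = df["q"] < alpha_q
    df = df.sort_values(["q", "D"], ascending=[True, False],
                        kind="stable").reset_index(drop=True)
    table = EnrichmentTable(table=df[list(EnrichmentTable.COLUMNS)])
    table.validate()
    return table


# ---------------------------------------------------------------------------
# reporting helpers
# ---------------------------------------------------------------------------

def mst_of_targets(targets: list[str], protein_links: pd.DataFrame
                   ) -> pd.DataFrame:
    """Minimum spanning forest over the significant targets.

    ``protein_links`` has columns protein1, protein2, combined_score; edge
    distance is 1000 - combined_score.  Kruskal with edges pre-sorted by
    (distance, protein1, protein2) gives a deterministic tie-break.  Returns
    an edge list (protein1, protein2, combined_score, distance); an edgeless
    forest (no links among targets) is returned with a warning.
    """
    import networkx as nx

    if len(targets) < 2:
        raise ValidationError("MST requires at least 2 significant targets")
    target_set = set(targets)
    g = nx.Graph()
    g.add_nodes_from(sorted(target_set))
    sub = protein_links[
        protein_links["protein1"].isin(target_set)
        & protein_links["protein2"].isin(target_set)
    ].copy()
    sub["distance"] = 1000 - sub["combined_score"]
    edges = sorted(
        (
            (min(r.protein1, r.protein2), max(r.protein1, r.protein2),
             float(r.distance), int(r.combined_score))
            for r in sub.itertuples(index=False)
        ),
        key=lambda e: (e[2], e[0], e[1]),
    )
    for a, b, dist, score in edges:
        if not g.has_edge(a, b):
            g.add_edge(a, b, distance=dist, combined_score=score)
    if g.number_of_edges() == 0:
        logger.warning("mst_of_targets: no links among significant targets")
    mst = nx.minimum_spanning_tree(g, weight="distance", algorithm="kruskal")
    rows = [
        {"protein1": a, "protein2": b,
         "combined_score": data["combined_score"],
         "distance": data["distance"]}
        for a, b, data in sorted(mst.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["protein1", "protein2",
                                       "combined_score", "distance"])


@dataclass
class RocResult:
    curves: dict[str, pd.DataFrame]  # direction -> (fpr, tpr, threshold)
    auc: dict[str, float]
    mean_auc: float


def roc_predictions(predicted: pd.DataFrame, observed: pd.DataFrame
                    ) -> RocResult:
    """ROC of direction calls against observed signature modulation.

    ``predicted``: columns (drug, feature, direction, score) — the match
    scores used as direction-call confidences.  ``observed``: columns
    (drug, feature, value) — e.g. the correlation between the signature and
    the drug's measured fold-change profile; negative values mean the
    signature was suppressed.  For the "-" curve the positive class is
    value < 0, for "+" it is value > 0.  AUC by trapezoid rule via
    scikit-learn.
    """
    from sklearn.metrics import auc as sk_auc
    from sklearn.metrics import roc_curve

    obs = observed.set_index(["drug", "feature"])["value"]
    curves: dict[str, pd.DataFrame] = {}
    aucs: dict[str, float] = {}
    for direction, sub in predicted.groupby("direction", sort=True):
        keyed = sub.set_index(["drug", "feature"])["score"]
        shared = keyed.index.intersection(obs.index)
        if len(shared) == 0:
            raise ValidationError("no matched (drug, feature) keys")
        y_score = keyed.loc[shared].to_numpy(dtype=float)
        vals = obs.loc[shared].to_numpy(dtype=float)
        y_true = (vals < 0) if direction == "-" else (vals > 0)
        if y_true.all() or not y_true.any():
            raise ValidationError(
                f"observed labels single-class for direction {direction!r}"
            )
        fpr, tpr, thr = roc_curve(y_true, y_score)
        curves[direction] = pd.DataFrame(
            {"fpr": fpr, "tpr": tpr, "threshold": thr}
        )
        aucs[direction] = float(sk_auc(fpr, tpr))
    return RocResult(curves=curves, auc=aucs,
                     mean_auc=float(np.mean(list(aucs.values()))))
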