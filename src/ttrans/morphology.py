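"""Protrusion-based morphological differentiation scoring.

The number of cell protrusions longer than a threshold d in an image is
approximately exponential in d, so the survival-count curve is fitted as

    n(d) = A * exp(-k * d)

by least squares on log counts.  Two scores derive from the fit:

    Y_np = A / N_bp          (protrusion count normalized by the total
                              cell-background interface length N_bp)
    Y_md = -1000 * k         (morphological differentiation score; higher,
                              i.e. less negative, means longer protrusions)

Length units (pixels vs micrometres) are caller-defined pass-through; the
scores are unit-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ValidationError

MIN_PROTRUSIONS = 10
GRID_SIZE = 50
MIN_COUNT_PER_BIN = 3


@dataclass
class ProtrusionFit:
    A: float  # fitted amplitude (protrusion count scale)
    k: float  # fitted decay per length unit
    N_bp: float  # total cell-background interface length
    Y_np: float  # normalized protrusions, A / N_bp
    Y_md: float  # morphological differentiation score, -1000 * k
    residual: float  # RMS residual of the log-count fit
    n_protrusions: int
    unit: str = ""


def _fit_log_counts(d: np.ndarray, counts: np.ndarray, n_bp: float,
                    n_total: int, unit: str) -> ProtrusionFit:
    keep = counts >= MIN_COUNT_PER_BIN
    if keep.sum() < 2:
        raise ValidationError("too few populated bins for the decay fit")
    x = d[keep]
    y = np.log(counts[keep].astype(float))
    if y[-1] >= y[0]:
        raise ValidationError("protrusion counts do not decay with length")
    slope, intercept = np.polyfit(x, y, 1)
    k = -float(slope)
    if k <= 0:
        raise ValidationError("protrusion counts do not decay with length")
    A = float(np.exp(intercept))
    resid = float(np.sqrt(np.mean((y - (intercept + slope * x)) ** 2)))
    return ProtrusionFit(
        A=A, k=k, N_bp=float(n_bp), Y_np=A / float(n_bp), Y_md=-1000.0 * k,
        residual=resid, n_protrusions=n_total, unit=unit,
    )


def fit_protrusion_decay(lengths=None, N_bp: float = None, *,
                         counts_table: pd.DataFrame | None = None,
                         unit: str = "") -> ProtrusionFit:
    """Fit the exponential decay of protrusion counts over length thresholds.

    Either ``lengths`` (raw per-protrusion lengths; a survival-count curve
    n(d) = #{lengths > d} is built on a 50-point grid from 0 to the 99th
    percentile) or ``counts_table`` (columns d, count — a precomputed
    counts-vs-threshold curve) must be given, plus the interface length
    ``N_bp``.  Bins with fewer than 3 protrusions are excluded from the
    log-linear fit.
    """
    if N_bp is None or N_bp <= 0:
        raise ValidationError("N_bp must be positive")
    if (lengths is None) == (counts_table is None):
        raise ValidationError("provide exactly one of lengths or counts_table")
    if counts_table is not None:
        d = counts_table["d"].to_numpy(dtype=float)
        counts = counts_table["count"].to_numpy(dtype=float)
        n_total = int(counts.max())
    else:
        lengths = np.asarray(lengths, dtype=float)
        if lengths.size < MIN_PROTRUSIONS:
            raise ValidationError(
                f"need >= {MIN_PROTRUSIONS} protrusions, got {lengths.size}"
            )
        d = np.linspace(0.0, np.quantile(lengths, 0.99), GRID_SIZE)
        sorted_lengths = np.sort(lengths)
        counts = lengths.size - np.searchsorted(sorted_lengths, d, side="right")
        n_total = int(lengths.size)
    return _fit_log_counts(d, counts, N_bp, n_total, unit)


def fit_images(measurements: pd.DataFrame, unit: str = "") -> pd.DataFrame:
    """Fit every image in a long (image_id, protrusion_length, N_bp) frame."""
    rows = []
    for image_id, sub in measurements.groupby("image_id", sort=True):
        fit = fit_protrusion_decay(
            lengths=sub["protrusion_length"].to_numpy(),
            N_bp=float(sub["N_bp"].iloc[0]),
            unit=unit,
        )
        rows.append({"image_id": image_id, "A": fit.A, "k": fit.k,
                     "N_bp": fit.N_bp, "Y_np": fit.Y_np, "Y_md": fit.Y_md,
                     "residual": fit.residual,
                     "n_protrusions": fit.n_protrusions})
    return pd.DataFrame(rows)


def bootstrap_morphology(fits: pd.DataFrame, groups: pd.Series | dict,
                         n_boot: int = 1000, seed: int = 0,
                         ci: float = 0.95) -> pd.DataFrame:
    """Percentile bootstrap of group mean Y_md and group contrasts.

    Images are resampled with replacement within each group; returns one row
    per group (mean and CI) and one per group pair (difference and CI).
    ``groups`` maps image_id -> group label; >= 3 images per group required.
    """
    import itertools
    import logging

    if n_boot < 100:
        logging.getLogger(__name__).warning(
            "bootstrap_morphology: n_boot=%d < 100 gives unstable CIs", n_boot
        )
    groups = pd.Series(groups)
    fits = fits.set_index("image_id") if "image_id" in fits.columns else fits
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2

    samples: dict[str, np.ndarray] = {}
    rows = []
    for label in sorted(groups.unique()):
        ids = groups.index[groups == label]
        vals = fits.loc[ids, "Y_md"].to_numpy(dtype=float)
        if vals.size < 3:
            raise ValidationError(f"group {label!r} has < 3 images")
        idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
        boot_means = vals[idx].mean(axis=1)
        samples[label] = boot_means
        rows.append({
            "kind": "group", "group": label, "contrast": "",
            "estimate": float(vals.mean()),
            "ci_low": float(np.quantile(boot_means, lo_q)),
            "ci_high": float(np.quantile(boot_means, hi_q)),
        })
    for a, b in itertools.combinations(sorted(samples), 2):
        diff = samples[a] - samples[b]
        est = (
            rows[[r["group"] for r in rows].index(a)]["estimate"]
            - rows[[r["group"] for r in rows].index(b)]["estimate"]
        )
        rows.append({
            "kind": "contrast", "group": "", "contrast": f"{a}-{b}",
            "estimate": float(est),
            "ci_low": float(np.quantile(diff, lo_q)),
            "ci_high": float(np.quantile(diff, hi_q)),
        })
    return pd.DataFrame(rows)
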