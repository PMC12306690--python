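"""Segmentation and feature-agreement metrics.

The segmentation metric is the Dice coefficient; artery/vein label rasters
are compared after merging crossings (label 3) into both classes, exactly
as artery and vein masks are recovered from a crossing-aware segmentation.
Feature tables are compared per feature by mean absolute error (MAE) and
Pearson correlation over paired non-missing values, with a seeded sign-flip
permutation test for paired differences in absolute error between two
candidate pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import LengthMismatch, ShapeMismatch
from .vesselgraph import split_av_labels

__all__ = [
    "dice",
    "av_dice",
    "AgreementReport",
    "feature_agreement",
    "paired_mae_test",
]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|).

    Two empty masks are defined as perfectly agreeing (1.0, with a warning):
    any other convention would corrupt averages over image sets in which
    some images legitimately contain no pixels of a class.
    """
    am = np.asarray(a).astype(bool)
    bm = np.asarray(b).astype(bool)
    if am.shape != bm.shape:
        raise ShapeMismatch(f"mask shapes differ: {am.shape} vs {bm.shape}")
    denom = int(am.sum()) + int(bm.sum())
    if denom == 0:
        warnings.warn("both masks empty; Dice defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * float((am & bm).sum()) / denom


def av_dice(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(artery Dice, vein Dice) between two 4-level A/V label rasters.

    Both rasters are first split with the crossing-merge rule (label 3
    counts for both classes).
    """
    p = np.asarray(pred)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ShapeMismatch(f"label shapes differ: {p.shape} vs {t.shape}")
    pa, pv = split_av_labels(p)
    ta, tv = split_av_labels(t)
    return dice(pa, ta), dice(pv, tv)


@dataclass
class AgreementReport:
    """Per-feature agreement between a candidate and a reference table."""

    table: pd.DataFrame  # index: feature; columns: mae, r, n [, p_vs_comparator]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="feature")

    def __getitem__(self, feature: str) -> pd.Series:
        return self.table.loc[feature]


def feature_agreement(
    candidate: pd.DataFrame,
    reference: pd.DataFrame,
    comparator: pd.DataFrame | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> AgreementReport:
    """MAE and Pearson r per feature over paired non-missing rows.

    Tables are indexed by image id with one column per feature; only rows
    present in both tables pair up.  When `comparator` is given (a second
    candidate against the same reference), a paired sign-flip permutation
    test on per-image absolute errors adds a p-value column flagging
    significant MAE differences between the two candidates.
    """
    common = candidate.index.intersection(reference.index)
    features = [c for c in candidate.columns if c in reference.columns]
    rows = {}
    for feat in features:
        c = pd.to_numeric(candidate.loc[common, feat], errors="coerce")
        r = pd.to_numeric(reference.loc[common, feat], errors="coerce")
        ok = c.notna() & r.notna()
        n = int(ok.sum())
        if n == 0:
            rows[feat] = {"mae": np.nan, "r": np.nan, "n": 0}
            continue
        err = (c[ok] - r[ok]).abs()
        mae = float(err.mean())
        if n >= 2 and c[ok].nunique() > 1 and r[ok].nunique() > 1:
            pearson = float(stats.pearsonr(c[ok], r[ok])[0])
        else:
            pearson = np.nan  # undefined variance
        row = {"mae": mae, "r": pearson, "n": n}
        if comparator is not None and feat in comparator.columns:
            c2 = pd.to_numeric(
                comparator.reindex(common)[feat], errors="coerce"
            )
            ok2 = ok & c2.notna()
            if int(ok2.sum()) >= 2:
                e1 = (c[ok2] - r[ok2]).abs().to_numpy()
                e2 = (c2[ok2] - r[ok2]).abs().to_numpy()
                row["p_vs_comparator"] = paired_mae_test(
                    e1, e2, n_perm=n_perm, seed=seed
                )
            else:
                row["p_vs_comparator"] = np.nan
        rows[feat] = row
    return AgreementReport(table=pd.DataFrame.from_dict(rows, orient="index"))


def paired_mae_test(
    errors_a: np.ndarray,
    errors_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided sign-flip permutation test on paired absolute errors.

    The statistic is the mean of d_i = |err_a|_i - |err_b|_i; under the
    null of no systematic difference each d_i is sign-symmetric, so the
    reference distribution is the statistic over random sign flips.  The
    returned p-value uses the add-one convention and is deterministic for a
    given seed.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise LengthMismatch(f"paired error vectors differ: {a.shape} vs {b.shape}")
    if len(a) < 2:
        raise LengthMismatch("need at least 2 pairs")
    d = a - b
    obs = abs(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, len(d)))
    perm = np.abs((signs * d).mean(axis=1))
    return float((np.sum(perm >= obs - 1e-12) + 1) / (n_perm + 1))
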