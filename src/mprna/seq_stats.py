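"""Downstream sequence statistics for called regions.

Covers the composition analyses usually run after region calling: k-mer
ridge regression (which k-mers discriminate enriched regions), Mann-Whitney
group comparisons, length-matched shuffle controls constrained to exon
intervals, and a simple log-odds PWM occurrence scanner.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from mprna.seq_stats_pwm import PWM, pwm_scan, read_meme  # noqa: F401  (re-export)

_MAX_K = 8


@dataclass
class KmerModel:
    """Fitted ridge model over all 4^k k-mer counts (standardized features)."""

    k: int
    kmers: list[str]
    weights: np.ndarray
    intercept: float
    alpha: float
    alpha_grid: list[float]
    cv_mse: dict[float, float]
    feature_means: np.ndarray
    feature_scales: np.ndarray

    def weight_table(self) -> pd.Series:
        return pd.Series(self.weights, index=self.kmers, name="weight").sort_values(ascending=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.feature_means) / self.feature_scales
        return Z @ self.weights + self.intercept


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in product("ACGT", repeat=k)]


def kmer_features(seqs: Sequence[str], k: int = 4) -> tuple[np.ndarray, list[str]]:
    """Overlapping k-mer count matrix (sequence x 4^k).

    Row sums equal L - k + 1 by construction.
    """
    if not (1 <= k <= _MAX_K):
        raise ValueError(f"k must be in 1..{_MAX_K} (4^{_MAX_K} features already = 65536)")
    kmers = all_kmers(k)
    index = {km: i for i, km in enumerate(kmers)}
    X = np.zeros((len(seqs), len(kmers)))
    for r, seq in enumerate(seqs):
        s = seq.upper().replace("U", "T")
        if len(s) < k:
            raise ValueError(f"sequence {r} shorter than k={k}")
        for i in range(len(s) - k + 1):
            try:
                X[r, index[s[i : i + k]]] += 1
            except KeyError:
                raise ValueError(f"sequence {r} has non-ACGT characters at {i}") from None
    return X, kmers


DEFAULT_ALPHA_GRID = tuple(10.0 ** np.arange(-2, 5))


def ridge_fit(
    X: np.ndarray,
    y: Sequence[float],
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    cv_folds: int = 5,
    seed: int = 0,
    kmers: Sequence[str] | None = None,
) -> KmerModel:
    """Ridge regression with the penalty chosen by K-fold cross-validated MSE.

    Features are standardized (zero-variance columns get unit scale);
    the winning alpha is refit on all data.  ``y`` may be binary labels or
    a continuous per-sequence response.  Fold assignment is seeded.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of sequences")
    if X.shape[0] < cv_folds:
        raise ValueError(f"need at least cv_folds={cv_folds} rows")
    if np.ptp(y) == 0:
        raise ValueError("response is constant; nothing to regress")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cv_mse: dict[float, float] = {}
    for alpha in alpha_grid:
        errs = []
        for tr, te in cv.split(Z):
            model = Ridge(alpha=alpha).fit(Z[tr], y[tr])
            resid = y[te] - model.predict(Z[te])
            errs.append(float(np.mean(resid**2)))
        cv_mse[float(alpha)] = float(np.mean(errs))
    best = min(cv_mse, key=cv_mse.get)
    final = Ridge(alpha=best).fit(Z, y)
    k = int(round(np.log2(X.shape[1]) / 2)) if kmers is None else len(kmers[0])
    return KmerModel(
        k=k,
        kmers=list(kmers) if kmers is not None else [f"f{i}" for i in range(X.shape[1])],
        weights=final.coef_,
        intercept=float(final.intercept_),
        alpha=best,
        alpha_grid=[float(a) for a in alpha_grid],
        cv_mse=cv_mse,
        feature_means=mu,
        feature_scales=sd,
    )


EXACT_NM_LIMIT = 400


def mann_whitney(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test.

    Exact enumeration when n*m <= 400 and there are no ties; otherwise the
    tie-corrected normal approximation with continuity correction.
    Returns (U of the first sample, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= EXACT_NM_LIMIT and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def shuffle_within_exons(
    regions: pd.DataFrame,
    exons: pd.DataFrame,
    seed: int = 0,
    n_tries: int = 100,
) -> pd.DataFrame:
    """Length-matched control regions placed uniformly within the same
    transcript's exons.

    ``regions`` and ``exons`` carry transcript_id, start, end (0-based,
    half-open); each control keeps its source length, falls entirely in
    one exon of the source transcript and differs from the source
    interval.  Infeasible regions come back with ``placed=False`` (and a
    warning) rather than being dropped silently.
    """
    import warnings

    rng = np.random.default_rng(seed)
    out = []
    for i, r in regions.reset_index(drop=True).iterrows():
        length = int(r["end"]) - int(r["start"])
        if length <= 0:
            raise ValueError(f"region {i}: non-positive length")
        ex = exons[exons["transcript_id"] == r["transcript_id"]]
        # all feasible (exon, start) placements, uniform over starts
        choices: list[int] = []
        for _, e in ex.iterrows():
            es, ee = int(e["start"]), int(e["end"])
            if ee - es >= length:
                choices.extend(range(es, ee - length + 1))
        placed = False
        start = None
        if choices:
            for _ in range(n_tries):
                start = int(choices[rng.integers(0, len(choices))])
                if start != int(r["start"]):
                    placed = True
                    break
        if not placed:
            warnings.warn(
                f"region {i} ({r['transcript_id']}:{r['start']}-{r['end']}): no feasible control placement",
                stacklevel=2,
            )
        out.append(
            {
                "transcript_id": r["transcript_id"],
                "start": start if placed else -1,
                "end": (start + length) if placed else -1,
                "source_start": int(r["start"]),
                "source_end": int(r["end"]),
                "placed": placed,
            }
        )
    return pd.DataFrame(out)


def region_enrichment_report(
    diff_values: dict[str, pd.Series],
    regions: pd.DataFrame,
    background_label: str = "background",
) -> tuple[pd.DataFrame, dict]:
    """Compare per-position nuclear-total values inside labeled region groups.

    ``diff_values`` maps transcript_id -> Series of d(p) indexed by grid
    position; ``regions`` carries transcript_id, start, end, label.
    Positions not covered by any region form the ``background`` group.
    Returns a per-group summary table and, for two groups, the
    Mann-Whitney comparison plus per-group value vectors (CDF-ready).
    """
    groups: dict[str, list[float]] = {}
    for tid, series in diff_values.items():
        pos = series.index.to_numpy()
        assigned = np.full(len(pos), "", dtype=object)
        sub = regions[regions["transcript_id"] == tid]
        for _, r in sub.iterrows():
            inside = (pos >= r["start"]) & (pos < r["end"])
            assigned[inside] = r["label"]
        for label in np.unique(assigned):
            name = label if label else background_label
            groups.setdefault(name, []).extend(series.to_numpy()[assigned == label])

    wanted = set(regions["label"]) | {background_label}
    empty = sorted(g for g in wanted if len(groups.get(g, [])) == 0)
    if empty or not groups:
        raise ValueError(f"group(s) with no positions: {empty or 'all'}")
    table = pd.DataFrame(
        [
            {"label": g, "n_positions": len(v), "median": float(np.median(v)), "mean": float(np.mean(v))}
            for g, v in sorted(groups.items())
        ]
    )
    extras: dict = {"values": {g: np.sort(np.asarray(v)) for g, v in groups.items()}}
    if len(groups) == 2:
        (ga, va), (gb, vb) = sorted(groups.items())
        u, p = mann_whitney(va, vb)
        extras["comparison"] = {"groups": (ga, gb), "U": u, "p": p}
    return table, extras
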