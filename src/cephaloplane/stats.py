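"""Observer-reliability statistics and the Friedman rank test.

Reliability of repeated landmark digitisation is summarised per landmark
and coordinate axis by the mean absolute coordinate difference between
paired digitisations and the Pearson correlation of the paired coordinate
vectors, with a two-sided p-value from the exact t transform
``t = r * sqrt((n-2) / (1-r^2))``.

Cross-plane comparisons use Friedman's test: within-subject (block) ranks
of a metric across the k reference planes, midranks for ties, the standard
tie correction, and a chi-square reference distribution with k-1 degrees of
freedom. Both statistics are computed from their defining formulas; SciPy
supplies only the t / chi-square tail probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import PairingError, UsageError
from .landmarks import LandmarkSet

AXES = ("X", "Y", "Z")


# ---------------------------------------------------------------------------
# Pearson correlation from its sum formula


def pearson_r(x, y) -> float:
    """Pearson correlation coefficient from the raw-sum formula.

    Returns NaN (with a warning) when either vector has zero variance:
    a constant coordinate carries no correlation information and must not
    be reported as r = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UsageError("pearson_r expects two equal-length 1D vectors")
    n = len(x)
    if n < 3:
        raise UsageError("pearson_r needs at least 3 pairs")
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    vx = n * sxx - sx * sx
    vy = n * syy - sy * sy
    if vx <= 0 or vy <= 0:
        warnings.warn("zero variance: Pearson r undefined", stacklevel=2)
        return float("nan")
    r = (n * sxy - sx * sy) / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def pearson_p_value(r: float, n: int) -> float:
    """Two-sided p for H0: rho = 0, via the exact t transform (df = n-2)."""
    if np.isnan(r):
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * _sps.t.sf(abs(t), df=n - 2))


# ---------------------------------------------------------------------------
# Reliability of repeated landmark digitisation


@dataclass
class ReliabilityReport:
    """Per-(landmark, axis) agreement between paired digitisations."""

    mode: str  # "intraobserver" or "interobserver"
    n_pairs: int
    table: pd.DataFrame = field(repr=False)  # index (landmark, axis)

    def to_csv(self, path) -> None:
        wide = self.table.unstack("axis")
        wide = wide.reorder_levels([1, 0], axis=1)
        wide = wide[[(ax, c) for ax in AXES for c in ("mean_abs_diff", "r", "p_value")]]
        wide.columns = [f"{ax}_{c}" for ax, c in wide.columns]
        wide.to_csv(path, float_format="%.6g")


def _pair_key(ls: LandmarkSet):
    return (ls.subject_id, ls.observer, ls.trial)


def pair_trials(trials, mode: str, trial_pair=(1, 2), observer_pair=None):
    """Pair landmark sets for a reliability comparison.

    intraobserver: for every (subject, observer), trial `trial_pair[0]`
    versus trial `trial_pair[1]`.
    interobserver: for every (subject, trial), observer_pair[0] versus
    observer_pair[1] (defaults to the two observers present).
    Returns a list of (LandmarkSet, LandmarkSet) pairs.
    """
    index = {}
    for ls in trials:
        key = _pair_key(ls)
        if key in index:
            raise PairingError(f"duplicate digitisation for {key}")
        index[key] = ls
    subjects = sorted({s for s, _, _ in index})
    observers = sorted({o for _, o, _ in index})
    pairs = []
    if mode == "intraobserver":
        t1, t2 = trial_pair
        for s in subjects:
            for o in observers:
                a, b = index.get((s, o, t1)), index.get((s, o, t2))
                if (a is None) != (b is None):
                    raise PairingError(
                        f"subject {s!r} observer {o!r}: trials {t1}/{t2} unmatched"
                    )
                if a is not None:
                    pairs.append((a, b))
    elif mode == "interobserver":
        if observer_pair is None:
            if len(observers) < 2:
                raise PairingError(
                    f"interobserver mode needs >=2 observers, found {observers}"
                )
            observer_pair = tuple(observers[:2])
        o1, o2 = observer_pair
        trials_seen = sorted({t for _, _, t in index})
        for s in subjects:
            for t in trials_seen:
                a, b = index.get((s, o1, t)), index.get((s, o2, t))
                if (a is None) != (b is None):
                    raise PairingError(
                        f"subject {s!r} trial {t}: observers {o1!r}/{o2!r} unmatched"
                    )
                if a is not None:
                    pairs.append((a, b))
    else:
        raise UsageError(f"unknown reliability mode {mode!r}")
    if not pairs:
        raise PairingError(f"no {mode} pairs could be formed")
    return pairs


def pairwise_reliability(
    trials,
    mode: str,
    landmarks=None,
    trial_pair=(1, 2),
    observer_pair=None,
    bonferroni: bool = False,
) -> ReliabilityReport:
    """Mean absolute difference, Pearson r and p per landmark and axis.

    `trials` is a flat list of LandmarkSet digitisations carrying subject,
    observer and trial metadata. At least 3 pairs per landmark are needed
    for a correlation. `bonferroni=True` multiplies p-values by the number
    of (landmark, axis) tests (off by default).
    """
    pairs = pair_trials(trials, mode, trial_pair, observer_pair)
    if landmarks is None:
        common = set(pairs[0][0].names)
        for a, b in pairs:
            common &= set(a.names) & set(b.names)
        landmarks = sorted(common)
    rows = []
    for lm in landmarks:
        a = np.array([p[0][lm] for p in pairs])
        b = np.array([p[1][lm] for p in pairs])
        if len(a) < 3:
            raise PairingError(
                f"landmark {lm!r}: need >=3 pairs for correlation, got {len(a)}"
            )
        for axis_idx, axis in enumerate(AXES):
            x, y = a[:, axis_idx], b[:, axis_idx]
            r = pearson_r(x, y)
            rows.append(
                {
                    "landmark": lm,
                    "axis": axis,
                    "mean_abs_diff": float(np.mean(np.abs(x - y))),
                    "r": r,
                    "p_value": pearson_p_value(r, len(x)),
                }
            )
    table = pd.DataFrame(rows).set_index(["landmark", "axis"])
    if bonferroni:
        table["p_value"] = np.minimum(table["p_value"] * len(table), 1.0)
    return ReliabilityReport(mode=mode, n_pairs=len(pairs), table=table)


# ---------------------------------------------------------------------------
# Friedman rank test


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    dof: int
    p_value: float
    n_blocks: int
    k_treatments: int


def midranks(row) -> np.ndarray:
    """Ranks 1..k with ties given the mean of their covered ranks."""
    row = np.asarray(row, dtype=float)
    order = np.argsort(row, kind="stable")
    ranks = np.empty(len(row))
    i = 0
    while i < len(row):
        j = i
        while j + 1 < len(row) and row[order[j + 1]] == row[order[i]]:
            j += 1
        # positions i..j share the average of ranks i+1..j+1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def friedman_test(blocks) -> FriedmanResult:
    """Friedman chi-square test across k treatments in n blocks.

    `blocks` is an (n, k) matrix: one row per block (subject), one column
    per treatment (reference plane). Midranks handle ties; the statistic is

        Q = [12 / (n k (k+1))] * sum_j Rj^2 - 3 n (k+1)

    divided by the tie correction ``1 - sum(t^3 - t) / (n k (k^2 - 1))``.
    p comes from the chi-square distribution with k-1 dof. Fully tied data
    (every block constant) yield Q = 0, p = 1.
    """
    X = np.asarray(blocks, dtype=float)
    if X.ndim != 2:
        raise UsageError("blocks must be a 2D (subjects x treatments) matrix")
    n, k = X.shape
    if n < 2 or k < 2:
        raise UsageError(f"need n >= 2 blocks and k >= 2 treatments, got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise UsageError("blocks contain missing or non-finite cells")
    R = np.vstack([midranks(row) for row in X])
    col_sums = R.sum(axis=0)
    q = (12.0 / (n * k * (k + 1))) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    # tie correction over the tie multiplicities of each block
    ties = 0.0
    for row in X:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n * k * (k * k - 1.0))
    if correction <= 0.0:  # every block fully tied: no evidence either way
        return FriedmanResult(0.0, k - 1, 1.0, n, k)
    q /= correction
    q = max(q, 0.0)
    p = float(_sps.chi2.sf(q, df=k - 1))
    return FriedmanResult(float(q), k - 1, p, n, k)
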