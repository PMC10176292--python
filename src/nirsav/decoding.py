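"""Across-participant MVPA: leave-one-participant-out SVM decoding of the
two stimulation conditions from channel-space activation patterns.

Patterns are per-participant condition-average window means, z-scored within
each channel across all infants.  A linear support-vector machine (C = 1, no
tuning) is trained per fold on the other participants' patterns; channels
without usable data for the held-out participant are dropped from both the
training and test patterns of that fold.  Significance is assessed by a
permutation scheme that independently keeps or swaps each participant's two
condition labels, with the inclusive p estimator

    p = (1 + #{permuted accuracy >= observed}) / (1 + n_permutations)

so that an observed accuracy above all 1000 permuted accuracies yields
exactly p = 1/1001.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .montage import Montage, default_montage

log = logging.getLogger(__name__)

LABELS = {"alternating": 0.0, "bimodal": 1.0}
SVM_C = 1.0

try:  # low-level libsvm path for permutation loops (same compiled solver)
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
    _HAVE_FAST = True
except ImportError:  # pragma: no cover
    _HAVE_FAST = False


@dataclass
class PatternSet:
    """2N condition-average patterns (rows) over a channel subset (columns).

    ``X`` is z-scored within channel over non-missing entries; missing
    channels are NaN (never imputed).  Row i corresponds to participant
    ``participants[i // 2]``... rows are ordered participant-major with the
    alternating pattern first, bimodal second.
    """

    X: np.ndarray
    participants: list[str]
    channel_ids: list[int]
    subset: str
    chromophore: str
    window: str
    age_group: str

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def labels(self) -> np.ndarray:
        return np.tile([LABELS["alternating"], LABELS["bimodal"]],
                       self.n_participants)


@dataclass
class DecodingResult:
    accuracy: float
    accuracy_by_participant: float
    n_folds: int
    p: float = float("nan")
    n_permutations: int = 0
    null_accuracies: np.ndarray = field(default_factory=lambda: np.empty(0))
    weights: pd.Series | None = None
    informative_channels: list[int] = field(default_factory=list)
    eligible_channels: list[int] = field(default_factory=list)
    subset: str = "all"
    chromophore: str = "HbO"
    window: str = "W1"
    age_group: str = "both"


# ---------------------------------------------------------------------------
# pattern construction
# ---------------------------------------------------------------------------
def build_patterns(
    table: pd.DataFrame,
    chromophore: str,
    window: str,
    subset: str = "all",
    age_group: str | None = None,
    montage: Montage | None = None,
) -> PatternSet:
    """Participant x condition mean-activation vectors, z-scored per channel.

    ``subset`` restricts channels by montage hemisphere ('all'|'left'|
    'right').  Channels with zero variance across patterns are dropped with
    a warning (normalisation undefined there).
    """
    montage = montage or default_montage()
    sub = table[(table.chromophore == chromophore) & (table.window == window)]
    if age_group is not None:
        sub = sub[sub.age_group == age_group]
    ids = montage.subset_ids(subset)
    wide = sub.pivot_table(index=["participant", "condition"], columns="channel",
                           values="mean")
    wide = wide.reindex(columns=ids)
    participants = sorted(wide.index.get_level_values(0).unique())
    rows = []
    for pid in participants:
        for cond in ("alternating", "bimodal"):
            if (pid, cond) in wide.index:
                rows.append(wide.loc[(pid, cond)].values)
            else:
                rows.append(np.full(len(ids), np.nan))
    X = np.asarray(rows, dtype=float)

    # a channel missing in either of a participant's patterns is unusable for
    # that participant as a whole
    for i in range(0, X.shape[0], 2):
        miss = np.isnan(X[i]) | np.isnan(X[i + 1])
        X[i, miss] = X[i + 1, miss] = np.nan

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0, ddof=1)
    dead = ~(sd > 0)
    if dead.any():
        keep = ~dead
        warnings.warn(
            f"dropping {int(dead.sum())} constant/empty channel(s): "
            f"{[ids[j] for j in np.flatnonzero(dead)]}"
        )
        X, ids = X[:, keep], [c for c, k in zip(ids, keep) if k]
        mu, sd = mu[keep], sd[keep]
    X = (X - mu) / sd
    return PatternSet(X, participants, list(ids), subset, chromophore, window,
                      age_group or "both")


# ---------------------------------------------------------------------------
# linear SVM fit/predict (fast path + reference path)
# ---------------------------------------------------------------------------
def _svc_predict(Xtr, ytr, Xte) -> np.ndarray:
    return SVC(kernel="linear", C=SVM_C).fit(Xtr, ytr).predict(Xte)


def _fast_predict(Xtr, ytr, Xte) -> np.ndarray:
    out = _libsvm.fit(Xtr, ytr, svm_type=0, kernel="linear", C=SVM_C)
    w = out[3][0] @ out[1]
    dec = Xte @ w + out[4][0]
    # libsvm decision sign: positive side is class 0 (labels are 0/1 floats)
    return np.where(dec > 0, 0.0, 1.0)


def fit_predict(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray,
                fast: bool = True) -> np.ndarray:
    """Train the linear max-margin boundary and predict test labels (0/1)."""
    if len(np.unique(ytr)) < 2:
        return np.full(len(Xte), ytr[0])
    if fast and _HAVE_FAST:
        return _fast_predict(np.ascontiguousarray(Xtr, dtype=np.float64),
                             np.ascontiguousarray(ytr, dtype=np.float64),
                             np.asarray(Xte, dtype=np.float64))
    return _svc_predict(Xtr, ytr, Xte)


# ---------------------------------------------------------------------------
# LOPO cross-validation
# ---------------------------------------------------------------------------
@dataclass
class _Fold:
    test_part: int
    Xtr: np.ndarray
    Xte: np.ndarray
    train_parts: np.ndarray  # participant index per training row


def _plan_folds(ps: PatternSet, missing_mode: str = "intersection") -> list[_Fold]:
    n = ps.n_participants
    folds = []
    avail = ~np.isnan(ps.X[0::2])  # (n_participants, n_channels)
    for t in range(n):
        train = np.delete(np.arange(n), t)
        mask = avail[t].copy()
        if missing_mode == "intersection":
            mask &= avail[train].all(axis=0)
        if mask.sum() < 1:
            log.warning("fold %s: no usable channels; fold skipped",
                        ps.participants[t])
            continue
        rows = np.sort(np.r_[2 * train, 2 * train + 1])
        Xtr = ps.X[np.ix_(rows, np.flatnonzero(mask))]
        Xte = ps.X[np.ix_([2 * t, 2 * t + 1], np.flatnonzero(mask))]
        if missing_mode == "test":  # training rows may still carry NaNs:
            Xtr = np.nan_to_num(Xtr)  # zero = channel grand mean after z-scoring
        folds.append(_Fold(t, np.ascontiguousarray(Xtr),
                           np.ascontiguousarray(Xte), train_parts=train))
    return folds


def _accuracy_for_flips(
    folds: list[_Fold], base: np.ndarray, flips: np.ndarray, fast: bool = True
) -> tuple[float, float]:
    """(per-pattern accuracy, per-participant accuracy) under per-participant
    label flips.  ``base`` is the canonical (alternating, bimodal) label pair."""
    correct = 0
    total = 0
    part_correct = 0
    for f in folds:
        ytr = np.empty(2 * len(f.train_parts))
        fl = flips[f.train_parts]
        ytr[0::2] = np.where(fl, base[1], base[0])
        ytr[1::2] = np.where(fl, base[0], base[1])
        yte = (base[::-1] if flips[f.test_part] else base)
        pred = fit_predict(f.Xtr, ytr, f.Xte, fast=fast)
        c = int((pred == yte).sum())
        correct += c
        total += 2
        part_correct += c == 2
    if total == 0:
        raise ValueError("no usable folds")
    return correct / total, part_correct / len(folds)


def lopo_accuracy(
    patterns: PatternSet,
    missing_mode: str = "intersection",
    fast: bool = True,
) -> DecodingResult:
    """Leave-one-participant-out accuracy over all 2N pattern predictions."""
    if patterns.n_participants < 3:
        raise ValueError("LOPO decoding needs at least 3 participants")
    folds = _plan_folds(patterns, missing_mode)
    base = np.array([LABELS["alternating"], LABELS["bimodal"]])
    flips = np.zeros(patterns.n_participants, dtype=bool)
    acc, acc_part = _accuracy_for_flips(folds, base, flips, fast)
    return DecodingResult(
        accuracy=acc, accuracy_by_participant=acc_part, n_folds=len(folds),
        subset=patterns.subset, chromophore=patterns.chromophore,
        window=patterns.window, age_group=patterns.age_group,
    )


def permutation_p(
    patterns: PatternSet,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    missing_mode: str = "intersection",
    fast: bool = True,
) -> DecodingResult:
    """Permutation test of LOPO accuracy.

    Each permutation independently keeps or swaps every participant's two
    condition labels (fair coin) and recomputes the full LOPO accuracy; ties
    count against the observed value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    folds = _plan_folds(patterns, missing_mode)
    base = np.array([LABELS["alternating"], LABELS["bimodal"]])
    n = patterns.n_participants
    observed, acc_part = _accuracy_for_flips(
        folds, base, np.zeros(n, dtype=bool), fast)
    null = np.empty(n_perm)
    for j in range(n_perm):
        flips = rng.random(n) < 0.5
        null[j], _ = _accuracy_for_flips(folds, base, flips, fast)
    p = (1.0 + np.sum(null >= observed - 1e-12)) / (1.0 + n_perm)
    return DecodingResult(
        accuracy=observed, accuracy_by_participant=acc_part, n_folds=len(folds),
        p=float(p), n_permutations=n_perm, null_accuracies=null,
        subset=patterns.subset, chromophore=patterns.chromophore,
        window=patterns.window, age_group=patterns.age_group,
    )


# ---------------------------------------------------------------------------
# informative channels
# ---------------------------------------------------------------------------
def informative_channels(
    patterns: PatternSet,
    availability_min: float = 0.8,
    top_fraction: float = 0.30,
) -> tuple[pd.Series, list[int]]:
    """Weight-based channel informativeness from a final model.

    Restricted to channels with usable data in at least ``availability_min``
    of participants, the classifier is retrained on the two grand-average
    condition patterns; informativeness per channel is the weight times the
    grand-average condition contrast, and the informative set is the top
    ``top_fraction`` (ceiling; ties at the threshold included).  By
    construction the set is identical for both classes.
    """
    avail = ~np.isnan(patterns.X[0::2])
    frac = avail.mean(axis=0)
    eligible = frac >= availability_min
    if not eligible.any():
        raise ValueError("no channel passes the availability threshold")
    cols = np.flatnonzero(eligible)
    ids = [patterns.channel_ids[j] for j in cols]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        alt = np.nanmean(patterns.X[0::2][:, cols], axis=0)
        bim = np.nanmean(patterns.X[1::2][:, cols], axis=0)
    Xavg = np.vstack([alt, bim])
    yavg = np.array([LABELS["alternating"], LABELS["bimodal"]])
    clf = SVC(kernel="linear", C=SVM_C).fit(Xavg, yavg)
    w = clf.coef_.ravel()
    # sign convention: w points from the negative toward the positive class;
    # score = w * (class contrast) is invariant under label exchange
    pos = Xavg[np.argmax(clf.classes_ == clf.classes_.max())]
    neg = Xavg[np.argmin(clf.classes_ == clf.classes_.max())]
    score = w * (pos - neg) / 2.0
    weights = pd.Series(score, index=ids, name="informativeness")
    k = int(np.ceil(top_fraction * len(ids)))
    order = weights.sort_values(ascending=False)
    thresh = order.iloc[k - 1]
    top = sorted(weights[weights >= thresh].index)
    return weights, top


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------
def decode(
    table: pd.DataFrame,
    chromophore: str,
    window: str,
    subset: str = "all",
    age_group: str | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    montage: Montage | None = None,
    missing_mode: str = "intersection",
) -> DecodingResult:
    """Full decoding analysis for one chromophore x window x subset."""
    patterns = build_patterns(table, chromophore, window, subset, age_group,
                              montage)
    res = permutation_p(patterns, n_perm=n_perm, seed=seed,
                        missing_mode=missing_mode)
    weights, top = informative_channels(patterns)
    res.weights = weights
    res.informative_channels = top
    res.eligible_channels = list(weights.index)
    return res
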