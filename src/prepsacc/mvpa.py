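"""Multi-voxel pattern analysis of pro- vs anti-saccade beta patterns.

Exemplars are per-run GLM beta vectors (one per run and class, from the
5-regressor direction-collapsed scheme).  Within each participant, betas are
normalised in two stages — the whole block to unit root-mean-square, then
each class's block to unit RMS — removing between-participant and
between-class magnitude differences so that only *pattern* information can
drive classification.  Participants' feature axes are then concatenated,
keeping the run-by-class exemplar structure intact for leave-one-run-out
cross-validation of a linear support-vector machine.  Significance is
assessed against an empirical permutation null (shuffled class labels, same
pipeline), using the null's 95th percentile as the criterion, and via the
distribution of t-test p-values over repeated voxel subsamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sp_stats
from sklearn.svm import SVC

from .glm import BetaEstimates

CLASSES = ("pro", "anti")
PHASES = {"preparation": "prep", "execution": "exec"}


@dataclass(frozen=True)
class ExemplarSet:
    """Labelled beta vectors: exemplars x voxels, with run/participant tags.

    ``voxel_participants`` tags every feature column with the participant it
    came from, so per-participant normalization remains well defined after
    cross-participant concatenation (which joins voxel axes, not exemplars).
    """

    features: np.ndarray
    labels: np.ndarray  # 'pro' | 'anti' per exemplar
    runs: np.ndarray  # run id per exemplar
    phase: str
    voxel_participants: np.ndarray

    def __post_init__(self) -> None:
        n, v = self.features.shape
        if not (len(self.labels) == len(self.runs) == n):
            raise ValueError("labels/runs length must match exemplar count")
        if len(self.voxel_participants) != v:
            raise ValueError("voxel_participants length must match voxel count")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")
        for run in np.unique(self.runs):
            sel = self.labels[self.runs == run]
            if sorted(sel) != sorted(CLASSES):
                raise ValueError(
                    f"run {run} must contribute exactly one exemplar per class"
                )

    @property
    def n_exemplars(self) -> int:
        return self.features.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.features.shape[1]

    def subsample_voxels(self, indices: np.ndarray) -> "ExemplarSet":
        return replace(
            self,
            features=self.features[:, indices],
            voxel_participants=self.voxel_participants[indices],
        )


@dataclass(frozen=True)
class DecodeResult:
    accuracy: float
    fold_accuracies: np.ndarray


@dataclass(frozen=True)
class PermutationNull:
    accuracies: np.ndarray
    n_permutations: int
    percentile_95: float


@dataclass(frozen=True)
class DecodingCurve:
    sizes: np.ndarray
    mean_accuracy: np.ndarray
    null_percentile_95: np.ndarray
    n_repeats: int
    accuracies: np.ndarray  # sizes x repeats


@dataclass(frozen=True)
class PValueHistogram:
    p_values: np.ndarray
    sample_voxels: int
    alpha: float = 0.05

    @property
    def count_below_alpha(self) -> int:
        return int(np.sum(self.p_values < self.alpha))


def build_exemplars(
    run_fits: list[BetaEstimates],
    phase: str,
    participant: int = 0,
    voxel_indices: np.ndarray | None = None,
) -> ExemplarSet:
    """One feature vector per (run, class) from per-run 5-regressor fits."""
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {sorted(PHASES)}")
    if not run_fits:
        raise ValueError("at least one run fit is required")
    prefix = PHASES[phase]
    feats, labels, runs = [], [], []
    for run_id, fit in enumerate(run_fits):
        for cls in CLASSES:
            col = fit.column(f"{prefix}_{cls}")
            feats.append(col if voxel_indices is None else col[voxel_indices])
            labels.append(cls)
            runs.append(run_id)
    features = np.vstack(feats)
    return ExemplarSet(
        features=features,
        labels=np.array(labels),
        runs=np.array(runs),
        phase=phase,
        voxel_participants=np.full(features.shape[1], participant),
    )


def normalize_exemplars(exemplars: ExemplarSet, method: str = "rms") -> ExemplarSet:
    """Two-stage normalization-to-one within each participant's voxel block.

    Stage 1 scales a participant's full block to unit magnitude (removes
    between-participant differences); stage 2 scales each class's sub-block
    likewise (removes between-class magnitude, leaving pattern shape only).
    ``method`` selects the magnitude statistic: root-mean-square (default)
    or ``max_abs``.
    """
    if method not in ("rms", "max_abs"):
        raise ValueError(f"unknown normalization method {method!r}")

    def magnitude(block: np.ndarray) -> float:
        if method == "rms":
            return float(np.sqrt(np.mean(block**2)))
        return float(np.max(np.abs(block)))

    feats = exemplars.features.astype(float).copy()
    for pid in np.unique(exemplars.voxel_participants):
        cols = exemplars.voxel_participants == pid
        block = feats[:, cols]
        scale = magnitude(block)
        if scale == 0:
            raise ValueError(f"all-zero feature block for participant {pid}")
        block = block / scale
        for cls in CLASSES:
            rows = exemplars.labels == cls
            sub = block[rows]
            scale_c = magnitude(sub)
            if scale_c == 0:
                raise ValueError(
                    f"all-zero class block ({cls}) for participant {pid}"
                )
            block[rows] = sub / scale_c
        feats[:, cols] = block
    return replace(exemplars, features=feats)


def concatenate_participants(sets: list[ExemplarSet]) -> ExemplarSet:
    """Join feature axes across participants, aligned by (run, class).

    Exemplar count is unchanged; voxel count is the sum over participants.
    """
    if not sets:
        raise ValueError("nothing to concatenate")
    first = sets[0]
    feats = [first.features]
    for other in sets[1:]:
        if other.phase != first.phase:
            raise ValueError("phase mismatch between participants")
        if not (
            np.array_equal(other.runs, first.runs)
            and np.array_equal(other.labels, first.labels)
        ):
            raise ValueError("run/class structure mismatch between participants")
        feats.append(other.features)
    return replace(
        first,
        features=np.hstack(feats),
        voxel_participants=np.concatenate([s.voxel_participants for s in sets]),
    )


def _fold_accuracies(
    features: np.ndarray,
    labels: np.ndarray,
    runs: np.ndarray,
    C: float = 1.0,
) -> np.ndarray:
    """Leave-one-run-out linear-SVM fold accuracies.

    An exemplar landing exactly on the decision boundary counts as
    misclassified (margin tie-break).
    """
    y = (labels == "anti").astype(int)
    accs = []
    for run in np.unique(runs):
        test = runs == run
        train = ~test
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"single class in training fold (run {run} left out)")
        clf = SVC(kernel="linear", C=C)
        clf.fit(features[train], y[train])
        scores = clf.decision_function(features[test])
        predicted = scores > 0  # score == 0 predicts class 0 either way
        correct = (predicted.astype(int) == y[test]) & (scores != 0)
        accs.append(float(np.mean(correct)))
    return np.array(accs)


def loro_cv_decode(exemplars: ExemplarSet, C: float = 1.0) -> DecodeResult:
    """Mean leave-one-run-out accuracy of the linear-kernel SVM."""
    if len(np.unique(exemplars.runs)) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    folds = _fold_accuracies(exemplars.features, exemplars.labels, exemplars.runs, C)
    return DecodeResult(accuracy=float(folds.mean()), fold_accuracies=folds)


def permuted_labels(
    exemplars: ExemplarSet, rng: np.random.Generator, scheme: str = "within_run"
) -> np.ndarray:
    """One random label assignment under the chosen permutation scheme.

    ``within_run`` (default) swaps each run's pro/anti pair independently, so
    every cross-validation fold stays class-balanced and the null accuracy
    distribution centres on chance.  ``free`` shuffles labels across all
    exemplars; training folds can then be unbalanced, which drags the null
    mean below chance (the classic small-sample cross-validation artifact).
    """
    if scheme == "within_run":
        labels = exemplars.labels.copy()
        for run in np.unique(exemplars.runs):
            idx = np.flatnonzero(exemplars.runs == run)
            if rng.random() < 0.5:
                labels[idx] = labels[idx][::-1]
        return labels
    if scheme == "free":
        # a shuffle may leave a training fold single-class on very small
        # sets; such assignments are undefined for LORO and are redrawn
        for _ in range(1000):
            labels = exemplars.labels[rng.permutation(exemplars.n_exemplars)]
            ok = all(
                len(np.unique(labels[exemplars.runs != run])) == 2
                for run in np.unique(exemplars.runs)
            )
            if ok:
                return labels
        raise ValueError("no valid label permutation found")
    raise ValueError(f"unknown permutation scheme {scheme!r}")


def permutation_null(
    exemplars: ExemplarSet,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
    C: float = 1.0,
    scheme: str = "within_run",
) -> PermutationNull:
    """Null accuracy distribution from label permutations.

    Each permutation re-labels the exemplars (see :func:`permuted_labels`)
    and repeats the identical leave-one-run-out analysis; the empirical 95th
    percentile is the significance criterion for the true-label accuracy.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    accs = np.empty(n_permutations)
    for i in range(n_permutations):
        labels = permuted_labels(exemplars, rng, scheme)
        folds = _fold_accuracies(exemplars.features, labels, exemplars.runs, C)
        accs[i] = folds.mean()
    return PermutationNull(
        accuracies=accs,
        n_permutations=n_permutations,
        percentile_95=float(np.percentile(accs, 95)),
    )


def decoding_curve(
    exemplars: ExemplarSet,
    sizes: list[int],
    n_repeats: int = 20,
    rng: np.random.Generator | None = None,
    n_permutations: int = 1000,
    C: float = 1.0,
    scheme: str = "within_run",
) -> DecodingCurve:
    """Accuracy vs voxel-sample size with a matching permutation criterion.

    Per size: ``n_repeats`` random voxel subsets are decoded with true labels
    and averaged; the null criterion at that size is the 95th percentile of
    ``n_permutations`` decodings each using a fresh random subset and a fresh
    label permutation.
    """
    rng = np.random.default_rng() if rng is None else rng
    sizes_arr = np.asarray(sizes, dtype=int)
    if np.any(np.diff(sizes_arr) <= 0):
        raise ValueError("sizes must be strictly increasing")
    if sizes_arr.max() > exemplars.n_voxels:
        raise ValueError(
            f"requested {sizes_arr.max()} voxels but only "
            f"{exemplars.n_voxels} available"
        )
    acc = np.empty((len(sizes_arr), n_repeats))
    null95 = np.empty(len(sizes_arr))
    for i, size in enumerate(sizes_arr):
        for j in range(n_repeats):
            idx = rng.choice(exemplars.n_voxels, size=size, replace=False)
            acc[i, j] = loro_cv_decode(exemplars.subsample_voxels(idx), C).accuracy
        null = np.empty(n_permutations)
        for k in range(n_permutations):
            idx = rng.choice(exemplars.n_voxels, size=size, replace=False)
            labels = permuted_labels(exemplars, rng, scheme)
            folds = _fold_accuracies(
                exemplars.features[:, idx], labels, exemplars.runs, C
            )
            null[k] = folds.mean()
        null95[i] = float(np.percentile(null, 95))
    return DecodingCurve(
        sizes=sizes_arr,
        mean_accuracy=acc.mean(axis=1),
        null_percentile_95=null95,
        n_repeats=n_repeats,
        accuracies=acc,
    )


def pvalue_histogram(
    exemplars: ExemplarSet,
    sample_voxels: int = 500,
    n_iterations: int = 1000,
    rng: np.random.Generator | None = None,
    C: float = 1.0,
    scheme: str = "within_run",
) -> PValueHistogram:
    """Distribution of p-values comparing true vs permuted fold accuracies.

    Each iteration draws a fresh random voxel subset and a fresh label
    permutation, decodes both, and records the two-sample t-test p-value
    between the two sets of fold accuracies.  Clustering of p-values below
    0.05 indicates pattern information; under the null the p-values are
    approximately uniform.
    """
    if sample_voxels > exemplars.n_voxels:
        raise ValueError("sample_voxels exceeds available voxels")
    rng = np.random.default_rng() if rng is None else rng
    ps = np.empty(n_iterations)
    for i in range(n_iterations):
        idx = rng.choice(exemplars.n_voxels, size=sample_voxels, replace=False)
        sub = exemplars.subsample_voxels(idx)
        true_folds = _fold_accuracies(sub.features, sub.labels, sub.runs, C)
        labels = permuted_labels(sub, rng, scheme)
        perm_folds = _fold_accuracies(sub.features, labels, sub.runs, C)
        if np.var(true_folds) == 0 and np.var(perm_folds) == 0:
            ps[i] = 1.0
            continue
        with warnings.catch_warnings():
            # fold accuracies take few discrete values; near-identical
            # samples legitimately occur and simply give p near 1
            warnings.simplefilter("ignore", RuntimeWarning)
            p = sp_stats.ttest_ind(true_folds, perm_folds).pvalue
        ps[i] = 1.0 if np.isnan(p) else float(p)
    return PValueHistogram(p_values=ps, sample_voxels=sample_voxels)
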