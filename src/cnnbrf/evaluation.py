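"""Cross-validation protocol, ranking metrics and case-study workflows.

Evaluation follows the rank-against-unlabeled protocol for bipartite link
prediction: known associations are split into five folds; for each fold
the held-out positives are zeroed in the training view, the full pipeline
is retrained, every pair is scored, and the AUC is the Mann-Whitney
probability that a held-out positive outscores a pair that is unlabeled
in the *full* dataset (ties credited ½). The 5-fold procedure is repeated
with fresh fold splits and the mean ± population standard deviation over
all fold AUCs is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .brf import BRFConfig
from .cnn_encoder import EncoderConfig
from .data_io import AssociationDataset
from .exceptions import ConfigurationError
from .model import MicrobeDrugModel, MicrobeDrugResults
from .pair_features import PairSet, enumerate_pairs
from .similarity import IntegratedSimilarities

__all__ = [
    "CVConfig",
    "CVResult",
    "FoldResult",
    "RankedPredictions",
    "rank_auc",
    "make_folds",
    "run_fold",
    "cross_validate",
    "pr_curve",
    "roc_points",
    "feature_correlation",
    "mask_drug",
    "rank_microbes_for_drug",
]


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def rank_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Mann-Whitney AUC: P(positive outscores negative), ties count ½."""
    pos = np.asarray(pos_scores, dtype=np.float64).ravel()
    neg = np.asarray(neg_scores, dtype=np.float64).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ConfigurationError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def pr_curve(
    pos_scores: np.ndarray, neg_scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precision/recall at every distinct threshold, descending.

    Returns ``(thresholds, recall, precision)``; a prediction is positive
    when its score is ≥ the threshold, so recall is monotone
    non-decreasing along the arrays.
    """
    pos = np.asarray(pos_scores, dtype=np.float64).ravel()
    neg = np.asarray(neg_scores, dtype=np.float64).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ConfigurationError("both score sets must be non-empty")
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    tp = (pos[None, :] >= thresholds[:, None]).sum(axis=1).astype(float)
    fp = (neg[None, :] >= thresholds[:, None]).sum(axis=1).astype(float)
    recall = tp / pos.size
    precision = tp / np.maximum(tp + fp, 1.0)
    return thresholds, recall, precision


def roc_points(
    pos_scores: np.ndarray, neg_scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points via scikit-learn's threshold sweep."""
    from sklearn.metrics import roc_curve

    y = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
    s = np.concatenate([pos_scores, neg_scores])
    fpr, tpr, _ = roc_curve(y, s)
    return fpr, tpr


def feature_correlation(
    encoded: np.ndarray,
) -> tuple[np.ndarray, dict]:
    """Pearson correlations between encoded feature columns.

    Constant columns get correlation 0 by convention and are listed in the
    summary under ``constant_columns``. The summary also describes the
    distribution of absolute off-diagonal correlations — the diagnostic for
    how independent the latent features are.
    """
    E = np.asarray(encoded, dtype=np.float64)
    if E.ndim != 2 or E.shape[1] < 2 or E.shape[0] < 3:
        raise ConfigurationError("need >= 3 rows and >= 2 columns")
    std = E.std(axis=0)
    constant = np.flatnonzero(std == 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        C = np.corrcoef(E, rowvar=False)
    C = np.nan_to_num(C, nan=0.0)
    C[constant, :] = 0.0
    C[:, constant] = 0.0
    np.fill_diagonal(C, 1.0)
    off = np.abs(C[np.triu_indices_from(C, k=1)])
    summary = {
        "mean_abs": float(off.mean()),
        "median_abs": float(np.median(off)),
        "max_abs": float(off.max()),
        "constant_columns": constant.tolist(),
    }
    return C, summary


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol parameters.

    ``negative_pool='full'`` scores held-out positives against every pair
    unlabeled in the full dataset (training-sampled negatives included —
    they are unlabeled too); ``'exclude_train_negatives'`` removes the
    sampled negatives from the pool. ``std_mode`` chooses whether the
    reported std is over all fold AUCs or over repeat means.
    """

    n_folds: int = 5
    n_repeats: int = 10
    sampler: str = "random"
    encoder_config: EncoderConfig = field(default_factory=EncoderConfig)
    brf_config: BRFConfig = field(default_factory=BRFConfig)
    master_seed: int = 0
    use_encoder: bool = True
    classifier: str = "brf"
    negative_pool: str = "full"
    std_mode: str = "folds"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")
        if self.negative_pool not in ("full", "exclude_train_negatives"):
            raise ConfigurationError("negative_pool: full|exclude_train_negatives")
        if self.std_mode not in ("folds", "repeat_means"):
            raise ConfigurationError("std_mode: folds|repeat_means")

    def repeat_seed(self, r: int) -> int:
        return int(
            np.random.SeedSequence([self.master_seed, r]).generate_state(1)[0]
            % (2**31)
        )


@dataclass
class FoldResult:
    auc: float
    pos_scores: np.ndarray
    neg_scores: np.ndarray
    results: MicrobeDrugResults | None = None


@dataclass
class CVResult:
    """Fold AUCs with mean ± std and per-repeat ROC/PR aggregates."""

    fold_aucs: np.ndarray  # (n_repeats, n_folds)
    mean_auc: float
    std_auc: float
    roc_by_repeat: list[tuple[np.ndarray, np.ndarray]]
    pr_by_repeat: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    config: CVConfig

    @property
    def repeat_means(self) -> np.ndarray:
        return self.fold_aucs.mean(axis=1)


def make_folds(positives: PairSet, n_folds: int, seed: int) -> list[PairSet]:
    """Seeded shuffle then contiguous chunking into n_folds disjoint test sets."""
    n = len(positives)
    if n < n_folds:
        raise ConfigurationError(f"{n} positives cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [positives.subset(chunk) for chunk in np.array_split(perm, n_folds)]


def mask_drug(dataset: AssociationDataset, drug: str) -> AssociationDataset:
    """Copy of the dataset with every association of *drug* zeroed."""
    u = dataset.drugs.position(drug)  # KeyError for unknown drugs
    A = dataset.A.copy()
    A[u, :] = 0
    return AssociationDataset(dataset.drugs, dataset.microbes, A)


def _training_view(dataset: AssociationDataset, test_pairs: PairSet) -> AssociationDataset:
    A = dataset.A.copy()
    if np.any(A[test_pairs.drug_index, test_pairs.microbe_index] != 1):
        raise ConfigurationError("test pairs must be known positives")
    A[test_pairs.drug_index, test_pairs.microbe_index] = 0
    return AssociationDataset(dataset.drugs, dataset.microbes, A)


def run_fold(
    dataset: AssociationDataset,
    sims: IntegratedSimilarities,
    test_pairs: PairSet,
    config: CVConfig,
    seed: int,
    *,
    keep_results: bool = False,
) -> FoldResult:
    """Train on the dataset with *test_pairs* zeroed, score everything.

    The held-out positives' scores are compared against the scores of all
    pairs unlabeled in the full dataset; the fold AUC is the tie-aware
    Mann-Whitney statistic of that comparison.
    """
    train_view = _training_view(dataset, test_pairs)
    model = MicrobeDrugModel(
        train_view,
        sims,
        encoder_config=config.encoder_config,
        brf_config=config.brf_config,
        sampler=config.sampler,
        use_encoder=config.use_encoder,
        classifier=config.classifier,
    )
    results = model.fit(seed=seed)
    scores = results.score_matrix

    pos_scores = scores[test_pairs.drug_index, test_pairs.microbe_index]
    neg_mask = dataset.A == 0
    if config.negative_pool == "exclude_train_negatives":
        neg = results.training_set.negatives
        neg_mask = neg_mask.copy()
        neg_mask[neg.drug_index, neg.microbe_index] = False
    neg_scores = scores[neg_mask]
    return FoldResult(
        auc=rank_auc(pos_scores, neg_scores),
        pos_scores=pos_scores,
        neg_scores=neg_scores,
        results=results if keep_results else None,
    )


def cross_validate(
    dataset: AssociationDataset,
    sims: IntegratedSimilarities,
    config: CVConfig | None = None,
    *,
    verbose: bool = False,
) -> CVResult:
    """Repeated k-fold cross-validation over the known associations."""
    config = config or CVConfig()
    pairs = enumerate_pairs(dataset)
    positives = pairs.subset(np.flatnonzero(pairs.label == 1))
    aucs = np.empty((config.n_repeats, config.n_folds))
    roc_by_repeat, pr_by_repeat = [], []
    for r in range(config.n_repeats):
        rs = config.repeat_seed(r)
        folds = make_folds(positives, config.n_folds, rs)
        pooled_pos, pooled_neg = [], []
        for f, test_pairs in enumerate(folds):
            fold = run_fold(dataset, sims, test_pairs, config, seed=rs + f)
            aucs[r, f] = fold.auc
            pooled_pos.append(fold.pos_scores)
            pooled_neg.append(fold.neg_scores)
            if verbose:
                print(f"repeat {r + 1} fold {f + 1}: AUC {fold.auc:.4f}")
        pp, pn = np.concatenate(pooled_pos), np.concatenate(pooled_neg)
        roc_by_repeat.append(roc_points(pp, pn))
        pr_by_repeat.append(pr_curve(pp, pn))
    flat = aucs.ravel() if config.std_mode == "folds" else aucs.mean(axis=1)
    return CVResult(
        fold_aucs=aucs,
        mean_auc=float(aucs.mean()),
        std_auc=float(np.std(flat)),  # population std
        roc_by_repeat=roc_by_repeat,
        pr_by_repeat=pr_by_repeat,
        config=config,
    )


# --------------------------------------------------------------------------
# case-study ranking
# --------------------------------------------------------------------------

def plot_curves(cv: "CVResult", path: str) -> None:
    """Save ROC and PR curves (last repeat's pooled scores) to *path*."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    fpr, tpr = cv.roc_by_repeat[-1]
    ax1.plot(fpr, tpr, label=f"AUC {cv.mean_auc:.3f}")
    ax1.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax1.set(xlabel="false positive rate", ylabel="true positive rate", title="ROC")
    ax1.legend()
    _, rec, prec = cv.pr_by_repeat[-1]
    ax2.plot(rec, prec)
    ax2.set(xlabel="recall", ylabel="precision", title="Precision-Recall")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass(frozen=True)
class RankedPredictions:
    """Top-k candidate microbes for one drug, best first."""

    drug: str
    ranking: tuple[tuple[str, float], ...]
    k: int


def rank_microbes_for_drug(
    results: MicrobeDrugResults, drug: str, k: int = 50
) -> RankedPredictions:
    """Rank candidate microbes for *drug* by descending association score.

    Microbes already associated with the drug in the training view are
    excluded; ties break toward the lower microbe index. When fewer than k
    candidates exist the list is truncated with a warning.
    """
    dataset = results.model.dataset
    u = dataset.drugs.position(drug)
    scores = results.score_matrix[u]
    candidates = np.flatnonzero(dataset.A[u] == 0)
    if k > candidates.size:
        warnings.warn(
            f"only {candidates.size} candidate microbes for {drug}; truncating top-{k}",
            stacklevel=2,
        )
        k = candidates.size
    # descending score, stable tie-break on microbe index
    order = candidates[np.lexsort((candidates, -scores[candidates]))][:k]
    ranking = tuple(
        (dataset.microbes.ids[v], float(scores[v])) for v in order
    )
    return RankedPredictions(drug=drug, ranking=ranking, k=k)
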