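"""Model / Results objects wiring the full prediction pipeline.

``MicrobeDrugModel`` holds the data (association dataset + integrated
similarities) and the hyperparameter configs; ``fit()`` assembles a
balanced training set, trains the convolutional encoder, fits the
Bernoulli random forest on the encoded features, scores every
microbe-drug pair and returns a ``MicrobeDrugResults`` carrying the
trained components, the nd × nm score matrix, diagnostics and a
``summary()`` table.

Alternative classifiers (plain random forest, logistic regression, kNN,
or the encoder's own sigmoid head) are available as thin reference
configurations for comparison runs; they are not reproductions of any
external published model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .brf import BRFConfig, BRFModel
from . import brf as _brf
from .cnn_encoder import EncoderConfig, TrainedEncoder, build_encoder, train_encoder
from .data_io import AssociationDataset
from .exceptions import ConfigurationError
from .pair_features import (
    PairSet,
    TrainingSet,
    build_training_set,
    feature_matrix,
    enumerate_pairs,
)
from .similarity import (
    IntegratedSimilarities,
    apply_structure_cutoff,
    integrate,
    jaccard_similarity,
)

__all__ = ["MicrobeDrugModel", "MicrobeDrugResults", "CLASSIFIERS"]

CLASSIFIERS = ("brf", "rf", "logreg", "knn", "cnn")


def _stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 fanned out from one master seed."""
    import zlib

    return int(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2**31)
    )


class MicrobeDrugModel:
    """Microbe-drug association predictor (encoder + Bernoulli forest).

    Parameters
    ----------
    dataset
        Known associations; its adjacency matrix supplies the positive
        labels (and only the labels — features come from similarities).
    sims
        Integrated drug/microbe similarity matrices aligned to the dataset
        catalogs.
    encoder_config, brf_config
        Hyperparameters; seeds inside them are overridden by the ``seed``
        passed to :meth:`fit` so one knob controls all randomness.
    sampler
        ``"random"`` (uniform) or ``"das"`` (density-aware stratified)
        negative sampling.
    use_encoder
        When False the classifier consumes raw pair features (the
        "without CNN" reference configuration).
    classifier
        ``"brf"`` (default), or a thin reference: ``"rf"``, ``"logreg"``,
        ``"knn"``, ``"cnn"`` (the encoder head alone).
    """

    def __init__(
        self,
        dataset: AssociationDataset,
        sims: IntegratedSimilarities,
        *,
        encoder_config: EncoderConfig | None = None,
        brf_config: BRFConfig | None = None,
        sampler: str = "random",
        use_encoder: bool = True,
        classifier: str = "brf",
    ) -> None:
        if classifier not in CLASSIFIERS:
            raise ConfigurationError(
                f"unknown classifier {classifier!r}; choose from {CLASSIFIERS}"
            )
        if dataset.n_drugs != sims.n_drugs or dataset.n_microbes != sims.n_microbes:
            raise ConfigurationError("dataset and similarities disagree on sizes")
        if classifier == "cnn" and not use_encoder:
            raise ConfigurationError("classifier 'cnn' requires use_encoder=True")
        self.dataset = dataset
        self.sims = sims
        self.encoder_config = encoder_config or EncoderConfig()
        self.brf_config = brf_config or BRFConfig()
        self.sampler = sampler
        self.use_encoder = use_encoder
        self.classifier = classifier

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_tables(
        cls,
        associations: str,
        structure_similarity: str,
        side_effects: str,
        microbe_similarity: str,
        *,
        cutoff: float = 0.5,
        **kwargs: Any,
    ) -> "MicrobeDrugModel":
        """Build a model straight from the four input files."""
        from . import data_io

        dataset = data_io.load_association_table(associations)
        ss2_raw = data_io.load_similarity_matrix(structure_similarity, dataset.drugs)
        mv = data_io.load_similarity_matrix(microbe_similarity, dataset.microbes)
        profiles = data_io.load_side_effects(side_effects)
        ss1 = jaccard_similarity(profiles, dataset.drugs)
        ss2 = apply_structure_cutoff(ss2_raw, cutoff)
        return cls(dataset, integrate(ss1, ss2, mv), **kwargs)

    @classmethod
    def from_synthetic(cls, spec=None, *, cutoff: float = 0.5, **kwargs: Any):
        """Convenience constructor around :func:`synthetic_data.generate`."""
        from .synthetic_data import generate

        dataset, drug_sim, profiles, microbe_sim = generate(spec)
        ss1 = jaccard_similarity(profiles, dataset.drugs)
        ss2 = apply_structure_cutoff(drug_sim, cutoff)
        return cls(dataset, integrate(ss1, ss2, microbe_sim), **kwargs)

    # -- fitting ----------------------------------------------------------
    def fit(self, seed: int = 0, *, compute_scores: bool = True) -> "MicrobeDrugResults":
        """Train encoder + classifier; returns the results object."""
        training = build_training_set(
            self.dataset, self.sims, sampler=self.sampler,
            seed=_stage_seed(seed, "negatives"),
        )
        X, y = training.design(self.sims)

        encoder: TrainedEncoder | None = None
        if self.use_encoder:
            enc_cfg = replace(self.encoder_config, seed=_stage_seed(seed, "encoder"))
            encoder = build_encoder(X.shape[1], enc_cfg)
            train_encoder(encoder, X, y)
            Z = encoder.encode(X)
        else:
            Z = X

        clf = self._fit_classifier(Z, y, seed)
        if self.classifier == "cnn":
            train_scores = encoder.predict_proba(X)
        else:
            train_scores = self._clf_scores(clf, Z)
        results = MicrobeDrugResults(
            model=self,
            seed=seed,
            training_set=training,
            encoder=encoder,
            classifier_name=self.classifier,
            classifier_=clf,
            train_scores=train_scores,
            train_labels=y,
        )
        if compute_scores:
            results.score_matrix  # noqa: B018 — materialise the cached property
        return results

    def _fit_classifier(self, Z: np.ndarray, y: np.ndarray, seed: int):
        s = _stage_seed(seed, "classifier")
        if self.classifier == "brf":
            return _brf.fit(Z, y, replace(self.brf_config, seed=s))
        if self.classifier == "cnn":
            return None  # the encoder head scores directly
        if self.classifier == "rf":
            from sklearn.ensemble import RandomForestClassifier

            clf = RandomForestClassifier(
                n_estimators=self.brf_config.n_trees, random_state=s
            )
        elif self.classifier == "logreg":
            from sklearn.linear_model import LogisticRegression

            clf = LogisticRegression(max_iter=1000, random_state=s)
        else:  # knn
            from sklearn.neighbors import KNeighborsClassifier

            clf = KNeighborsClassifier()
        clf.fit(Z, y.astype(int))
        return clf

    @staticmethod
    def _clf_scores(clf, Z: np.ndarray) -> np.ndarray:
        if isinstance(clf, BRFModel):
            return clf.predict_proba(Z)
        return clf.predict_proba(Z)[:, 1]


@dataclass
class MicrobeDrugResults:
    """Fitted pipeline: trained components, scores and diagnostics."""

    model: MicrobeDrugModel
    seed: int
    training_set: TrainingSet
    encoder: TrainedEncoder | None
    classifier_name: str
    classifier_: Any
    train_scores: np.ndarray
    train_labels: np.ndarray
    _score_matrix: np.ndarray | None = field(default=None, repr=False)

    # -- scoring ----------------------------------------------------------
    def score_pairs(self, pairs: PairSet, *, chunk: int = 16384) -> np.ndarray:
        """Association scores in [0, 1] for arbitrary pairs."""
        out = np.empty(len(pairs))
        for start in range(0, len(pairs), chunk):
            sub = pairs.subset(np.arange(start, min(start + chunk, len(pairs))))
            F = feature_matrix(sub, self.model.sims)
            if self.classifier_name == "cnn":
                out[start : start + len(sub)] = self.encoder.predict_proba(F)
                continue
            Z = self.encoder.encode(F) if self.encoder is not None else F
            if isinstance(self.classifier_, BRFModel):
                out[start : start + len(sub)] = self.classifier_.predict_proba(Z)
            else:
                out[start : start + len(sub)] = self.classifier_.predict_proba(Z)[:, 1]
        return out

    @property
    def score_matrix(self) -> np.ndarray:
        """nd × nm matrix of association scores for every pair."""
        if self._score_matrix is None:
            pairs = enumerate_pairs(self.model.dataset)
            self._score_matrix = self.score_pairs(pairs).reshape(
                self.model.dataset.n_drugs, self.model.dataset.n_microbes
            )
        return self._score_matrix

    def rank_microbes(self, drug: str, k: int = 50):
        """Top-k candidate microbes for *drug* (delegates to evaluation)."""
        from .evaluation import rank_microbes_for_drug

        return rank_microbes_for_drug(self, drug, k=k)

    # -- diagnostics ------------------------------------------------------
    def train_auc(self) -> float:
        from .evaluation import rank_auc

        return rank_auc(
            self.train_scores[self.train_labels == 1],
            self.train_scores[self.train_labels == 0],
        )

    def summary(self) -> str:
        """Human-readable fit report."""
        ds, m = self.model.dataset, self.model
        lines = [
            "Microbe-Drug Association Model Results",
            "=" * 46,
            f"{'drugs':<28}{ds.n_drugs:>18}",
            f"{'microbes':<28}{ds.n_microbes:>18}",
            f"{'known associations':<28}{ds.n_associations:>18}",
            f"{'training pairs (1:1)':<28}{2 * len(self.training_set.positives):>18}",
            f"{'negative sampler':<28}{m.sampler:>18}",
            f"{'classifier':<28}{self.classifier_name:>18}",
            f"{'encoder':<28}{('on' if self.encoder else 'off'):>18}",
        ]
        if self.encoder is not None:
            curve = self.encoder.training_loss_curve
            lines += [
                f"{'latent dimension':<28}{self.encoder.output_dim:>18}",
                f"{'encoder epochs':<28}{len(curve):>18}",
                f"{'loss first -> last epoch':<28}"
                f"{curve[0]:>9.4f} ->{curve[-1]:>7.4f}",
            ]
        if isinstance(self.classifier_, BRFModel):
            cfg = self.classifier_.config
            lines += [
                f"{'trees':<28}{cfg.n_trees:>18}",
                f"{'p1 / p2':<28}{f'{cfg.p1} / {cfg.p2}':>18}",
            ]
        lines += [
            f"{'training AUC':<28}{self.train_auc():>18.4f}",
            f"{'seed':<28}{self.seed:>18}",
            "=" * 46,
        ]
        return "\n".join(lines)
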