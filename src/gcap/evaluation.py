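"""Metrics and evaluation protocols.

AUC is the probability that a random positive outranks a random negative
(ties count half); AUPR is average precision with step-function integration.
Protocols: repeated stratified k-fold cross-validation over pairs,
incremental removal of known interactions per drug, leave-one-drug-out
(de novo / cold start), and a SMILES-sequence-similarity leakage filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .labeling import BenchmarkDataset, OUTCOME_CODES
from .model import GCAPModel, ModelConfig, PairFeatures
from .pipeline import FeaturizationContext
from .training import TrainingConfig, train


class UndefinedMetricError(ValueError):
    """Scores cannot be ranked: only one class present."""


def compute_auc(scores, labels) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise UndefinedMetricError("AUC needs both a positive and a negative label")
    return float(roc_auc_score(labels, scores))


def compute_aupr(scores, labels) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise UndefinedMetricError("AUPR needs both a positive and a negative label")
    return float(average_precision_score(labels, scores))


@dataclass
class EvalMetrics:
    """Task-1 AUC/AUPR plus per-class vectors for task 2.

    Classes without a positive test pair are flagged in ``excluded_classes``
    and carry NaN in the per-class vectors (excluded from averages).
    """

    auc: float
    aupr: float
    per_class_auc: np.ndarray = field(default_factory=lambda: np.full(7, np.nan))
    per_class_aupr: np.ndarray = field(default_factory=lambda: np.full(7, np.nan))
    excluded_classes: tuple[str, ...] = ()
    n_test: int = 0


def _score_in_chunks(
    model: GCAPModel, features: list[PairFeatures], chunk: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    assoc, classes = [], []
    for start in range(0, len(features), chunk):
        a, c, _ = model.forward_batch(features[start : start + chunk])
        assoc.append(a.data[:, 0])
        classes.append(c.data)
    return np.concatenate(assoc), np.vstack(classes)


def _evaluate_split(
    model: GCAPModel,
    test_feats: list[PairFeatures],
    y_serious: np.ndarray,
    y_classes: np.ndarray,
) -> EvalMetrics:
    assoc, cls = _score_in_chunks(model, test_feats)
    auc = compute_auc(assoc, y_serious)
    aupr = compute_aupr(assoc, y_serious)
    per_auc = np.full(7, np.nan)
    per_aupr = np.full(7, np.nan)
    excluded = []
    serious_mask = y_serious.astype(bool)
    for k, code in enumerate(OUTCOME_CODES):
        truth = y_classes[serious_mask, k]
        if truth.size == 0 or truth.min() == truth.max():
            excluded.append(code)
            continue
        per_auc[k] = compute_auc(cls[serious_mask, k], truth)
        per_aupr[k] = compute_aupr(cls[serious_mask, k], truth)
    return EvalMetrics(
        auc=auc,
        aupr=aupr,
        per_class_auc=per_auc,
        per_class_aupr=per_aupr,
        excluded_classes=tuple(excluded),
        n_test=len(test_feats),
    )


def _fold_matrices(
    context: FeaturizationContext, test_idx: np.ndarray
) -> np.ndarray:
    """Training-fold seriousness matrix: held-out pairs' entries zeroed."""
    r_ser = context.matrices.r_seriousness.copy()
    for p in test_idx:
        d, s = context.pairs[p]
        r_ser[context.matrices.drug_index[d], context.matrices.adr_index[s]] = 0
    return r_ser


def _train_and_eval(
    context: FeaturizationContext,
    model: GCAPModel,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    train_config: TrainingConfig,
    r_seriousness: np.ndarray | None = None,
    r_interaction: np.ndarray | None = None,
) -> EvalMetrics:
    r_ser = _fold_matrices(context, test_idx) if r_seriousness is None else r_seriousness
    train_feats = context.features_for(train_idx, r_seriousness=r_ser, r_interaction=r_interaction)
    test_feats = context.features_for(test_idx, r_seriousness=r_ser, r_interaction=r_interaction)
    result = train(
        model,
        train_feats,
        context.y_serious[train_idx],
        context.y_classes[train_idx],
        train_config,
    )
    if result.best_state is not None:
        model.load_state_dict(result.best_state)
    return _evaluate_split(
        model, test_feats, context.y_serious[test_idx], context.y_classes[test_idx]
    )


def cross_validate(
    context: FeaturizationContext,
    model_factory,
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
    train_config: TrainingConfig | None = None,
    reshuffle: bool = True,
) -> list[EvalMetrics]:
    """Repeated stratified k-fold CV over pairs (serious vs non-serious).

    Folds partition the pair set; each repeat reshuffles the folds (or, with
    ``reshuffle=False``, keeps the folds fixed and only reseeds the model).
    ``model_factory(context, seed)`` must return a fresh model.
    """
    y = context.y_serious.astype(int)
    if y.sum() < folds or (1 - y).sum() < folds:
        raise ValueError("fewer positives or negatives than folds")
    train_config = train_config or TrainingConfig()
    out: list[EvalMetrics] = []
    for rep in range(repeats):
        split_seed = seed + rep if reshuffle else seed
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=split_seed)
        for fold_id, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
            model = model_factory(context, seed + 1000 * rep + fold_id)
            cfg = TrainingConfig(
                alpha=train_config.alpha,
                learning_rate=train_config.learning_rate,
                batch_size=train_config.batch_size,
                epochs=train_config.epochs,
                seed=seed + 1000 * rep + fold_id,
                severity_mask_mode=train_config.severity_mask_mode,
            )
            out.append(_train_and_eval(context, model, tr, te, cfg))
    return out


def incremental_removal_eval(
    context: FeaturizationContext,
    model_factory,
    fractions: tuple[float, ...] = (0.1,),
    seed: int = 0,
    train_config: TrainingConfig | None = None,
    min_degree: int = 10,
) -> dict[float, EvalMetrics]:
    """Remove a fraction of each well-connected drug's interactions as test.

    For every drug with more than ``min_degree`` known interactions,
    ``floor(fraction * degree)`` (at least 1) randomly chosen pairs move to
    the test set; the model trains on the remainder.
    """
    train_config = train_config or TrainingConfig()
    rng = np.random.default_rng(seed)
    degree: dict[str, list[int]] = {}
    for p, (d, _) in enumerate(context.pairs):
        degree.setdefault(d, []).append(p)
    results: dict[float, EvalMetrics] = {}
    for frac in fractions:
        if not 0 < frac < 1:
            raise ValueError("fractions must lie in (0, 1)")
        test_idx: list[int] = []
        for d, plist in degree.items():
            if len(plist) > min_degree:
                k = max(1, int(np.floor(frac * len(plist))))
                test_idx.extend(rng.choice(plist, size=k, replace=False))
        if not test_idx:
            import warnings

            warnings.warn(f"fraction {frac} removed no pairs", stacklevel=2)
            continue
        test_idx = np.array(sorted(test_idx))
        train_idx = np.setdiff1d(np.arange(context.n_pairs), test_idx)
        model = model_factory(context, seed)
        results[frac] = _train_and_eval(
            context, model, train_idx, test_idx, train_config
        )
    return results


def de_novo_eval(
    context: FeaturizationContext,
    model_factory,
    train_config: TrainingConfig | None = None,
    seed: int = 0,
    drugs: list[str] | None = None,
) -> dict[str, EvalMetrics | None]:
    """Leave-one-drug-out cold start.

    The held-out drug's row is zeroed in both matrices (its profile features
    and its labels vanish from training); the model then scores all its
    pairs.  Drugs whose pairs are single-class get ``None`` (metric flagged
    undefined).
    """
    train_config = train_config or TrainingConfig()
    results: dict[str, EvalMetrics | None] = {}
    all_idx = np.arange(context.n_pairs)
    for drug in drugs if drugs is not None else context.dataset.drugs:
        i = context.matrices.drug_index[drug]
        test_idx = np.array([p for p, (d, _) in enumerate(context.pairs) if d == drug])
        train_idx = np.setdiff1d(all_idx, test_idx)
        r_int = context.matrices.r_interaction.copy()
        r_ser = context.matrices.r_seriousness.copy()
        r_int[i, :] = 0
        r_ser[i, :] = 0
        model = model_factory(context, seed)
        y_test = context.y_serious[test_idx]
        if y_test.size == 0 or y_test.min() == y_test.max():
            results[drug] = None
            continue
        results[drug] = _train_and_eval(
            context,
            model,
            train_idx,
            test_idx,
            train_config,
            r_seriousness=r_ser,
            r_interaction=r_int,
        )
    return results


def smiles_similarity(a: str, b: str) -> float:
    """Sequence similarity 1 - edit_distance(a, b) / max(|a|, |b|)."""
    if not a or not b:
        raise ValueError("empty SMILES string")
    dist = edlib.align(a, b)["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def leakage_filter(
    dataset: BenchmarkDataset,
    smiles_table: pd.DataFrame,
    query_drug: str,
    threshold: float = 0.9,
) -> BenchmarkDataset:
    """Drop training drugs too similar to the query drug.

    Removal applies to drugs (other than the query) whose SMILES sequence
    similarity to the query reaches the threshold; with ``threshold=1.0``
    only exact duplicates go.
    """
    smiles = dict(zip(smiles_table["drug"], smiles_table["smiles"]))
    query_smi = smiles[query_drug]
    drop = {
        d
        for d in dataset.drugs
        if d != query_drug and smiles_similarity(smiles[d], query_smi) >= threshold
    }
    keep_pairs = {(d, s) for (d, s) in dataset.interactions if d not in drop}
    return BenchmarkDataset(
        drugs=[d for d in dataset.drugs if d not in drop],
        adrs=list(dataset.adrs),
        interactions=keep_pairs,
        labels={p: lab for p, lab in dataset.labels.items() if p in keep_pairs},
        rejects=dataset.rejects,
    )
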