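"""Zero-shot molecule -> morphology retrieval and downstream probes.

Retrieval decodes a query molecule's latent mean into morphology space and
ranks every candidate profile by the likelihood of the decoded features
(higher likelihood = lower reconstruction NLL = better rank); a cosine
ranking on raw representations is provided as the encoder-style baseline.
Ranking quality is summarized with single-relevant NDCG@k and HIT@k.

Downstream evaluation fits a small feed-forward probe on frozen molecular
representations under a grouped (scaffold-style) split, reporting AUC for
classification tasks and MAE for regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.metrics import mean_absolute_error, roc_auc_score
from sklearn.neural_network import MLPClassifier, MLPRegressor

from .objective import reconstruction_nll

logger = logging.getLogger(__name__)

__all__ = [
    "RetrievalResult",
    "rank_by_decoded_likelihood",
    "rank_by_cosine",
    "ndcg_at_k",
    "hit_at_k",
    "grouped_split",
    "probe_evaluate",
]


@dataclass
class RetrievalResult:
    query_id: str
    ranked_candidate_ids: list[str]
    rank_of_truth: int  # 1-based
    scores: dict[str, float]


def _rank(query_id: str, ids: Sequence[str], scores: np.ndarray, truth_id: str | None) -> RetrievalResult:
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    ranked = [ids[i] for i in order]
    rank = ranked.index(truth_id) + 1 if truth_id is not None else 0
    return RetrievalResult(query_id, ranked, rank, {ids[i]: float(scores[i]) for i in order})


def rank_by_decoded_likelihood(
    molecule_id: str,
    decoded: np.ndarray,
    candidate_ids: Sequence[str],
    candidates: np.ndarray,
    truth_id: str | None = None,
    likelihood: str = "gaussian_mse",
) -> RetrievalResult:
    """Rank morphology candidates by likelihood of the decoded features.

    score(c) = -nll(decoded, c); ties break by candidate id.  ``decoded`` is
    the morphology decoder's output for the query molecule (callers usually
    decode the latent mean).
    """
    candidates = np.asarray(candidates, dtype=float)
    if len(candidate_ids) == 0:
        raise ValueError("candidate set must be nonempty")
    if candidates.shape[0] != len(candidate_ids):
        raise ValueError("candidate ids and matrix row count differ")
    decoded = np.asarray(decoded, dtype=float)
    if decoded.shape != candidates.shape[1:]:
        raise ValueError("decoded feature dimension does not match candidates")
    scores = np.array(
        [-reconstruction_nll(decoded, candidates[i], likelihood) for i in range(len(candidate_ids))]
    )
    return _rank(molecule_id, list(candidate_ids), scores, truth_id)


def rank_by_cosine(
    query_id: str,
    query_repr: np.ndarray,
    candidate_ids: Sequence[str],
    candidate_reprs: np.ndarray,
    truth_id: str | None = None,
) -> RetrievalResult:
    """Encoder-style baseline: rank candidates by cosine to the query vector."""
    q = np.asarray(query_repr, dtype=float)
    C = np.asarray(candidate_reprs, dtype=float)
    qn = np.linalg.norm(q)
    cn = np.linalg.norm(C, axis=1)
    scores = np.full(len(candidate_ids), -1.0)
    if qn == 0:
        logger.warning("zero-norm query vector %r; all scores set to -1", query_id)
    else:
        ok = cn > 0
        if not ok.all():
            logger.warning("%d zero-norm candidate vector(s) scored -1", int((~ok).sum()))
        scores[ok] = (C[ok] @ q) / (cn[ok] * qn)
    return _rank(query_id, list(candidate_ids), scores, truth_id)


def ndcg_at_k(rank_of_truth: int, k: int) -> float:
    """Single-relevant NDCG: 1 / log2(rank + 1) when rank <= k, else 0."""
    if rank_of_truth < 1 or k < 1:
        raise ValueError("rank and k must be >= 1")
    return 1.0 / math.log2(rank_of_truth + 1) if rank_of_truth <= k else 0.0


def hit_at_k(rank_of_truth: int, k: int) -> int:
    """1 iff the true candidate appears within the top k."""
    if rank_of_truth < 1 or k < 1:
        raise ValueError("rank and k must be >= 1")
    return int(rank_of_truth <= k)


# ---------------------------------------------------------------------------
# grouped (scaffold-style) splitting


def grouped_split(
    group_keys: Sequence,
    ratios: tuple[float, float, float] = (0.6, 0.15, 0.25),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic grouped split into (train, valid, test) index arrays.

    Items sharing a group key (e.g. a structural scaffold) are assigned
    atomically to one fold.  Target counts come from a largest-remainder
    apportionment of the ratios; groups are sorted by (size descending, key
    ascending) and fill test first, then valid, then train.
    """
    ratios = tuple(float(r) for r in ratios)
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be positive and sum to 1")
    keys = [str(k) for k in group_keys]
    n = len(keys)
    groups: dict[str, list[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    if len(groups) < 3:
        raise ValueError("need at least 3 groups to form 3 splits")

    # largest-remainder apportionment over (train, valid, test)
    raw = [r * n for r in ratios]
    counts = [int(math.floor(x)) for x in raw]
    remainder = n - sum(counts)
    frac_order = sorted(range(3), key=lambda i: (-(raw[i] - counts[i]), -i))  # ties -> test first
    for i in range(remainder):
        counts[frac_order[i % 3]] += 1
    target_train, target_valid, target_test = counts

    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    test: list[int] = []
    valid: list[int] = []
    train: list[int] = []
    for key, members in ordered:
        if len(test) < target_test:
            test.extend(members)
        elif len(valid) < target_valid:
            valid.extend(members)
        else:
            train.extend(members)
    return (np.array(sorted(train), dtype=int), np.array(sorted(valid), dtype=int),
            np.array(sorted(test), dtype=int))


# ---------------------------------------------------------------------------
# probes


def probe_evaluate(
    representations: np.ndarray,
    labels: np.ndarray,
    task_type: str,
    splits: tuple[np.ndarray, np.ndarray, np.ndarray],
    seed: int = 0,
    hidden: int = 32,
    alphas: Sequence[float] = (1e-4, 1e-2),
) -> dict:
    """Fit a small feed-forward probe per task; select on valid, score on test.

    ``labels`` is (n, n_tasks); NaN marks missing entries (multi-task).
    Classification reports per-task AUC (degenerate single-class test tasks
    are skipped and listed); regression reports MAE on the original scale.
    """
    if task_type not in ("classification", "regression"):
        raise ValueError("task_type must be 'classification' or 'regression'")
    X = np.asarray(representations, dtype=float)
    Y = np.atleast_2d(np.asarray(labels, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    train, valid, test = splits
    per_task: dict[int, float] = {}
    skipped: list[int] = []
    for t in range(Y.shape[1]):
        y = Y[:, t]
        tr = train[~np.isnan(y[train])]
        va = valid[~np.isnan(y[valid])]
        te = test[~np.isnan(y[test])]
        if task_type == "classification" and (len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2):
            logger.warning("task %d skipped: single class in train or test fold", t)
            skipped.append(t)
            continue
        if task_type == "regression" and (len(te) == 0 or len(tr) == 0):
            skipped.append(t)
            continue
        best_score, best_model = None, None
        for alpha in alphas:
            if task_type == "classification":
                model = MLPClassifier(hidden_layer_sizes=(hidden,), alpha=alpha,
                                      max_iter=500, random_state=seed)
                model.fit(X[tr], y[tr].astype(int))
                if len(va) and len(np.unique(y[va])) > 1:
                    score = roc_auc_score(y[va], model.predict_proba(X[va])[:, 1])
                else:
                    score = 0.0
            else:
                model = MLPRegressor(hidden_layer_sizes=(hidden,), alpha=alpha,
                                     max_iter=500, random_state=seed)
                model.fit(X[tr], y[tr])
                score = -mean_absolute_error(y[va], model.predict(X[va])) if len(va) else 0.0
            if best_score is None or score > best_score:
                best_score, best_model = score, model
        if task_type == "classification":
            per_task[t] = float(roc_auc_score(y[te], best_model.predict_proba(X[te])[:, 1]))
        else:
            per_task[t] = float(mean_absolute_error(y[te], best_model.predict(X[te])))
    metric = "auc" if task_type == "classification" else "mae"
    values = list(per_task.values())
    return {
        "metric": metric,
        "per_task": per_task,
        "mean": float(np.mean(values)) if values else float("nan"),
        "skipped_tasks": skipped,
        "n_train": int(len(train)),
        "n_valid": int(len(valid)),
        "n_test": int(len(test)),
    }
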