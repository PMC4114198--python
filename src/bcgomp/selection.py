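"""Insulation-subset selection: greedy OMP, ad hoc patterns, budget CV.

The estimator behind these wrappers is
:class:`bcgomp.estimators.OmpBcgInference`; functions here accept
channels x time :class:`Recording` objects.
"""

from __future__ import annotations

import numpy as np

from .core import ChannelSubset, InferenceModel, Recording, ValidationError
from .estimators import OmpBcgInference, OmpTrace

__all__ = [
    "fit_inference",
    "omp_select",
    "lines_pattern",
    "patches_pattern",
    "random_pattern",
    "cross_validate_budget",
    "OmpTrace",
]


def fit_inference(Xbcg: Recording, subset: ChannelSubset) -> InferenceModel:
    """Least-squares expanded inference matrix for a given subset.

    Minimises ``||X - W_tilde X[subset, :]||_F^2``; on row-rank-deficient
    selected rows the minimum-norm minimiser is returned (with a warning).
    """
    if len(subset) == 0:
        raise ValidationError("subset must contain at least one channel")
    if Xbcg.n_samples < len(subset):
        raise ValidationError(
            f"need T >= |subset| ({len(subset)}), got T={Xbcg.n_samples}")
    est = OmpBcgInference(subset=list(subset)).fit(Xbcg.data.T)
    return est.to_model(fs=Xbcg.fs, T=Xbcg.n_samples, method="explicit")


def omp_select(Xbcg: Recording, budget: int = 20,
               demean: bool = False) -> tuple[InferenceModel, OmpTrace]:
    """Greedy selection of ``budget`` channels with per-step LS refit."""
    est = OmpBcgInference(budget=budget, demean=demean,
                          keep_scores=True).fit(Xbcg.data.T)
    model = est.to_model(fs=Xbcg.fs, T=Xbcg.n_samples, method="omp",
                         budget=budget)
    return model, est.trace_


def _quadrant_centroids(positions: np.ndarray) -> list[np.ndarray]:
    """Centroids of the anterior/right/posterior/left angular quadrants."""
    center = positions.mean(axis=0)
    rel = positions - center
    ang = np.arctan2(rel[:, 1], rel[:, 0])          # 0 = right, pi/2 = front
    cents = []
    for a0 in (np.pi / 2, 0.0, -np.pi / 2, np.pi):  # anterior, R, posterior, L
        d = np.angle(np.exp(1j * (ang - a0)))
        members = np.abs(d) <= np.pi / 4
        if members.any():
            cents.append(positions[members].mean(axis=0))
        else:
            cents.append(center)
    return cents


def _nearest_free(positions, point, used) -> int:
    d = np.linalg.norm(positions - point, axis=1)
    for j in np.argsort(d):
        if int(j) not in used:
            return int(j)
    raise ValidationError("montage exhausted")


def lines_pattern(positions: np.ndarray, groups: int = 4,
                  per_group: int = 5) -> ChannelSubset:
    """Collinear nearest-neighbour runs, one per angular quadrant.

    Each run starts at the channel nearest the quadrant centroid and walks
    outward radially, always stepping to one of the current channel's
    nearest unused neighbours that makes the most radial progress.
    """
    if positions is None:
        raise ValidationError("lines pattern requires montage positions")
    positions = np.asarray(positions, dtype=float)
    C = positions.shape[0]
    if groups * per_group > C:
        raise ValidationError("pattern larger than montage")
    center = positions.mean(axis=0)
    cents = _quadrant_centroids(positions)
    used: set[int] = set()
    out: list[int] = []
    for g in range(groups):
        cent = cents[g % 4]
        d = cent - center
        nd = np.linalg.norm(d)
        direction = d / nd if nd > 0 else np.array([0.0, 1.0])
        cur = _nearest_free(positions, cent, used)
        used.add(cur)
        out.append(cur + 1)
        for _ in range(per_group - 1):
            dists = np.linalg.norm(positions - positions[cur], axis=1)
            order = [int(j) for j in np.argsort(dists)[1:]
                     if int(j) not in used]
            cand = order[:8]
            if not cand:
                raise ValidationError("montage exhausted")
            # forward progress along the radial direction, low lateral drift
            best, best_score = cand[0], -np.inf
            for j in cand:
                delta = positions[j] - positions[cur]
                fwd = float(delta @ direction)
                lat = abs(direction[0] * delta[1] - direction[1] * delta[0])
                score = fwd - 0.5 * lat
                if score > best_score:
                    best, best_score = j, score
            cur = best
            used.add(cur)
            out.append(cur + 1)
    return ChannelSubset(out, C)


def patches_pattern(positions: np.ndarray, groups: int = 4,
                    per_group: int = 5) -> ChannelSubset:
    """Circular patches: a centre channel per quadrant centroid plus its
    nearest unused neighbours."""
    if positions is None:
        raise ValidationError("patches pattern requires montage positions")
    positions = np.asarray(positions, dtype=float)
    C = positions.shape[0]
    if groups * per_group > C:
        raise ValidationError("pattern larger than montage")
    cents = _quadrant_centroids(positions)
    used: set[int] = set()
    out: list[int] = []
    for g in range(groups):
        cent = cents[g % 4]
        c0 = _nearest_free(positions, cent, used)
        used.add(c0)
        out.append(c0 + 1)
        dists = np.linalg.norm(positions - positions[c0], axis=1)
        added = 0
        for j in np.argsort(dists)[1:]:
            if added >= per_group - 1:
                break
            if int(j) in used:
                continue
            used.add(int(j))
            out.append(int(j) + 1)
            added += 1
    return ChannelSubset(out, C)


def random_pattern(C: int, budget: int, seed: int = 0) -> ChannelSubset:
    """Uniformly random ``budget``-subset of [1..C] (permutation order)."""
    if budget > C:
        raise ValidationError(f"budget {budget} exceeds C={C}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(C)[:budget]
    return ChannelSubset([int(i) + 1 for i in perm], C)


def cross_validate_budget(Xbcg: Recording, budgets, n_folds: int = 13):
    """Per-budget mean held-out artifact-estimation error.

    The recording is split into ``n_folds`` contiguous equal segments;
    for each fold the greedy selection is trained on that fold alone and
    the inference evaluated (ave nRMSE, %) on the concatenation of all
    other folds.  Returns a DataFrame with columns ``budget`` and
    ``mean_ave_nrmse``.
    """
    import pandas as pd

    from .evaluation import ave_nrmse

    budgets = sorted(int(b) for b in budgets)
    T = Xbcg.n_samples
    if n_folds < 1 or n_folds > T / Xbcg.fs:
        raise ValidationError(
            f"n_folds={n_folds} must be within [1, {T / Xbcg.fs:.0f}] "
            "(at least one second per fold)")
    fold_len = T // n_folds
    X = Xbcg.data
    errs = {b: [] for b in budgets}
    for k in range(n_folds):
        tr = X[:, k * fold_len: (k + 1) * fold_len]
        if n_folds == 1:
            te = tr
        else:
            te = np.concatenate(
                [X[:, : k * fold_len], X[:, (k + 1) * fold_len:]], axis=1)
        est = OmpBcgInference(budget=max(budgets)).fit(tr.T)
        order = list(est.subset_.indices)
        for b in budgets:
            sub = ChannelSubset(order[:b], Xbcg.n_channels)
            model = OmpBcgInference(subset=list(sub)).fit(tr.T).to_model()
            pred = model.W @ te[sub.row_indices]
            nins = sub.complement()
            errs[b].append(
                ave_nrmse(te[nins.row_indices], pred))
    return pd.DataFrame(
        {"budget": budgets,
         "mean_ave_nrmse": [float(np.mean(errs[b])) for b in budgets]})
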