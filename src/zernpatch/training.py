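"""Three-stage grid-search weight optimization on a hub-protein dataset.

A hub dataset collects proteins ("hubs") that bind several partners
through the same interface.  Superimposing two complexes of the same hub
puts the two partner interfaces into a common frame; patch pairs whose
seed points then lie within 5 Å are labeled as corresponding.  Partner
pairs with fewer than five correspondences are discarded, and a hub needs
at least two retained partners.

The weights are trained in three stages, each an exhaustive grid search
over 0.0–2.0 in steps of 0.1 (a coordinate-descent mode is available for
speed; objectives are deterministic either way, and ties resolve to the
lexicographically smallest weight vector):

1. feature weights — maximize the fraction of query patches whose
   minimum-pDist counterpart is a labeled correspondent;
2. patch-score weights — maximize the recovery of labeled correspondents
   by the auction matching;
3. interface-score weights — minimize the mean rank at which a query
   partner retrieves its co-hub partners from the pool of all partners.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import FEATURES, ScoreWeights
from .descriptors import PatchDescriptorSet
from .scoring import match_patches

__all__ = [
    "HubPartner",
    "HubDataset",
    "label_correspondences",
    "grid_search_feature_weights",
    "grid_search_patch_weights",
    "grid_search_ppi_weights",
]

GRID = np.round(np.arange(0.0, 2.0 + 1e-9, 0.1), 10)


@dataclass
class HubPartner:
    """One partner interface of a hub, with its transform into the hub frame."""

    hub_id: str
    name: str
    descriptors: PatchDescriptorSet
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def seeds_in_hub_frame(self) -> np.ndarray:
        return self.descriptors.seeds @ self.rotation.T + self.translation


def label_correspondences(
    complex_a: HubPartner,
    complex_b: HubPartner,
    cutoff: float = 5.0,
) -> list[tuple[int, int]]:
    """All patch pairs with seed distance < cutoff in the common hub frame.

    A patch may correspond to several patches; every such pair is kept.
    Raises when no pair qualifies.
    """
    sa = complex_a.seeds_in_hub_frame()
    sb = complex_b.seeds_in_hub_frame()
    d = np.sqrt(((sa[:, None, :] - sb[None, :, :]) ** 2).sum(-1))
    pairs = [(int(i), int(j)) for i, j in np.argwhere(d < cutoff)]
    if not pairs:
        raise ValueError(
            f"no corresponding patches between {complex_a.name} and {complex_b.name}"
        )
    return pairs


@dataclass
class HubDataset:
    """Partner interfaces plus labeled correspondences per partner pair."""

    partners: list[HubPartner]
    correspondences: dict[tuple[int, int], list[tuple[int, int]]]

    @classmethod
    def build(
        cls,
        partners: list[HubPartner],
        cutoff: float = 5.0,
        min_pairs: int = 5,
    ) -> "HubDataset":
        """Label all same-hub partner pairs, applying the retention rules.

        Partner pairs with fewer than ``min_pairs`` correspondences are
        discarded; partners left without any retained pair are dropped,
        and hubs must keep ≥ 2 partners.
        """
        corr: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for a in range(len(partners)):
            for b in range(a + 1, len(partners)):
                if partners[a].hub_id != partners[b].hub_id:
                    continue
                try:
                    pairs = label_correspondences(partners[a], partners[b], cutoff)
                except ValueError:
                    continue
                if len(pairs) >= min_pairs:
                    corr[(a, b)] = pairs
        used = sorted({i for ab in corr for i in ab})
        remap = {old: new for new, old in enumerate(used)}
        kept = [partners[i] for i in used]
        corr2 = {
            (remap[a], remap[b]): pairs for (a, b), pairs in corr.items()
        }
        hubs: dict[str, int] = {}
        for p in kept:
            hubs[p.hub_id] = hubs.get(p.hub_id, 0) + 1
        if not corr2 or all(v < 2 for v in hubs.values()):
            raise ValueError("hub dataset is empty after retention rules")
        return cls(partners=kept, correspondences=corr2)

    def hub_ids(self) -> list[str]:
        return [p.hub_id for p in self.partners]


def _query_blocks(dataset: HubDataset):
    """Per-(pair, direction) feature-distance tensors for stage 1.

    Yields (D, corr) with D of shape (n_query, n_candidate, 5) and boolean
    corr of the same leading shape; queries without any correspondent are
    dropped (they cannot be scored as success or failure).
    """
    blocks = []
    for (a, b), pairs in dataset.correspondences.items():
        da, db = dataset.partners[a].descriptors, dataset.partners[b].descriptors
        Fa = np.stack([da.feature_matrix(f) for f in FEATURES], axis=-1)
        Fb = np.stack([db.feature_matrix(f) for f in FEATURES], axis=-1)
        # distance per feature: (n_a, n_b, 5)
        D = np.sqrt(((Fa[:, None, :, :] - Fb[None, :, :, :]) ** 2).sum(axis=2))
        corr = np.zeros(D.shape[:2], dtype=bool)
        for i, j in pairs:
            corr[i, j] = True
        for Dq, mask in ((D, corr), (D.transpose(1, 0, 2), corr.T)):
            has = mask.any(axis=1)
            if has.any():
                blocks.append((Dq[has], mask[has]))
    return blocks


def _stage1_objective(blocks, W: np.ndarray, chunk: int = 20000) -> np.ndarray:
    """Success fraction for each weight row in W (shape (k, 5))."""
    total = sum(D.shape[0] for D, _ in blocks)
    successes = np.zeros(len(W))
    for start in range(0, len(W), chunk):
        Wc = W[start : start + chunk]
        succ = np.zeros(len(Wc))
        for D, mask in blocks:
            q, c, _ = D.shape
            S = D.reshape(q * c, 5) @ Wc.T
            arg = S.reshape(q, c, -1).argmin(axis=1)  # (q, k)
            succ += mask[np.arange(q)[:, None], arg].sum(axis=0)
        successes[start : start + len(Wc)] = succ
    return successes / total


def grid_search_feature_weights(
    dataset: HubDataset,
    grid: np.ndarray = GRID,
    method: str = "exhaustive",
) -> tuple[tuple[float, ...], float, list]:
    """Stage 1: feature weights by nearest-descriptor correspondent recovery.

    Returns (weights, objective, trace).  ``method='coordinate'`` sweeps
    one axis at a time (two passes) instead of the full 21⁵ grid.
    """
    blocks = _query_blocks(dataset)
    if not blocks:
        raise ValueError("dataset has no labeled queries")
    trace: list[tuple[tuple[float, ...], float]] = []
    if method == "exhaustive":
        W = np.array(list(itertools.product(grid, repeat=5)))
        obj = _stage1_objective(blocks, W)
        best = int(np.argmax(obj))  # first occurrence = lexicographically smallest
        trace.append((tuple(W[best]), float(obj[best])))
        return tuple(W[best]), float(obj[best]), trace
    if method != "coordinate":
        raise ValueError("method must be 'exhaustive' or 'coordinate'")
    w = np.zeros(5)
    for _ in range(2):
        for axis in range(5):
            cand = np.tile(w, (len(grid), 1))
            cand[:, axis] = grid
            obj = _stage1_objective(blocks, cand)
            w = cand[int(np.argmax(obj))].copy()
            trace.append((tuple(w), float(obj.max())))
    final = _stage1_objective(blocks, w[None, :])[0]
    return tuple(w), float(final), trace


def _stage2_objective(
    dataset: HubDataset,
    feature_w: tuple[float, ...],
    patch_w: tuple[float, float, float],
    denominator: str = "labels",
) -> float:
    w = ScoreWeights(feature_w=tuple(feature_w), patch_w=tuple(patch_w))
    identified = 0
    total = 0
    for (a, b), pairs in dataset.correspondences.items():
        da = dataset.partners[a].descriptors
        db = dataset.partners[b].descriptors
        match = match_patches(da, db, w)
        id_to_idx_a = {p.patch_id: i for i, p in enumerate(da.patches)}
        id_to_idx_b = {p.patch_id: i for i, p in enumerate(db.patches)}
        labeled = set(pairs)
        matched = {
            (id_to_idx_a[pa], id_to_idx_b[pb]) for pa, pb in match.pairs
        }
        identified += len(matched & labeled)
        total += len(labeled) if denominator == "labels" else len(matched)
    return identified / total if total else 0.0


def grid_search_patch_weights(
    dataset: HubDataset,
    feature_w: tuple[float, ...],
    grid: np.ndarray = GRID,
    method: str = "exhaustive",
    denominator: str = "labels",
) -> tuple[tuple[float, float, float], float, list]:
    """Stage 2: patch-score weights by auction correspondent recovery.

    ``denominator`` chooses whether recovery is measured against all
    labeled correspondence pairs (default) or against the matched pairs.
    """
    trace: list[tuple[tuple[float, ...], float]] = []
    best_w: tuple[float, float, float] | None = None
    best_obj = -1.0
    if method == "exhaustive":
        combos = itertools.product(grid, repeat=3)
    elif method == "coordinate":
        combos = None
    else:
        raise ValueError("method must be 'exhaustive' or 'coordinate'")
    if combos is not None:
        for wp, wr, wa in combos:
            obj = _stage2_objective(dataset, feature_w, (wp, wr, wa), denominator)
            if obj > best_obj:
                best_obj, best_w = obj, (float(wp), float(wr), float(wa))
                trace.append((best_w, best_obj))
        return best_w, best_obj, trace
    w = np.zeros(3)
    for _ in range(2):
        for axis in range(3):
            best_axis_obj, best_val = -1.0, w[axis]
            for g in grid:
                cand = w.copy()
                cand[axis] = g
                obj = _stage2_objective(dataset, feature_w, tuple(cand), denominator)
                if obj > best_axis_obj:
                    best_axis_obj, best_val = obj, g
            w[axis] = best_val
            trace.append((tuple(w), best_axis_obj))
    final = _stage2_objective(dataset, feature_w, tuple(w), denominator)
    return (float(w[0]), float(w[1]), float(w[2])), float(final), trace


def grid_search_ppi_weights(
    dataset: HubDataset,
    feature_w: tuple[float, ...] | None = None,
    patch_w: tuple[float, float, float] | None = None,
    grid: np.ndarray = GRID,
    min_partners: int = 3,
    chunk: int = 20000,
) -> tuple[tuple[float, float, float, float], float, list]:
    """Stage 3: interface-score weights by mean co-hub retrieval rank.

    Only hubs with ≥ ``min_partners`` partners provide queries; every
    partner in the dataset is a retrieval candidate.  The four averaged
    match terms are precomputed per partner pair with the (fixed) feature
    and patch weights, so the 21⁴ search is a pure reweighting.  Ranks are
    midranks: 1 + #(strictly smaller) + ½·#(tied others), so degenerate
    weight vectors that score every candidate equally are not rewarded.
    """
    base = ScoreWeights()
    w = ScoreWeights(
        feature_w=tuple(feature_w) if feature_w else base.feature_w,
        patch_w=tuple(patch_w) if patch_w else base.patch_w,
    )
    n = len(dataset.partners)
    hub_ids = dataset.hub_ids()
    counts: dict[str, int] = {}
    for h in hub_ids:
        counts[h] = counts.get(h, 0) + 1
    eligible = [i for i in range(n) if counts[hub_ids[i]] >= min_partners]
    if not eligible:
        raise ValueError(f"no hub has ≥ {min_partners} partners")

    terms = np.zeros((n, n, 4))
    for a in range(n):
        for b in range(a + 1, n):
            m = match_patches(
                dataset.partners[a].descriptors, dataset.partners[b].descriptors, w
            )
            t = (m.avg_pdist, m.avg_rmsd_term, m.avg_appd, m.sd)
            terms[a, b] = terms[b, a] = t

    queries = []
    for q in eligible:
        cands = [i for i in range(n) if i != q]
        true_mask = np.array([hub_ids[i] == hub_ids[q] for i in cands])
        if not true_mask.any():
            warnings.warn(f"query {dataset.partners[q].name} has no co-hub partner")
            continue
        queries.append((q, cands, true_mask))
    if not queries:
        raise ValueError("no usable queries")

    W = np.array(list(itertools.product(grid, repeat=4)))
    mean_rank = np.zeros(len(W))
    for start in range(0, len(W), chunk):
        Wc = W[start : start + chunk]
        rank_sum = np.zeros(len(Wc))
        n_true = 0
        for q, cands, true_mask in queries:
            T = terms[q, cands]  # (C, 4)
            S = T @ Wc.T  # (C, k)
            smaller = (S[None, :, :] < S[:, None, :]).sum(axis=1)
            tied = (S[None, :, :] == S[:, None, :]).sum(axis=1) - 1
            ranks = 1 + smaller + 0.5 * tied  # (C, k) midranks
            rank_sum += ranks[true_mask].sum(axis=0)
            n_true += int(true_mask.sum())
        mean_rank[start : start + len(Wc)] = rank_sum / n_true
    best = int(np.argmin(mean_rank))  # first occurrence = lexicographically smallest
    trace = [(tuple(W[best]), float(mean_rank[best]))]
    return tuple(W[best]), float(mean_rank[best]), trace
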