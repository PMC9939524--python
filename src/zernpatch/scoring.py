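"""Patch matching between two interfaces and the final interface score.

Patches of two interfaces are put in one-to-one correspondence with a
forward auction algorithm (ε-scaling bipartite assignment) minimizing a
per-pair cost built from the weighted descriptor distance (pDist), the
patch-position-histogram distance (APPD) and, after a Kabsch
superposition of matched seed points, the per-pair seed deviation.  The
matching objective is

    PatchScore = w_P · avg(pDist) + w_R · RMSD + w_A · avg(APPD)

and the final interface distance is

    Score = k_P · avg(pDist) + k_R · avg(deviation) + k_A · avg(APPD) + k_S · SD

where SD = |n_A − n_B| / max(n_A, n_B) penalizes interface size
difference.  The score is 0 for identical interfaces and symmetric in its
arguments (the smaller patch set always bids; equal sizes are ordered by
a canonical content key).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .config import FEATURES, ScoreWeights
from .descriptors import PatchDescriptors, PatchDescriptorSet
from .patching import APPHistogram
from .structure import ParameterizedStructure

__all__ = [
    "MatchResult",
    "SuperpositionResult",
    "pdist",
    "appd",
    "kabsch_superpose",
    "auction_assignment",
    "match_patches",
    "size_difference",
    "ppi_score",
    "zscore_rank",
    "identify_hotspot_patches",
]


def pdist(
    a: PatchDescriptors, b: PatchDescriptors, w: ScoreWeights | None = None
) -> float:
    """Weighted sum over features of Euclidean distances between descriptors."""
    w = w or ScoreWeights()
    total = 0.0
    for wi, feat in zip(w.feature_w, FEATURES):
        da, db = a.zernike[feat], b.zernike[feat]
        if len(da) != len(db):
            raise ValueError(f"descriptor length mismatch for feature {feat!r}")
        total += wi * float(np.linalg.norm(da - db))
    return total


def appd(a: APPHistogram, b: APPHistogram) -> float:
    """L2 distance between two normalized patch-position histograms."""
    if a.bin_width != b.bin_width or a.n_bins != b.n_bins:
        raise ValueError("incompatible histogram binning")
    return float(np.linalg.norm(a.bins - b.bins))


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    rmsd: float
    deviations: np.ndarray  # per-pair, Å
    degenerate: bool = False

    def transform(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.rotation.T + self.translation


def kabsch_superpose(pa: np.ndarray, pb: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of pa onto pb (proper rotation).

    One or two point pairs are treated as perfectly superimposable
    (RMSD 0, flagged degenerate): they do not constrain a rotation in a
    way that is useful for scoring.
    """
    pa = np.asarray(pa, dtype=float).reshape(-1, 3)
    pb = np.asarray(pb, dtype=float).reshape(-1, 3)
    if len(pa) != len(pb):
        raise ValueError("point sets must have equal counts")
    if len(pa) == 0:
        raise ValueError("point sets must be non-empty")
    if len(pa) <= 2:
        t = pb.mean(axis=0) - pa.mean(axis=0)
        return SuperpositionResult(
            rotation=np.eye(3),
            translation=t,
            rmsd=0.0,
            deviations=np.zeros(len(pa)),
            degenerate=True,
        )
    ca, cb = pa.mean(axis=0), pb.mean(axis=0)
    H = (pa - ca).T @ (pb - cb)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    moved = pa @ R.T + t
    dev = np.sqrt(((moved - pb) ** 2).sum(axis=1))
    rmsd = float(np.sqrt((dev**2).mean()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, deviations=dev)


def auction_assignment(
    cost: np.ndarray,
    eps0: float | None = None,
    final_eps: float | None = None,
    scale: float = 5.0,
) -> np.ndarray:
    """Minimum-cost assignment of rows onto columns by forward auction.

    ``cost`` has shape (n_rows, n_cols) with n_rows ≤ n_cols.  ε-scaling
    starts at ε₀ = max cost / (n + 1) and divides by ``scale`` until
    ε < 1/n (n = number of columns); the returned assignment cost is
    within n·ε_final of the optimum.  Bid ties resolve to the
    lowest-index column, and unassigned rows bid in increasing index
    order, making the procedure deterministic.

    Returns ``col_of_row`` with one column index per row.
    """
    cost = np.asarray(cost, dtype=float)
    n_real, n_cols = cost.shape
    if n_real > n_cols:
        raise ValueError("auction requires n_rows ≤ n_cols")
    n = n_cols
    max_abs = float(np.abs(cost).max()) if cost.size else 0.0
    if n_real < n_cols:
        # pad to a square problem with constant-cost dummy rows: dummies
        # are indifferent between columns, so the real rows receive the
        # optimal rectangular assignment and the ε-guarantee is preserved
        # (plain forward auction is only ε-optimal on square problems)
        pad = np.full((n_cols - n_real, n_cols), max_abs)
        cost = np.vstack([cost, pad])
    n_rows = n_cols
    benefit = -cost
    if eps0 is None:
        eps0 = max(max_abs / (n + 1), 1e-9)
    if final_eps is None:
        final_eps = 0.5 / n
    prices = np.zeros(n_cols)
    eps = max(eps0, final_eps)
    col_of_row = np.full(n_rows, -1, dtype=int)
    row_of_col = np.full(n_cols, -1, dtype=int)
    while True:
        col_of_row.fill(-1)
        row_of_col.fill(-1)
        while True:
            unassigned = np.flatnonzero(col_of_row < 0)
            if unassigned.size == 0:
                break
            i = unassigned[0]
            values = benefit[i] - prices
            j = int(np.argmax(values))  # argmax takes the lowest index on ties
            w1 = values[j]
            if n_cols > 1:
                others = np.delete(values, j)
                w2 = others.max()
            else:
                w2 = w1 - eps
            prices[j] += w1 - w2 + eps
            prev = row_of_col[j]
            if prev >= 0:
                col_of_row[prev] = -1
            row_of_col[j] = i
            col_of_row[i] = j
        if eps <= final_eps:
            return col_of_row[:n_real]
        eps = max(eps / scale, final_eps)


@dataclass
class MatchResult:
    """Patch correspondence between two interfaces plus score terms.

    ``pairs`` holds (patch_id_A, patch_id_B) in the caller's argument
    order, regardless of which side acted as the auction bidder.
    """

    pairs: list[tuple[int, int]]
    pair_pdist: np.ndarray
    pair_appd: np.ndarray
    pair_deviation: np.ndarray
    rmsd: float
    avg_pdist: float
    avg_rmsd_term: float
    avg_appd: float
    sd: float
    patch_score: float
    ppi_score: float
    n_a: int = 0
    n_b: int = 0
    seeds_a: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    seeds_b: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    degenerate_superposition: bool = False


def size_difference(n_a: int, n_b: int) -> float:
    """|n_A − n_B| divided by the larger patch count."""
    if n_a < 1 or n_b < 1:
        raise ValueError("patch counts must be ≥ 1")
    return abs(n_a - n_b) / max(n_a, n_b)


def _canonical_key(dset: PatchDescriptorSet) -> bytes:
    parts = [p.zernike[f].tobytes() for p in dset.patches for f in FEATURES]
    parts += [np.asarray(p.seed, dtype=float).tobytes() for p in dset.patches]
    return b"".join(parts)


def match_patches(
    A: PatchDescriptorSet,
    B: PatchDescriptorSet,
    w: ScoreWeights | None = None,
    max_iter: int = 10,
) -> MatchResult:
    """Auction matching of patches, iterated with superposition feedback.

    The initial per-pair cost is w_P·pDist + w_A·APPD.  After each
    assignment the matched seed points are Kabsch-superposed and the cost
    gains a w_R·deviation term (deviation of every candidate pair under
    the current superposition); the loop stops when the assignment is
    stable or after ``max_iter`` rounds.  The smaller patch set always
    bids; equal-size inputs are ordered by a canonical content key, so the
    result is symmetric in A and B.
    """
    if len(A) == 0 or len(B) == 0:
        raise ValueError("cannot match empty patch sets")
    w = w or ScoreWeights()
    if A.order != B.order:
        raise ValueError("descriptor order mismatch")
    swapped = len(A) > len(B) or (
        len(A) == len(B) and _canonical_key(A) > _canonical_key(B)
    )
    S, L = (B, A) if swapped else (A, B)  # S bids onto L

    w_p, w_r, w_a = w.patch_w
    n_s, n_l = len(S), len(L)
    P = np.empty((n_s, n_l))
    D = np.empty((n_s, n_l))
    for i, ps in enumerate(S.patches):
        for j, pl in enumerate(L.patches):
            P[i, j] = pdist(ps, pl, w)
            D[i, j] = appd(ps.app, pl.app)
    base_cost = w_p * P + w_a * D

    assign = auction_assignment(base_cost)
    seeds_s, seeds_l = S.seeds, L.seeds
    sup = kabsch_superpose(seeds_s, seeds_l[assign])
    for _ in range(max_iter):
        moved = sup.transform(seeds_s)
        delta = np.sqrt(((moved[:, None, :] - seeds_l[None, :, :]) ** 2).sum(-1))
        new_assign = auction_assignment(base_cost + w_r * delta)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        sup = kabsch_superpose(seeds_s, seeds_l[assign])

    sup = kabsch_superpose(seeds_s, seeds_l[assign])
    pair_pdist = P[np.arange(n_s), assign]
    pair_appd = D[np.arange(n_s), assign]
    pair_dev = sup.deviations
    avg_pdist = float(pair_pdist.mean())
    avg_appd = float(pair_appd.mean())
    avg_dev = float(pair_dev.mean())
    patch_score = w_p * avg_pdist + w_r * sup.rmsd + w_a * avg_appd

    sd = size_difference(len(A), len(B))
    k_p, k_r, k_a, k_s = w.ppi_k
    score = k_p * avg_pdist + k_r * avg_dev + k_a * avg_appd + k_s * sd

    ids_s = [p.patch_id for p in S.patches]
    ids_l = [p.patch_id for p in L.patches]
    if swapped:
        pairs = [(ids_l[j], ids_s[i]) for i, j in enumerate(assign)]
        seeds_a, seeds_b = seeds_l[assign], seeds_s
    else:
        pairs = [(ids_s[i], ids_l[j]) for i, j in enumerate(assign)]
        seeds_a, seeds_b = seeds_s, seeds_l[assign]
    return MatchResult(
        pairs=pairs,
        pair_pdist=pair_pdist,
        pair_appd=pair_appd,
        pair_deviation=pair_dev,
        rmsd=sup.rmsd,
        avg_pdist=avg_pdist,
        avg_rmsd_term=avg_dev,
        avg_appd=avg_appd,
        sd=sd,
        patch_score=patch_score,
        ppi_score=score,
        n_a=len(A),
        n_b=len(B),
        seeds_a=seeds_a,
        seeds_b=seeds_b,
        degenerate_superposition=sup.degenerate,
    )


def ppi_score(
    match: MatchResult, n_a: int, n_b: int, w: ScoreWeights | None = None
) -> float:
    """Recombine a match's averaged terms into the interface distance."""
    if not match.pairs:
        raise ValueError("match has no pairs")
    w = w or ScoreWeights()
    k_p, k_r, k_a, k_s = w.ppi_k
    return (
        k_p * match.avg_pdist
        + k_r * match.avg_rmsd_term
        + k_a * match.avg_appd
        + k_s * size_difference(n_a, n_b)
    )


def zscore_rank(
    references: Sequence[Mapping[str, float]],
) -> list[tuple[str, float]]:
    """Average per-reference Z-scores and rank ascending (most similar first).

    Each reference is a mapping query → interface score.  Z-scores use the
    population standard deviation within each reference; zero variance is
    an error.  All references must score the same queries.
    """
    if not references:
        raise ValueError("at least one reference score set required")
    keys = list(references[0].keys())
    for ref in references:
        if set(ref.keys()) != set(keys):
            raise ValueError("reference score sets must share queries")
        if len(ref) < 2:
            raise ValueError("need at least 2 scores per reference set")
    z_sum = {k: 0.0 for k in keys}
    for ref in references:
        vals = np.array([ref[k] for k in keys], dtype=float)
        std = vals.std()  # population
        if std == 0:
            raise ValueError("zero variance in a reference score set")
        mean = vals.mean()
        for k in keys:
            z_sum[k] += (ref[k] - mean) / std
    avg = {k: z_sum[k] / len(references) for k in keys}
    return sorted(avg.items(), key=lambda kv: (kv[1], kv[0]))


def identify_hotspot_patches(
    match: MatchResult,
    structure: ParameterizedStructure,
    hotspot_residues: Sequence[tuple[str, int]],
    cutoff: float = 5.0,
    side: str = "a",
) -> list[dict]:
    """Flag matched patches whose seed lies < cutoff from a hotspot residue.

    ``hotspot_residues`` lists (chain_id, residue_seq) pairs on
    ``structure`` (the complex the chosen ``side`` of the match belongs
    to).  Returns one record per hotspot patch with the covered residues.
    """
    seeds = match.seeds_a if side == "a" else match.seeds_b
    pair_ids = [p[0 if side == "a" else 1] for p in match.pairs]
    results = []
    residue_atoms: dict[tuple[str, int], list[np.ndarray]] = {}
    for atom in structure.heavy_atoms():
        residue_atoms.setdefault((atom.chain_id, atom.residue_seq), []).append(
            np.asarray(atom.position)
        )
    for chain, seq in hotspot_residues:
        if (chain, seq) not in residue_atoms:
            raise ValueError(f"unknown hotspot residue {chain}{seq}")
    for pid, seed in zip(pair_ids, seeds):
        covered = []
        for chain, seq in hotspot_residues:
            xyz = np.array(residue_atoms[(chain, seq)])
            if np.sqrt(((xyz - seed) ** 2).sum(1)).min() < cutoff:
                covered.append((chain, seq))
        if covered:
            results.append(
                {"patch_id": int(pid), "seed": seed, "residues": covered}
            )
    return results
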