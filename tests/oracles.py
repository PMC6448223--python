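"""Independent reference implementations used to pin algorithm semantics.

These deliberately avoid the code paths they check: clustering is a
literal transliteration of the greedy rule with explicit Python loops, and
the superposition oracle minimizes RMSD numerically over a quaternion
parameterization instead of solving in closed form.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def brute_force_qt(d: np.ndarray, cutoff: float, max_clusters: int = 5):
    """Literal greedy quality-threshold clustering.

    Returns (labels, populations, founders) with labels 1..K and 0 for
    unclustered; ties on neighbor count break to the lowest frame index.
    """
    n = d.shape[0]
    labels = [0] * n
    unassigned = set(range(n))
    populations, founders = [], []
    for rank in range(1, max_clusters + 1):
        if not unassigned:
            break
        best_frame, best_count = None, -1
        for i in sorted(unassigned):
            count = sum(1 for j in unassigned if d[i][j] <= cutoff)
            if count > best_count:
                best_frame, best_count = i, count
        members = [j for j in sorted(unassigned) if d[best_frame][j] <= cutoff]
        for j in members:
            labels[j] = rank
        unassigned -= set(members)
        populations.append(len(members))
        founders.append(best_frame)
    return np.array(labels), populations, founders


def _quat_to_rot(q: np.ndarray) -> np.ndarray:
    q = q / np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quaternion_min_rmsd(mobile: np.ndarray, reference: np.ndarray,
                        n_restarts: int = 8, seed: int = 0) -> float:
    """Minimum RMSD over proper rotations + translation, found numerically.

    Centers both point sets (the optimal translation maps centroid to
    centroid) and minimizes over unit quaternions with multiple restarts.
    """
    pm = mobile - mobile.mean(axis=0)
    pr = reference - reference.mean(axis=0)

    def objective(q: np.ndarray) -> float:
        rot = _quat_to_rot(q)
        return float(np.sqrt(np.mean(np.sum((pm @ rot.T - pr) ** 2, axis=1))))

    rng = np.random.default_rng(seed)
    best = np.inf
    starts = [np.array([1.0, 0, 0, 0])] + [
        rng.normal(size=4) for _ in range(n_restarts - 1)
    ]
    for q0 in starts:
        res = minimize(objective, q0 / np.linalg.norm(q0), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
        best = min(best, res.fun)
    return best


def label_accuracy(true_labels: np.ndarray, found_labels: np.ndarray) -> float:
    """Best-matching fraction of agreeing labels (Hungarian assignment)."""
    from scipy.optimize import linear_sum_assignment

    true_ids = np.unique(true_labels)
    found_ids = np.unique(found_labels)
    confusion = np.zeros((len(true_ids), len(found_ids)))
    for a, t in enumerate(true_ids):
        for b, f in enumerate(found_ids):
            confusion[a, b] = np.sum((true_labels == t) & (found_labels == f))
    rows, cols = linear_sum_assignment(-confusion)
    return confusion[rows, cols].sum() / true_labels.size


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return _quat_to_rot(q / np.linalg.norm(q))
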