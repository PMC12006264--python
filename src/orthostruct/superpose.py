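"""Alignment-guided rigid superposition with iterative pruning.

Residue pairs come from the study's multiple sequence alignment (not
from a structural aligner), so every deviation is attributable to an
alignment column and comparable across species.  The fit is a standard
least-squares rigid superposition (Kabsch, via SVD, reflection
corrected) refined Matchmaker-style: fit, drop pairs deviating more than
the prune cutoff, refit, until the retained set stabilises.  Under the
final transform every pair — pruned or not — gets a CA–CA deviation, and
pairs are classed matched (< 2 Å), different (≥ 2 Å) or unscored when
either residue sits in a low-confidence region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AlignmentFrame, StructureModel
from .msa_map import build_column_map
from .order_disorder import OrderMask

__all__ = [
    "ResiduePairing",
    "SuperpositionResult",
    "pair_residues",
    "kabsch_fit",
    "matchmaker_superpose",
    "classify_pairs",
    "species_specific_differences",
    "RMSD_MATCH_THRESHOLD",
]

#: CA–CA deviation below which a confident pair counts as structurally
#: matched; at or above it, significantly different.
RMSD_MATCH_THRESHOLD = 2.0


@dataclass(frozen=True)
class ResiduePairing:
    """CA-paired residues of two models over shared alignment columns."""

    id_a: str
    id_b: str
    columns: np.ndarray    # (n,) strictly increasing alignment columns
    index_a: np.ndarray    # (n,) 0-based residue indices into model A
    index_b: np.ndarray
    coords_a: np.ndarray   # (n,3) CA coordinates
    coords_b: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.columns) <= 0):
            raise ValueError("pairing columns must be strictly increasing")

    def __len__(self) -> int:
        return len(self.columns)


def pair_residues(
    frame: AlignmentFrame, id_a: str, id_b: str,
    model_a: StructureModel, model_b: StructureModel,
) -> ResiduePairing:
    """Pair residues of two models through their alignment rows.

    Models must match their rows' ungapped sequences residue-for-residue;
    columns where either side is gapped or lacks a CA atom are excluded
    (a missing CA draws a warning).
    """
    for rid, model in ((id_a, model_a), (id_b, model_b)):
        seq = frame.sequence(rid).residues
        if len(seq) != len(model):
            raise ValueError(
                f"{rid!r}: alignment row has {len(seq)} residues but model "
                f"has {len(model)}"
            )
        for i, (s, r) in enumerate(zip(seq, model.residues)):
            if s != "X" and r.one_letter != "X" and s != r.one_letter:
                raise ValueError(
                    f"{rid!r}: residue {i + 1} is {s} in the alignment but "
                    f"{r.one_letter} in the model"
                )
    cmap = build_column_map(frame)
    ca_a, ca_b = model_a.ca_coords(), model_b.ca_coords()
    cols, ia, ib, pa, pb = [], [], [], [], []
    for c in range(1, frame.n_columns + 1):
        ra = cmap.residue_at(id_a, c)
        rb = cmap.residue_at(id_b, c)
        if ra == 0 or rb == 0:
            continue
        if np.any(np.isnan(ca_a[ra - 1])) or np.any(np.isnan(ca_b[rb - 1])):
            import warnings
            warnings.warn(f"column {c}: residue without CA excluded from pairing")
            continue
        cols.append(c)
        ia.append(ra - 1)
        ib.append(rb - 1)
        pa.append(ca_a[ra - 1])
        pb.append(ca_b[rb - 1])
    return ResiduePairing(
        id_a, id_b,
        np.array(cols, dtype=np.int64),
        np.array(ia, dtype=np.int64),
        np.array(ib, dtype=np.int64),
        np.array(pa, dtype=float).reshape(-1, 3),
        np.array(pb, dtype=float).reshape(-1, 3),
    )


def kabsch_fit(
    points_a: np.ndarray, points_b: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of B onto A.

    Returns (rotation R, translation t, rmsd) minimising
    Σ wᵢ‖aᵢ − (R bᵢ + t)‖²; R is a proper rotation (reflection
    corrected).  Requires ≥ 3 non-collinear points.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"point sets must both be (n,3); got {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 point pairs, got {n}")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    ca = w @ a
    cb = w @ b
    a0 = a - ca
    b0 = b - cb
    # covariance rank < 2 means the configuration is (nearly) collinear
    h = (b0 * w[:, None]).T @ a0
    u, s, vt = np.linalg.svd(h)
    scale = max(s[0], 1e-12)
    if s[1] / scale < 1e-8:
        raise ValueError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = ca - rot @ cb
    resid = a - (b @ rot.T + t)
    rmsd = float(np.sqrt(np.sum(w * np.sum(resid**2, axis=1))))
    return rot, t, rmsd


@dataclass(frozen=True)
class SuperpositionResult:
    """Outcome of a pruned rigid superposition over a residue pairing."""

    pairing: ResiduePairing
    rotation: np.ndarray       # (3,3), proper
    translation: np.ndarray    # (3,)
    retained: np.ndarray       # (n,) bool — pairs used in the final fit
    deviations: np.ndarray     # (n,) CA–CA Å under the final transform
    rmsd: float                # over retained pairs
    n_iterations: int
    classes: tuple[str, ...] = ()  # filled by classify_pairs

    def __post_init__(self):
        r = self.rotation
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > 1e-6:
            raise ValueError("rotation is not proper (det != +1)")

    def transformed_b(self) -> np.ndarray:
        return self.pairing.coords_b @ self.rotation.T + self.translation


def matchmaker_superpose(
    pairing: ResiduePairing,
    prune_cutoff: float = 2.0,
    max_iter: int = 100,
) -> SuperpositionResult:
    """Iteratively pruned rigid superposition of a residue pairing.

    Fit on retained pairs, drop pairs whose deviation exceeds the prune
    cutoff, refit; stop when the retained set stops changing, at
    ``max_iter``, or when pruning would leave fewer than 3 pairs.  Final
    deviations are computed for ALL pairs under the final transform.
    """
    n = len(pairing)
    if n < 3:
        raise ValueError(f"pairing has {n} pairs; need at least 3")
    retained = np.ones(n, dtype=bool)
    rot = np.eye(3)
    t = np.zeros(3)
    iters = 0
    for iters in range(1, max_iter + 1):
        rot, t, _ = kabsch_fit(pairing.coords_a[retained], pairing.coords_b[retained])
        moved = pairing.coords_b @ rot.T + t
        dev = np.linalg.norm(pairing.coords_a - moved, axis=1)
        keep = retained & (dev <= prune_cutoff)
        if keep.sum() < 3 or np.array_equal(keep, retained):
            break
        retained = keep
    moved = pairing.coords_b @ rot.T + t
    deviations = np.linalg.norm(pairing.coords_a - moved, axis=1)
    rmsd = float(np.sqrt(np.mean(deviations[retained] ** 2)))
    return SuperpositionResult(pairing, rot, t, retained, deviations, rmsd, iters)


def classify_pairs(
    result: SuperpositionResult,
    mask_a: OrderMask | None = None,
    mask_b: OrderMask | None = None,
    rmsd_threshold: float = RMSD_MATCH_THRESHOLD,
) -> SuperpositionResult:
    """Class every pair: matched (< threshold), different (≥ threshold),
    or unscored when either residue's confidence is low.

    Masks are indexed by model residue order; absent masks mean all
    residues are treated as confident.
    """
    p = result.pairing
    classes = []
    for k in range(len(p)):
        conf_a = mask_a.confidence_state[p.index_a[k]] if mask_a else "confident"
        conf_b = mask_b.confidence_state[p.index_b[k]] if mask_b else "confident"
        if conf_a == "low" or conf_b == "low":
            classes.append("unscored")
        elif result.deviations[k] < rmsd_threshold:
            classes.append("matched")
        else:
            classes.append("different")
    return SuperpositionResult(
        p, result.rotation, result.translation, result.retained,
        result.deviations, result.rmsd, result.n_iterations, tuple(classes),
    )


def species_specific_differences(
    results: dict[tuple[str, str], SuperpositionResult],
    focal_id: str,
) -> dict[int, dict[tuple[str, str], str]]:
    """Columns structurally different in every pairing with the focal
    species but matched among all the others.

    ``results`` maps species-id pairs to classified superpositions that
    must share one alignment frame.  Returns column → per-pairing class
    evidence for the columns that qualify.
    """
    if not results:
        return {}
    focal_pairs = {k: v for k, v in results.items() if focal_id in k}
    other_pairs = {k: v for k, v in results.items() if focal_id not in k}
    if not focal_pairs:
        raise ValueError(f"no pairings involve focal species {focal_id!r}")
    if len({tuple(sorted(k)) for k in results}) != len(results):
        raise ValueError("duplicate species pairs in results")
    class_by_col: dict[tuple[str, str], dict[int, str]] = {}
    for key, res in results.items():
        if not res.classes:
            raise ValueError(f"pairing {key} has not been classified")
        class_by_col[key] = dict(zip(res.pairing.columns.tolist(), res.classes))
    candidate_cols: set[int] | None = None
    for key, cbc in class_by_col.items():
        if key in focal_pairs:
            cols = {c for c, cl in cbc.items() if cl == "different"}
            candidate_cols = cols if candidate_cols is None else candidate_cols & cols
    if not candidate_cols:
        return {}
    out: dict[int, dict[tuple[str, str], str]] = {}
    for c in sorted(candidate_cols):
        ok = all(
            class_by_col[key].get(c) == "matched" for key in other_pairs
        )
        if ok:
            out[c] = {key: class_by_col[key].get(c, "absent") for key in results}
    return out
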