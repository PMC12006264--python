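"""The shared alignment-column coordinate system.

Every cross-species statement in the pipeline (substitutions, structural
deviations, hydrogen bonds, contacts) is keyed to alignment columns, so
this module owns the residue↔column maps, the pairwise difference
counter, region projection across species, and the per-column
conservation track.

Gap rule for pairwise differences (documented and configurable): a column
where exactly one of the two rows is gapped counts as a difference
(an indel column); a column where both are gapped is excluded entirely.
The percentage denominator is the number of columns where at least one of
the pair has a residue (the union length).  This is the only reading
under which pairwise counts can exceed the shorter sequence's length, as
the study's divergence figures require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GAP, AlignmentFrame, RegionSet

__all__ = [
    "ColumnMap",
    "PairwiseDiff",
    "build_column_map",
    "pairwise_differences",
    "pairwise_matrix",
    "project_regions",
    "per_residue_identity",
    "DEFAULT_CONSERVATION_CLASSES",
]

#: sentinel for "gap" in column→residue maps
NO_RESIDUE = 0


@dataclass(frozen=True)
class ColumnMap:
    """Bidirectional residue↔column maps for every row of a frame.

    Arrays are 1-based with index 0 unused; ``col_to_res`` holds the
    sentinel 0 at gap columns.
    """

    frame: AlignmentFrame
    res_to_col: dict[str, np.ndarray]
    col_to_res: dict[str, np.ndarray]

    def column_of(self, rid: str, residue: int) -> int:
        arr = self.res_to_col[rid]
        if not (1 <= residue < len(arr)):
            raise IndexError(f"residue {residue} out of range for {rid!r}")
        return int(arr[residue])

    def residue_at(self, rid: str, column: int) -> int:
        """Residue number at a column, or 0 if the row is gapped there."""
        arr = self.col_to_res[rid]
        if not (1 <= column < len(arr)):
            raise IndexError(f"column {column} out of range")
        return int(arr[column])


def build_column_map(frame: AlignmentFrame) -> ColumnMap:
    res_to_col: dict[str, np.ndarray] = {}
    col_to_res: dict[str, np.ndarray] = {}
    n = frame.n_columns
    for rid, gapped in frame.rows:
        c2r = np.zeros(n + 1, dtype=np.int64)
        r2c = [0]
        res = 0
        for c, ch in enumerate(gapped, start=1):
            if ch != GAP:
                res += 1
                c2r[c] = res
                r2c.append(c)
        res_to_col[rid] = np.array(r2c, dtype=np.int64)
        col_to_res[rid] = c2r
    return ColumnMap(frame, res_to_col, col_to_res)


@dataclass(frozen=True)
class PairwiseDiff:
    """Difference counts between two alignment rows under the gap rule."""

    id_a: str
    id_b: str
    n_substitutions: int   # both residues present and different
    n_indel_columns: int   # exactly one of the pair gapped
    n_compared: int        # columns with >= 1 residue among the pair

    @property
    def n_differences(self) -> int:
        return self.n_substitutions + self.n_indel_columns

    @property
    def percent(self) -> float:
        if self.n_compared == 0:
            return 0.0
        return 100.0 * self.n_differences / self.n_compared

    @property
    def percent_rounded(self) -> int:
        return int(round(self.percent))


def pairwise_differences(
    frame: AlignmentFrame,
    id_a: str,
    id_b: str,
    *,
    count_indels: bool = True,
    denominator: str = "union",
) -> PairwiseDiff:
    """Count substitutions and indel columns between two rows.

    ``denominator`` selects the percentage base: ``"union"`` (columns with
    at least one residue among the pair, the default) or ``"reference"``
    (ungapped length of ``id_a``).  ``count_indels=False`` drops indel
    columns from the difference count (they stay in the record).
    """
    a = frame.row(id_a)
    b = frame.row(id_b)
    n_sub = n_indel = n_comp = 0
    for ca, cb in zip(a, b):
        ga, gb = ca == GAP, cb == GAP
        if ga and gb:
            continue
        n_comp += 1
        if ga != gb:
            n_indel += 1
        elif ca != cb:
            n_sub += 1
    if denominator == "reference":
        n_comp = len(a.replace(GAP, ""))
    elif denominator != "union":
        raise ValueError(f"unknown denominator rule {denominator!r}")
    if not count_indels:
        n_indel = 0
    return PairwiseDiff(id_a, id_b, n_sub, n_indel, n_comp)


def pairwise_matrix(frame: AlignmentFrame, ids: list[str] | None = None,
                    **kwargs) -> dict[tuple[str, str], PairwiseDiff]:
    """All unordered pairs among ``ids`` (default: every row)."""
    ids = ids or frame.ids
    out = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            out[(a, b)] = pairwise_differences(frame, a, b, **kwargs)
    return out


def project_regions(frame: AlignmentFrame, regions: RegionSet, target_id: str) -> RegionSet:
    """Map reference-coordinate regions onto another row via columns.

    Each reference residue interval is walked column by column; target
    residues at those columns (where the target is not gapped) define the
    projected interval as their (min, max) span.  Regions entirely gapped
    in the target are listed in ``empty_regions``.
    """
    cmap = build_column_map(frame)
    ref = regions.reference_id
    if ref not in frame.ids:
        raise KeyError(f"region reference {ref!r} not in alignment")
    ref_len = len(frame.sequence(ref))
    projected = []
    empty = []
    for name, start, end in regions.regions:
        if end > ref_len:
            raise ValueError(
                f"region {name!r} ({start},{end}) exceeds reference length {ref_len}"
            )
        targets = []
        for r in range(start, end + 1):
            col = cmap.column_of(ref, r)
            tr = cmap.residue_at(target_id, col)
            if tr != NO_RESIDUE:
                targets.append(tr)
        if targets:
            projected.append((name, min(targets), max(targets)))
        else:
            empty.append(name)
    return RegionSet(
        target_id,
        tuple(projected),
        reference_length=len(frame.sequence(target_id)),
        empty_regions=tuple(empty),
    )


#: thresholds on the fraction of rows identical to the reference; the
#: endpoint classes come from the study's conservation track, the
#: intermediate cuts are this package's defaults.
DEFAULT_CONSERVATION_CLASSES = (
    (1.0, "complete"),
    (0.75, "high"),
    (0.5, "moderate"),
    (0.0, "low"),
)


def per_residue_identity(
    frame: AlignmentFrame,
    reference_id: str,
    classes: tuple[tuple[float, str], ...] = DEFAULT_CONSERVATION_CLASSES,
):
    """Per-column conservation relative to a reference row.

    Returns one record per column: ``(column, fraction, class, ref_gapped)``.
    The fraction is the share of non-reference rows whose character equals
    the reference character; a gapped other row never matches a residue.
    Columns where the reference is gapped carry fraction NaN and are
    flagged.
    """
    ref = frame.row(reference_id)
    others = [g for rid, g in frame.rows if rid != reference_id]
    if not others:
        raise ValueError("need at least one non-reference row")
    out = []
    for c in range(frame.n_columns):
        rc = ref[c]
        if rc == GAP:
            out.append((c + 1, float("nan"), "gap", True))
            continue
        matches = sum(1 for g in others if g[c] == rc)
        frac = matches / len(others)
        label = classes[-1][1]
        for threshold, name in classes:
            if frac >= threshold:
                label = name
                break
        out.append((c + 1, frac, label, False))
    return out
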