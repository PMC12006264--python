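"""Lineage-specific substitutions, Miyata biochemical scoring, and
category-stratified exact tests.

Substitutions are inferred per alignment column between an ancestral-node
row and a descendant row; indel columns are tracked as separate events
and never Miyata-scored.  Each substitution gets a Miyata distance — a
biochemical dissimilarity combining side-chain polarity and volume — and
an integer class 0..4 (0 = most similar, 4 = least), then counts are
stratified by functional region and by structural order state and
compared between lineages with Fisher's exact test under a Bonferroni
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .io_formats import GAP, AlignmentFrame, RegionSet
from .msa_map import build_column_map

__all__ = [
    "MiyataTable",
    "MIYATA",
    "miyata_distance",
    "miyata_class",
    "SubstitutionRecord",
    "IndelEvent",
    "LineageChanges",
    "infer_lineage_substitutions",
    "region_columns",
    "order_state_by_column",
    "annotate_records",
    "StratifiedCounts",
    "stratify",
    "ContingencyTable",
    "fisher_exact",
    "bonferroni_adjust",
    "CategoryComparison",
    "category_tests",
]

# ---------------------------------------------------------------------------
# Miyata distance
# ---------------------------------------------------------------------------

#: Side-chain polarity and volume per residue (Grantham's physicochemical
#: scales, the property columns behind the Miyata distance).  Polarity is
#: dimensionless; volume in Å³.
AA_PROPERTIES: dict[str, tuple[float, float]] = {
    "A": (8.1, 31.0),
    "R": (10.5, 124.0),
    "N": (11.6, 56.0),
    "D": (13.0, 54.0),
    "C": (5.5, 55.0),
    "Q": (10.5, 85.0),
    "E": (12.3, 83.0),
    "G": (9.0, 3.0),
    "H": (10.4, 96.0),
    "I": (5.2, 111.0),
    "L": (4.9, 111.0),
    "K": (11.3, 119.0),
    "M": (5.7, 105.0),
    "F": (5.2, 132.0),
    "P": (8.0, 32.5),
    "S": (9.2, 32.0),
    "T": (8.6, 61.0),
    "W": (5.4, 170.0),
    "Y": (6.2, 136.0),
    "V": (5.9, 84.0),
}

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class MiyataTable:
    """The 20×20 Miyata distance grid and the property columns behind it.

    d(a,b) = sqrt((|p_a − p_b|/σ_p)² + (|v_a − v_b|/σ_v)²) where σ_p, σ_v
    are the standard deviations of polarity and volume across the 20
    residues (population convention, ddof=0).
    """

    polarity: dict[str, float]
    volume: dict[str, float]
    sigma_p: float
    sigma_v: float
    grid: np.ndarray  # indexed by AA_ORDER

    @classmethod
    def from_properties(
        cls, properties: dict[str, tuple[float, float]] = AA_PROPERTIES
    ) -> "MiyataTable":
        polarity = {a: p for a, (p, _) in properties.items()}
        volume = {a: v for a, (_, v) in properties.items()}
        p = np.array([polarity[a] for a in AA_ORDER])
        v = np.array([volume[a] for a in AA_ORDER])
        sp = float(np.std(p, ddof=0))
        sv = float(np.std(v, ddof=0))
        grid = np.sqrt(
            (np.abs(p[:, None] - p[None, :]) / sp) ** 2
            + (np.abs(v[:, None] - v[None, :]) / sv) ** 2
        )
        return cls(polarity, volume, sp, sv, grid)

    def distance(self, aa1: str, aa2: str) -> float:
        i = AA_ORDER.index(aa1)
        j = AA_ORDER.index(aa2)
        return float(self.grid[i, j])

    def max_distance(self) -> float:
        return float(self.grid.max())

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.grid, index=list(AA_ORDER), columns=list(AA_ORDER))


MIYATA = MiyataTable.from_properties()

#: sentinel for pairs that cannot be Miyata-scored ('X' or non-canonical)
UNSCORED = float("nan")


def miyata_distance(aa1: str, aa2: str, table: MiyataTable = MIYATA) -> float:
    """Miyata biochemical distance between two residues.

    Returns NaN (never silently 0) when either residue is 'X' or outside
    the 20 canonical codes.
    """
    if aa1 not in AA_ORDER or aa2 not in AA_ORDER:
        return UNSCORED
    return table.distance(aa1, aa2)


def miyata_class(raw: float, cap: int = 4) -> int:
    """Integer class: round-half-up of the raw distance, capped.

    0 is the most biochemically similar change; the cap (default 4) the
    least, since raw distances exceed 4 for extreme pairs.
    """
    if math.isnan(raw):
        raise ValueError("cannot class an unscored (NaN) distance")
    if raw < 0:
        raise ValueError(f"negative Miyata distance {raw}")
    return min(cap, int(math.floor(raw + 0.5)))


# ---------------------------------------------------------------------------
# lineage substitutions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstitutionRecord:
    """One lineage-specific amino-acid change at an alignment column."""

    column: int
    lineage: str
    ancestral: str
    derived: str
    miyata_raw: float
    miyata_class_: int | None  # None when unscored ('X' involved)
    region_tags: frozenset[str] = frozenset()
    order_state: str = "unscored"  # ordered | disordered | unscored


@dataclass(frozen=True)
class IndelEvent:
    column: int
    lineage: str
    kind: str  # "insertion" (ancestor gapped) | "deletion" (descendant gapped)


@dataclass(frozen=True)
class LineageChanges:
    ancestor_id: str
    descendant_id: str
    substitutions: tuple[SubstitutionRecord, ...]
    indels: tuple[IndelEvent, ...]


def infer_lineage_substitutions(
    frame: AlignmentFrame, ancestor_id: str, descendant_id: str,
    table: MiyataTable = MIYATA, cap: int = 4,
) -> LineageChanges:
    """Column-wise changes from an ancestral row to a descendant row.

    A substitution record is emitted where both rows have residues and
    they differ; columns where exactly one is gapped become insertion or
    deletion events (never Miyata-scored).
    """
    anc = frame.row(ancestor_id)
    der = frame.row(descendant_id)
    subs: list[SubstitutionRecord] = []
    indels: list[IndelEvent] = []
    for c, (a, d) in enumerate(zip(anc, der), start=1):
        ga, gd = a == GAP, d == GAP
        if ga and gd:
            continue
        if ga:
            indels.append(IndelEvent(c, descendant_id, "insertion"))
        elif gd:
            indels.append(IndelEvent(c, descendant_id, "deletion"))
        elif a != d:
            raw = miyata_distance(a, d, table)
            klass = None if math.isnan(raw) else miyata_class(raw, cap)
            subs.append(SubstitutionRecord(c, descendant_id, a, d, raw, klass))
    return LineageChanges(ancestor_id, descendant_id, tuple(subs), tuple(indels))


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def region_columns(frame: AlignmentFrame, regions: RegionSet) -> dict[str, set[int]]:
    """Alignment-column sets per region, via the reference row's map."""
    cmap = build_column_map(frame)
    ref = regions.reference_id
    out: dict[str, set[int]] = {}
    for name, start, end in regions.regions:
        out[name] = {cmap.column_of(ref, r) for r in range(start, end + 1)}
    return out


def order_state_by_column(frame: AlignmentFrame, species_id: str,
                          order_states: list[str]) -> dict[int, str]:
    """Project a species' per-residue order states onto alignment columns.

    ``order_states`` is indexed by residue (0-based list over the
    ungapped sequence of ``species_id``).
    """
    cmap = build_column_map(frame)
    n_res = len(frame.sequence(species_id))
    if len(order_states) != n_res:
        raise ValueError(
            f"order states length {len(order_states)} != sequence length {n_res}"
        )
    return {
        cmap.column_of(species_id, r + 1): order_states[r] for r in range(n_res)
    }


def annotate_records(
    records: tuple[SubstitutionRecord, ...],
    region_cols: dict[str, set[int]] | None = None,
    order_by_col: dict[str, dict[int, str]] | None = None,
) -> tuple[SubstitutionRecord, ...]:
    """Fill region tags and order state on substitution records.

    ``order_by_col`` maps lineage id → {column: state} so each lineage is
    judged by its own species' mask.
    """
    out = []
    for r in records:
        tags = frozenset(
            name for name, cols in (region_cols or {}).items() if r.column in cols
        )
        state = r.order_state
        if order_by_col and r.lineage in order_by_col:
            state = order_by_col[r.lineage].get(r.column, "unscored")
        out.append(replace(r, region_tags=tags, order_state=state))
    return tuple(out)


@dataclass
class StratifiedCounts:
    """Counts per (category × lineage × Miyata class).

    Categories are "total", one per region name, "ordered" and
    "disordered".  Class None (unscored) is keyed as -1.
    """

    counts: dict[tuple[str, str, int], int] = field(default_factory=dict)
    lineages: tuple[str, ...] = ()
    categories: tuple[str, ...] = ()

    def count(self, category: str, lineage: str, klass: int | None = None) -> int:
        if klass is not None:
            return self.counts.get((category, lineage, klass), 0)
        return sum(
            v for (c, l, _), v in self.counts.items()
            if c == category and l == lineage
        )

    def ordered_disordered_ratio(self, lineage: str) -> float | None:
        """Ratio of changes in ordered vs disordered residues; None (an
        explicit NA) when the disordered count is zero."""
        dis = self.count("disordered", lineage)
        if dis == 0:
            return None
        return self.count("ordered", lineage) / dis


def stratify(
    records: tuple[SubstitutionRecord, ...],
    region_cols: dict[str, set[int]] | None = None,
    order_by_col: dict[str, dict[int, str]] | None = None,
) -> StratifiedCounts:
    """Tally substitution records per category, lineage and Miyata class.

    A record inside two overlapping regions is counted once per region.
    """
    records = annotate_records(records, region_cols, order_by_col)
    out = StratifiedCounts()
    lineages, cats = set(), {"total"}
    for r in records:
        klass = -1 if r.miyata_class_ is None else r.miyata_class_
        lineages.add(r.lineage)
        keys = ["total"] + sorted(r.region_tags)
        if r.order_state in ("ordered", "disordered"):
            keys.append(r.order_state)
        for k in keys:
            cats.add(k)
            out.counts[(k, r.lineage, klass)] = out.counts.get((k, r.lineage, klass), 0) + 1
    for name in (region_cols or {}):
        cats.add(name)
    cats |= {"ordered", "disordered"}
    out.lineages = tuple(sorted(lineages))
    out.categories = tuple(sorted(cats))
    return out


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """A 2×2 table [[a, b], [c, d]] of non-negative counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError(f"table entries must be non-negative integers: {self}")

    @property
    def margins_positive(self) -> bool:
        return (self.a + self.b > 0 and self.c + self.d > 0
                and self.a + self.c > 0 and self.b + self.d > 0)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of
    all tables (at fixed margins) no more likely than the observed one.
    """
    if not table.margins_positive:
        raise ValueError(f"degenerate margins in {table}")
    _, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    return float(min(p, 1.0))


def bonferroni_adjust(p_values: list[float], m: int | None = None) -> list[float]:
    """Bonferroni correction: each adjusted p = min(1, m·p).

    ``m`` defaults to the number of tests; it may be larger (a declared
    family) but never smaller than 1.
    """
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError(f"family size m={m} < 1")
    if m < len(p_values):
        raise ValueError(f"family size m={m} smaller than number of tests")
    return [min(1.0, m * p) for p in p_values]


@dataclass(frozen=True)
class CategoryComparison:
    """One Fisher comparison of a category's counts between two groups."""

    category: str
    group_a: str
    group_b: str
    count_a: int
    count_b: int
    exposure_a: int
    exposure_b: int
    p_raw: float
    p_adjusted: float = float("nan")
    family_size: int = 0
    note: str = ""


def category_tests(
    counts: dict[str, dict[str, int]],
    exposures: dict[str, dict[str, int]] | None = None,
    totals: dict[str, int] | None = None,
) -> list[CategoryComparison]:
    """Fisher tests of category counts between every pair of groups.

    ``counts[category][group]`` is the in-category count.  The 2×2 table
    per (category, group pair) is count vs out-of-category count; the
    out-count comes from ``exposures`` (e.g. residues available per
    category) when given, else from ``totals`` (the group's grand total),
    else from the sum over categories.  Bonferroni family size m = number
    of tests actually performed; degenerate tables are reported untested
    with a note.
    """
    comparisons: list[CategoryComparison] = []
    groups_of = {cat: sorted(g) for cat, g in counts.items()}
    for cat in sorted(counts):
        groups = groups_of[cat]
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                na, nb = counts[cat][ga], counts[cat][gb]
                if exposures is not None:
                    ea, eb = exposures[cat][ga], exposures[cat][gb]
                elif totals is not None:
                    ea, eb = totals[ga], totals[gb]
                else:
                    ea = sum(counts[c].get(ga, 0) for c in counts)
                    eb = sum(counts[c].get(gb, 0) for c in counts)
                t = ContingencyTable(na, max(ea - na, 0), nb, max(eb - nb, 0))
                if not t.margins_positive:
                    comparisons.append(CategoryComparison(
                        cat, ga, gb, na, nb, ea, eb,
                        p_raw=float("nan"), note="degenerate margins, test skipped",
                    ))
                    continue
                comparisons.append(CategoryComparison(
                    cat, ga, gb, na, nb, ea, eb, p_raw=fisher_exact(t),
                ))
    tested = [c for c in comparisons if not math.isnan(c.p_raw)]
    m = len(tested)
    if m:
        adj = bonferroni_adjust([c.p_raw for c in tested], m)
        adj_iter = iter(adj)
        comparisons = [
            replace(c, p_adjusted=next(adj_iter), family_size=m)
            if not math.isnan(c.p_raw) else replace(c, family_size=m)
            for c in comparisons
        ]
    return comparisons
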