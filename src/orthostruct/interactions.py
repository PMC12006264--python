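"""Geometric hydrogen-bond detection and PAE-filtered interface contacts.

Hydrogen bonds are called without explicit hydrogens from heavy-atom
geometry: a donor–acceptor pair bonds when its distance is at most the
base distance plus a relaxation tolerance and the angle at the donor
(antecedent–donor–acceptor) is at least the base angle minus an angle
relaxation.  Intra-chain bonds are catalogued only between residues more
than a minimum separation apart in sequence; bonds between chains of a
complex are all catalogued.  Interface contacts are residue pairs of two
chains within a heavy-atom distance cutoff whose predicted aligned error
is below the confidence cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import AlignmentFrame, PaeMatrix, RegionSet, StructureModel
from .substitutions import CategoryComparison, category_tests

__all__ = [
    "DONOR_ACCEPTOR_TABLE",
    "HBond",
    "Contact",
    "detect_hbonds",
    "interface_contacts",
    "compare_catalogs",
    "BASE_DISTANCE",
    "BASE_ANGLE",
]

#: heavy-atom donor–acceptor distance (Å) before relaxation; small-molecule
#: crystal-structure H-bond surveys put typical N/O···O/N separations near
#: 2.9 ± 0.4 Å, so 3.3 Å is the inclusive base criterion here.
BASE_DISTANCE = 3.3
#: minimal angle (degrees) at the donor (antecedent–donor–acceptor) before
#: relaxation; below ~90° the putative hydrogen cannot point at the acceptor.
BASE_ANGLE = 90.0

# donor/acceptor heavy atoms per residue type with the antecedent heavy
# atom used for the angle term.  Backbone N donates (antecedent CA; the
# proline ring nitrogen cannot donate) and backbone O accepts (antecedent
# C) in every residue type.  Sulfur centres are omitted (weak donors/
# acceptors, not catalogued here).
_SIDECHAIN_DONORS: dict[str, list[tuple[str, str]]] = {
    "ARG": [("NE", "CD"), ("NH1", "CZ"), ("NH2", "CZ")],
    "ASN": [("ND2", "CG")],
    "GLN": [("NE2", "CD")],
    "HIS": [("ND1", "CG"), ("NE2", "CD2")],
    "LYS": [("NZ", "CE")],
    "SER": [("OG", "CB")],
    "THR": [("OG1", "CB")],
    "TRP": [("NE1", "CD1")],
    "TYR": [("OH", "CZ")],
}
_SIDECHAIN_ACCEPTORS: dict[str, list[tuple[str, str]]] = {
    "ASN": [("OD1", "CG")],
    "ASP": [("OD1", "CG"), ("OD2", "CG")],
    "GLN": [("OE1", "CD")],
    "GLU": [("OE1", "CD"), ("OE2", "CD")],
    "HIS": [("ND1", "CG"), ("NE2", "CD2")],
    "SER": [("OG", "CB")],
    "THR": [("OG1", "CB")],
    "TYR": [("OH", "CZ")],
}

_STANDARD = set(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL UNK".split()
)


def donor_acceptor_table(residue_name: str) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """(donors, acceptors) as (atom, antecedent) lists for a residue type."""
    donors = [] if residue_name == "PRO" else [("N", "CA")]
    donors += _SIDECHAIN_DONORS.get(residue_name, [])
    acceptors = [("O", "C")] + _SIDECHAIN_ACCEPTORS.get(residue_name, [])
    return donors, acceptors


DONOR_ACCEPTOR_TABLE = {
    name: donor_acceptor_table(name) for name in sorted(_STANDARD)
}


@dataclass(frozen=True)
class HBond:
    donor_chain: str
    donor_residue: int      # 0-based residue index within its chain
    donor_atom: str
    acceptor_chain: str
    acceptor_residue: int
    acceptor_atom: str
    distance: float         # donor–acceptor heavy-atom Å
    angle: float            # antecedent–donor–acceptor degrees
    scope: str              # "intra" | "inter"

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("non-positive H-bond distance")
        if not (0.0 <= self.angle <= 180.0):
            raise ValueError(f"H-bond angle {self.angle} outside [0,180]")
        if self.scope == "intra" and self.donor_chain != self.acceptor_chain:
            raise ValueError("intra-chain bond across chains")


@dataclass(frozen=True)
class Contact:
    residue_a: int          # 0-based index in chain A
    residue_b: int          # 0-based index in chain B
    min_distance: float     # minimum heavy-atom Å
    pae: float              # combined predicted aligned error Å


def _sites(models: list[StructureModel], role: str):
    """Flatten donor or acceptor sites:
    (chain_idx, res_idx, res_number, atom, xyz, antecedent_xyz)."""
    sites = []
    for ci, model in enumerate(models):
        for ri, res in enumerate(model.residues):
            if res.name not in _STANDARD:
                import warnings
                warnings.warn(
                    f"chain {model.chain_id}: unknown residue type {res.name}; skipped"
                )
                continue
            donors, acceptors = donor_acceptor_table(res.name)
            for atom_name, ante_name in (donors if role == "donor" else acceptors):
                atom = res.atom(atom_name)
                ante = res.atom(ante_name)
                if atom is None or ante is None:
                    continue
                sites.append((ci, ri, res.number, atom_name,
                              np.array(atom.xyz), np.array(ante.xyz)))
    return sites


def detect_hbonds(
    models: StructureModel | list[StructureModel],
    dist_tol: float = 0.4,
    angle_tol: float = 20.0,
    min_separation: int = 5,
) -> list[HBond]:
    """Geometric hydrogen bonds within and between chains.

    A bond is called when donor–acceptor distance ≤ BASE_DISTANCE +
    ``dist_tol`` and the donor angle ≥ BASE_ANGLE − ``angle_tol``.
    Intra-chain bonds are kept only when the residues' sequence numbers
    are more than ``min_separation`` apart; inter-chain bonds are all
    kept.
    """
    if isinstance(models, StructureModel):
        models = [models]
    donors = _sites(models, "donor")
    acceptors = _sites(models, "acceptor")
    if not donors or not acceptors:
        return []
    max_dist = BASE_DISTANCE + dist_tol
    min_angle = BASE_ANGLE - angle_tol
    acc_xyz = np.array([s[4] for s in acceptors])
    tree = cKDTree(acc_xyz)
    bonds = []
    for dci, dri, dnum, datom, dxyz, dante in donors:
        for j in tree.query_ball_point(dxyz, max_dist):
            aci, ari, anum, aatom, axyz, _ = acceptors[j]
            if aci == dci and ari == dri:
                continue  # no bonds within a residue
            dist = float(np.linalg.norm(dxyz - axyz))
            if dist > max_dist or dist <= 0:
                continue
            v1 = dante - dxyz
            v2 = axyz - dxyz
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle < min_angle:
                continue
            scope = "intra" if aci == dci else "inter"
            if scope == "intra" and abs(dnum - anum) <= min_separation:
                continue
            bonds.append(HBond(
                models[dci].chain_id, dri, datom,
                models[aci].chain_id, ari, aatom,
                dist, angle, scope,
            ))
    bonds.sort(key=lambda b: (b.donor_chain, b.donor_residue, b.donor_atom,
                              b.acceptor_chain, b.acceptor_residue, b.acceptor_atom))
    return bonds


def interface_contacts(
    model_a: StructureModel,
    model_b: StructureModel,
    pae: PaeMatrix,
    pae_cutoff: float = 5.0,
    dist_cutoff: float = 4.0,
) -> list[Contact]:
    """Residue-pair contacts between two chains, PAE-gated.

    The PAE matrix is indexed over the concatenated residues (A then B);
    a pair's PAE is the conservative max of the two directions and must
    be strictly below ``pae_cutoff``.  The geometric criterion is the
    minimum heavy-atom distance ≤ ``dist_cutoff``.
    """
    na, nb = len(model_a), len(model_b)
    if pae.n != na + nb:
        raise ValueError(
            f"PAE is {pae.n}×{pae.n} but chains have {na}+{nb}={na + nb} residues"
        )
    xyz_a, idx_a = _atom_cloud(model_a)
    xyz_b, idx_b = _atom_cloud(model_b)
    tree_b = cKDTree(xyz_b)
    pairs = tree_b.query_ball_point(xyz_a, dist_cutoff)
    min_dist: dict[tuple[int, int], float] = {}
    for ai, neighbours in enumerate(pairs):
        for bj in neighbours:
            i, j = idx_a[ai], idx_b[bj]
            d = float(np.linalg.norm(xyz_a[ai] - xyz_b[bj]))
            key = (i, j)
            if d < min_dist.get(key, np.inf):
                min_dist[key] = d
    contacts = []
    for (i, j), d in sorted(min_dist.items()):
        p = max(pae[i, na + j], pae[na + j, i])
        if p < pae_cutoff:
            contacts.append(Contact(int(i), int(j), d, p))
    return contacts


def _atom_cloud(model: StructureModel) -> tuple[np.ndarray, np.ndarray]:
    xyz, idx = [], []
    for ri, res in enumerate(model.residues):
        for a in res.atoms:
            if a.element in ("H", "D"):
                continue
            xyz.append(a.xyz)
            idx.append(ri)
    return np.array(xyz, dtype=float), np.array(idx, dtype=np.int64)


def catalog_category_counts(
    bonds: list[HBond],
    frame: AlignmentFrame,
    species_id: str,
    region_cols: dict[str, set[int]] | None = None,
    order_by_col: dict[int, str] | None = None,
    focal_chain: str = "A",
) -> dict[str, int]:
    """Category counts for one species' bond catalog.

    Cross-species bond identity runs through alignment columns of the
    focal species' chain (the chain whose sequence is a row of the
    frame; by file convention the first chain, "A").  A bond lands in a
    region when any focal-chain partner's column is in it, and counts as
    "ordered"/"disordered" when all its focal-chain partners share that
    state.  Bonds with no focal-chain partner contribute to the total
    only.
    """
    from .msa_map import build_column_map

    cmap = build_column_map(frame)
    r2c = cmap.res_to_col[species_id]
    counts = {"total": len(bonds), "ordered": 0, "disordered": 0}
    for name in (region_cols or {}):
        counts[name] = 0
    for b in bonds:
        cols = []
        if b.donor_chain == focal_chain:
            cols.append(int(r2c[b.donor_residue + 1]))
        if b.acceptor_chain == focal_chain:
            cols.append(int(r2c[b.acceptor_residue + 1]))
        if not cols:
            continue
        for name, rcols in (region_cols or {}).items():
            if any(c in rcols for c in cols):
                counts[name] += 1
        if order_by_col is not None:
            states = {order_by_col.get(c, "unscored") for c in cols}
            if states == {"ordered"}:
                counts["ordered"] += 1
            elif states == {"disordered"}:
                counts["disordered"] += 1
    return counts


def compare_catalogs(
    catalogs: dict[str, list[HBond]],
    frame: AlignmentFrame,
    regions: RegionSet | None = None,
    masks_by_col: dict[str, dict[int, str]] | None = None,
) -> tuple[list[CategoryComparison], dict[str, dict[str, int]]]:
    """Fisher comparison of bond catalogs between species, by category.

    Returns (comparisons, per-category counts).  The "total" category is
    tested as a rate against each species' residue count; every other
    category as in-category vs out-of-category bonds.  Degenerate tables
    (e.g. two empty catalogs) are reported untested with a reason.  The
    Bonferroni family is the set of tests actually performed.
    """
    import math as _math
    from dataclasses import replace as _replace

    from .substitutions import (
        ContingencyTable, bonferroni_adjust, fisher_exact, region_columns,
    )

    missing = [s for s in catalogs if s not in frame.ids]
    if missing:
        raise KeyError(f"species {missing} not in alignment frame")
    region_cols = region_columns(frame, regions) if regions else None
    per_species = {}
    for sid, bonds in catalogs.items():
        per_species[sid] = catalog_category_counts(
            bonds, frame, sid, region_cols,
            (masks_by_col or {}).get(sid),
        )
    categories = sorted({c for v in per_species.values() for c in v})
    counts = {
        cat: {sid: per_species[sid].get(cat, 0) for sid in per_species}
        for cat in categories
    }
    species = sorted(per_species)
    seq_len = {sid: len(frame.sequence(sid)) for sid in species}
    comparisons: list[CategoryComparison] = []
    for cat in categories:
        for i, sa in enumerate(species):
            for sb in species[i + 1:]:
                na, nb = counts[cat][sa], counts[cat][sb]
                if cat == "total":
                    ea, eb = seq_len[sa], seq_len[sb]
                    t = ContingencyTable(na, ea, nb, eb)
                else:
                    ea, eb = counts["total"][sa], counts["total"][sb]
                    t = ContingencyTable(na, max(ea - na, 0), nb, max(eb - nb, 0))
                if not t.margins_positive:
                    comparisons.append(CategoryComparison(
                        cat, sa, sb, na, nb, ea, eb, p_raw=float("nan"),
                        note="degenerate margins, test skipped",
                    ))
                else:
                    comparisons.append(CategoryComparison(
                        cat, sa, sb, na, nb, ea, eb, p_raw=fisher_exact(t),
                    ))
    tested = [c for c in comparisons if not _math.isnan(c.p_raw)]
    if tested:
        adj = iter(bonferroni_adjust([c.p_raw for c in tested], len(tested)))
        comparisons = [
            _replace(c, p_adjusted=next(adj), family_size=len(tested))
            if not _math.isnan(c.p_raw) else _replace(c, family_size=len(tested))
            for c in comparisons
        ]
    return comparisons, counts
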