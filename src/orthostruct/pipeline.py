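"""End-to-end orchestration of the cross-species comparison.

Runs the stages in their natural order — alignment bookkeeping →
order/disorder masks → ancestral substitutions with category tests →
confidence-gated superpositions → interaction catalogs — over a bundle
directory laid out the way :mod:`orthostruct.synthetic_data` writes one
(``alignment.fasta`` with an ``ancestor`` row, ``<sp>.pdb``,
``<sp>_complex.pdb``, ``<sp>_pae.json``, ``<sp>_plddt.tsv``,
``<sp>_adopt.tsv``, ``regions.tsv``).  Structure-side stages degrade
gracefully when their inputs are absent; every table is written as TSV
with a ``#``-prefixed metadata header recording the thresholds used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .io_formats import (
    AlignmentFrame, RegionSet, read_alignment, read_pae, read_regions,
    read_score_track, read_structure,
)
from .msa_map import pairwise_matrix, per_residue_identity
from .order_disorder import (
    DEFAULT_ADOPT_Z_THRESHOLD, DEFAULT_PLDDT_THRESHOLD, OrderMask,
    classify_confidence, classify_order, consensus_mask,
)
from .substitutions import (
    CategoryComparison, infer_lineage_substitutions, order_state_by_column,
    region_columns, stratify, category_tests,
)
from .superpose import (
    RMSD_MATCH_THRESHOLD, classify_pairs, matchmaker_superpose, pair_residues,
    species_specific_differences,
)
from .interactions import compare_catalogs, detect_hbonds, interface_contacts

ANCESTOR_ID = "ancestor"


@dataclass(frozen=True)
class RunConfig:
    """All thresholds of the comparison, with the study's defaults."""

    rmsd_threshold: float = RMSD_MATCH_THRESHOLD   # Å, matched/different cut
    prune_cutoff: float = 2.0                      # Å, superposition pruning
    max_iter: int = 100
    pae_cutoff: float = 5.0                        # Å, contacts kept below
    contact_distance: float = 4.0                  # Å, min heavy-atom distance
    hbond_dist_tol: float = 0.4                    # Å relaxation
    hbond_angle_tol: float = 20.0                  # degrees relaxation
    min_separation: int = 5                        # intra-chain residue gap
    plddt_threshold: float = DEFAULT_PLDDT_THRESHOLD
    adopt_z_threshold: float = DEFAULT_ADOPT_Z_THRESHOLD
    miyata_cap: int = 4
    denominator: str = "union"
    count_indels: bool = True

    def __post_init__(self):
        for name in ("rmsd_threshold", "prune_cutoff", "pae_cutoff",
                     "contact_distance", "plddt_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CompareReport:
    """In-memory results of a full comparison run."""

    frame: AlignmentFrame
    species: list[str]
    divergence: pd.DataFrame
    masks: dict[str, OrderMask] = field(default_factory=dict)
    lineage_changes: dict = field(default_factory=dict)
    substitution_comparisons: list[CategoryComparison] = field(default_factory=list)
    superpositions: dict = field(default_factory=dict)
    specific_differences: dict[str, dict] = field(default_factory=dict)
    hbond_catalogs: dict = field(default_factory=dict)
    contact_catalogs: dict = field(default_factory=dict)
    hbond_comparisons: list[CategoryComparison] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)


def _meta_header(config: RunConfig, extra: dict | None = None) -> str:
    lines = [f"# orthostruct {__version__}"]
    for k, v in asdict(config).items():
        lines.append(f"# {k} = {v}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k} = {v}")
    return "\n".join(lines) + "\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig,
               extra: dict | None = None, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_header(config, extra))
        df.to_csv(fh, sep="\t", index=index)


def divergence_table(frame: AlignmentFrame, ids: list[str] | None = None,
                     count_indels: bool = True,
                     denominator: str = "union") -> pd.DataFrame:
    """Long-format pairwise difference table over the frame's rows."""
    pairs = pairwise_matrix(frame, ids, count_indels=count_indels,
                            denominator=denominator)
    rows = []
    for (a, b), d in pairs.items():
        rows.append({
            "id_a": a, "id_b": b,
            "substitutions": d.n_substitutions,
            "indel_columns": d.n_indel_columns,
            "differences": d.n_differences,
            "compared_columns": d.n_compared,
            "percent": round(d.percent, 4),
            "percent_rounded": d.percent_rounded,
        })
    return pd.DataFrame(rows)


def load_bundle_masks(bundle: Path, species: list[str],
                      config: RunConfig) -> dict[str, OrderMask]:
    """Per-species consensus masks from the bundle's score tracks, with
    plDDT lifted from the single-chain model when no track file exists."""
    masks = {}
    for sid in species:
        plddt_path = bundle / f"{sid}_plddt.tsv"
        if plddt_path.exists():
            plddt = read_score_track(plddt_path, "plddt", sid)
        elif (bundle / f"{sid}.pdb").exists():
            plddt = read_structure(bundle / f"{sid}.pdb")[0].plddt_track()
        else:
            continue
        conf = classify_confidence(plddt, config.plddt_threshold)
        adopt_path = bundle / f"{sid}_adopt.tsv"
        order = None
        if adopt_path.exists():
            order = classify_order(
                read_score_track(adopt_path, "adopt_z", sid),
                config.adopt_z_threshold,
            )
        masks[sid] = consensus_mask(
            sid, conf, order,
            plddt_threshold=config.plddt_threshold,
            adopt_z_threshold=config.adopt_z_threshold,
        )
    return masks


def compare_bundle(bundle: str | Path, outdir: str | Path | None = None,
                   config: RunConfig = RunConfig()) -> CompareReport:
    """Run the full comparison over a bundle directory.

    Writes report TSVs and ``summary.txt`` under ``outdir`` when given;
    always returns the in-memory :class:`CompareReport`.
    """
    bundle = Path(bundle)
    frame = read_alignment(bundle / "alignment.fasta")
    species = [i for i in frame.ids if i != ANCESTOR_ID]
    report = CompareReport(
        frame=frame, species=species,
        divergence=divergence_table(
            frame, count_indels=config.count_indels,
            denominator=config.denominator,
        ),
    )

    regions = None
    if (bundle / "regions.tsv").exists():
        regions = read_regions(bundle / "regions.tsv",
                               reference_id=ANCESTOR_ID if ANCESTOR_ID in frame.ids else None)
    report.masks = load_bundle_masks(bundle, species, config)

    # --- lineage substitutions and category tests -----------------------
    if ANCESTOR_ID in frame.ids:
        region_cols = region_columns(frame, regions) if regions else None
        order_by_col = {
            sid: order_state_by_column(frame, sid, list(m.order_state))
            for sid, m in report.masks.items()
        }
        all_records = []
        for sid in species:
            changes = infer_lineage_substitutions(
                frame, ANCESTOR_ID, sid, cap=config.miyata_cap
            )
            report.lineage_changes[sid] = changes
            all_records.extend(changes.substitutions)
        strat = stratify(tuple(all_records), region_cols, order_by_col)
        counts = {
            cat: {sid: strat.count(cat, sid) for sid in species}
            for cat in strat.categories
        }
        totals = {sid: strat.count("total", sid) for sid in species}
        report.substitution_comparisons = category_tests(
            {c: v for c, v in counts.items() if c != "total"}, totals=totals,
        )
    else:
        report.skipped.append("substitutions: no 'ancestor' row in alignment")

    # --- superpositions -------------------------------------------------
    structures = {
        sid: read_structure(bundle / f"{sid}.pdb")[0]
        for sid in species if (bundle / f"{sid}.pdb").exists()
    }
    if len(structures) >= 2:
        ids = sorted(structures)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                pairing = pair_residues(frame, a, b, structures[a], structures[b])
                result = matchmaker_superpose(
                    pairing, config.prune_cutoff, config.max_iter
                )
                result = classify_pairs(
                    result, report.masks.get(a), report.masks.get(b),
                    config.rmsd_threshold,
                )
                report.superpositions[(a, b)] = result
        if len(ids) >= 3:
            for focal in ids:
                report.specific_differences[focal] = species_specific_differences(
                    report.superpositions, focal
                )
    else:
        report.skipped.append("superpose: fewer than two structure models")

    # --- interactions ---------------------------------------------------
    complexes = {
        sid: read_structure(bundle / f"{sid}_complex.pdb")
        for sid in species if (bundle / f"{sid}_complex.pdb").exists()
    }
    for sid in species:
        chains = complexes.get(sid) or ([structures[sid]] if sid in structures else None)
        if chains is None:
            continue
        report.hbond_catalogs[sid] = detect_hbonds(
            chains, config.hbond_dist_tol, config.hbond_angle_tol,
            config.min_separation,
        )
        pae_path = bundle / f"{sid}_pae.json"
        if len(chains) >= 2 and pae_path.exists():
            report.contact_catalogs[sid] = interface_contacts(
                chains[0], chains[1], read_pae(pae_path),
                config.pae_cutoff, config.contact_distance,
            )
    if report.hbond_catalogs:
        masks_by_col = {
            sid: order_state_by_column(frame, sid, list(m.order_state))
            for sid, m in report.masks.items() if sid in report.hbond_catalogs
        }
        report.hbond_comparisons, _ = compare_catalogs(
            report.hbond_catalogs, frame, regions, masks_by_col
        )
    else:
        report.skipped.append("interactions: no structure models")

    if outdir is not None:
        write_report(report, Path(outdir), config)
    return report


def _comparisons_df(comparisons: list[CategoryComparison]) -> pd.DataFrame:
    return pd.DataFrame([{
        "category": c.category, "group_a": c.group_a, "group_b": c.group_b,
        "count_a": c.count_a, "count_b": c.count_b,
        "exposure_a": c.exposure_a, "exposure_b": c.exposure_b,
        "p_raw": c.p_raw, "p_adjusted": c.p_adjusted,
        "family_size": c.family_size, "note": c.note,
    } for c in comparisons])


def write_report(report: CompareReport, outdir: Path,
                 config: RunConfig = RunConfig()) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(report.divergence, outdir / "divergence.tsv", config)

    if ANCESTOR_ID in report.frame.ids and len(report.frame.ids) > 1:
        recs = per_residue_identity(report.frame, ANCESTOR_ID)
        _write_tsv(
            pd.DataFrame(recs, columns=[
                "column", "fraction_identical", "class", "reference_gapped",
            ]),
            outdir / "conservation.tsv", config,
        )

    if report.masks:
        rows = [
            {"species": sid, "residue": i + 1,
             "confidence_state": m.confidence_state[i],
             "order_state": m.order_state[i], "policy": m.policy}
            for sid, m in report.masks.items() for i in range(len(m))
        ]
        _write_tsv(pd.DataFrame(rows), outdir / "masks.tsv", config)

    if report.lineage_changes:
        rows = []
        for sid, ch in report.lineage_changes.items():
            for r in ch.substitutions:
                rows.append({
                    "lineage": sid, "column": r.column,
                    "ancestral": r.ancestral, "derived": r.derived,
                    "miyata_raw": (round(r.miyata_raw, 4)
                                   if not math.isnan(r.miyata_raw) else ""),
                    "miyata_class": ("" if r.miyata_class_ is None
                                     else r.miyata_class_),
                })
            for e in ch.indels:
                rows.append({
                    "lineage": sid, "column": e.column, "ancestral": "",
                    "derived": e.kind, "miyata_raw": "", "miyata_class": "",
                })
        _write_tsv(pd.DataFrame(rows), outdir / "substitutions.tsv", config)
        _write_tsv(_comparisons_df(report.substitution_comparisons),
                   outdir / "substitution_tests.tsv", config)

    if report.superpositions:
        rows = []
        for (a, b), res in report.superpositions.items():
            p = res.pairing
            for k in range(len(p)):
                rows.append({
                    "id_a": a, "id_b": b, "column": int(p.columns[k]),
                    "residue_a": int(p.index_a[k] + 1),
                    "residue_b": int(p.index_b[k] + 1),
                    "deviation": round(float(res.deviations[k]), 4),
                    "retained": bool(res.retained[k]),
                    "class": res.classes[k] if res.classes else "",
                })
        _write_tsv(pd.DataFrame(rows), outdir / "superposition_pairs.tsv", config)
        transforms = {
            f"{a}|{b}": {
                "rotation": res.rotation.tolist(),
                "translation": res.translation.tolist(),
                "rmsd_retained": res.rmsd,
                "n_retained": int(res.retained.sum()),
            }
            for (a, b), res in report.superpositions.items()
        }
        import json as _json
        with open(outdir / "superposition_transforms.json", "w") as fh:
            _json.dump(transforms, fh, indent=1)

    if report.hbond_catalogs:
        rows = []
        for sid, bonds in report.hbond_catalogs.items():
            for b in bonds:
                rows.append({
                    "species": sid,
                    "donor_chain": b.donor_chain,
                    "donor_residue": b.donor_residue + 1,
                    "donor_atom": b.donor_atom,
                    "acceptor_chain": b.acceptor_chain,
                    "acceptor_residue": b.acceptor_residue + 1,
                    "acceptor_atom": b.acceptor_atom,
                    "distance": round(b.distance, 3),
                    "angle": round(b.angle, 1),
                    "scope": b.scope,
                })
        _write_tsv(pd.DataFrame(rows), outdir / "hbonds.tsv", config)
        _write_tsv(_comparisons_df(report.hbond_comparisons),
                   outdir / "hbond_tests.tsv", config)

    if report.contact_catalogs:
        rows = []
        for sid, contacts in report.contact_catalogs.items():
            for c in contacts:
                rows.append({
                    "species": sid, "residue_a": c.residue_a + 1,
                    "residue_b": c.residue_b + 1,
                    "min_distance": round(c.min_distance, 3),
                    "pae": round(c.pae, 2),
                })
        _write_tsv(pd.DataFrame(rows), outdir / "contacts.tsv", config)

    with open(outdir / "summary.txt", "w") as fh:
        fh.write(_meta_header(config))
        fh.write(f"species: {', '.join(report.species)}\n\n")
        fh.write("pairwise divergence (percent, rounded):\n")
        for _, r in report.divergence.iterrows():
            fh.write(f"  {r.id_a} vs {r.id_b}: {r.percent_rounded}% "
                     f"({r.substitutions} subs + {r.indel_columns} indel cols "
                     f"/ {r.compared_columns})\n")
        if report.specific_differences:
            fh.write("\nspecies-specific structural differences (columns):\n")
            for focal, cols in report.specific_differences.items():
                span = ", ".join(str(c) for c in sorted(cols)) or "none"
                fh.write(f"  {focal}: {span}\n")
        for title, comps in (
            ("substitution category tests", report.substitution_comparisons),
            ("hydrogen-bond category tests", report.hbond_comparisons),
        ):
            if comps:
                fh.write(f"\n{title} (family m="
                         f"{comps[0].family_size}):\n")
                for c in comps:
                    p = "NA" if math.isnan(c.p_raw) else f"{c.p_raw:.4g}"
                    pa = ("NA" if math.isnan(c.p_adjusted)
                          else f"{c.p_adjusted:.4g}")
                    fh.write(f"  {c.category}: {c.group_a} ({c.count_a}) vs "
                             f"{c.group_b} ({c.count_b}) p={p} p_adj={pa}"
                             f"{' [' + c.note + ']' if c.note else ''}\n")
        if report.skipped:
            fh.write("\nskipped stages:\n")
            for s in report.skipped:
                fh.write(f"  {s}\n")
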