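"""Synthetic ortholog families with planted, fully-known ground truth.

The generator emulates the shape of the study system — a star phylogeny
of closely related species descending from one ancestral ("node A")
sequence, a partially disordered protein with region-structured
substitution rates (disordered spans diverge faster than the ordered
core), schematic helical backbones whose per-region displacement, plDDT
and PAE block structure are controlled, and a two-chain complex with a
planted, PAE-confident interface.  Every quantity the pipeline is meant
to recover (substitution events, indels, displaced spans, contacts,
hydrogen-bond sites) is returned in a truth ledger, and every output file
is written in the exact formats the io layer reads.

It does not emulate real folding: backbones are ideal-helix or smoothed
random-walk traces with schematic N/C/O (and Ser OG) placement, and
displacements are rigid span translations so the planted per-residue
deviation equals the plan magnitude exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .io_formats import (
    AA_1TO3, AlignmentFrame, Atom, PaeMatrix, RegionSet, Residue,
    ResidueScoreTrack, Sequence, StructureModel,
    write_alignment, write_fasta, write_pae, write_regions,
    write_score_track, write_structure,
)

__all__ = [
    "SimConfig",
    "default_config",
    "make_backbone",
    "build_model",
    "transform_model",
    "evolve_family",
    "make_comparison_bundle",
    "TruthLedger",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: plDDT / order-Z values planted inside vs outside disorder spans
PLDDT_HIGH, PLDDT_LOW = 90.0, 40.0
ADOPT_HIGH, ADOPT_LOW = 8.0, -2.0


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults are the study-shaped conditions.

    Rates are per-site substitution probabilities per lineage; spans are
    1-based inclusive in root coordinates.
    """

    seed: int = 2026
    n_species: int = 4
    length: int = 400
    default_rate: float = 0.05
    rate_regions: tuple[tuple[int, int, float], ...] = ()
    indel_events_mean: float = 1.0      # Poisson mean deletion events/lineage
    insertion_events_mean: float = 0.5  # Poisson mean insertion events/lineage
    max_indel_span: int = 3
    displacement_plan: tuple[tuple[str, int, int, float], ...] = ()
    disorder_spans: tuple[tuple[int, int], ...] = ()
    interface_contacts: tuple[int, ...] = ()   # root positions paired (i, i)
    hbond_sites: tuple[int, ...] = ()          # root positions pinned to SER
    partner_length: int = 0                    # 0 → same as length
    interface_offset: float = 3.5              # chain separation, Å
    noise_sigma: float = 0.05

    def __post_init__(self):
        for s, e, r in self.rate_regions:
            if not (1 <= s <= e <= self.length) or not (0 <= r <= 1):
                raise ValueError(f"bad rate region ({s},{e},{r})")
        if not (0.0 <= self.default_rate <= 1.0):
            raise ValueError("default_rate outside [0,1]")
        for s, e in self.disorder_spans:
            if not (1 <= s <= e <= self.length):
                raise ValueError(f"disorder span ({s},{e}) outside sequence")
        for sid, s, e, mag in self.displacement_plan:
            if not (1 <= s <= e <= self.length) or mag < 0:
                raise ValueError(f"bad displacement ({sid},{s},{e},{mag})")

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(f"sp{i + 1}" for i in range(self.n_species))


def default_config(seed: int = 2026) -> SimConfig:
    """The canonical end-to-end scenario: 4 species, 400 residues, a
    partially disordered protein (fast-evolving disordered termini, slow
    ordered core), one species-specific 5-residue displacement in the
    confident core, and a 4-contact PAE-confident interface."""
    return SimConfig(
        seed=seed,
        n_species=4,
        length=400,
        default_rate=0.05,
        rate_regions=((1, 60, 0.15), (341, 400, 0.15)),
        disorder_spans=((1, 60), (341, 400)),
        displacement_plan=(("sp3", 180, 184, 4.0),),
        interface_contacts=(120, 150, 200, 250),
        hbond_sites=(150, 200),
    )


# ---------------------------------------------------------------------------
# backbones
# ---------------------------------------------------------------------------

def make_backbone(
    length: int,
    kind: str = "helix",
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """CA trace of an ideal α-helix or a smoothed random-walk coil.

    The helix uses a 1.5 Å rise and ~100° turn per residue at 2.3 Å
    radius, giving consecutive CA–CA distances of ≈ 3.8 Å; the coil takes
    fixed 3.8 Å steps with bounded direction changes.  Gaussian noise of
    ``noise_sigma`` Å is added per coordinate.  Returns (length, 3).
    """
    if length < 3:
        raise ValueError(f"backbone length {length} < 3")
    rng = rng or np.random.default_rng(0)
    if kind == "helix":
        i = np.arange(length)
        theta = np.deg2rad(100.0) * i
        ca = np.stack(
            [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i], axis=1
        )
    elif kind == "coil":
        steps = [np.array([3.8, 0.0, 0.0])]
        for _ in range(length - 2):
            # bounded turn keeps CA-CA near 3.8 and avoids self-overlap
            perturb = rng.normal(scale=0.8, size=3)
            d = steps[-1] + perturb
            steps.append(3.8 * d / np.linalg.norm(d))
        ca = np.concatenate(
            [np.zeros((1, 3)), np.cumsum(steps, axis=0)], axis=0
        )
    else:
        raise ValueError(f"unknown backbone kind {kind!r}")
    if noise_sigma > 0:
        ca = ca + rng.normal(scale=noise_sigma, size=ca.shape)
    return ca


def build_model(
    chain_id: str,
    sequence: str,
    ca: np.ndarray,
    plddt: np.ndarray | None = None,
) -> StructureModel:
    """Assemble a StructureModel around a CA trace.

    N, C and O are placed schematically from the local chain direction;
    serines get CB and OG so hydrogen-bond detection has side-chain
    donor/acceptor sites.  Residue numbering is 1..n.
    """
    n = len(sequence)
    if ca.shape != (n, 3):
        raise ValueError(f"CA trace shape {ca.shape} != ({n},3)")
    plddt = np.full(n, PLDDT_HIGH) if plddt is None else np.asarray(plddt, float)
    residues = []
    for i, aa in enumerate(sequence):
        prev_ca = ca[i - 1] if i > 0 else ca[i] - (ca[i + 1] - ca[i])
        next_ca = ca[i + 1] if i < n - 1 else ca[i] + (ca[i] - ca[i - 1])
        d = next_ca - prev_ca
        d = d / max(np.linalg.norm(d), 1e-9)
        # a direction roughly perpendicular to the chain
        p = np.cross(d, [0.0, 0.0, 1.0])
        if np.linalg.norm(p) < 1e-6:
            p = np.cross(d, [0.0, 1.0, 0.0])
        p = p / np.linalg.norm(p)
        atoms = [
            Atom("N", "N", tuple(ca[i] - 1.2 * d + 0.6 * p)),
            Atom("CA", "C", tuple(ca[i])),
            Atom("C", "C", tuple(ca[i] + 1.2 * d + 0.4 * p)),
            Atom("O", "O", tuple(ca[i] + 1.2 * d + 0.4 * p + 1.23 * p)),
        ]
        if aa == "S":
            # OG along +x so interface serines of two chains offset in x
            # face each other with ideal donor geometry
            cb = ca[i] + 1.5 * p
            og = cb + np.array([1.4, 0.0, 0.0])
            atoms.append(Atom("CB", "C", tuple(cb)))
            atoms.append(Atom("OG", "O", tuple(og)))
        residues.append(
            Residue(AA_1TO3.get(aa, "UNK"), i + 1, tuple(atoms), float(plddt[i]))
        )
    return StructureModel(chain_id, tuple(residues))


def transform_model(model: StructureModel, rot: np.ndarray,
                    shift: np.ndarray) -> StructureModel:
    """Rigidly transform every atom of a model (x → R x + t)."""
    residues = []
    for r in model.residues:
        atoms = tuple(
            Atom(a.name, a.element, tuple(rot @ np.asarray(a.xyz) + shift))
            for a in r.atoms
        )
        residues.append(Residue(r.name, r.number, atoms, r.plddt))
    return StructureModel(model.chain_id, residues=tuple(residues))


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _rate_array(config: SimConfig) -> np.ndarray:
    rates = np.full(config.length, config.default_rate)
    for s, e, r in config.rate_regions:
        rates[s - 1:e] = r
    return rates


def random_root_sequence(config: SimConfig, rng: np.random.Generator) -> str:
    seq = list(rng.choice(list(_AA20), size=config.length))
    for pos in config.hbond_sites:
        seq[pos - 1] = "S"
    return "".join(seq)


@dataclass
class TruthLedger:
    """Everything planted, for end-to-end recovery checks."""

    seed: int
    root: str
    substitutions: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)
    deletions: dict[str, list[int]] = field(default_factory=dict)
    insertions: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    displacement_plan: list[tuple[str, int, int, float]] = field(default_factory=list)
    interface_contacts: list[int] = field(default_factory=list)
    hbond_sites: list[int] = field(default_factory=list)
    disorder_spans: list[tuple[int, int]] = field(default_factory=list)

    def n_substitutions(self, species: str) -> int:
        return len(self.substitutions.get(species, []))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        with open(path) as fh:
            d = json.load(fh)
        out = cls(seed=d["seed"], root=d["root"])
        out.substitutions = {
            k: [tuple(x) for x in v] for k, v in d["substitutions"].items()
        }
        out.deletions = {k: list(v) for k, v in d["deletions"].items()}
        out.insertions = {
            k: [tuple(x) for x in v] for k, v in d["insertions"].items()
        }
        out.displacement_plan = [tuple(x) for x in d["displacement_plan"]]
        out.interface_contacts = list(d["interface_contacts"])
        out.hbond_sites = list(d["hbond_sites"])
        out.disorder_spans = [tuple(x) for x in d["disorder_spans"]]
        return out


def evolve_family(
    root: str, config: SimConfig, rng: np.random.Generator | None = None,
) -> tuple[AlignmentFrame, TruthLedger]:
    """Star-phylogeny descendants of a root sequence with planted truth.

    Deletions are drawn first, substitutions only at surviving sites, so
    the ledger's substitution list matches exactly what an
    ancestor-vs-descendant column walk can recover.  Positions pinned by
    the interface/H-bond plan are immune to both.
    """
    if len(root) != config.length:
        raise ValueError(f"root length {len(root)} != config.length {config.length}")
    rng = rng or np.random.default_rng(config.seed)
    rates = _rate_array(config)
    pinned = set(config.hbond_sites) | set(config.interface_contacts)
    for sid, s, e, _ in config.displacement_plan:
        pinned |= set(range(s, e + 1))  # keep planted spans alignable
    truth = TruthLedger(
        seed=config.seed, root=root,
        displacement_plan=list(config.displacement_plan),
        interface_contacts=list(config.interface_contacts),
        hbond_sites=list(config.hbond_sites),
        disorder_spans=list(config.disorder_spans),
    )
    per_species: dict[str, dict] = {}
    for sid in config.species_ids:
        deleted: set[int] = set()
        n_del = rng.poisson(config.indel_events_mean)
        for _ in range(n_del):
            span = int(rng.integers(1, config.max_indel_span + 1))
            start = int(rng.integers(1, config.length - span + 2))
            cand = set(range(start, start + span))
            if cand & pinned:
                continue
            deleted |= cand
        insertions: list[tuple[int, str]] = []
        n_ins = rng.poisson(config.insertion_events_mean)
        for _ in range(n_ins):
            span = int(rng.integers(1, config.max_indel_span + 1))
            after = int(rng.integers(0, config.length + 1))
            ins_seq = "".join(rng.choice(list(_AA20), size=span))
            insertions.append((after, ins_seq))
        subs: dict[int, str] = {}
        draws = rng.random(config.length)
        for pos in range(1, config.length + 1):
            if pos in deleted or pos in pinned:
                continue
            if draws[pos - 1] < rates[pos - 1]:
                new = root[pos - 1]
                while new == root[pos - 1]:
                    new = str(rng.choice(list(_AA20)))
                subs[pos] = new
        per_species[sid] = {
            "deleted": deleted, "insertions": insertions, "subs": subs,
        }
        truth.substitutions[sid] = [
            (pos, root[pos - 1], aa) for pos, aa in sorted(subs.items())
        ]
        truth.deletions[sid] = sorted(deleted)
        truth.insertions[sid] = sorted(insertions)

    # global column layout: per root slot, first one insertion block per
    # species that inserts there, then the root-position column
    rows = {sid: [] for sid in ("ancestor", *config.species_ids)}
    ins_at: dict[str, dict[int, str]] = {
        sid: dict(per_species[sid]["insertions"]) for sid in config.species_ids
    }
    root_column: dict[int, int] = {}
    col = 0
    for pos in range(0, config.length + 1):
        for sid in config.species_ids:
            block = ins_at[sid].get(pos)
            if block:
                for ch in block:
                    col += 1
                    for rid in rows:
                        rows[rid].append(ch if rid == sid else "-")
        if pos == 0:
            continue
        col += 1
        root_column[pos] = col
        rows["ancestor"].append(root[pos - 1])
        for sid in config.species_ids:
            st = per_species[sid]
            if pos in st["deleted"]:
                rows[sid].append("-")
            else:
                rows[sid].append(st["subs"].get(pos, root[pos - 1]))
    frame = AlignmentFrame(tuple(
        (rid, "".join(chars)) for rid, chars in rows.items()
    ))
    return frame, truth


# ---------------------------------------------------------------------------
# full comparison bundles
# ---------------------------------------------------------------------------

def _species_profile(root_positions: list[int], spans, high, low) -> np.ndarray:
    """Per-residue values from root-coordinate spans; inserted residues
    (root position 0) take the low value."""
    inside = np.zeros(max(root_positions, default=0) + 1, dtype=bool)
    for s, e in spans:
        if s <= len(inside) - 1:
            inside[s:min(e, len(inside) - 1) + 1] = True
    return np.array(
        [low if (p == 0 or (p < len(inside) and inside[p])) else high
         for p in root_positions]
    )


def make_comparison_bundle(
    config: SimConfig, outdir: str | Path,
) -> tuple[Path, TruthLedger]:
    """Generate every pipeline input under ``outdir``; returns the dir
    and the truth ledger (also written as ``truth.json``).

    Files per species ``sp<k>``: ``sp<k>.pdb`` (chain A alone),
    ``sp<k>_complex.pdb`` (chains A+B), ``sp<k>_pae.json`` (complex PAE),
    ``sp<k>_plddt.tsv``, ``sp<k>_adopt.tsv``; plus ``sequences.fasta``,
    ``alignment.fasta``, ``regions.tsv`` and ``truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    root = random_root_sequence(config, rng)
    frame, truth = evolve_family(root, config, rng)
    write_alignment(frame, outdir / "alignment.fasta")
    write_fasta(
        [frame.sequence(rid) for rid in frame.ids], outdir / "sequences.fasta"
    )

    # region annotation on the ancestor (root) coordinates: the ordered
    # core plus each disorder span
    regions = [("core", 1, config.length)]
    if config.disorder_spans:
        spans = sorted(config.disorder_spans)
        core_start = 1
        core = []
        for s, e in spans:
            if s > core_start:
                core.append((core_start, s - 1))
            core_start = e + 1
        if core_start <= config.length:
            core.append((core_start, config.length))
        regions = [("core", core[0][0], core[0][1])] if core else []
        for i, (s, e) in enumerate(core[1:], start=2):
            regions.append((f"core{i}", s, e))
        for i, (s, e) in enumerate(spans, start=1):
            regions.append((f"disordered{i}", s, e))
    region_set = RegionSet("ancestor", tuple(regions), config.length)
    write_regions(region_set, outdir / "regions.tsv")

    # partner chain (B): fixed across species, serine at H-bond sites
    lb = config.partner_length or config.length
    partner_seq = list(rng.choice(list(_AA20), size=lb))
    for pos in config.hbond_sites:
        if pos <= lb:
            partner_seq[pos - 1] = "S"
    partner_seq = "".join(partner_seq)

    root_ca = make_backbone(config.length, "helix", 0.0)
    partner_ca = make_backbone(lb, "helix", 0.0) + np.array(
        [config.interface_offset, 0.0, 0.0]
    )

    displacement_by_species: dict[str, list[tuple[int, int, float]]] = {}
    for sid, s, e, mag in config.displacement_plan:
        displacement_by_species.setdefault(sid, []).append((s, e, mag))

    for sid in config.species_ids:
        seq = frame.sequence(sid).residues
        # map each species residue to its root position (0 for insertions)
        gapped_anc = frame.row("ancestor")
        gapped_sp = frame.row(sid)
        root_pos_of: list[int] = []
        anc_pos = 0
        for ca_ch, sp_ch in zip(gapped_anc, gapped_sp):
            if ca_ch != "-":
                anc_pos += 1
            if sp_ch != "-":
                root_pos_of.append(anc_pos if ca_ch != "-" else 0)
        assert len(root_pos_of) == len(seq)

        ca = np.empty((len(seq), 3))
        for i, p in enumerate(root_pos_of):
            if p > 0:
                ca[i] = root_ca[p - 1]
            else:  # inserted residue: sit near its predecessor
                ca[i] = (ca[i - 1] + np.array([0.0, 3.0, 1.5])
                         if i > 0 else root_ca[0] + np.array([0.0, 3.0, 0.0]))
        for s, e, mag in displacement_by_species.get(sid, []):
            for i, p in enumerate(root_pos_of):
                if s <= p <= e:
                    ca[i] = ca[i] + np.array([0.0, mag, 0.0])
        if config.noise_sigma > 0:
            ca = ca + rng.normal(scale=config.noise_sigma, size=ca.shape)

        plddt = _species_profile(root_pos_of, config.disorder_spans,
                                 PLDDT_HIGH, PLDDT_LOW)
        adopt = _species_profile(root_pos_of, config.disorder_spans,
                                 ADOPT_HIGH, ADOPT_LOW)

        # models are assembled in the canonical frame and transformed
        # whole, so all internal geometry is identical across species
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-20, 20, size=3)
        model_a = transform_model(build_model("A", seq, ca, plddt), rot, shift)
        write_structure([model_a], outdir / f"{sid}.pdb")

        # complex: chains A+B share one rigid frame so the interface is kept
        rot2 = Rotation.random(rng=rng).as_matrix()
        shift2 = rng.uniform(-20, 20, size=3)
        model_ac = transform_model(build_model("A", seq, ca, plddt), rot2, shift2)
        model_bc = transform_model(
            build_model("B", partner_seq, partner_ca, np.full(lb, PLDDT_HIGH)),
            rot2, shift2,
        )
        write_structure([model_ac, model_bc], outdir / f"{sid}_complex.pdb")

        # complex PAE: low inside each chain's ordered block, low across
        # the planted interface pairs, high elsewhere
        na = len(seq)
        pae = np.full((na + lb, na + lb), 25.0)
        ordered_a = np.array([v == PLDDT_HIGH for v in plddt])
        idx_a = np.where(ordered_a)[0]
        pae[np.ix_(idx_a, idx_a)] = 2.0
        pae[na:, na:] = 2.0
        res_index_of_root = {p: i for i, p in enumerate(root_pos_of) if p > 0}
        for pos in config.interface_contacts:
            i = res_index_of_root.get(pos)
            j = pos - 1 if pos <= lb else None
            if i is not None and j is not None:
                pae[i, na + j] = 2.0
                pae[na + j, i] = 2.0
        for pos in config.hbond_sites:
            i = res_index_of_root.get(pos)
            if i is not None and pos <= lb:
                pae[i, na + pos - 1] = 2.0
                pae[na + pos - 1, i] = 2.0
        np.fill_diagonal(pae, 0.0)
        write_pae(PaeMatrix(pae), outdir / f"{sid}_pae.json")

        write_score_track(
            ResidueScoreTrack(sid, tuple(
                (i + 1, float(v)) for i, v in enumerate(plddt)), "plddt"),
            outdir / f"{sid}_plddt.tsv",
        )
        write_score_track(
            ResidueScoreTrack(sid, tuple(
                (i + 1, float(v)) for i, v in enumerate(adopt)), "adopt_z"),
            outdir / f"{sid}_adopt.tsv",
        )

    truth.to_json(outdir / "truth.json")
    return outdir, truth
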