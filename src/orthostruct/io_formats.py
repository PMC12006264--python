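"""Readers and writers for every external format the pipeline touches.

All coordinates are Ångström, residue numbering is 1-based, alignment
columns are 1-based, and region intervals are 1-based inclusive.  plDDT
is carried in the B-factor column of predicted models (the AlphaFold /
ColabFold output convention) and is lifted onto residues from the CA atom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import numpy as np
import pandas as pd
import gemmi
from Bio import SeqIO

__all__ = [
    "FormatError",
    "Sequence",
    "AlignmentFrame",
    "Atom",
    "Residue",
    "StructureModel",
    "PaeMatrix",
    "ResidueScoreTrack",
    "RegionSet",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "read_structure",
    "write_structure",
    "read_pae",
    "write_pae",
    "read_score_track",
    "write_score_track",
    "read_regions",
    "write_regions",
]

GAP = "-"
CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")
_ALLOWED_AA = CANONICAL_AA | {"X"}

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}
AA_1TO3["X"] = "UNK"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# sequences and alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sequence:
    """An ungapped protein sequence in 1-letter codes.

    ``species`` defaults to the record id; it exists so multi-protein
    studies can keep ortholog families apart.
    """

    id: str
    residues: str
    species: str = ""

    def __post_init__(self):
        if not self.residues:
            raise FormatError(f"sequence {self.id!r}: empty residue string")
        bad = set(self.residues) - _ALLOWED_AA
        if bad:
            raise FormatError(
                f"sequence {self.id!r}: illegal characters {sorted(bad)} "
                "(20 canonical codes plus 'X' allowed; gaps are not)"
            )
        if not self.species:
            object.__setattr__(self, "species", self.id)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignmentFrame:
    """A multiple sequence alignment: equal-length gapped rows.

    Rows keep file order; ``row(id)`` fetches the gapped string and
    ``sequence(id)`` its ungapped :class:`Sequence`.
    """

    rows: tuple[tuple[str, str], ...]  # (id, gapped string)

    def __post_init__(self):
        if not self.rows:
            raise FormatError("alignment with no rows")
        lengths = {len(g) for _, g in self.rows}
        if len(lengths) != 1:
            ragged = [i for i, g in self.rows if len(g) != len(self.rows[0][1])]
            raise FormatError(f"ragged alignment rows: {ragged}")
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate row ids in alignment")
        n = self.n_columns
        for c in range(n):
            if all(g[c] == GAP for _, g in self.rows):
                raise FormatError(f"alignment column {c + 1} is all gaps")
        for rid, g in self.rows:
            Sequence(rid, g.replace(GAP, ""))  # validates characters

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def row(self, rid: str) -> str:
        for i, g in self.rows:
            if i == rid:
                return g
        raise KeyError(f"row {rid!r} not in alignment (have {self.ids})")

    def sequence(self, rid: str) -> Sequence:
        return Sequence(rid, self.row(rid).replace(GAP, ""))


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read ungapped FASTA records; gap characters are a hard error."""
    path = Path(path)
    records = _read_fasta_raw(path)
    out = []
    for rid, seq, line_no in records:
        if GAP in seq:
            raise FormatError(
                f"{path.name}:{line_no}: record {rid!r} contains gap "
                "characters; use read_alignment for aligned FASTA"
            )
        try:
            out.append(Sequence(rid, seq))
        except FormatError as e:
            raise FormatError(f"{path.name}:{line_no}: {e}") from e
    return out


def _read_fasta_raw(path: Path) -> list[tuple[str, str, int]]:
    """Parse FASTA via Biopython, retaining the line number of each header
    so errors can name it."""
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    header_lines: dict[int, int] = {}
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            if line.startswith(">"):
                header_lines[len(header_lines)] = n
            elif not header_lines and line.strip():
                raise FormatError(f"{path.name}:{n}: expected FASTA header '>'")
    with open(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise FormatError(f"{path.name}: no FASTA records")
    return [
        (r.id, str(r.seq).upper(), header_lines.get(i, 0))
        for i, r in enumerate(records)
    ]


def write_fasta(sequences: Iterable[Sequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i:i + width] + "\n")


def read_alignment(path: str | Path) -> AlignmentFrame:
    """Read an aligned FASTA into an :class:`AlignmentFrame`."""
    path = Path(path)
    records = _read_fasta_raw(path)
    return AlignmentFrame(tuple((rid, seq) for rid, seq, _ in records))


def write_alignment(frame: AlignmentFrame, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, g in frame.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(g), width):
                fh.write(g[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass(frozen=True)
class Residue:
    name: str          # 3-letter code
    number: int        # 1-based author numbering
    atoms: tuple[Atom, ...]
    plddt: float       # 0-100, from the CA B-factor

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return AA_3TO1.get(self.name, "X")


@dataclass(frozen=True)
class StructureModel:
    """One chain of a predicted model: ordered residues with heavy atoms."""

    chain_id: str
    residues: tuple[Residue, ...]
    has_hydrogens: bool = False

    def __post_init__(self):
        nums = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise FormatError(
                f"chain {self.chain_id}: residue numbers not strictly increasing"
            )
        for r in self.residues:
            if not r.atoms:
                raise FormatError(f"chain {self.chain_id}: residue {r.number} has no atoms")
            if not (0.0 <= r.plddt <= 100.0):
                raise FormatError(
                    f"chain {self.chain_id}: residue {r.number} plDDT {r.plddt} outside [0,100]"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(n,3) CA coordinates; NaN rows where CA is absent."""
        out = np.full((len(self.residues), 3), np.nan)
        for i, r in enumerate(self.residues):
            ca = r.atom("CA")
            if ca is not None:
                out[i] = ca.xyz
        return out

    def plddt_track(self) -> "ResidueScoreTrack":
        return ResidueScoreTrack(
            id=self.chain_id,
            scores=tuple((r.number, r.plddt) for r in self.residues),
            kind="plddt",
        )


_HEAVY = {"H", "D"}


def read_structure(path: str | Path) -> list[StructureModel]:
    """Read a PDB or mmCIF file into one StructureModel per chain.

    plDDT comes from each residue's CA B-factor (first atom if CA is
    missing, with a warning).  Hydrogens, if present, are kept and the
    model flagged.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except Exception as e:  # gemmi raises RuntimeError on parse failures
        raise FormatError(f"{path.name}: cannot parse structure: {e}") from e
    st.setup_entities()
    if len(st) == 0:
        raise FormatError(f"{path.name}: no models")
    models = []
    for chain in st[0]:
        residues = []
        for res in chain:
            atoms = tuple(
                Atom(a.name, a.element.name, (a.pos.x, a.pos.y, a.pos.z))
                for a in res
            )
            if not atoms:
                continue
            ca = next((a for a in res if a.name == "CA"), None)
            if ca is None:
                import warnings
                warnings.warn(
                    f"{path.name}: chain {chain.name} residue "
                    f"{res.seqid.num} has no CA; plDDT from first atom"
                )
                bfac = res[0].b_iso
            else:
                bfac = ca.b_iso
            residues.append(Residue(res.name, res.seqid.num, atoms, float(bfac)))
        if residues:
            has_h = any(
                a.element in _HEAVY for r in residues for a in r.atoms
            )
            models.append(StructureModel(chain.name, tuple(residues), has_h))
    if not models:
        raise FormatError(f"{path.name}: zero atoms")
    return models


def write_structure(models: TypingSequence[StructureModel], path: str | Path) -> None:
    """Write chains to PDB (plDDT into the B-factor column)."""
    st = gemmi.Structure()
    st.name = Path(path).stem
    model = gemmi.Model("1")
    for m in models:
        chain = gemmi.Chain(m.chain_id)
        for r in m.residues:
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.number, " ")
            for a in r.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.xyz)
                atom.b_iso = r.plddt
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# PAE matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PaeMatrix:
    """Predicted aligned error in Å over n residues; not necessarily symmetric."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise FormatError(f"PAE matrix not square: shape {v.shape}")
        if np.any(v < 0):
            raise FormatError("PAE matrix has negative entries")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, ij) -> float:
        return float(self.values[ij])


def read_pae(path: str | Path) -> PaeMatrix:
    """Read a PAE JSON file.

    Accepts the two dialects in circulation: a list of rows, or a flat
    list of n² values (also the AlphaFold-DB wrapper ``{"predicted_aligned_error":
    rows}`` and ColabFold's ``{"pae": rows}``).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, list) and len(data) == 1 and isinstance(data[0], dict):
        data = data[0]
    if isinstance(data, dict):
        for key in ("predicted_aligned_error", "pae", "distance"):
            if key in data:
                data = data[key]
                break
        else:
            raise FormatError(f"{path.name}: no PAE payload in JSON object")
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        n = int(round(arr.size ** 0.5))
        if n * n != arr.size:
            raise FormatError(
                f"{path.name}: flat PAE list of {arr.size} values is not a square"
            )
        arr = arr.reshape(n, n)
    return PaeMatrix(arr)


def write_pae(pae: PaeMatrix, path: str | Path, flat: bool = False) -> None:
    vals = pae.values
    payload = vals.ravel().tolist() if flat else vals.tolist()
    with open(path, "w") as fh:
        json.dump(payload, fh)


# ---------------------------------------------------------------------------
# score tracks and regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueScoreTrack:
    """A per-residue scalar track (plDDT or a disorder Z-score)."""

    id: str
    scores: tuple[tuple[int, float], ...]
    kind: str  # "plddt" | "adopt_z"

    def __post_init__(self):
        if self.kind not in ("plddt", "adopt_z"):
            raise FormatError(f"unknown track kind {self.kind!r}")
        nums = [n for n, _ in self.scores]
        if len(set(nums)) != len(nums):
            dupes = sorted({n for n in nums if nums.count(n) > 1})
            raise FormatError(f"track {self.id!r}: duplicate residue numbers {dupes}")
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise FormatError(f"track {self.id!r}: residue numbers not increasing")

    def __len__(self) -> int:
        return len(self.scores)

    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.scores], dtype=float)


def read_score_track(path: str | Path, kind: str, id: str | None = None) -> ResidueScoreTrack:
    """Read a delimited (TSV/CSV) table of residue number and score."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path.name}: empty score track") from None
    if df.empty:
        raise FormatError(f"{path.name}: empty score track")
    if df.shape[1] < 2:
        raise FormatError(f"{path.name}: need residue and score columns")
    res_col, score_col = df.columns[0], df.columns[1]
    for i, v in enumerate(df[score_col]):
        try:
            float(v)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path.name}: non-numeric score {v!r} at data row {i + 1}"
            ) from None
    scores = tuple(
        (int(n), float(s)) for n, s in zip(df[res_col], df[score_col])
    )
    return ResidueScoreTrack(id=id or path.stem, scores=scores, kind=kind)


def write_score_track(track: ResidueScoreTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("residue\tscore\n")
        for n, v in track.scores:
            fh.write(f"{n}\t{v:g}\n")


@dataclass(frozen=True)
class RegionSet:
    """Named 1-based inclusive intervals on a reference sequence.

    Overlaps are allowed (functional regions overlap freely); names are
    unique.  ``empty_regions`` records names that projected to nothing in
    a target sequence.
    """

    reference_id: str
    regions: tuple[tuple[str, int, int], ...]
    reference_length: int | None = None
    empty_regions: tuple[str, ...] = ()

    def __post_init__(self):
        names = [n for n, _, _ in self.regions]
        if len(set(names)) != len(names):
            raise FormatError("duplicate region names")
        for name, start, end in self.regions:
            if not (1 <= start <= end):
                raise FormatError(f"region {name!r}: bad interval ({start},{end})")
            if self.reference_length is not None and end > self.reference_length:
                raise FormatError(
                    f"region {name!r}: end {end} exceeds reference length "
                    f"{self.reference_length}"
                )

    def names(self) -> list[str]:
        return [n for n, _, _ in self.regions]

    def interval(self, name: str) -> tuple[int, int]:
        for n, s, e in self.regions:
            if n == name:
                return (s, e)
        raise KeyError(name)

    def mask(self, length: int) -> dict[str, np.ndarray]:
        """Boolean membership per region over residues 1..length."""
        out = {}
        for name, s, e in self.regions:
            m = np.zeros(length, dtype=bool)
            m[s - 1:e] = True
            out[name] = m
        return out


def read_regions(path: str | Path, reference_id: str | None = None,
                 reference_length: int | None = None) -> RegionSet:
    """Read a region config table with columns name, start, end."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("name", "start", "end") if c not in cols]
    if missing:
        raise FormatError(f"{path.name}: missing columns {missing}")
    ref = reference_id
    if ref is None:
        ref = str(df[cols["reference"]].iloc[0]) if "reference" in cols else path.stem
    regions = tuple(
        (str(r[cols["name"]]), int(r[cols["start"]]), int(r[cols["end"]]))
        for _, r in df.iterrows()
    )
    return RegionSet(ref, regions, reference_length)


def write_regions(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tstart\tend\treference\n")
        for name, s, e in regions.regions:
            fh.write(f"{name}\t{s}\t{e}\t{regions.reference_id}\n")
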