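"""Reading protein chains and distilling them into observation streams.

Two observation streams feed every estimator in this package:

* backbone observations — for each residue ``i`` with four intact virtual
  C-alpha bonds around it, the trimer ``(s_{i-1}, s_i, s_{i+1})`` together with
  the virtual-dihedral pair ``(gamma_{i-1}, gamma_i)``, both angles in
  ``[0, 2*pi)``;
* contact observations — for each unordered residue pair at sequence
  separation >= 5 whose nearest heavy-atom approach is within 12 A, the letter
  pair and the contact distance.

Angles are stored on the ``[0, 2*pi)`` branch so that the packaged Voronoi
seeds (which span 0.0-6.1 rad) apply directly.  Internally residues are
0-indexed; positions stored on observations are 1-based.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .constants import (
    AA_INDEX,
    CONTACT_DISTANCE_CAP,
    MIN_CONTACT_SEPARATION,
)
from .errors import FormatError, GeometryError

logger = logging.getLogger(__name__)

#: accepted virtual C-alpha bond length range (A); bonds outside are chain breaks
CA_BOND_RANGE: tuple[float, float] = (2.8, 4.2)

FOLD_CLASSES = ("1", "2", "3", "4", "7")
UNKNOWN_CLASS = "unknown"


# ---------------------------------------------------------------------------
# domain types


@dataclass
class StructureRecord:
    """One protein chain: sequence, C-alpha trace, and heavy-atom coordinates."""

    id: str
    sequence: str
    ca_coords: np.ndarray  # (L, 3) float64, Angstrom
    heavy_atoms: list[np.ndarray]  # per residue (n_atoms, 3)
    fold_class: str = UNKNOWN_CLASS

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if not (len(self.sequence) == len(self.ca_coords) == len(self.heavy_atoms)):
            raise ValueError("sequence, ca_coords and heavy_atoms must align")
        if len(self.sequence) and not np.isfinite(self.ca_coords).all():
            raise ValueError("non-finite C-alpha coordinates")
        for atoms in self.heavy_atoms:
            if len(atoms) == 0:
                raise ValueError("every residue needs at least one heavy atom")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BackboneObservation:
    trimer: tuple[str, str, str]
    gamma_pair: tuple[float, float]
    source_id: str
    position: int  # 1-based central-residue index

    def __post_init__(self) -> None:
        g1, g2 = self.gamma_pair
        if not (0.0 <= g1 < 2.0 * math.pi and 0.0 <= g2 < 2.0 * math.pi):
            raise ValueError("gamma angles must lie in [0, 2*pi)")


@dataclass(frozen=True)
class ContactObservation:
    pair: tuple[str, str]  # unordered; stored sorted
    distance: float  # Angstrom
    separation: int
    source_id: str
    positions: tuple[int, int]  # 1-based

    def __post_init__(self) -> None:
        if self.separation < MIN_CONTACT_SEPARATION:
            raise ValueError("contact separation below minimum")
        if not 0.0 < self.distance <= CONTACT_DISTANCE_CAP:
            raise ValueError("contact distance outside (0, 12] A")


@dataclass
class Dataset:
    """Aggregated observation streams over a set of structures.

    ``n_d`` is the number of residues contributing a backbone observation
    (one observation per residue, so it equals ``len(backbone_obs)`` unless
    explicitly overridden).  ``class_index`` maps fold-class labels to the
    record ids they contain; ``records`` optionally retains the parsed
    structures (needed for threading).
    """

    backbone_obs: list[BackboneObservation]
    contact_obs: list[ContactObservation]
    n_d: int = -1
    class_index: dict[str, tuple[str, ...]] = field(default_factory=dict)
    records: dict[str, StructureRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_d < 0:
            self.n_d = len(self.backbone_obs)
        if (self.backbone_obs or self.contact_obs) and self.n_d <= 0:
            raise ValueError("n_d must be positive when observations exist")
        if not self.class_index:
            ids = sorted(
                {o.source_id for o in self.backbone_obs}
                | {o.source_id for o in self.contact_obs}
            )
            self.class_index = {UNKNOWN_CLASS: tuple(ids)}

    # -- cached array views used by the vectorized estimators ---------------

    @cached_property
    def backbone_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(trimer letter indices (n,3) int64, gamma pairs (n,2) float64)."""
        n = len(self.backbone_obs)
        tri = np.empty((n, 3), dtype=np.int64)
        gam = np.empty((n, 2), dtype=float)
        for r, ob in enumerate(self.backbone_obs):
            tri[r, 0] = AA_INDEX[ob.trimer[0]]
            tri[r, 1] = AA_INDEX[ob.trimer[1]]
            tri[r, 2] = AA_INDEX[ob.trimer[2]]
            gam[r, 0] = ob.gamma_pair[0]
            gam[r, 1] = ob.gamma_pair[1]
        return tri, gam

    @cached_property
    def contact_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(pair letter indices (n,2) int64 sorted, distances (n,) float64)."""
        n = len(self.contact_obs)
        pairs = np.empty((n, 2), dtype=np.int64)
        dist = np.empty(n, dtype=float)
        for r, ob in enumerate(self.contact_obs):
            i, j = AA_INDEX[ob.pair[0]], AA_INDEX[ob.pair[1]]
            pairs[r, 0], pairs[r, 1] = min(i, j), max(i, j)
            dist[r] = ob.distance
        return pairs, dist

    # -- subsetting ----------------------------------------------------------

    def subset(self, classes: Iterable[str]) -> "Dataset":
        """Restrict to records belonging to the given fold classes."""
        wanted: set[str] = set()
        keep_classes = {}
        for c in classes:
            ids = self.class_index.get(str(c), ())
            keep_classes[str(c)] = ids
            wanted.update(ids)
        bb = [o for o in self.backbone_obs if o.source_id in wanted]
        cc = [o for o in self.contact_obs if o.source_id in wanted]
        recs = {k: v for k, v in self.records.items() if k in wanted}
        return Dataset(bb, cc, class_index=keep_classes, records=recs)


# ---------------------------------------------------------------------------
# geometry


def virtual_dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle of four points, IUPAC sign convention, mapped to [0, 2*pi).

    The standard branch (-pi, pi] is shifted by adding 2*pi to negative values.
    Raises :class:`GeometryError` for coincident consecutive points or
    collinear consecutive triples.
    """
    p = np.asarray([p1, p2, p3, p4], dtype=float)
    b = np.diff(p, axis=0)  # b1, b2, b3
    norms = np.linalg.norm(b, axis=1)
    if np.any(norms < 1e-9):
        raise GeometryError("coincident consecutive points")
    n1 = np.cross(b[0], b[1])
    n2 = np.cross(b[1], b[2])
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("collinear consecutive points")
    m1 = np.cross(n1, b[1] / norms[1])
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.atan2(y, x)
    if ang < 0.0:
        ang += 2.0 * math.pi
    return ang % (2.0 * math.pi)


def _dihedral_series(ca: np.ndarray) -> np.ndarray:
    """Torsion about each virtual bond (i, i+1), i = 1..L-3; NaN if degenerate.

    Vectorized version of :func:`virtual_dihedral` over a C-alpha trace;
    element ``t`` is the torsion of points ``(t, t+1, t+2, t+3)``.
    """
    b = np.diff(ca, axis=0)
    n1 = np.cross(b[:-2], b[1:-1])
    n2 = np.cross(b[1:-1], b[2:])
    bn = np.linalg.norm(b[1:-1], axis=1)
    m1 = np.cross(n1, b[1:-1] / np.where(bn > 0, bn, 1.0)[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    ang = np.arctan2(y, x)
    ang = np.where(ang < 0.0, ang + 2.0 * np.pi, ang) % (2.0 * np.pi)
    bad = (
        (np.linalg.norm(n1, axis=1) < 1e-9)
        | (np.linalg.norm(n2, axis=1) < 1e-9)
        | (bn < 1e-9)
    )
    return np.where(bad, np.nan, ang)


# ---------------------------------------------------------------------------
# reading


def _one_letter(resname: str) -> str | None:
    """One-letter code for a residue name; 'X' for nonstandard amino acids;
    None for non-amino-acid residues (waters, ligands)."""
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return None
    code = info.one_letter_code.upper()
    return code if code in AA_INDEX else "X"


def read_structure(path, class_label: str | None = None) -> StructureRecord:
    """Parse one chain from a PDB file into a :class:`StructureRecord`.

    The first model is used (a warning is logged for multi-model files) and
    the first chain containing a C-alpha.  Residues lacking a C-alpha are
    dropped with a warning; alternate locations resolve to the
    highest-occupancy conformer (ties: first encountered).
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: unreadable structure: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models")
    if len(st) > 1:
        logger.warning("%s: %d models; using the first", path.name, len(st))
    model = st[0]

    sequence: list[str] = []
    ca: list[list[float]] = []
    heavy: list[np.ndarray] = []
    for chain in model:
        for res in chain:
            letter = _one_letter(res.name)
            if letter is None:
                continue
            # resolve altlocs: per atom name keep the highest occupancy
            by_name: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.is_hydrogen():
                    continue
                prev = by_name.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    by_name[atom.name] = atom
            ca_atom = by_name.get("CA")
            if ca_atom is None:
                logger.warning(
                    "%s: residue %s %s lacks a C-alpha; dropped",
                    path.name,
                    res.name,
                    res.seqid.num,
                )
                continue
            sequence.append(letter)
            ca.append([ca_atom.pos.x, ca_atom.pos.y, ca_atom.pos.z])
            heavy.append(
                np.array(
                    [[a.pos.x, a.pos.y, a.pos.z] for a in by_name.values()],
                    dtype=float,
                )
            )
        if sequence:
            break  # single-chain convention: first chain with residues
    if not sequence:
        raise FormatError(f"{path}: no parseable residues with C-alpha")
    return StructureRecord(
        id=path.stem,
        sequence="".join(sequence),
        ca_coords=np.asarray(ca),
        heavy_atoms=heavy,
        fold_class=str(class_label) if class_label is not None else UNKNOWN_CLASS,
    )


# ---------------------------------------------------------------------------
# observation extraction


def extract_backbone_observations(record: StructureRecord) -> list[BackboneObservation]:
    """Trimer/dihedral-pair observations for every residue with intact context.

    Residue ``i`` (0-based) contributes when the four virtual bonds spanned by
    C-alphas ``i-2..i+2`` all have lengths inside :data:`CA_BOND_RANGE` and no
    trimer member is 'X'.  gamma_{i-1} is the torsion about bond (i-1, i),
    gamma_i about bond (i, i+1).
    """
    L = len(record)
    if L < 5:
        return []
    ca = record.ca_coords
    bond_len = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    intact = (bond_len >= CA_BOND_RANGE[0]) & (bond_len <= CA_BOND_RANGE[1])
    torsion = _dihedral_series(ca)  # torsion[t] is about bond (t+1, t+2)
    out: list[BackboneObservation] = []
    for i in range(2, L - 2):
        if not intact[i - 2 : i + 2].all():
            continue
        trimer = (record.sequence[i - 1], record.sequence[i], record.sequence[i + 1])
        if "X" in trimer:
            continue
        g1 = torsion[i - 2]  # about bond (i-1, i)
        g2 = torsion[i - 1]  # about bond (i, i+1)
        if math.isnan(g1) or math.isnan(g2):
            continue
        out.append(
            BackboneObservation(
                trimer=trimer,
                gamma_pair=(float(g1), float(g2)),
                source_id=record.id,
                position=i + 1,
            )
        )
    return out


def extract_contact_observations(
    record: StructureRecord,
    cap: float = CONTACT_DISTANCE_CAP,
    min_sep: int = MIN_CONTACT_SEPARATION,
) -> list[ContactObservation]:
    """Nearest-heavy-atom-approach contacts at sequence separation >= min_sep.

    Each unordered residue pair appears at most once; a pair qualifies when
    its minimum heavy-atom distance is <= ``cap``.
    """
    L = len(record)
    if L < min_sep + 1:
        return []
    ca = record.ca_coords
    reach = np.array(
        [float(np.linalg.norm(atoms - ca[r], axis=1).max()) for r, atoms in enumerate(record.heavy_atoms)]
    )
    # C-alpha prefilter: a residue pair can only be within `cap` if the CA
    # distance is within cap plus both side-chain reaches
    d_ca = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=2)
    limit = cap + reach[:, None] + reach[None, :]
    ii, jj = np.triu_indices(L, k=min_sep)
    cand = d_ca[ii, jj] <= limit[ii, jj]
    out: list[ContactObservation] = []
    for i, j in zip(ii[cand], jj[cand]):
        ai, aj = record.heavy_atoms[i], record.heavy_atoms[j]
        diff = ai[:, None, :] - aj[None, :, :]
        dmin = float(np.sqrt((diff**2).sum(axis=2)).min())
        if 0.0 < dmin <= cap:
            si, sj = record.sequence[i], record.sequence[j]
            if "X" in (si, sj):
                continue
            out.append(
                ContactObservation(
                    pair=tuple(sorted((si, sj))),
                    distance=dmin,
                    separation=int(j - i),
                    source_id=record.id,
                    positions=(int(i) + 1, int(j) + 1),
                )
            )
    return out


# ---------------------------------------------------------------------------
# dataset assembly and export


def read_sidecar(path) -> dict[str, str]:
    """Read a ``structure_id<TAB>scop_class`` sidecar TSV."""
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            mapping[row[0]] = str(row[1]) if len(row) > 1 else UNKNOWN_CLASS
    return mapping


def load_dataset(paths: Sequence, sidecar=None) -> Dataset:
    """Read structures, attach fold classes, and aggregate observations."""
    classes: Mapping[str, str] = read_sidecar(sidecar) if sidecar is not None else {}
    records: dict[str, StructureRecord] = {}
    bb: list[BackboneObservation] = []
    cc: list[ContactObservation] = []
    for p in paths:
        rec = read_structure(p)
        rec.fold_class = classes.get(rec.id, UNKNOWN_CLASS)
        records[rec.id] = rec
        bb.extend(extract_backbone_observations(rec))
        cc.extend(extract_contact_observations(rec))
    if not records:
        raise FormatError("no readable structures")
    for sid in classes:
        if sid not in records:
            logger.warning("sidecar id %r matches no structure", sid)
    class_index: dict[str, list[str]] = {}
    for rec in records.values():
        class_index.setdefault(rec.fold_class, []).append(rec.id)
    return Dataset(
        backbone_obs=bb,
        contact_obs=cc,
        class_index={k: tuple(sorted(v)) for k, v in sorted(class_index.items())},
        records=records,
    )


def export_fasta(records: Iterable[StructureRecord], path, rule=None) -> None:
    """Write (optionally rule-rewritten) sequences as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.sequence if rule is None else rule.apply(rec.sequence)
            fh.write(f">{rec.id} class={rec.fold_class}\n{seq}\n")


def dump_observations_tsv(dataset: Dataset, backbone_path, contact_path) -> None:
    """Dump observation streams as TSV tables."""
    with open(backbone_path, "w") as fh:
        fh.write("id\ti\ttrimer\tgamma1\tgamma2\n")
        for o in dataset.backbone_obs:
            fh.write(
                f"{o.source_id}\t{o.position}\t{''.join(o.trimer)}"
                f"\t{o.gamma_pair[0]:.6f}\t{o.gamma_pair[1]:.6f}\n"
            )
    with open(contact_path, "w") as fh:
        fh.write("id\ti\tj\taa_i\taa_j\td_c\n")
        for o in dataset.contact_obs:
            fh.write(
                f"{o.source_id}\t{o.positions[0]}\t{o.positions[1]}"
                f"\t{o.pair[0]}\t{o.pair[1]}\t{o.distance:.6f}\n"
            )
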