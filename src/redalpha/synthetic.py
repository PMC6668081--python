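"""Synthetic structure and observation generator with planted statistics.

Real evaluations of sequence/structure coding run on large non-redundant
crystal-structure sets; those corpora are not shipped here.  This module
plants a configurable sequence -> structure coupling so every downstream
stage (descriptor optimization, MI estimation, rule search, threading) can
be exercised and validated against closed-form expectations:

* each of the 20 letters belongs to one of ``g`` groups;
* the backbone dihedral pair of a residue is drawn from a basin (categorical
  over ``K`` basin centers on the torus, per central-residue group) plus
  isotropic angular noise;
* the contact distance of a residue pair is drawn from a truncated normal
  on (2, 12] A whose mean depends on the unordered group pair;
* contacts occur at ``contact_rate`` stored (unordered) contacts per residue,
  at sequence separation >= 5.

The generator emulates only the statistical structure the estimators
consume; excluded volume, side-chain packing, and real fold topology are
deliberately absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path


import gemmi
import numpy as np
from scipy import stats

from .constants import AA_ORDER, MIN_CONTACT_SEPARATION
from .errors import ConfigurationError
from .structure_io import BackboneObservation, ContactObservation, Dataset

TWO_PI = 2.0 * math.pi

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

#: virtual C-alpha bond length used for generated traces (A)
CA_BOND = 3.8

DEFAULT_CHAIN_LENGTH_RANGE = (50, 300)


@dataclass
class PlantedModel:
    """Planted sequence -> structure statistics.

    group_partition
        letter -> group index (0..g-1), covering all 20 letters.
    basin_centers
        (K, 2) basin centers in [0, 2*pi)^2, radians.
    backbone_emission
        (g, K) categorical over basins per central-residue group.
    sigma
        isotropic angular noise around the basin center, radians.
    contact_mu, contact_tau
        (g, g) symmetric truncated-normal mean (A, in (2, 12]) and common sd.
    contact_rate
        expected stored (unordered) contacts per residue.
    """

    group_partition: dict[str, int]
    basin_centers: np.ndarray
    backbone_emission: np.ndarray
    sigma: float
    contact_mu: np.ndarray
    contact_tau: float
    contact_rate: float = 1.0
    seed: int = 0
    chain_length_range: tuple[int, int] = DEFAULT_CHAIN_LENGTH_RANGE

    def __post_init__(self) -> None:
        self.basin_centers = np.asarray(self.basin_centers, dtype=float)
        self.backbone_emission = np.asarray(self.backbone_emission, dtype=float)
        self.contact_mu = np.asarray(self.contact_mu, dtype=float)
        if set(self.group_partition) != set(AA_ORDER):
            raise ConfigurationError(
                "group_partition must assign every letter to exactly one group"
            )
        g = self.n_groups
        if self.backbone_emission.shape != (g, self.n_basins):
            raise ConfigurationError("backbone_emission must have shape (g, K)")
        sums = self.backbone_emission.sum(axis=1)
        if np.any(self.backbone_emission < 0) or np.any(np.abs(sums - 1.0) > 1e-12):
            raise ConfigurationError("each categorical emission must sum to 1")
        if self.basin_centers.min() < 0.0 or self.basin_centers.max() >= TWO_PI:
            raise ConfigurationError("basin centers must lie in [0, 2*pi)^2")
        if self.contact_mu.shape != (g, g) or not np.allclose(
            self.contact_mu, self.contact_mu.T
        ):
            raise ConfigurationError("contact_mu must be a symmetric (g, g) matrix")
        if self.contact_mu.min() <= 2.0 or self.contact_mu.max() > 12.0:
            raise ConfigurationError("contact means must lie in (2, 12] A")
        if self.contact_tau <= 0.0:
            raise ConfigurationError("contact_tau must be positive")
        if self.sigma < 0.0:
            raise ConfigurationError("sigma must be nonnegative")
        if self.contact_rate < 0.0:
            raise ConfigurationError("contact_rate must be nonnegative")

    @property
    def n_groups(self) -> int:
        return int(max(self.group_partition.values())) + 1

    @property
    def n_basins(self) -> int:
        return len(self.basin_centers)

    @property
    def group_table(self) -> np.ndarray:
        """Letter-index -> group index, length 20."""
        return np.array([self.group_partition[a] for a in AA_ORDER], dtype=np.int64)


def default_model(seed: int = 0, **overrides) -> PlantedModel:
    """Four physicochemical groups, three secondary-structure-like basins plus
    a diffuse one, and group-pair-dependent contact distances."""
    groups = {}
    for a in "ACFILMVWY":
        groups[a] = 0  # hydrophobic
    for a in "HNQST":
        groups[a] = 1  # polar
    for a in "DEKR":
        groups[a] = 2  # charged
    for a in "GP":
        groups[a] = 3  # special
    centers = np.array([[0.87, 0.87], [3.3, 3.3], [5.0, 5.0], [1.9, 4.7]])
    emission = np.array(
        [
            [0.45, 0.35, 0.10, 0.10],
            [0.30, 0.20, 0.30, 0.20],
            [0.40, 0.10, 0.30, 0.20],
            [0.10, 0.15, 0.40, 0.35],
        ]
    )
    mu = np.array(
        [
            [4.5, 6.5, 7.5, 6.0],
            [6.5, 6.0, 7.0, 6.5],
            [7.5, 7.0, 8.5, 7.0],
            [6.0, 6.5, 7.0, 5.5],
        ]
    )
    params = dict(
        group_partition=groups,
        basin_centers=centers,
        backbone_emission=emission,
        sigma=0.25,
        contact_mu=mu,
        contact_tau=1.0,
        contact_rate=1.0,
        seed=seed,
    )
    params.update(overrides)
    return PlantedModel(**params)


def informative_letters_model(
    members: str = "ADEGILPSTV", sigma: float = 0.2, seed: int = 0
) -> PlantedModel:
    """A model whose information is fully preserved by one known alphabet.

    The 20 letters form ``len(members)`` redundant pairs: each pair couples
    one member letter with one excluded partner, shares a dedicated backbone
    basin, and has a distinctive contact-distance mean.  Rewriting every
    partner onto its member loses nothing, so ``members`` (and any other
    one-letter-per-pair transversal) retains the full planted mutual
    information, while an alphabet keeping both letters of one pair and
    neither letter of another must merge two distinct basins and lose
    information.  Backbone and contact signals share the same group
    structure, so the optimal alphabet is weight-independent.
    """
    members = "".join(sorted(set(members)))
    n = len(members)
    partners = [a for a in AA_ORDER if a not in members]
    if len(partners) != n:
        raise ConfigurationError("members must be half of the 20-letter code")
    groups = {m: i for i, m in enumerate(members)}
    groups.update({p: i for i, p in enumerate(partners)})
    # distinct basin centers on a coarse torus grid
    side = math.ceil(math.sqrt(n))
    step = TWO_PI / side
    centers = np.array(
        [[(i % side + 0.5) * step, (i // side + 0.5) * step] for i in range(n)]
    )
    emission = np.full((n, n), 0.05 / max(n - 1, 1))
    np.fill_diagonal(emission, 0.95)
    emission /= emission.sum(axis=1, keepdims=True)
    mu = np.empty((n, n))
    vals = np.linspace(4.5, 9.5, n)
    for g in range(n):
        for h in range(g, n):
            mu[g, h] = mu[h, g] = vals[(g + h) % n]
    return PlantedModel(
        group_partition=groups,
        basin_centers=centers,
        backbone_emission=emission,
        sigma=sigma,
        contact_mu=mu,
        contact_tau=0.8,
        contact_rate=1.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# observation sampling


def _chain_lengths(model: PlantedModel, n_residues: int, rng) -> list[int]:
    lo, hi = model.chain_length_range
    lengths: list[int] = []
    left = n_residues
    while left > 0:
        L = int(rng.integers(lo, hi + 1))
        L = min(L, max(left, 10))
        lengths.append(L)
        left -= L
    return lengths


def generate_observations(
    model: PlantedModel, n_residues: int, seed: int | None = None
) -> Dataset:
    """Sample a Dataset of backbone and contact observations from the model.

    Chains of random length are drawn until ``n_residues`` residues exist;
    every interior residue yields one backbone observation, and stored
    contacts are sampled at ``contact_rate`` per residue with sequence
    separation >= 5.
    """
    if n_residues < 3:
        raise ConfigurationError("n_residues must be >= 3")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    gtab = model.group_table
    bb: list[BackboneObservation] = []
    cc: list[ContactObservation] = []
    for ci, L in enumerate(_chain_lengths(model, n_residues, rng)):
        sid = f"synth{ci:04d}"
        seq_idx = rng.integers(0, 20, size=L)
        seq = "".join(AA_ORDER[i] for i in seq_idx)
        groups = gtab[seq_idx]
        # backbone: one observation per interior residue
        inner = np.arange(1, L - 1)
        cum = np.cumsum(model.backbone_emission, axis=1)
        u = rng.random(len(inner))
        basins = np.array(
            [np.searchsorted(cum[g], x) for g, x in zip(groups[inner], u)]
        )
        gam = model.basin_centers[basins] + rng.normal(
            0.0, model.sigma, size=(len(inner), 2)
        )
        gam = np.mod(gam, TWO_PI)
        for pos, b, (g1, g2) in zip(inner, basins, gam):
            i = int(pos)
            bb.append(
                BackboneObservation(
                    trimer=(seq[i - 1], seq[i], seq[i + 1]),
                    gamma_pair=(float(g1), float(g2)),
                    source_id=sid,
                    position=i + 1,
                )
            )
        # contacts
        if L > 2 * MIN_CONTACT_SEPARATION:
            n_contacts = int(rng.poisson(model.contact_rate * L))
            if n_contacts:
                ii = rng.integers(0, L - MIN_CONTACT_SEPARATION, size=n_contacts)
                jj = ii + MIN_CONTACT_SEPARATION + (
                    rng.random(n_contacts) * (L - ii - MIN_CONTACT_SEPARATION)
                ).astype(np.int64)
                mu = model.contact_mu[groups[ii], groups[jj]]
                a = (2.0 - mu) / model.contact_tau
                b = (12.0 - mu) / model.contact_tau
                d = stats.truncnorm.rvs(
                    a, b, loc=mu, scale=model.contact_tau,
                    size=n_contacts, random_state=rng,
                )
                for i, j, dist in zip(ii, jj, d):
                    cc.append(
                        ContactObservation(
                            pair=tuple(sorted((seq[i], seq[j]))),
                            distance=float(dist),
                            separation=int(j - i),
                            source_id=sid,
                            positions=(int(i) + 1, int(j) + 1),
                        )
                    )
    return Dataset(backbone_obs=bb, contact_obs=cc)


# ---------------------------------------------------------------------------
# coordinate building


def _place_next(p1, p2, p3, r: float, theta: float, phi: float) -> np.ndarray:
    """Natural-extension placement: next point at bond length r, bond angle
    theta, and torsion phi relative to (p1, p2, p3)."""
    b1 = p2 - p1
    b2 = p3 - p2
    b2n = b2 / np.linalg.norm(b2)
    n = np.cross(b1, b2)
    n /= np.linalg.norm(n)
    m = np.cross(n, b2n)
    d = np.array(
        [
            -r * math.cos(theta),
            r * math.sin(theta) * math.cos(phi),
            -r * math.sin(theta) * math.sin(phi),
        ]
    )
    return p3 + d[0] * b2n + d[1] * m + d[2] * n


def _build_trace(torsions: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """C-alpha trace with the given per-bond torsions (about bonds 1..L-3)."""
    L = len(torsions) + 3
    ca = np.zeros((L, 3))
    ca[1] = [CA_BOND, 0.0, 0.0]
    th0 = thetas[0]
    ca[2] = ca[1] + CA_BOND * np.array([-math.cos(th0), math.sin(th0), 0.0])
    for t in range(L - 3):
        ca[t + 3] = _place_next(
            ca[t], ca[t + 1], ca[t + 2], CA_BOND, thetas[min(t + 1, len(thetas) - 1)], torsions[t]
        )
    return ca


#: per-basin bond angle: helix-like basins are tighter than extended ones
def _bond_angle_for(center: np.ndarray) -> float:
    helix_like = np.linalg.norm(center - np.array([0.87, 0.87])) < 1.0
    return math.radians(91.0) if helix_like else math.radians(115.0)


def _classify_fold(states: np.ndarray, model: PlantedModel, L: int) -> str:
    """Heuristic fold-class label from the fragment-state composition."""
    centers = model.basin_centers
    helix = int(np.argmin(np.linalg.norm(centers - [0.87, 0.87], axis=1)))
    strand = int(np.argmin(np.linalg.norm(centers - [3.3, 3.3], axis=1)))
    fh = float(np.mean(states == helix))
    fs = float(np.mean(states == strand))
    if L < 50:
        return "7"
    if fh > 0.5:
        return "1"
    if fs > 0.5:
        return "2"
    if fh > 0.2 and fs > 0.2:
        return "3"
    return "4"


def generate_coordinate_files(
    model: PlantedModel,
    n_chains: int,
    chain_length: int,
    out_dir,
    seed: int | None = None,
) -> tuple[list[Path], Path]:
    """Write PDB files of poly-CA-plus-pseudo-sidechain chains and a class
    sidecar TSV; returns (pdb paths, sidecar path).

    Each residue draws a fragment state from its group's backbone emission;
    the virtual torsion about bond (i, i+1) is that state's basin value plus
    noise, so read-back dihedral pairs land in the planted basins.  One
    pseudo side-chain atom (CB) sits 1.5 A off each C-alpha to make
    nearest-atom-approach distances nondegenerate.
    """
    if chain_length < 10:
        raise ConfigurationError("chain_length must be >= 10")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    rng = np.random.default_rng(model.seed if seed is None else seed)
    gtab = model.group_table
    cum = np.cumsum(model.backbone_emission, axis=1)
    paths: list[Path] = []
    sidecar = out_dir / "classes.tsv"
    with open(sidecar, "w") as side_fh:
        for ci in range(n_chains):
            sid = f"chain{ci:04d}"
            L = chain_length
            seq_idx = rng.integers(0, 20, size=L)
            seq = "".join(AA_ORDER[i] for i in seq_idx)
            u = rng.random(L)
            states = np.array(
                [np.searchsorted(cum[gtab[s]], x) for s, x in zip(seq_idx, u)]
            )
            # torsion about bond (i, i+1) from residue i's state (i = 1..L-3)
            tors = model.basin_centers[states[1 : L - 2], 1] + rng.normal(
                0.0, model.sigma, size=L - 3
            )
            thetas = np.array(
                [_bond_angle_for(model.basin_centers[s]) for s in states[1 : L - 1]]
            )
            ca = _build_trace(np.mod(tors, TWO_PI), thetas)
            cb = _pseudo_sidechains(ca, rng)
            path = out_dir / f"{sid}.pdb"
            _write_pdb(path, sid, seq, ca, cb)
            paths.append(path)
            side_fh.write(f"{sid}\t{_classify_fold(states, model, L)}\n")
    return paths, sidecar


def _pseudo_sidechains(ca: np.ndarray, rng) -> np.ndarray:
    """One CB pseudo-atom per residue, 1.5 A off the local backbone plane."""
    L = len(ca)
    cb = np.empty_like(ca)
    for i in range(L):
        if 0 < i < L - 1:
            b1 = ca[i] - ca[i - 1]
            b2 = ca[i + 1] - ca[i]
            n = np.cross(b1, b2)
            nn = np.linalg.norm(n)
            u = n / nn if nn > 1e-9 else np.array([0.0, 0.0, 1.0])
        else:
            u = np.array([0.0, 0.0, 1.0])
        cb[i] = ca[i] + 1.5 * u
    return cb


def _write_pdb(path: Path, sid: str, seq: str, ca: np.ndarray, cb: np.ndarray) -> None:
    st = gemmi.Structure()
    st.name = sid
    mdl = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, letter in enumerate(seq):
        res = gemmi.Residue()
        res.name = THREE_LETTER[letter]
        res.seqid = gemmi.SeqId(i + 1, " ")
        for name, pos in (("CA", ca[i]), ("CB", cb[i])):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element("C")
            atom.occ = 1.0
            atom.b_iso = 0.0
            atom.pos = gemmi.Position(*pos)
            res.add_atom(atom)
        chain.add_residue(res)
    mdl.add_chain(chain)
    st.add_model(mdl)
    st.setup_entities()
    st.write_pdb(str(path))
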