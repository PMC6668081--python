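"""Frequency models and mutual-information estimators.

The package's central statistic is the per-residue mutual information between
sequence and discretized structure,

    I = (1/n_d) * sum_obs ln[ f(c | s) / f(c) ]        (nats),

estimated from observed frequencies ``f`` with two safeguards against
self-memorization:

* leave-one-out (``loo``): each observation's own count is removed from the
  joint count, the conditional total, the marginal count, and the grand total
  before computing its contribution;
* background regularization (``lam``): frequencies are convex-mixed with a
  background, ``f(c|s) = (N(c,s) [-1] + lam*b(c)) / (N(s) [-1] + lam)`` with
  ``b(c) = N(c)/n`` the marginal background, and
  ``f(c) = (N(c) [-1] + lam/K) / (n [-1] + lam)`` with ``K`` the number of
  structural states.  ``lam`` vanishes relative to counts as data grow.

Four estimators are provided: the backbone term (trimer -> Voronoi cell), its
trimer-normalized variant in which each of the 8000 full-alphabet trimers
contributes equally, the contact term (letter pair -> distance bin, summed
over each residue's contact environment), and their weighted total.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .alphabets import SubstitutionRule
from .constants import N_LETTERS, N_TRIMERS
from .descriptors import ContactDiscretization, VoronoiPartition, assign_bins
from .errors import ConfigurationError
from .structure_io import Dataset

Conditioning = Literal["trimer", "central"]


# ---------------------------------------------------------------------------
# shared pointwise machinery


def _pointwise_log_terms(
    cond: np.ndarray,
    states: np.ndarray,
    n_states: int,
    lam: float,
    loo: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-observation ``ln f(state|cond)`` and ``ln f(state)``.

    ``cond`` are nonnegative integer condition codes, ``states`` integer
    structural-state codes in ``0..n_states-1``.  Raises on a nonpositive log
    argument (possible only at lam == 0 with loo on).
    """
    n = len(states)
    if n == 0:
        raise ConfigurationError("no observations")
    if loo and n < 2:
        raise ConfigurationError("leave-one-out requires at least 2 observations")
    n_state = np.bincount(states, minlength=n_states).astype(float)
    background = n_state / n
    # joint and conditional-total counts via compact codes
    cond_codes, cond_inv = np.unique(cond, return_inverse=True)
    n_cond = np.bincount(cond_inv).astype(float)
    jkeys = cond_inv * n_states + states
    n_joint = np.bincount(jkeys, minlength=len(cond_codes) * n_states).astype(float)
    sub = 1.0 if loo else 0.0
    num = n_joint[jkeys] - sub + lam * background[states]
    den = n_cond[cond_inv] - sub + lam
    marg_num = n_state[states] - sub + lam / n_states
    marg_den = n - sub + lam
    if np.any(num <= 0.0) or np.any(marg_num <= 0.0) or den.min() <= 0.0:
        raise ConfigurationError(
            "nonpositive frequency estimate; use lam > 0 with leave-one-out"
        )
    return np.log(num / den), np.log(marg_num / marg_den)


def _dataset_hash(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# frequency models


@dataclass
class BackboneFrequencyModel:
    """Counts linking reduced trimer sequence to Voronoi backbone cells."""

    partition: VoronoiPartition
    rule: SubstitutionRule
    lam: float
    loo: bool
    conditioning: Conditioning
    n_d: int
    cells: np.ndarray  # (n_d,) 0-based cell per observation
    cond: np.ndarray  # (n_d,) reduced trimer code (or central letter code)
    full_trimers: np.ndarray  # (n_d,) full-alphabet trimer code, pre-rule

    @property
    def k(self) -> int:
        return self.partition.k

    def n_cell(self) -> np.ndarray:
        """N(cell), length k."""
        return np.bincount(self.cells, minlength=self.k)

    def n_cond(self) -> dict[int, int]:
        """N(trimer) (or N(central letter)) keyed by code."""
        codes, counts = np.unique(self.cond, return_counts=True)
        return dict(zip(codes.tolist(), counts.tolist()))

    def n_joint(self) -> dict[tuple[int, int], int]:
        """N(cell, trimer) keyed by (cond code, cell)."""
        keys, counts = np.unique(
            np.stack([self.cond, self.cells], axis=1), axis=0, return_counts=True
        )
        return {(int(a), int(b)): int(c) for (a, b), c in zip(keys, counts)}


@dataclass
class ContactFrequencyModel:
    """Counts linking reduced unordered letter pairs to contact-distance bins."""

    disc: ContactDiscretization
    rule: SubstitutionRule
    lam: float
    loo: bool
    n_d: int  # residue count for the per-residue average
    n_contacts: int
    bins: np.ndarray  # (n_contacts,) 0-based bin per stored contact
    pairs: np.ndarray  # (n_contacts,) unordered reduced pair code lo*20+hi

    def n_bin(self) -> np.ndarray:
        return np.bincount(self.bins, minlength=self.disc.m)

    def n_pair(self) -> dict[int, int]:
        codes, counts = np.unique(self.pairs, return_counts=True)
        return dict(zip(codes.tolist(), counts.tolist()))


@dataclass(frozen=True)
class MIResult:
    """The four estimator values (nats) and their provenance."""

    i_bb: float
    i_bb_norm: float
    i_c: float
    i_total: float
    alpha: float = 1.0
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if abs(self.i_total - (self.i_bb + self.alpha * self.i_c)) > 1e-12:
            raise ConfigurationError("i_total must equal i_bb + alpha * i_c")


# ---------------------------------------------------------------------------
# fitting


def _trimer_codes(tri: np.ndarray) -> np.ndarray:
    return (tri[:, 0] * N_LETTERS + tri[:, 1]) * N_LETTERS + tri[:, 2]


def fit_backbone(
    dataset: Dataset,
    partition: VoronoiPartition,
    rule: SubstitutionRule | None = None,
    lam: float = 1.0,
    loo: bool = True,
    conditioning: Conditioning = "trimer",
) -> BackboneFrequencyModel:
    """Tally backbone counts after rewriting sequences under the rule."""
    if not dataset.backbone_obs:
        raise ConfigurationError("dataset has no backbone observations")
    rule = rule if rule is not None else SubstitutionRule.identity()
    tri, gam = dataset.backbone_arrays
    reduced = rule.table[tri]
    full_codes = _trimer_codes(tri)
    if conditioning == "trimer":
        cond = _trimer_codes(reduced)
    elif conditioning == "central":
        cond = reduced[:, 1]
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown conditioning {conditioning!r}")
    cells = partition.assign(gam)
    return BackboneFrequencyModel(
        partition=partition,
        rule=rule,
        lam=float(lam),
        loo=bool(loo),
        conditioning=conditioning,
        n_d=len(cells),
        cells=cells,
        cond=cond,
        full_trimers=full_codes,
    )


def fit_contact(
    dataset: Dataset,
    disc: ContactDiscretization,
    rule: SubstitutionRule | None = None,
    lam: float = 1.0,
    loo: bool = True,
) -> ContactFrequencyModel:
    """Tally contact counts; contacts beyond the discretization cap are dropped
    from both numerator and denominator counts."""
    if not dataset.contact_obs:
        raise ConfigurationError("dataset has no contact observations")
    if dataset.n_d < 1:
        raise ConfigurationError("contact MI needs n_d >= 1 residues")
    rule = rule if rule is not None else SubstitutionRule.identity()
    pairs, dist = dataset.contact_arrays
    reduced = rule.table[pairs]
    lo = np.minimum(reduced[:, 0], reduced[:, 1])
    hi = np.maximum(reduced[:, 0], reduced[:, 1])
    bins = assign_bins(dist, disc)
    keep = bins >= 0
    return ContactFrequencyModel(
        disc=disc,
        rule=rule,
        lam=float(lam),
        loo=bool(loo),
        n_d=dataset.n_d,
        n_contacts=int(keep.sum()),
        bins=bins[keep],
        pairs=(lo * N_LETTERS + hi)[keep],
    )


# ---------------------------------------------------------------------------
# estimators


def mi_backbone(model: BackboneFrequencyModel) -> float:
    """Per-residue backbone mutual information (nats)."""
    log_cond, log_marg = _pointwise_log_terms(
        model.cond, model.cells, model.k, model.lam, model.loo
    )
    return float((log_cond - log_marg).sum() / model.n_d)


def mi_backbone_normalized(model: BackboneFrequencyModel) -> float:
    """Trimer-normalized backbone MI: each of the 8000 full-alphabet trimers
    contributes its mean per-occurrence log-ratio; unobserved trimers
    contribute 0; the average divides by 8000 unconditionally."""
    log_cond, log_marg = _pointwise_log_terms(
        model.cond, model.cells, model.k, model.lam, model.loo
    )
    codes, inv = np.unique(model.full_trimers, return_inverse=True)
    occ = np.bincount(inv).astype(float)
    weights = 1.0 / occ[inv]
    return float(((log_cond - log_marg) * weights).sum() / N_TRIMERS)


def mi_contact(model: ContactFrequencyModel) -> float:
    """Per-residue contact-environment MI: every stored unordered contact
    belongs to both endpoint residues, so it enters the residue-environment
    double sum twice."""
    if model.n_contacts == 0:
        return 0.0
    log_cond, log_marg = _pointwise_log_terms(
        model.pairs, model.bins, model.disc.m, model.lam, model.loo
    )
    return float(2.0 * (log_cond - log_marg).sum() / model.n_d)


def mi_total(i_bb: float, i_c: float, alpha: float = 1.0) -> float:
    """Weighted total MI: i_bb + alpha * i_c."""
    if alpha < 0:
        raise ConfigurationError("alpha must be nonnegative")
    return i_bb + alpha * i_c


def compute_mi(
    dataset: Dataset,
    partition: VoronoiPartition,
    disc: ContactDiscretization,
    rule: SubstitutionRule | None = None,
    lam: float = 1.0,
    loo: bool = True,
    alpha: float = 1.0,
) -> MIResult:
    """Fit both frequency models and evaluate all four estimators."""
    bb = fit_backbone(dataset, partition, rule, lam, loo)
    cc = fit_contact(dataset, disc, rule, lam, loo)
    i_bb = mi_backbone(bb)
    i_norm = mi_backbone_normalized(bb)
    i_c = mi_contact(cc)
    rule_str = (rule or SubstitutionRule.identity()).as_string()
    tri, gam = dataset.backbone_arrays
    return MIResult(
        i_bb=i_bb,
        i_bb_norm=i_norm,
        i_c=i_c,
        i_total=mi_total(i_bb, i_c, alpha),
        alpha=alpha,
        provenance={
            "dataset": _dataset_hash(tri, gam),
            "rule": rule_str,
            "lam": lam,
            "loo": loo,
        },
    )


# ---------------------------------------------------------------------------
# fast rule-objective evaluator


class RuleObjective:
    """Objective function over substitution rules for a fixed dataset.

    Precomputes per-bucket count arrays for the distinct (full trimer, cell)
    and (letter pair, bin) combinations so that evaluating one rule costs two
    bincounts and two log passes; the marginal terms ``ln f(c)`` do not depend
    on the rule and are folded into constants.  Results are memoized per rule
    image, which leaves any search trajectory unchanged while avoiding
    recomputation of revisited rules.
    """

    def __init__(
        self,
        dataset: Dataset,
        partition: VoronoiPartition,
        disc: ContactDiscretization | None = None,
        objective: str = "i_total",
        lam: float = 1.0,
        loo: bool = True,
        alpha: float = 1.0,
    ) -> None:
        if objective not in ("i_bb", "i_bb_norm", "i_total"):
            raise ConfigurationError(f"unknown objective {objective!r}")
        if objective == "i_total" and disc is None:
            raise ConfigurationError("i_total requires a contact discretization")
        self.objective = objective
        self.lam = float(lam)
        self.loo = bool(loo)
        self.alpha = float(alpha)
        self.n_d = dataset.n_d
        self._cache: dict[bytes, float] = {}
        sub = 1.0 if loo else 0.0

        # --- backbone buckets: distinct (full trimer, cell) ---
        tri, gam = dataset.backbone_arrays
        if len(tri) == 0:
            raise ConfigurationError("dataset has no backbone observations")
        self.k = partition.k
        cells = partition.assign(gam)
        full = _trimer_codes(tri)
        keys = full * self.k + cells
        uniq, counts = np.unique(keys, return_counts=True)
        self._bb_full = uniq // self.k
        self._bb_cell = uniq % self.k
        self._bb_abc = np.stack(
            [
                self._bb_full // (N_LETTERS * N_LETTERS),
                (self._bb_full // N_LETTERS) % N_LETTERS,
                self._bb_full % N_LETTERS,
            ]
        )
        self._bb_cnt = counts.astype(float)
        n = float(len(cells))
        n_cell = np.bincount(cells, minlength=self.k).astype(float)
        self._bb_bg = n_cell / n
        log_marg = np.log(
            (n_cell[self._bb_cell] - sub + lam / self.k) / (n - sub + lam)
        )
        self._m_bb = float((self._bb_cnt * log_marg).sum() / self.n_d)
        # trimer-normalized weights: each full trimer weighted 1/occurrences
        occ = np.bincount(
            self._bb_full, weights=self._bb_cnt, minlength=0
        )
        self._bb_wnorm = self._bb_cnt / occ[self._bb_full]
        self._m_norm = float((self._bb_wnorm * log_marg).sum() / N_TRIMERS)

        # --- contact buckets: distinct (unordered pair, bin) ---
        self._has_contacts = False
        if disc is not None and dataset.contact_obs:
            pairs, dist = dataset.contact_arrays
            bins = assign_bins(dist, disc)
            keep = bins >= 0
            pairs, bins = pairs[keep], bins[keep]
            if len(bins):
                self.m = disc.m
                pk = pairs[:, 0] * N_LETTERS + pairs[:, 1]
                ckeys = pk * self.m + bins
                cu, cc = np.unique(ckeys, return_counts=True)
                self._c_lo = (cu // self.m) // N_LETTERS
                self._c_hi = (cu // self.m) % N_LETTERS
                self._c_bin = cu % self.m
                self._c_cnt = cc.astype(float)
                nc = float(len(bins))
                n_bin = np.bincount(bins, minlength=self.m).astype(float)
                self._c_bg = n_bin / nc
                c_marg = np.log(
                    (n_bin[self._c_bin] - sub + lam / self.m) / (nc - sub + lam)
                )
                self._m_c = float(2.0 * (self._c_cnt * c_marg).sum() / self.n_d)
                self._has_contacts = True
        if objective == "i_total" and not self._has_contacts:
            raise ConfigurationError("i_total objective needs contact observations")

    # -- component evaluation ------------------------------------------------

    def components(self, table: np.ndarray) -> tuple[float, float, float]:
        """(i_bb, i_bb_norm, i_c) under the rule image ``table`` (length 20)."""
        sub = 1.0 if self.loo else 0.0
        lam = self.lam
        # compact member codes: the image set has n <= 20 letters, so reduced
        # trimer keys fit in n^3 instead of 20^3, shrinking the bincounts
        members, ctable = np.unique(table, return_inverse=True)
        n = len(members)
        abc = ctable[self._bb_abc]
        rt = (abc[0] * n + abc[1]) * n + abc[2]
        jk = rt * self.k + self._bb_cell
        joint = np.bincount(jk, weights=self._bb_cnt, minlength=n * n * n * self.k)
        condt = np.bincount(rt, weights=self._bb_cnt, minlength=n * n * n)
        log_ratio = np.log(
            (joint[jk] - sub + lam * self._bb_bg[self._bb_cell])
            / (condt[rt] - sub + lam)
        )
        i_bb = float((self._bb_cnt * log_ratio).sum() / self.n_d) - self._m_bb
        i_norm = float((self._bb_wnorm * log_ratio).sum() / N_TRIMERS) - self._m_norm
        i_c = 0.0
        if self._has_contacts:
            lo = ctable[self._c_lo]
            hi = ctable[self._c_hi]
            pk = np.minimum(lo, hi) * n + np.maximum(lo, hi)
            jk = pk * self.m + self._c_bin
            joint = np.bincount(jk, weights=self._c_cnt, minlength=n * n * self.m)
            condp = np.bincount(pk, weights=self._c_cnt, minlength=n * n)
            clog = np.log(
                (joint[jk] - sub + lam * self._c_bg[self._c_bin])
                / (condp[pk] - sub + lam)
            )
            i_c = float(2.0 * (self._c_cnt * clog).sum() / self.n_d) - self._m_c
        return i_bb, i_norm, i_c

    def __call__(self, rule: SubstitutionRule | np.ndarray) -> float:
        table = rule.table if isinstance(rule, SubstitutionRule) else rule
        key = table.astype(np.int8).tobytes()
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        i_bb, i_norm, i_c = self.components(table)
        if self.objective == "i_bb":
            value = i_bb
        elif self.objective == "i_bb_norm":
            value = i_norm
        else:
            value = i_bb + self.alpha * i_c
        self._cache[key] = value
        return value
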