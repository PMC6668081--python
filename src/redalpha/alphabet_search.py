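"""Substitution-rule optimization and reduced-alphabet surveys.

For a fixed reduced alphabet the best substitution rule is the one whose
virtual mutagenesis retains the most mutual information between the rewritten
sequences and the (fixed) structural descriptors.  The rule space for an
n-letter alphabet has n^(20-n) states; it is searched either exhaustively
(small spaces) or by a restart hill climb that reassigns 1-3 excluded
letters per proposal.  Surveys run the rule search over many alphabets and
rank a query alphabet within the resulting objective spectrum.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .alphabets import (
    PREBIOTIC,
    ReducedAlphabet,
    SubstitutionRule,
    apply_rule,
    count_reduced_alphabets,
    count_substitution_rules,
    enumerate_alphabets,
)
from .constants import AA_ORDER, N_LETTERS
from .errors import ConfigurationError
from .mc import MCParams
from .mi_core import RuleObjective

__all__ = [
    "PREBIOTIC",
    "ReducedAlphabet",
    "SubstitutionRule",
    "SurveyResult",
    "apply_rule",
    "count_reduced_alphabets",
    "count_substitution_rules",
    "enumerate_alphabets",
    "optimize_rule_mc",
    "optimize_rule_exhaustive",
    "survey_alphabets",
    "rank_and_percentile",
    "compare_mc_exhaustive",
    "alphabet_seed",
]

DEFAULT_RULE_BUDGET = 10**6


def alphabet_seed(master_seed: int, alphabet: ReducedAlphabet) -> int:
    """Deterministic per-alphabet RNG seed below 2**31, independent of
    evaluation order and worker count."""
    digest = hashlib.sha256(f"{master_seed}:{alphabet.canonical}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _rule_from_state(
    alphabet: ReducedAlphabet, state: np.ndarray, base: np.ndarray, members: np.ndarray
) -> SubstitutionRule:
    table = base.copy()
    table[list(alphabet.excluded_indices)] = members[state]
    return SubstitutionRule.from_string("".join(AA_ORDER[i] for i in table))


def _make_evaluator(dataset, partition, disc, objective, lam, loo, alpha):
    if partition is None:
        raise ConfigurationError("a fitted Voronoi partition is required")
    return RuleObjective(
        dataset, partition, disc=disc, objective=objective, lam=lam, loo=loo, alpha=alpha
    )


def optimize_rule_mc(
    dataset,
    alphabet: ReducedAlphabet,
    partition=None,
    disc=None,
    objective: str = "i_total",
    mc: MCParams = MCParams(),
    seed: int = 0,
    lam: float = 1.0,
    loo: bool = True,
    alpha: float = 1.0,
    evaluator: RuleObjective | None = None,
    return_trace: bool = False,
):
    """Restart hill climb over substitution rules; returns (rule, objective).

    Proposals reassign a uniform-random 1..max_move of the excluded letters
    to uniform-random members; only strictly improving proposals are
    accepted; a restart stops after ``patience`` consecutive rejections.
    Ties between equally scoring rules break toward the lexicographically
    smaller rule string.
    """
    ev = evaluator or _make_evaluator(dataset, partition, disc, objective, lam, loo, alpha)
    members = np.array(alphabet.member_indices, dtype=np.int64)
    excluded = np.array(alphabet.excluded_indices, dtype=np.int64)
    e, n = len(excluded), len(members)
    base = np.arange(N_LETTERS, dtype=np.int64)
    if e == 0:
        rule = SubstitutionRule.identity()
        return (rule, ev(rule), [ev(rule)]) if return_trace else (rule, ev(rule))
    rng = np.random.default_rng(seed)
    max_move = min(mc.max_move, e)

    def table_of(state: np.ndarray) -> np.ndarray:
        t = base.copy()
        t[excluded] = members[state]
        return t

    best_obj = -np.inf
    best_state: np.ndarray | None = None
    best_str = ""
    trace: list[float] = []
    block = 2048
    for _ in range(mc.restarts):
        state = rng.integers(0, n, size=e)
        obj = ev(table_of(state))
        trace.append(obj)
        stall = 0
        while stall < mc.patience:
            # pre-draw a block of proposals to keep the loop cheap
            sizes = rng.integers(1, max_move + 1, size=block)
            perms = np.argsort(rng.random((block, e)), axis=1)
            values = rng.integers(0, n, size=(block, e))
            for b in range(block):
                t = sizes[b]
                pos = perms[b, :t]
                cand = state.copy()
                cand[pos] = values[b, :t]
                cand_obj = ev(table_of(cand))
                if cand_obj > obj:
                    state, obj = cand, cand_obj
                    trace.append(obj)
                    stall = 0
                else:
                    stall += 1
                    if stall >= mc.patience:
                        break
        state_str = "".join(AA_ORDER[i] for i in table_of(state))
        if obj > best_obj or (obj == best_obj and state_str < best_str):
            best_obj, best_state, best_str = obj, state.copy(), state_str
    rule = _rule_from_state(alphabet, best_state, base, members)
    if return_trace:
        return rule, best_obj, trace
    return rule, best_obj


def optimize_rule_exhaustive(
    dataset,
    alphabet: ReducedAlphabet,
    partition=None,
    disc=None,
    objective: str = "i_total",
    lam: float = 1.0,
    loo: bool = True,
    alpha: float = 1.0,
    budget: int = DEFAULT_RULE_BUDGET,
    evaluator: RuleObjective | None = None,
):
    """Global maximum over all n^(20-n) substitution rules by enumeration.

    Refuses (with guidance) when the rule space exceeds ``budget``; use
    :func:`optimize_rule_mc` for larger rule spaces.
    """
    n_rules = count_substitution_rules(alphabet.n)
    if n_rules > budget:
        raise ConfigurationError(
            f"{n_rules} rules exceed the enumeration budget ({budget}); "
            "use optimize_rule_mc for this alphabet size"
        )
    ev = evaluator or _make_evaluator(dataset, partition, disc, objective, lam, loo, alpha)
    members = np.array(alphabet.member_indices, dtype=np.int64)
    excluded = np.array(alphabet.excluded_indices, dtype=np.int64)
    e, n = len(excluded), len(members)
    base = np.arange(N_LETTERS, dtype=np.int64)
    if e == 0:
        rule = SubstitutionRule.identity()
        return rule, ev(rule)
    best_obj = -np.inf
    best_state: tuple[int, ...] | None = None
    best_str = ""
    for assignment in itertools.product(range(n), repeat=e):
        table = base.copy()
        table[excluded] = members[list(assignment)]
        obj = ev(table)
        s = "".join(AA_ORDER[i] for i in table)
        if obj > best_obj or (obj == best_obj and s < best_str):
            best_obj, best_state, best_str = obj, assignment, s
    rule = _rule_from_state(
        alphabet, np.array(best_state, dtype=np.int64), base, members
    )
    return rule, best_obj


# ---------------------------------------------------------------------------
# surveys


@dataclass
class SurveyResult:
    """Ranked alphabet survey: one row per alphabet, sorted by objective
    (descending; ties by alphabet string for determinism)."""

    table: pd.DataFrame
    objective: str

    def __post_init__(self) -> None:
        self.table = self.table.sort_values(
            ["objective", "alphabet"], ascending=[False, True]
        ).reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.table)

    def row_of(self, alphabet: ReducedAlphabet) -> pd.Series:
        hit = self.table[self.table["alphabet"] == alphabet.canonical]
        if hit.empty:
            raise ConfigurationError(
                f"alphabet {alphabet.canonical} is not in the survey"
            )
        return hit.iloc[0]


def survey_alphabets(
    dataset,
    n: int = 10,
    objective: str = "i_total",
    alphabet_subset=None,
    mc: MCParams = MCParams(),
    seed: int = 0,
    workers: int = 1,
    partition=None,
    disc=None,
    lam: float = 1.0,
    loo: bool = True,
    alpha: float = 1.0,
) -> SurveyResult:
    """Optimize the substitution rule for every alphabet and rank them.

    ``alphabet_subset`` restricts the survey (otherwise all C(20, n)
    alphabets are evaluated).  Per-alphabet seeds derive from the master
    seed and the alphabet's canonical string, so results are independent of
    evaluation order and worker count.
    """
    alphabets = (
        list(alphabet_subset)
        if alphabet_subset is not None
        else list(enumerate_alphabets(n))
    )
    ev = _make_evaluator(dataset, partition, disc, objective, lam, loo, alpha)

    def one(alphabet: ReducedAlphabet, evaluator) -> dict:
        rule, obj = optimize_rule_mc(
            dataset,
            alphabet,
            objective=objective,
            mc=mc,
            seed=alphabet_seed(seed, alphabet),
            evaluator=evaluator,
        )
        return {
            "alphabet": alphabet.canonical,
            "rule": rule.as_string(),
            "objective": obj,
        }

    if workers > 1:
        rows = Parallel(n_jobs=workers)(delayed(one)(a, ev) for a in alphabets)
    else:
        rows = [one(a, ev) for a in alphabets]
    return SurveyResult(table=pd.DataFrame(rows), objective=objective)


def rank_and_percentile(
    survey: SurveyResult, alphabet: ReducedAlphabet
) -> tuple[int, float]:
    """(rank, percentile) of an alphabet within a survey.

    rank = 1 + number of alphabets with strictly greater objective;
    percentile = (1 - n_better / N) * 100.
    """
    row = survey.row_of(alphabet)
    n_better = int((survey.table["objective"] > row["objective"]).sum())
    return n_better + 1, percentile_from_count(n_better, survey.n)


def percentile_from_count(n_better: int, total: int) -> float:
    """Percentile of an item that ``n_better`` of ``total`` entries beat."""
    if total < 1 or not 0 <= n_better <= total:
        raise ConfigurationError("invalid rank inputs")
    return (1.0 - n_better / total) * 100.0


# ---------------------------------------------------------------------------
# MC-vs-exhaustive agreement check


def random_alphabets(
    n_alphabets: int, size: int, seed: int = 0
) -> list[ReducedAlphabet]:
    """Distinct uniformly drawn alphabets of the given size."""
    if n_alphabets > count_reduced_alphabets(size):
        raise ConfigurationError("more alphabets requested than exist")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[ReducedAlphabet] = []
    while len(out) < n_alphabets:
        letters = frozenset(
            AA_ORDER[i] for i in rng.choice(N_LETTERS, size=size, replace=False)
        )
        alphabet = ReducedAlphabet(letters)
        if alphabet.canonical not in seen:
            seen.add(alphabet.canonical)
            out.append(alphabet)
    return out


def compare_mc_exhaustive(
    dataset,
    alphabets,
    partition=None,
    disc=None,
    objective: str = "i_total",
    mc: MCParams = MCParams(),
    seed: int = 0,
    lam: float = 1.0,
    loo: bool = True,
    alpha: float = 1.0,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """For each alphabet run both rule searches and record whether the hill
    climb attained the enumeration optimum (|difference| <= tol)."""
    rows = []
    for alphabet in alphabets:
        ev = _make_evaluator(dataset, partition, disc, objective, lam, loo, alpha)
        _, exact = optimize_rule_exhaustive(
            dataset, alphabet, objective=objective, evaluator=ev
        )
        _, approx = optimize_rule_mc(
            dataset,
            alphabet,
            objective=objective,
            mc=mc,
            seed=alphabet_seed(seed, alphabet),
            evaluator=ev,
        )
        rows.append(
            {
                "alphabet": alphabet.canonical,
                "exhaustive": exact,
                "mc": approx,
                "match": bool(abs(exact - approx) <= tol),
            }
        )
    return pd.DataFrame(rows)
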