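#!/usr/bin/env python
"""Survey reduced alphabets by optimized mutual information.

For a sample of 10-letter alphabets (always including the prebiotic set
{A,D,E,G,I,L,P,S,T,V}), optimize the substitution rule on the corpus via
the restart hill climb and rank alphabets by the retained total mutual
information.  Writes the ranked table and the prebiotic rank/percentile
under results/survey/.
"""

import json
from pathlib import Path

from redalpha import MCParams
from redalpha.alphabet_search import (
    PREBIOTIC,
    random_alphabets,
    rank_and_percentile,
    survey_alphabets,
)
from redalpha.descriptors import ContactDiscretization, VoronoiPartition
from redalpha.structure_io import load_dataset

SEED = 2026
N_SAMPLED = 300
ROOT = Path(__file__).resolve().parent.parent
CORPUS = ROOT / "scratch" / "corpus" / "structures"
DESC = ROOT / "results" / "descriptors"
OUT = ROOT / "results" / "survey"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    paths = sorted(CORPUS.glob("*.pdb"))
    if not paths or not (DESC / "partition.json").exists():
        raise SystemExit("run 01 and 02 first")
    dataset = load_dataset(paths, CORPUS / "classes.tsv")
    partition = VoronoiPartition.from_json(DESC / "partition.json")
    disc = ContactDiscretization.from_json(DESC / "contact_discretization.json")

    sample = random_alphabets(N_SAMPLED, 10, seed=SEED)
    subset = [PREBIOTIC] + [a for a in sample if a.canonical != PREBIOTIC.canonical]
    survey = survey_alphabets(
        dataset,
        n=10,
        objective="i_total",
        alphabet_subset=subset,
        mc=MCParams(patience=300, restarts=2),
        seed=SEED,
        partition=partition,
        disc=disc,
    )
    table = survey.table.copy()
    table["rank"] = range(1, len(table) + 1)
    table.to_csv(OUT / "survey.tsv", sep="\t", index=False, float_format="%.6f")
    rank, pct = rank_and_percentile(survey, PREBIOTIC)
    summary = {
        "objective": "i_total",
        "alphabets": survey.n,
        "prebiotic_rank": rank,
        "prebiotic_percentile": round(pct, 2),
        "best_alphabet": table.iloc[0]["alphabet"],
        "best_rule": table.iloc[0]["rule"],
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2))
    print(f"surveyed {survey.n} alphabets on {len(dataset.records)} chains")
    print(
        f"prebiotic set ranks {rank}/{survey.n} "
        f"({pct:.2f} percentile) under i_total"
    )
    print(f"best: {table.iloc[0]['alphabet']} (rule {table.iloc[0]['rule']})")


if __name__ == "__main__":
    main()
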