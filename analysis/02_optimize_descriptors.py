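#!/usr/bin/env python
"""Fit the information-optimized structural descriptors.

Scans the number of Voronoi cells k for the backbone dihedral-pair
descriptor and the (d_max, m) grid for the contact-distance descriptor on
the corpus from 01_generate_corpus.py, maximizing leave-one-out mutual
information.  Both curves rise and then fall: too-coarse descriptors cannot
express sequence dependence, too-fine ones cannot be populated by the data.
Writes the scan tables and the selected descriptors under
results/descriptors/.
"""

from pathlib import Path

from redalpha import MCParams, optimize_contact_discretization, optimize_voronoi, scan_k
from redalpha.structure_io import load_dataset

SEED = 2026
ROOT = Path(__file__).resolve().parent.parent
CORPUS = ROOT / "scratch" / "corpus" / "structures"
OUT = ROOT / "results" / "descriptors"

K_VALUES = [2, 4, 8, 16, 32, 64]
MC = MCParams(patience=150, restarts=3)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    paths = sorted(CORPUS.glob("*.pdb"))
    if not paths:
        raise SystemExit("run 01_generate_corpus.py first")
    dataset = load_dataset(paths, CORPUS / "classes.tsv")

    best_k, ktable = scan_k(dataset, K_VALUES, mc=MC, seed=SEED)
    ktable.to_csv(OUT / "k_scan.tsv", sep="\t", index=False, float_format="%.6f")
    partition, obj = optimize_voronoi(dataset, best_k, mc=MC, seed=SEED + 1)
    partition.to_json(OUT / "partition.json")
    print(f"backbone descriptor: k={best_k} (objective {obj:.4f} nats)")
    print(ktable.to_string(index=False))

    disc, mtable = optimize_contact_discretization(
        dataset,
        d_max_values=[6.0, 8.0, 10.0, 12.0],
        m_values=[2, 5, 10, 20, 35, 50, 75, 100],
    )
    mtable.to_csv(OUT / "contact_scan.tsv", sep="\t", index=False, float_format="%.6f")
    disc.to_json(OUT / "contact_discretization.json")
    best = mtable.loc[mtable["objective"].idxmax()]
    print(
        f"contact descriptor: d_max={disc.d_max} A, m={disc.m} "
        f"(objective {best['objective']:.4f} nats)"
    )


if __name__ == "__main__":
    main()
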