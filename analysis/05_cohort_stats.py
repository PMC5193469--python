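"""Cohort statistics on the 33-case fixture.

Renders the clinicopathological frequency table, the per-case
deleted/altered arm counts (group means 2 / 2.7 / 0.3 / 0.3 / 1.75,
total 1.9 under the whole-chromosome-9-counts-once convention), and
the Yates-corrected chi-square for the 9p OII-vs-OIII comparison
(p = 0.002).

Usage: python analysis/05_cohort_stats.py [--out-dir results]
"""

import argparse
from pathlib import Path

from oligofish.cohort_stats import (chi_square_test, deletion_count_summary,
                                    group_frequency_table)
from oligofish.fixtures import load_fixture


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cohort = load_fixture("cohort")
    table = group_frequency_table(cohort)
    table.to_csv(args.out_dir / "frequency_table.csv")
    print(table.to_string())

    dels = deletion_count_summary(cohort)
    dels.per_case.to_csv(args.out_dir / "deletion_counts.csv", index=False)
    print("\nmean deleted arms per case:")
    print(f"  total {dels.total_mean:.2f}")
    for g, m in dels.group_means.items():
        print(f"  {g}: {m:.2f}")

    n_del_oii = int((cohort.loc[cohort.group == "OII", "status_9p"]
                     == "DELETED").sum())
    n_del_oiii = int((cohort.loc[cohort.group == "OIII", "status_9p"]
                      == "DELETED").sum())
    tab = [[n_del_oii, 13 - n_del_oii], [n_del_oiii, 10 - n_del_oiii]]
    stat, p = chi_square_test(tab)
    print(f"\n9p loss OII vs OIII {tab}: Yates chi2 = {stat:.2f}, p = {p:.4f}")
    print(f"wrote tables to {args.out_dir}/")


if __name__ == "__main__":
    main()
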