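"""Osmotic-stress induction panel recovered by the 2^-ddCt method.

Simulates qPCR Ct tables (16S rRNA internal standard, 3 replicates,
0.3-cycle noise) for the osmotic-stress panel -- antitoxin gene induced 3x,
protease genes 2x/4x/3x/6x -- and reports the recovered fold changes with
the >2 / <0.5 significance rule.
"""

from _common import RESULTS, SEED
from tamine.qpcr import fold_change_report
from tamine.synth import DEFAULT_TRUE_FOLDS, make_ct_table


def main() -> None:
    table = make_ct_table(DEFAULT_TRUE_FOLDS, n_replicates=3, sd=0.3, seed=SEED)
    table.to_csv(RESULTS / "05_ct_table.tsv", sep="\t", index=False)
    report = fold_change_report(table)
    report.to_csv(RESULTS / "05_fold_changes.tsv", sep="\t", index=False,
                  float_format="%.3f")
    print(report.to_string(index=False))
    print("true folds:", DEFAULT_TRUE_FOLDS)
    print(f"fold table -> {RESULTS / '05_fold_changes.tsv'}")


if __name__ == "__main__":
    main()
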