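"""Recompute the clinical-table statistics from printed summaries.

The effect sizes and tests of the study's demographic / neuropsychological
tables are functions of the printed per-group means, SDs and counts, so
they can be recomputed exactly: pooled-SD Cohen's d and the pooled
two-sample t test per row, Fisher's exact test for the sex table.  Writes
results/clinical_tables.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cortexcam import analyze

ROWS = [
    # name, control (mean, sd), patient (mean, sd)
    ("Age (years)", (66.00, 6.37), (65.96, 5.94)),
    ("Education", (13.76, 2.70), (12.14, 3.94)),
    ("RBDQ-KR", (4.94, 3.36), (47.53, 19.46)),
    ("SCOPA-AUT", (5.88, 4.40), (13.02, 7.76)),
    ("PSQI", (3.39, 1.55), (6.92, 4.31)),
    ("ESS", (4.2, 2.74), (5.27, 3.32)),
    ("MoCA total", (27.45, 1.49), (25.57, 3.04)),
    ("MMSE", (28.88, 1.29), (27.27, 2.14)),
]
SEX = [[33, 16], [29, 20]]
N = 49


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for name, ctl, pat in ROWS:
        t, p = analyze.independent_t_test(ctl[0], ctl[1], N, pat[0], pat[1], N)
        d = analyze.cohen_d(ctl[0], ctl[1], N, pat[0], pat[1], N)
        rows.append({"variable": name, "t": t, "p_value": p, "cohen_d": d})
    table = pd.DataFrame(rows)
    p_sex = analyze.fisher_exact(np.array(SEX))

    table.to_csv(out / "clinical_tables.csv", index=False)
    print(table.round(3).to_string(index=False))
    print(f"Sex (Fisher exact, two-sided): p = {p_sex:.3f}")


if __name__ == "__main__":
    main()
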