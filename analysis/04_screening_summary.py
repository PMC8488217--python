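"""Aggregate drug/pathway/stem-cell screening hits across the cohort.

Counts, per category, how many patients carry a hit in each gene and in
which sample roles it appears — the tabular equivalent of a
gene x patient screening heatmap.  Writes results/screening_summary.tsv.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
REPORT = ROOT / "results" / "report"
OUT = ROOT / "results" / "screening_summary.tsv"


def main() -> None:
    path = REPORT / "screening.tsv"
    if not path.exists():
        raise SystemExit("report not found - run analysis/02_run_pipeline.py first")
    hits = pd.read_csv(path, sep="\t")
    if hits.empty:
        print("no screening hits in this cohort")
        pd.DataFrame(columns=["category", "gene", "n_patients", "n_variants",
                              "sample_roles"]).to_csv(OUT, sep="\t", index=False)
        return
    summary = (hits.groupby(["category", "gene"])
               .agg(n_patients=("patient", "nunique"),
                    n_variants=("pos", "nunique"),
                    sample_roles=("sample_roles",
                                  lambda s: ",".join(sorted(
                                      set(",".join(s.dropna()).split(","))
                                      - {""}))))
               .reset_index()
               .sort_values(["category", "n_patients", "gene"],
                            ascending=[True, False, True]))
    summary.to_csv(OUT, sep="\t", index=False)
    for category, sub in summary.groupby("category"):
        top = ", ".join(f"{r.gene} ({r.n_patients}p)"
                        for r in sub.head(5).itertuples())
        print(f"{category}: {len(sub)} genes; most recurrent: {top}")
    ctc_hits = hits[hits["sample_roles"].fillna("").str.contains("CTC")]
    print(f"{ctc_hits['gene'].nunique()} screened genes carried by CTCs "
          f"across {ctc_hits['patient'].nunique()} patients")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
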