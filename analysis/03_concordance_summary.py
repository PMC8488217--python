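"""Summarize PM/PG/CTC concordance across the cohort.

Aggregates the per-patient report into the cohort-level claims the
pipeline is designed to test: shared-mutation proportions split by
progressive-lesion type, TMB trajectories, and the pooled triple-overlap
fractions.  Writes results/concordance_summary.tsv.
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
REPORT = ROOT / "results" / "report"
OUT = ROOT / "results" / "concordance_summary.tsv"


def main() -> None:
    mirror_path = REPORT / "report.json"
    if not mirror_path.exists():
        raise SystemExit("report not found - run analysis/02_run_pipeline.py first")
    mirror = json.loads(mirror_path.read_text())
    shared = pd.read_csv(REPORT / "shared_proportions.tsv", sep="\t")
    tmb = pd.read_csv(REPORT / "tmb.tsv", sep="\t")

    # lesion type is encoded in the patient prefix of the simulated cohort:
    # L* lymph-node progressive biopsy, T* lung/hydrothorax lesion
    shared["group"] = shared["patient"].str[0].map(
        {"L": "lymph", "T": "tumor_like"})
    ctc_pg = shared[shared["comparison"] == "ctc_pg_of_pg"].dropna(
        subset=["value"])
    rows = []
    for group, sub in ctc_pg.groupby("group"):
        rows.append({"quantity": f"mean_shared_ctc_pg_of_pg_{group}",
                     "value": round(sub["value"].mean(), 4),
                     "n": len(sub)})
        print(f"CTC-PG sharing ({group}): mean "
              f"{100 * sub['value'].mean():.1f}% over {len(sub)} patients "
              f"(range {100 * sub['value'].min():.1f}-"
              f"{100 * sub['value'].max():.1f}%)")

    directions = tmb["direction"].value_counts()
    n_both = int(tmb["direction"].isin(
        ["increased", "decreased", "unchanged"]).sum())
    if n_both:
        frac_up = directions.get("increased", 0) / n_both
        rows.append({"quantity": "frac_patients_tmb_increased",
                     "value": round(frac_up, 4), "n": n_both})
        print(f"TMB increased in {directions.get('increased', 0)}/{n_both} "
              f"patients with paired PM/PG ({100 * frac_up:.1f}%)")

    cohort = mirror["cohort"]
    for key in ("frac_of_pm", "frac_of_pg"):
        rows.append({"quantity": f"pooled_triple_overlap_{key}",
                     "value": round(cohort[key], 6), "n": len(mirror["patients"])})
    print(f"pooled PM∩PG∩CTC overlap: {100 * cohort['frac_of_pm']:.2f}% of PM, "
          f"{100 * cohort['frac_of_pg']:.2f}% of PG mutations")

    pd.DataFrame(rows).to_csv(OUT, sep="\t", index=False)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
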