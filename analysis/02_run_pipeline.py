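"""Run the somatic + CTC filtering pipeline on the simulated cohort.

Reads the fixture written by 01_simulate_cohort.py through the same file
interfaces a user's data would take, executes tumor-vs-WBC somatic
calling, the five-step CTC cascade with rescue, TMB, Venn concordance and
screening, and writes the tabular report under results/report/.
"""

from pathlib import Path

from ctcconcord import RunConfig, run_cohort

ROOT = Path(__file__).resolve().parents[1]
FIXTURE = ROOT / "results" / "fixture"
OUT = ROOT / "results" / "report"


def main() -> None:
    if not FIXTURE.exists():
        raise SystemExit("fixture not found - run analysis/01_simulate_cohort.py first")
    config = RunConfig(
        variants=str(FIXTURE / "variants.tsv"),
        samples=str(FIXTURE / "samples.tsv"),
        readcounts=str(FIXTURE / "readcounts.tsv"),
        popdb=str(FIXTURE / "popdb.tsv"),
        blacklist=str(FIXTURE / "blacklist.bed"),
        hotspots=str(FIXTURE / "hotspots.tsv"),
        out_dir=str(OUT))
    report, files = run_cohort(config)
    print(f"processed {len(report.patients)} patients "
          f"({len(report.failures)} failures)")
    for p in report.patients:
        removed = {a.step: a.n_removed for a in p.audit}
        rescued = sum(1 for w in p.rescue_verdicts if w.decision == "rescued")
        print(f"  {p.patient_id}: |PM|={len(p.pm_set) if p.pm_set is not None else '-'} "
              f"|PG|={len(p.pg_set) if p.pg_set is not None else '-'} "
              f"|CTC final|={len(p.ctc_set)} "
              f"(popdb -{removed.get('population_db', 0)}, "
              f"blacklist -{removed.get('blacklist', 0)}, "
              f"wbc -{removed.get('wbc_controls', 0)}, "
              f"concordance -{removed.get('tumor_concordance', 0)}, "
              f"rescued +{rescued})")
    print(f"cohort pooled triple overlap: "
          f"{100 * report.cohort_frac_of_pm:.2f}% of PM, "
          f"{100 * report.cohort_frac_of_pg:.2f}% of PG mutations")
    print(f"wrote {len(files)} files to {OUT}")


if __name__ == "__main__":
    main()
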