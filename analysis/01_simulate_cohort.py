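"""Simulate the default study cohort and write it as pipeline input files.

Nine patients: six with lymph-node progressive biopsies (low configured
CTC-PG sharing, 5%), three with lung/hydrothorax progressive lesions
(high sharing, 30%); one patient per group has no primary sample.  The
fixture tree under results/fixture/ is exactly what the pipeline reads.
"""

from pathlib import Path

from ctcconcord import study_cohort, write_fixture

SEED = 20210722
OUT = Path(__file__).resolve().parents[1] / "results" / "fixture"


def main() -> None:
    cohort = study_cohort(SEED)
    files = write_fixture(cohort, OUT)
    n_calls = sum(len(s.calls) for b in cohort.bundles for s in b.samples)
    print(f"simulated {len(cohort.bundles)} patients "
          f"({n_calls} observed calls, {len(cohort.popdb)} popdb sites, "
          f"{len(cohort.blacklist)} blacklist intervals)")
    for b in cohort.bundles:
        truth = cohort.truth[b.patient_id]
        roles = ",".join(sorted({s.role for s in b.samples}))
        pm = "-" if truth.pm is None else len(truth.pm)
        print(f"  {b.patient_id}: PM={pm} PG={len(truth.pg)} "
              f"CTC={len(truth.ctc)} roles=[{roles}]")
    print(f"wrote {len(files)} files to {OUT}")


if __name__ == "__main__":
    main()
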