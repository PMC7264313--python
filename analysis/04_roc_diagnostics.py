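#!/usr/bin/env python
"""ROC analysis of the screening ratio on the simulated cohort.

Builds the empirical ROC of the MVC%pred:MP%pred ratio for the metabolic
pool against non-metabolic myalgia (the study's primary comparison) and
against healthy controls (the secondary one), selects the Youden-optimal
cutoff, and reports sensitivity, specificity, likelihood ratios and the
diagnostic odds ratio with 95% confidence intervals.
"""

import json
from pathlib import Path

from myoscreen import Group, METABOLIC_GROUPS, read_cohort
from myoscreen.cli import roc_report, _sig6

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = read_cohort(OUT / "cohort.csv").records
    positives = [g.value for g in METABOLIC_GROUPS]

    for ref, name in [
        (Group.NON_METABOLIC_MYALGIA.value, "roc_report.json"),
        (Group.CONTROL.value, "roc_control_report.json"),
    ]:
        report = roc_report(records, positives, ref)
        (OUT / name).write_text(json.dumps(_sig6(report), indent=2) + "\n")
        print(f"metabolic pool vs {ref}:")
        print(f"  AUC {report['auc']:.3f} (95% CI {report['auc_ci'][0]:.3f}-"
              f"{report['auc_ci'][1]:.3f})")
        print(f"  Youden cutoff {report['cutoff']:.3f}: se {report['se']:.3f}, "
              f"sp {report['sp']:.3f}, J {report['youden_j']:.3f}")
        print(f"  LR+ {report['lr_pos']['value']:.1f}, "
              f"LR- {report['lr_neg']['value']:.2f}, "
              f"DOR {report['dor']['value']:.1f}")
    print(f"wrote reports under {OUT}")


if __name__ == "__main__":
    main()
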