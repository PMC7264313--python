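#!/usr/bin/env python
"""Bayesian screening worked example from the published 2x2 counts.

Recovers the integer confusion matrix behind the published sensitivity
69.6% and specificity 96.7% (23 metabolic vs 60 myalgia subjects at the
1.30 cutoff), computes LR+, LR- and the DOR with confidence intervals, and
updates the 15% pretest probability of metabolic myopathy to the posttest
probability after a positive and a negative screen.
"""

import json
from pathlib import Path

from myoscreen import (
    confusion_from_rates, likelihood_ratios, diagnostic_odds_ratio, posttest,
)
from myoscreen.cli import _sig6

OUT = Path(__file__).resolve().parent.parent / "results"


def main(pretest: float = 0.15) -> None:
    cm = confusion_from_rates(0.696, 0.967, 23, 60)
    lr_pos, lr_neg = likelihood_ratios(cm)
    dor = diagnostic_odds_ratio(cm)
    pos = posttest(pretest, lr_pos.value)
    neg = posttest(pretest, lr_neg.value)

    print(f"counts at cutoff 1.30: tp={cm.tp} fn={cm.fn} fp={cm.fp} tn={cm.tn}")
    print(f"LR+ {lr_pos.value:.1f} (95% CI {lr_pos.ci[0]:.1f}-{lr_pos.ci[1]:.1f})")
    print(f"LR- {lr_neg.value:.2f} (95% CI {lr_neg.ci[0]:.2f}-{lr_neg.ci[1]:.2f})")
    print(f"DOR {dor.value:.1f} (95% CI {dor.ci[0]:.1f}-{dor.ci[1]:.1f})")
    print(f"pretest probability {pretest:.0%} -> odds {pos.pretest_odds:.2f}")
    print(f"positive screen: posttest probability {pos.posttest_prob:.1%}")
    print(f"negative screen: posttest probability {neg.posttest_prob:.1%}")

    payload = {
        "counts": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
        "lr_pos": lr_pos.value, "lr_pos_ci": list(lr_pos.ci),
        "lr_neg": lr_neg.value, "lr_neg_ci": list(lr_neg.ci),
        "dor": dor.value, "dor_ci": list(dor.ci),
        "pretest_prob": pretest,
        "posttest_prob_positive": pos.posttest_prob,
        "posttest_prob_negative": neg.posttest_prob,
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "screening_worked_example.json").write_text(
        json.dumps(_sig6(payload), indent=2) + "\n"
    )
    print(f"wrote {OUT / 'screening_worked_example.json'}")


if __name__ == "__main__":
    main()
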