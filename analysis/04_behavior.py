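"""Analyze the simulated operant learner.

Applies the learning criterion (sigmoid fit, asymptote lower-CI threshold,
geometric run-length rule) and the probe-generalization analysis to the
simulated 2AFC trial log, writing daily summaries and the learning
assessment JSON under results/simulated/.
"""

import json
from pathlib import Path

from songphen.io import RunConfig
from songphen.pipeline import cmd_behave

OUT = Path("results/simulated")
SEED = 1


def main() -> None:
    cfg = RunConfig(seed=SEED)
    payload = cmd_behave(cfg, OUT / "behavior_trials.csv", OUT)
    learn = payload["learning"]
    probe = payload["probe"]
    print(f"fitted asymptote: {learn['upper_asymptote']:.1f}% "
          f"(threshold {learn['threshold']:.1f}%)")
    print(f"required run: {learn['required_run']} days; "
          f"learning day: {learn['learning_day']}")
    print(f"probe accuracy: {probe['probe_pct_correct']:.1f}% "
          f"(generalized: {probe['generalized']})")


if __name__ == "__main__":
    main()
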