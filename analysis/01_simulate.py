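"""Generate the synthetic study: motif WAVs, ground truth, behavior log.

Eight synthetic birds, 16 training + 4 probe renditions per context at
22.05 kHz, with the default context effects (courtship F0 +5%,
non-courtship spectral widening 0.3 and pulse asymmetry 0.4), plus one
simulated 2AFC learner (30 days x 500 trials, 50 -> 85% accuracy).

Writes results/simulated/ (WAVs, ground_truth.tsv, behavior_trials.csv).
"""

from pathlib import Path

from songphen.io import RunConfig
from songphen.pipeline import cmd_simulate
from songphen.synthgen import BehaviorConfig, SynthConfig

OUT = Path("results/simulated")
SEED = 1


def main() -> None:
    cfg = RunConfig(seed=SEED)
    cfg.synth = SynthConfig(
        n_birds=8, renditions_per_context=16, probe_renditions_per_context=4,
        rate_hz=22050.0, seed=SEED,
    )
    cfg.behavior = BehaviorConfig(
        days=30, trials_per_day=500, p_start=0.5, p_asymptote=0.85,
        inflection_day=10.0, slope=1.0, seed=SEED,
    )
    manifest = cmd_simulate(cfg, OUT)
    print(f"wrote {manifest['n_motifs']} motifs and {manifest['n_trials']} trials to {OUT}")


if __name__ == "__main__":
    main()
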