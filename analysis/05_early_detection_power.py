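#!/usr/bin/env python
"""Early-detection power: dynamics metrics vs volume at 12 h.

Repeats a two-group experiment (control vs treated, 4 replicates each)
in which the groups share one size distribution but the treated group's
shell dynamic fraction has dropped by 12 h. Each run pushes all eight
spheroids through the full pipeline and records the one-way ANOVA
p-values for mean LIV and for volume.

Finding: the mean-LIV ANOVA rejects in essentially every run while the
volume ANOVA rejects at its nominal false-positive level — intracellular-
dynamics contrast detects the treatment long before morphology can.
"""

from pathlib import Path

from spheroid_doct.config import PipelineConfig
from spheroid_doct.pipeline import early_detection_experiment

OUT = Path(__file__).resolve().parents[1] / "results" / "power"
SEED = 31
N_RUNS = 100


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(seed=SEED)
    df = early_detection_experiment(N_RUNS, cfg)
    df.to_csv(OUT / "power_runs.csv", index=False)
    liv_rate = (df["p_mean_liv"] < 0.05).mean()
    vol_rate = (df["p_volume"] < 0.05).mean()
    print(f"runs                   : {N_RUNS}")
    print(f"mean-LIV ANOVA power   : {liv_rate:.0%} of runs reject at alpha=0.05")
    print(f"volume ANOVA rejects   : {vol_rate:.0%} (groups share one size distribution)")


if __name__ == "__main__":
    main()
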