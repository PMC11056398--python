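"""Full pipeline on a synthetic cohort: simulate -> extract -> fit -> evaluate.

Simulates a 40-case phantom cohort with a noiseless BMD link, extracts the
45 texture features per (case, vertebral level), fits the linear and ANN
regressors against the lumbar reference and prints the pooled and
per-level Pearson correlations between predicted and reference BMD.
"""

import tempfile
from pathlib import Path

from bonetex import PipelineConfig, SyntheticCohortSpec, run_all, run_simulate

with tempfile.TemporaryDirectory() as tmp:
    cohort_csv = run_simulate(
        Path(tmp) / "cohort", cohort_spec=SyntheticCohortSpec(n_cases=40, seed=7)
    )
    config = PipelineConfig(targets=("lumbar_total", "lumbar_total_excl_L1"))
    feature_csv, report = run_all(cohort_csv, Path(tmp) / "out", config)
    frame = report.to_frame()
    print(frame[["target", "model", "stratum", "n", "pearson_r"]]
          .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# With a noiseless density->BMD link the texture features predict the
# reference almost perfectly (r ~ 0.99); real cohorts add biological and
# measurement noise, which lowers r toward the moderate correlations seen
# in clinical opportunistic-screening studies.
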