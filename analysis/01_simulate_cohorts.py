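"""Generate the synthetic experiments every later stage runs on.

Produces two cohorts emulating the masked-orientation paradigm:

* ``results/cohort_exp1.csv`` — 20 observers, 550 trials each (5 SOAs x 110),
  visibility reports generated by the weighted-evidence-and-visibility (WEV)
  model with per-observer parameters drawn from documented ranges;
* ``results/cohort_exp2_joint.csv`` — 12 observers at the dual-report scale
  (5 SOAs x 81), with visibility and confidence reported on every trial; the
  two judgments share each trial's identification evidence but weight the
  identity-irrelevant strength evidence differently (w_vis > w_conf).

Writes per-observer generating parameters alongside, so later stages can
score recovery against the truth.
"""

import pathlib

import pandas as pd

from visconf.data_model import EXP2_DESIGN
from visconf.io import params_to_json, write_manifest, write_trials
from visconf.models import ModelSpec
from visconf.synthetic import CohortConfig, generate_cohort, generate_joint, sample_parameters

import numpy as np

SEED = 20240601
N_EXP1 = 20
N_JOINT = 12
W_VIS, W_CONF = 0.50, 0.42  # visibility weights strength evidence more

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main():
    config = CohortConfig(preset="exp1", n_participants=N_EXP1, spec=ModelSpec("wev"), seed=SEED)
    trials, truth = generate_cohort(config)
    write_trials(trials, RESULTS / "cohort_exp1.csv")
    pd.DataFrame(
        [{"participant": pid, "params_json": params_to_json(p)} for pid, p in truth.items()]
    ).to_csv(RESULTS / "cohort_exp1_truth.csv", index=False)
    print(f"exp1 cohort: {N_EXP1} observers x {len(trials) // N_EXP1} trials "
          f"-> {RESULTS / 'cohort_exp1.csv'}")

    root = np.random.SeedSequence([SEED, 2])
    frames = []
    for i, child in enumerate(root.spawn(N_JOINT)):
        rng = np.random.default_rng(child)
        params = sample_parameters("wev", rng, EXP2_DESIGN)
        joint = generate_joint(
            params, w_vis=W_VIS, w_conf=W_CONF, design=EXP2_DESIGN, noise_mode="shared", seed=rng
        )
        joint.insert(0, "participant", f"j{i + 1:03d}")
        frames.append(joint)
    joint_trials = pd.concat(frames, ignore_index=True)
    joint_trials.to_csv(RESULTS / "cohort_exp2_joint.csv", index=False, float_format="%.10g")
    print(f"joint cohort: {N_JOINT} observers x {len(joint_trials) // N_JOINT} trials "
          f"(w_vis={W_VIS}, w_conf={W_CONF}, shared report noise) "
          f"-> {RESULTS / 'cohort_exp2_joint.csv'}")
    write_manifest(RESULTS / "cohorts.manifest.json",
                   dict(stage="01_simulate", n_exp1=N_EXP1, n_joint=N_JOINT,
                        w_vis=W_VIS, w_conf=W_CONF), SEED)


if __name__ == "__main__":
    main()
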