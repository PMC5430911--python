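"""Build the parametric GLM and recover an interaction effect from ROI BOLD.

Assembles the two-condition design matrix (8 categorical + 8 parametric
regressors, modulators serially orthogonalized as evidence -> prior ->
interaction), simulates an ROI whose activity loads only on the
prior-by-evidence interaction column, and recovers it with the GLM contrast.
"""

import numpy as np
import pandas as pd

from intentprior.glm import build_design_matrix, fit_glm
from intentprior.observer import ObserverConfig, prior_trace
from intentprior.synthetic import BoldSimConfig, simulate_bold
from intentprior.task_design import TaskConfig, assemble_session, generate_run

runs = [
    generate_run(TaskConfig(task_type="basic", seed=1)),
    generate_run(TaskConfig(task_type="superordinate", seed=2)),
]
events = assemble_session(runs)

mods = []
for d in runs:
    trials = d.task_trials()
    seq = [t.intention for t in trials]
    trace = prior_trace(seq, ObserverConfig(alpha=1.5), labels=d.config.intentions)
    mods.append(pd.DataFrame({
        "trial_index": [t.index for t in trials],
        "evidence": [t.evidence_level for t in trials],
        "prior": trace.prob_of(seq),
        "condition": d.config.task_type,
    }))

n_vol = int(np.ceil(sum(d.total_duration_s for d in runs) / 2.5)) + 4
dm = build_design_matrix(events, pd.concat(mods, ignore_index=True),
                         tr=2.5, n_volumes=n_vol)
n_cat = sum("_x_" not in c for c in dm.task_columns)
print(f"design matrix: {dm.frame.shape[0]} volumes x {dm.frame.shape[1]} columns")
print(f"task regressors: {len(dm.task_columns)} "
      f"({n_cat} categorical + {len(dm.task_columns) - n_cat} parametric)")
e = dm.frame["infer_basic_x_evidence"]
p = dm.frame["infer_basic_x_prior"]
print(f"|evidence . prior| after orthogonalization: {abs(e @ p):.2e}")

target = "infer_basic_x_evidence_x_prior"
sig_sd = float(dm.frame[target].std())
y = simulate_bold(dm, {target: 1.0},
                  BoldSimConfig(n_volumes=n_vol + 5, noise_sd=sig_sd), seed=9)
fit = fit_glm(y, dm, contrasts=[dm.contrast_vector({target: 1.0})])
print(f"interaction beta = {fit.betas[target]:.2f} (true 1.0), "
      f"t({fit.df}) = {fit.t_stats[0]:.2f}")
print("-> shared variance between evidence and prior is credited to evidence")
print("   by the fixed orthogonalization order, so the interaction column")
print("   carries only its unique signal.")
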