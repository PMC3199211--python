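"""Learn CRF weights by maximum likelihood with SPA gradients.

Node features are the per-pixel model's likelihood costs, edge features
the L* contrast across neighboring pixels.  The partition-function term
of the gradient is approximated by the single MAP labeling (saddle-point
approximation); the best-scoring iterate is kept because SPA updates can
oscillate, and edge weights are clipped to stay positive.
"""

import warnings

import numpy as np

from dermcrf import (
    DatasetRanges,
    LabelSet,
    PipelineConfig,
    build_grid,
    crf_features_from_pp,
    fit_pp_model,
    generate_dataset,
)
from dermcrf.evaluation import compute_stack
from dermcrf.training import CrfInstance, train_weights

warnings.filterwarnings("ignore", category=RuntimeWarning)

data = generate_dataset(10, DatasetRanges(height=32, width=32), seed=5)
cfg = PipelineConfig()
pairs = [compute_stack(img, cfg) for img, _ in data]
truths = [m for _, m in data]
model = fit_pp_model([p[0] for p in pairs], truths, LabelSet((0, 1)))

instances = []
for (stack, lab), truth in zip(pairs, truths):
    g = build_grid(32, 32)
    feats = crf_features_from_pp(model.likelihood_map(stack), lab, g)
    instances.append(CrfInstance(feats, truth, g))

trace = train_weights(instances, cfg.training_config())
print(f"ran {trace.n_iterations} iterations (cap {cfg.n_itr}), converged={trace.converged}")
print(f"best weights w = {np.round(trace.best_w.w, 4)} at iteration {trace.best_index}")
print(f"edge weight stayed positive throughout: {min(w.w[1] for w in trace.weights):.2e}")
print("w[0] weights the per-pixel likelihood cost, w[1] the boundary contrast cost")
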