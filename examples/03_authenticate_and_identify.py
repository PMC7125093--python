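"""Two-layer biometric evaluation: intruder detection, then identification.

Half the subjects are enrolled (non-intruders); a one-class SVM trained on
their session-1 feature vectors must accept their session-2 vectors (TAR)
and reject the never-seen subjects (TRR).  A multi-class linear SVM scores
identification accuracy by 10-fold cross-validation.
"""

import numpy as np

from eegselect import (
    EvaluationConfig,
    apply_car,
    compute_feature_cache,
    crossval_identification,
    evaluate_authentication,
    make_benchmark_instance,
    train_one_class,
)

epochset, split, informative = make_benchmark_instance("easy", seed=1)
epochset = apply_car(epochset)
cache = compute_feature_cache(epochset)
print(f"enrolled subjects:  {sorted(split.non_intruders)}")
print(f"intruders:          {sorted(split.intruders)}")

# restrict to the channels that actually carry subject signatures
mask = sorted(informative)[:4]
x_train = np.vstack([cache.instance_matrix(s, "1", mask)
                     for s in sorted(split.non_intruders)])
y_train = np.concatenate([[s] * cache.blocks[(s, "1")].shape[0]
                          for s in sorted(split.non_intruders)])
genuine = np.vstack([cache.instance_matrix(s, "2", mask)
                     for s in sorted(split.non_intruders)])
intruder = np.vstack([cache.instance_matrix(s, "2", mask)
                      for s in sorted(split.intruders)])

model = train_one_class(x_train, nu=0.01, gamma=0.1)
auth = evaluate_authentication(model, genuine, intruder)
accuracy, std = crossval_identification(x_train, y_train, k=10, seed=0)

print(f"\nchannels used:      {len(mask)} of {epochset.n_channels}")
print(f"TAR (genuine kept): {auth.tar:.2f}  "
      f"({auth.n_genuine_accepted}/{auth.n_genuine} session-2 epochs)")
print(f"TRR (intruders out):{auth.trr:.2f}  "
      f"({auth.n_intruder - auth.n_intruder_accepted}/{auth.n_intruder})")
print(f"FAR:                {auth.far:.2f}  (= 1 - TRR)")
print(f"identification:     {accuracy:.2f} +/- {std:.2f} (10-fold CV)")

# High TAR and TRR together mean the enrolled subjects pass while unknown
# subjects are stopped; the identification accuracy says how reliably an
# accepted epoch is attributed to the right enrolled subject.
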