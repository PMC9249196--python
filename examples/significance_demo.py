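"""Does the directional-filter initialisation help?  The subset procedure.

Trains the same architecture twice - once with the directional first layer,
once with random initialisation everywhere - then splits one test set into
density-preserving subsets, scores each subset under both models, and runs a
one-sided Welch test on the subset accuracies.
"""

import numpy as np

from cvmstage import (CNNDF, ModelConfig, TrainConfig, crop_and_resize,
                      density_preserving_subsets, generate_dataset,
                      merge_six_to_five, subset_significance, train_cnndf)


def prep(samples):
    x = np.stack([crop_and_resize(s.pixels, s.true_box) for s in samples])
    y = merge_six_to_five(np.array([s.label for s in samples]))
    return x.astype(np.float32), y


xtr, ytr = prep(generate_dataset(30, seed=5))    # 180 training images
xte, yte = prep(generate_dataset(20, seed=6))    # 120 test images

accs = {}
for name, random_init in [("with directional filters", False),
                          ("without (random init)", True)]:
    model = CNNDF(ModelConfig(num_classes=5, seed=2, random_init=random_init))
    train_cnndf(model, xtr, ytr, TrainConfig(epochs=15, seed=2))
    preds = model.predict(xte)
    subset_accs = []
    for idx in density_preserving_subsets(yte, n_subsets=7, subset_size=30,
                                          seed=3):
        subset_accs.append(float((preds[idx] == yte[idx]).mean()))
    accs[name] = subset_accs
    print(f"{name}: subset accuracies {np.round(subset_accs, 2)}")

res = subset_significance(accs["without (random init)"],
                          accs["with directional filters"])
print(f"\nmean without {res.mean_without:.3f} (sd {res.std_without:.3f}) vs "
      f"mean with {res.mean_with:.3f} (sd {res.std_with:.3f})")
print(f"one-sided Welch p-value: {res.p_value:.4f}")
# a small p-value supports the claim that the directional initialisation
# improves accuracy; at this demo scale both models sit near the ceiling on
# the synthetic task, so the measured difference (and its significance) is
# modest - the procedure, not the effect size, is the point here.
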