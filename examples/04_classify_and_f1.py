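"""Train the dilated-CNN diffusion classifier and score it with the
class-frequency-weighted F1.

Two grossly different processes (Brownian motion vs a nearly frozen CTRW)
are separable almost perfectly; the interesting regime is the full
six-class benchmark, which scripts/acceptance.py evaluates at scale.
"""

from lptraj.classifier import (ClassifierConfig, classify, extract_features,
                               train_classifier, weighted_f1)
from lptraj.simulate import make_labeled_dataset

train = make_labeled_dataset(("BM", "CTRW"), n_per_class=150, T=200, seed=5,
                             alpha_ranges={"CTRW": (0.2, 0.2)})
clf, history = train_classifier(train, ClassifierConfig(epochs=8, seed=3))

held_out = make_labeled_dataset(("BM", "CTRW"), n_per_class=100, T=200,
                                seed=6, alpha_ranges={"CTRW": (0.2, 0.2)})
probs, labels = classify(clf, held_out)
report = weighted_f1(labels, held_out.labels)
print("held-out weighted F1: %.3f" % report.weighted_f1)
for cls in report.classes:
    print("  %s: precision %.3f, recall %.3f, F1 %.3f (n=%d)"
          % (cls, report.precision[cls], report.recall[cls],
             report.f1[cls], report.counts[cls]))

features = extract_features(clf, held_out)
print("penultimate-layer features:", features.shape,
      "(these 128-d vectors feed the Fréchet-distance comparison)")
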