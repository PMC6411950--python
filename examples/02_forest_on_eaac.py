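"""Train the 1000-tree forest on EAAC features and evaluate it.

EAAC counts residue frequencies in an 8-residue window slid across the
31-mer (480 features). The printed report shows the held-out ROC area, the
partial area below 10% FPR (max 0.1), and the threshold metrics at the
specificity-90% operating point.
"""

import numpy as np

from kmalpred.dataset import build_windows, split_by_protein
from kmalpred.encodings import eaac_matrix
from kmalpred.evaluation import evaluate
from kmalpred.models import train_forest
from kmalpred.synthetic import SyntheticConfig, generate_proteome

truth = generate_proteome(SyntheticConfig(n_proteins=400, seed=7))
windows, _ = build_windows(truth.proteins, truth.sites)
split = split_by_protein(windows, 0.8, seed=1)

X_train, names = eaac_matrix(split.train)
y_train = np.array([w.label for w in split.train])
model = train_forest(X_train, y_train, names, n_trees=1000, seed=0)

X_test, _ = eaac_matrix(split.test)
y_test = np.array([w.label for w in split.test])
report = evaluate(model.predict_scores(X_test), y_test, target_sp=0.90)

for key, value in report.summary().items():
    print(f"{key:10s} {value:.4f}" if isinstance(value, float) else f"{key:10s} {value}")
# AUC near 0.9 on the strong-effect fixture means the forest recovered the
# planted composition motif from held-out proteins; AUC01 close to its 0.1
# ceiling is what matters for low-false-positive prediction in practice.
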