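"""Train the variational quantum circuit on a scaled-down synthetic study.

A ~300-subject strong-signal cohort is split 80/20, reduced to 6 principal
components, and a 6-qubit, 3-block VQC is trained for both tasks: age
regression (sigmoid output decoded to the training age range) and sex
classification (threshold at 0.5).  MAE is in years; R^2 and accuracy are
dimensionless.
"""

from brainvqc import (
    classification_metrics,
    default_effects,
    fit_preprocess,
    generate_cohort,
    regression_metrics,
    split,
    VQCClassifier,
    VQCConfig,
    VQCRegressor,
)
from brainvqc.cohort import scaled_demographics

table = generate_cohort(scaled_demographics(300), default_effects(noise_scale=0.25), seed=11)
sp = split(table, seed=12)
indexed = table.set_index("subject_id", drop=False)
train, test = indexed.loc[list(sp.train_ids)], indexed.loc[list(sp.test_ids)]

pre = fit_preprocess(train, k=6)
X_train, X_test = pre.transform(train), pre.transform(test)

reg = VQCRegressor(VQCConfig(n_qubits=6, n_blocks=3, task="regression", seed=5, epochs=100))
reg.fit(X_train, train["age"].to_numpy())
m = regression_metrics(test["age"].to_numpy(), reg.predict(X_test))
print(f"age regression:  test MAE {m.mae:.2f} years, RMSE {m.rmse:.2f}, R^2 {m.r2:.3f} "
      f"({len(reg.history_)} epochs)")

clf = VQCClassifier(VQCConfig(n_qubits=6, n_blocks=3, task="classification", seed=5, epochs=100))
clf.fit(X_train, train["sex"].to_numpy())
c = classification_metrics(test["sex"].to_numpy(), clf.predict(X_test))
print(f"sex classification: test accuracy {c.accuracy:.3f}, precision {c.precision:.3f}, "
      f"recall {c.recall:.3f}, F1 {c.f1:.3f}")
print("predictions stay inside the training age range by construction: "
      f"[{reg.codec_.age_min:.1f}, {reg.codec_.age_max:.1f}] years")
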