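"""Learning-curve comparison of the classical baselines on the full cohort.

Every model is trained with its published hyperparameters on growing
training-set sizes and scored against one fixed 231-subject test partition —
the experiment behind the training-size sweep.  (The quantum model can be
added via models=(..., 'VQC') with a scaled-down VQCConfig.)
"""

import warnings

from brainvqc import generate_cohort, run_learning_curve

warnings.filterwarnings("ignore")

table = generate_cohort(seed=7)
result = run_learning_curve(
    table,
    sizes=(0.05, 0.20, 0.80),          # training sizes 57, 231, 925
    models=("LR", "RF", "SVR"),
    task="regression",
    seed=3,
    k=17,
)

test = result[result["partition"] == "test"]
print(test.pivot_table(index="train_size", columns="model", values="mae").round(2))
print("\ntest MAE (years) vs training size: more data helps every model;")
print("the fixed test partition makes the columns directly comparable.")
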