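"""Min-max scaling, PCA reduction and the 80/20 split arithmetic.

Preprocessing is fitted on the training partition only: each of the 34
volumes is scaled to [0, 1] and the scaled matrix reduced to k = 17
principal components — one per qubit of the quantum model.  The floor-based
split of 1157 subjects reproduces the 925-train / 231-test partition, and
the learning-curve fractions give the sweep sizes {57, ..., 925}.
"""

from brainvqc import fit_preprocess, generate_cohort, split, subsample_train

table = generate_cohort(seed=7)
sp = split(table, seed=3)
print(f"split: {len(sp.train_ids)} train / {len(sp.test_ids)} test "
      f"(1 remainder subject dropped by the floor rule)")

sizes = [len(subsample_train(sp, f, seed=4)) for f in (0.05, 0.10, 0.20, 0.40, 0.60, 0.80)]
print("learning-curve training sizes:", sizes)

train = table.set_index("subject_id", drop=False).loc[list(sp.train_ids)]
model = fit_preprocess(train, k=17)
share = model.explained_variance / model.explained_variance.sum()
print(f"PCA: {model.k} components; first three explain "
      f"{share[0]:.1%}, {share[1]:.1%}, {share[2]:.1%} of the retained variance")

scores = model.transform(train)
print(f"component scores: shape {scores.shape}, "
      f"range [{scores.min():.2f}, {scores.max():.2f}]")
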