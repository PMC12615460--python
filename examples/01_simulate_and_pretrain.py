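"""Generate synthetic behavior segments and pretrain the sequence autoencoder.

Builds the default synthetic dataset (4 behavior classes, 8 keypoints in
2-D, 800 train / 200 test segments), z-scores it, and trains the
bidirectional-GRU encoder-decoder on the reconstruction task alone — no
labels involved.  The falling loss curve shows the latent space organizing
itself around the segments' movement dynamics.
"""

import ethoclust as ec

config = ec.SynthConfig(seed=0)
train, test = ec.generate(config)
print(f"dataset: {len(train)} train / {len(test)} test segments, "
      f"{train.n_features} features, classes {train.class_names}")

train_p, stats = ec.preprocess(train)

model_cfg = ec.ModelConfig(input_dim=train.n_features, epochs=50, seed=0)
model = ec.pretrain(train_p, model_cfg, stats=stats)

h = model.history["reconstruction"]
print(f"reconstruction loss over {len(h)} epochs: "
      f"{h[0]:.3f} -> {h[9]:.3f} -> {h[-1]:.3f}")
print("a z-scored segment has unit variance, so a loss of "
      f"{h[-1]:.2f} means the decoder reproduces ~{100 * (1 - h[-1]):.0f}% "
      "of the per-frame variance from the latent vector alone")

latents = model.encode(train_p)
print(f"latent matrix: {latents.values.shape[0]} segments x "
      f"{latents.values.shape[1]} dimensions")
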