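"""Train the depthwise-separable residual 3D classifier.

Three residual blocks (each halving the spatial sides) of paired
depthwise-separable convolutions with PReLU, then a linear head; Adam at
learning rate 3e-4 for five epochs. Depthwise separation keeps the
parameter count at C(K^3+O) per convolution instead of C*O*K^3.
"""

import bayeshead as bh

cfg = bh.SynthConfig(n_subjects=60, shape=(16, 16, 16), effect_size=0.5,
                     noise_sd=0.02, ambiguous_fraction=0.0, seed=2)
ds = bh.split_dataset(bh.generate_dataset(cfg), 0.8, seed=2)

spec = bh.NetworkSpec(input_shape=cfg.shape, block_channels=(4, 8, 16))
net = bh.build_network(spec, seed=2)
print(f"trainable parameters: {net.n_params()}")
print(f"separable conv (C=16, K=3, O=16): {bh.count_separable_params(16, 3, 16)} weights "
      f"vs {16 * 16 * 27} for a full convolution")

net = bh.train(net, ds, bh.TrainConfig(seed=2))
for entry in net.training_log:
    print(f"epoch {entry['epoch']}: loss {entry['loss']:.3f}, accuracy {entry['accuracy']:.2f}")

test = ds.partition("test")
acc = (net.forward(test.stack()).argmax(axis=1) == test.labels).mean()
print(f"held-out accuracy: {acc:.2f}")
# Loss should fall monotonically and held-out accuracy approach 1.0 on this
# strongly separable, unambiguous cohort.
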