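# Reference VGG-style architecture: 19 weight-bearing layers
# (16 convolutional + 3 dense).  Shipped for architecture parity only;
# pretrained weights are out of scope and this file is never required by
# the desk-scale pipeline.
input_channels: 1
weight_seed: 0
padding: zero
# Gram statistics from the first conv of each block (conv1_1 .. conv5_1),
# the usual texture-synthesis choice.
gram_layers: [0, 3, 6, 11, 16]
layers:
  - {kind: conv, out_channels: 64, kernel: 3}    # conv1_1
  - {kind: conv, out_channels: 64, kernel: 3}    # conv1_2
  - {kind: pool, pool_mode: max}
  - {kind: conv, out_channels: 128, kernel: 3}   # conv2_1
  - {kind: conv, out_channels: 128, kernel: 3}   # conv2_2
  - {kind: pool, pool_mode: max}
  - {kind: conv, out_channels: 256, kernel: 3}   # conv3_1
  - {kind: conv, out_channels: 256, kernel: 3}   # conv3_2
  - {kind: conv, out_channels: 256, kernel: 3}   # conv3_3
  - {kind: conv, out_channels: 256, kernel: 3}   # conv3_4
  - {kind: pool, pool_mode: max}
  - {kind: conv, out_channels: 512, kernel: 3}   # conv4_1
  - {kind: conv, out_channels: 512, kernel: 3}   # conv4_2
  - {kind: conv, out_channels: 512, kernel: 3}   # conv4_3
  - {kind: conv, out_channels: 512, kernel: 3}   # conv4_4
  - {kind: pool, pool_mode: max}
  - {kind: conv, out_channels: 512, kernel: 3}   # conv5_1
  - {kind: conv, out_channels: 512, kernel: 3}   # conv5_2
  - {kind: conv, out_channels: 512, kernel: 3}   # conv5_3
  - {kind: conv, out_channels: 512, kernel: 3}   # conv5_4
  - {kind: pool, pool_mode: max}
  - {kind: dense, out_channels: 4096}            # fc6
  - {kind: dense, out_channels: 4096}            # fc7
  - {kind: dense, out_channels: 1000, activation: none}  # fc8
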