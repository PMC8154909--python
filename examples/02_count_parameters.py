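"""Build the full-size residual network and count its parameters.

The network: two initial convolutions (64/32 maps, kernels 8/3), average
pooling, eight residual modules (64/32 maps, kernel 50, batch norm,
50% dropout), global average pooling, one output neuron.  It consumes the
8 linearly independent channels of a 12-lead ECG and accepts both 1.2-s
median beats and 10-s rhythm strips without rebuilding.
"""

import numpy as np

from ecglens import ArchitectureSpec, build_network, count_parameters

net = build_network(ArchitectureSpec.full())
print("total parameters (incl. batch-norm statistics):",
      count_parameters(net, include_nontrainable=True))
print("trainable parameters:",
      count_parameters(net, include_nontrainable=False))

out_median = net.forward(np.zeros((1, 8, 600), dtype=np.float32))
out_rhythm = net.forward(np.zeros((1, 8, 5000), dtype=np.float32))
print("one scalar per record, any length:",
      out_median.shape, out_rhythm.shape)
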