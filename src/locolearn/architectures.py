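"""The three reference architectures used throughout the package.

* ``mnist_mlp`` — 784 -> 1000 -> 1000 -> 1000 dense ReLU stack
  (2,784,000 weight words; 3,000 post-layer activations per sample).
* ``cifar_convnet_5`` — three 5x5 stride-1 conv layers (96, 128, 256
  maps) each followed by 3x3/stride-2 max pooling, then two 2048-unit
  dense layers (13,716,512 weight words; 40,960 activations per sample).
* ``cifar_convnet_10`` — C64-C64-MP-C128-C128-MP-C256-C256-MP-C512-C512-
  MP-C512-C512-MP with 3x3 kernels and 2x2/stride-2 pooling (9,402,048
  weight words; 156,160 activations per sample).

Convolutions are size-preserving ("same" padded); every pooling stage
halves the spatial size, so the 5-layer net flattens to 4096 entering the
first dense layer and the 10-layer net ends at 512 activations after the
final pool.
"""

from __future__ import annotations

from .net_core import ConvSpec, DenseSpec, NetworkSpec, PoolSpec

__all__ = ["mnist_mlp", "cifar_convnet_5", "cifar_convnet_10", "REFERENCE_NETS"]


def mnist_mlp(num_classes: int = 10, use_batchnorm: bool = False,
              dropout_rates=(0.0, 0.0, 0.0)) -> NetworkSpec:
    layers = []
    sizes = [784, 1000, 1000, 1000]
    for i in range(3):
        layers.append(DenseSpec(sizes[i], sizes[i + 1], use_batchnorm=use_batchnorm,
                                dropout_rate=dropout_rates[i]))
    return NetworkSpec(tuple(layers), num_classes=num_classes, input_shape=784)


def cifar_convnet_5(num_classes: int = 10, use_batchnorm: bool = True) -> NetworkSpec:
    pool = PoolSpec(window=3, stride=2, padding=1)
    layers = (
        ConvSpec(3, 96, kernel=(5, 5), pool=pool, use_batchnorm=use_batchnorm),
        ConvSpec(96, 128, kernel=(5, 5), pool=pool, use_batchnorm=use_batchnorm),
        ConvSpec(128, 256, kernel=(5, 5), pool=pool, use_batchnorm=use_batchnorm),
        DenseSpec(4096, 2048, use_batchnorm=use_batchnorm),
        DenseSpec(2048, 2048, use_batchnorm=use_batchnorm),
    )
    return NetworkSpec(layers, num_classes=num_classes, input_shape=(3, 32, 32))


def cifar_convnet_10(num_classes: int = 10, use_batchnorm: bool = True) -> NetworkSpec:
    pool = PoolSpec(window=2, stride=2, padding=0)
    chans = [3, 64, 64, 128, 128, 256, 256, 512, 512, 512, 512]
    layers = []
    for i in range(10):
        layers.append(
            ConvSpec(chans[i], chans[i + 1], kernel=(3, 3),
                     pool=pool if i % 2 == 1 else None,
                     use_batchnorm=use_batchnorm)
        )
    return NetworkSpec(tuple(layers), num_classes=num_classes, input_shape=(3, 32, 32))


REFERENCE_NETS = {
    "mnist_mlp": mnist_mlp,
    "cifar_convnet_5": cifar_convnet_5,
    "cifar_convnet_10": cifar_convnet_10,
}
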