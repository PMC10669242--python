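"""The canonical 18-layer residual network, used as the accounting reference.

Basic blocks at widths 64/128/256/512, batch normalisation, 1x1 projection
shortcuts, global average pooling and a linear classification head.  An
optional variant inserts one SAT module per basic block (applied to the
residual branch before the addition).
"""

from __future__ import annotations

import numpy as np

from . import nn
from .csat import SATModule

__all__ = ["BasicBlock", "ResNet18", "build_resnet18"]


class BasicBlock(nn.Module):
    def __init__(self, cin, cout, stride=1, with_sat=False):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(cout)
        self.relu = nn.ReLU()
        self.conv2 = nn.Conv2d(cout, cout, 3, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.shortcut = nn.Sequential(
                nn.Conv2d(cin, cout, 1, stride=stride, bias=False),
                nn.BatchNorm2d(cout))
        else:
            self.shortcut = nn.Identity()
        self.sat = SATModule() if with_sat else nn.Identity()

    def forward(self, x):
        y = self.bn2(self.conv2(self.relu(self.bn1(self.conv1(x)))))
        return (self.sat(y) + self.shortcut(x)).relu()


class ResNet18(nn.Module):
    def __init__(self, num_classes=1000, with_sat=False):
        super().__init__()
        self.conv1 = nn.Conv2d(3, 64, 7, stride=2, padding=3, bias=False)
        self.bn1 = nn.BatchNorm2d(64)
        self.relu = nn.ReLU()
        self.maxpool = nn.MaxPool2d(3, 2, padding=1)
        widths = [64, 128, 256, 512]
        layers = []
        cin = 64
        for i, w in enumerate(widths):
            stride = 1 if i == 0 else 2
            layers.append(BasicBlock(cin, w, stride, with_sat))
            layers.append(BasicBlock(w, w, 1, with_sat))
            cin = w
        self.layers = nn.Sequential(*layers)
        self.fc = nn.Linear(512, num_classes, bias=True)

    def forward(self, x):
        x = self.maxpool(self.relu(self.bn1(self.conv1(x))))
        x = self.layers(x)
        pooled = x.mean(axis=(2, 3))
        return self.fc(pooled).softmax(axis=-1)


def build_resnet18(num_classes=1000, with_sat=False, seed=0):
    model = ResNet18(num_classes, with_sat)
    model.init_parameters(np.random.default_rng(seed))
    return model
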