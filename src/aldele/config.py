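"""Model configuration: toolkit combinations, task heads and hyperparameters.

Toolkits
    1  whole-compound descriptor vector through a dense network
    2  r-radius subgraph molecular graph through a GNN
    3  n-gram word sequence through a CNN
    4  smoothed + logistic-scaled PSSM through a CNN
    5  wild-type-normalized structural energy terms, PCA-reduced

The named presets M1..M6 are the published toolkit combinations; the fixed
one-dimension modes (protein_only / compound_only) restrict which side's
features may be used at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

COMPOUND_TOOLKITS = {1, 2}
PROTEIN_TOOLKITS = {3, 4, 5}

PRESETS: dict[str, frozenset[int]] = {
    "M1": frozenset({2, 3}),
    "M2": frozenset({2, 4}),
    "M3": frozenset({2, 3, 4}),
    "M4": frozenset({1, 2, 3}),
    "M5": frozenset({1, 2, 3, 4}),
    "M6": frozenset({1, 2, 3, 4, 5}),
}


@dataclass
class ModelConfig:
    toolkits: frozenset = frozenset({2, 3})
    mode: str = "cpi"                     # cpi | protein_only | compound_only
    task: str = "regression"              # regression | classification
    num_classes: int = 4
    r: int = 2                            # subgraph radius
    n: int = 3                            # n-gram order
    w: int = 21                           # PSSM smoothing window
    dim: int = 10                         # embedding / hidden dimensionality
    layers_gnn: int = 3
    layers_cnn: int = 3
    layers_nn: int = 3
    cnn_kernel: int = 3
    k_descriptors: int = 10               # retained descriptors (toolkit 1)
    k_energy: int = 32                    # PCA components (toolkit 5)
    lambda_l2: float = 1e-6
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 1   # per-sample updates, as is conventional for this model family
    seed: int = 0

    def __post_init__(self):
        self.toolkits = frozenset(int(t) for t in self.toolkits)
        if not self.toolkits or not self.toolkits <= {1, 2, 3, 4, 5}:
            raise ValueError(f"toolkits must be a non-empty subset of 1..5, got {set(self.toolkits)}")
        if self.mode not in {"cpi", "protein_only", "compound_only"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.task not in {"regression", "classification"}:
            raise ValueError(f"unknown task {self.task!r}")
        if self.mode == "cpi":
            if not (self.toolkits & COMPOUND_TOOLKITS):
                raise ValueError("cpi mode requires at least one compound toolkit (1 or 2)")
            if not (self.toolkits & PROTEIN_TOOLKITS):
                raise ValueError("cpi mode requires at least one protein toolkit (3, 4 or 5)")
        elif self.mode == "protein_only":
            if self.toolkits & COMPOUND_TOOLKITS:
                raise ValueError("protein_only mode forbids compound toolkits 1-2")
        elif self.mode == "compound_only":
            if self.toolkits & PROTEIN_TOOLKITS:
                raise ValueError("compound_only mode forbids protein toolkits 3-5")
        if self.r < 0:
            raise ValueError("r must be non-negative")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.w < 1 or self.w % 2 == 0:
            raise ValueError("w must be an odd positive integer")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "ModelConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; expected one of {sorted(PRESETS)}")
        return cls(toolkits=PRESETS[name], **overrides)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["toolkits"] = sorted(self.toolkits)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["toolkits"] = frozenset(d["toolkits"])
        return cls(**d)
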