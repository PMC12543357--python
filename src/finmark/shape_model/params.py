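"""The nine tunable training parameters of the shape predictor."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Any, Mapping

__all__ = ["Hyperparameters", "DEFAULT_HYPERPARAMETERS"]


@dataclass(frozen=True)
class Hyperparameters:
    """Training knobs of the cascaded regression-tree predictor.

    cascade_depth
        Number of sequential refinement stages (boosting cascades).
    tree_depth
        Depth of each regression tree (2**depth leaves).
    trees_per_cascade
        Number of boosted trees fit within one cascade stage.
    learning_rate
        Per-leaf shrinkage ("nu"), in (0, 1].
    oversampling
        Randomly perturbed initial shapes generated per training image.
    feature_pool_size
        Candidate pixel locations sampled per cascade; split features are
        intensity differences between pairs drawn from this pool.
    test_splits
        Candidate (pair, threshold) splits evaluated at each tree node.
    feature_pool_padding
        Relative margin around the unit box within which feature pixels
        may be sampled.
    regularization
        Spatial proximity prior ("lambda"): candidate pixel pairs are
        accepted with probability exp(-distance / lambda), favouring
        nearby pairs.
    """

    cascade_depth: int = 10
    tree_depth: int = 4
    trees_per_cascade: int = 500
    learning_rate: float = 0.1
    oversampling: int = 20
    feature_pool_size: int = 400
    test_splits: int = 20
    feature_pool_padding: float = 0.0
    regularization: float = 0.1

    def __post_init__(self) -> None:
        if self.cascade_depth < 1:
            raise ValueError("cascade_depth must be >= 1")
        if self.tree_depth < 1:
            raise ValueError("tree_depth must be >= 1")
        if self.trees_per_cascade < 1:
            raise ValueError("trees_per_cascade must be >= 1")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in (0, 1]")
        if self.oversampling < 1:
            raise ValueError("oversampling must be >= 1")
        if self.feature_pool_size < 1:
            raise ValueError("feature_pool_size must be >= 1")
        if self.test_splits < 1:
            raise ValueError("test_splits must be >= 1")
        if self.feature_pool_padding < 0.0:
            raise ValueError("feature_pool_padding must be >= 0")
        if self.regularization < 0.0:
            raise ValueError("regularization must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Hyperparameters":
        return cls(**dict(d))


DEFAULT_HYPERPARAMETERS = Hyperparameters()
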